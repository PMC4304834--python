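# Methods

## Model

A 450K-style probe reports a beta value β ∈ [0, 1], the fraction of array
signal from the methylated allele. Under bisulfite-only (BS) conversion
both 5mC and 5hmC protect the cytosine, so E[β_BS] = 5mC + 5hmC at that
CpG; under oxidative bisulfite (oxBS) the 5hmC is oxidised away first, so
E[β_oxBS] = 5mC. The per-probe estimator of the 5hmC fraction is therefore

    Δβ = mean(β, BS replicates) − mean(β, oxBS replicates),

and a negative Δβ is chemically impossible signal: the oxidation only
removes apparent methylation. This asymmetry is what makes the design
self-calibrating — the negative tail of significant Δβ values measures the
method's own false-discovery rate (`empirical_fdr = n_neg_sig /
(n_called + n_neg_sig)`).

Assumptions: replicate noise is independent across arrays and exchangeable
within an arm; conversion chemistry is complete (switchable via the
generator's efficiency parameters); BS and oxBS aliquots come from the same
DNA so the only systematic between-arm difference at a probe is its 5hmC
content.

## Per-probe test

Each probe gets an unpaired two-sample t-test on replicate betas: pooled
variance, df = n_BS + n_oxBS − 2, two-sided p. The test is written out
explicitly (with `scipy.stats.t` supplying the tail) rather than called
through a convenience wrapper so that degenerate inputs follow documented
rules: when all replicate betas are identical in both arms and the means
agree, p := 1 and stat := 0; when the means differ with zero pooled
variance (possible under a noiseless simulation or saturated betas),
p := the smallest positive float, stat := ±∞, with a warning. A plain
t-test, not a moderated/shrinkage variant, is the default because it is
reproducible from first principles with 2–3 replicates per arm and has no
hidden hyperparameters; the arms are compared group-wise (unpaired) since
conversion replicates carry no natural pairing.

Benjamini–Hochberg adjustment (`adjust_bh`, delegating to statsmodels) is
applied per group over exactly the post-filter probe set, and the test
suite cross-checks it against a literal brute-force step-up
implementation.

## Calling regimes

* `threshold`: HMC iff Δβ ≥ 0.30 and nominal p < 0.05. The spec for this
  regime defines only the positive rule; the sign-mirrored rule
  (Δβ ≤ −0.30, p < 0.05) labels NEG_SIG so the empirical FDR remains
  defined. 0.30 is deliberately conservative: with two replicates per arm
  the multiplicity-adjusted p rarely clears BH, so the magnitude threshold
  carries the specificity.
* `fdr`: HMC iff q < 0.05 and Δβ > 0; NEG_SIG iff q < 0.05 and Δβ < 0.
  Appropriate once a third replicate (or lower-noise protocol) gives BH
  enough power; it then also recovers 5hmC levels in the 0–30% range.

NEG_SIG probes are written to the call table with their label but excluded
from all downstream 5hmC outputs (enrichment input is the HMC set only).
Δβ is never clipped: the negative values are the FDR estimate's raw
material.

## Filtering

Detection rule: a probe fails when its detection p exceeds 0.01 in ANY
sample of the analysis set — the stricter of the two common readings; an
all-samples rule is available (`detection_rule="all"`). Removal order is
fixed (detection first, then X/Y) so report counts are disjoint.
Sex-chromosome removal is a flag, default on, because mixed-sex sample
sets make X/Y betas uninterpretable. `CallConfig.filter_detection` makes
"detection filtering requested" explicit; requesting it without a
detection matrix is a hard error rather than a silent skip.

## Enrichment

The null model draws |call set| probes from the post-filter background
without replacement and counts probes per category. Only the category
counts of a draw matter, so each permutation is sampled directly from the
multivariate hypergeometric distribution — the exact law of those counts —
making B = 50,000 permutations on a full-array background effectively
free. Per category we report percent enrichment
100 · (observed − null mean) / null mean and add-one-corrected one-sided
p-values, (#{null ≥ obs} + 1)/(B + 1) for enrichment and its mirror for
depletion; the smaller, doubled and capped at 1, is the two-sided p.
B defaults to 1000.

Each probe carries exactly one gene-feature category, collapsed from
multi-transcript annotations by the precedence
TSS200 > TSS1500 > 5′UTR > 1st exon > body > 3′UTR, with intergenic as the
fallback; the precedence is a configurable argument of the collapser.
Promoter behaviour is reported through TSS200 and TSS1500 separately.
Tests verify permutation p-values against exact `scipy.stats.hypergeom`
tails within Monte-Carlo error.

## QC

Beta densities use a fixed 101-bin histogram on [0, 1] (no kernel, hence
no bandwidth choice); a sample's "methylated mode" is the density argmax
over β ≥ 0.5, and for tissue carrying 5hmC the oxBS arms' methylated peak
sits left of the BS arms'. Replicate agreement is the squared Pearson
correlation over shared non-missing probes within each (group, treatment);
pairs below a configurable floor (default R² 0.95, the level separating
older low-input protocols from current kits) are flagged. Constant vectors
give R² = NA with a warning. Bootstrap-supported dendrograms are out of
scope; the correlation table covers the replicate-QC need.

## Synthetic data

The generator draws, per probe: a 5mC background from a bimodal Beta
mixture (low mode ≈ 0.09, weight 0.6; high mode ≈ 0.8, weight 0.4 — the
classic two-peak beta landscape); for a configurable fraction of probes
(default 15% in the brain-like preset, matching the share of array CpGs at
which 5hmC is detectable in brain), a 5hmC level from Beta(1.4, 4.1)
rescaled to [0.04, 0.59], i.e. range 4–59% with mean 18%, the reported
brain profile; a uniform level distribution is available. 5mC values
violating 5mC + 5hmC ≤ 1 are redrawn (up to 100 rounds, then set to
1 − 5hmC). Replicate measurements are independent N(truth, sd) draws
clipped to [0, 1] with sd 0.03 by default (mid-range of realistic
replicate noise; yields replicate R² ≈ 0.99 over a bimodal landscape).
Noise is on the beta scale, not M-values, matching the analysis scale.
Detection failures occur per measurement at rate 0.001 (failed
measurements draw detection p from [0.05, 1]); 2.4% of probes land on X/Y
(2:1 X:Y), mirroring array composition. Feature and CpG-island proportions
default to 450K-like values (body 31%, intergenic 21%, TSS1500 14%,
TSS200 13%, 5′UTR 12%, 1st exon 5%, 3′UTR 4%; islands 31%). Optional
per-category propensity weights (`BRAIN_FEATURE_WEIGHTS`,
`BRAIN_CGI_WEIGHTS`) place 5hmC preferentially in gene bodies and away
from promoters/islands, renormalised to preserve the global fraction.
Conversion-efficiency parameters (oxidation, bisulfite) default to 1.0.

What the simulator does not emulate: Infinium I/II chemistry differences,
chip/batch spatial effects, probe cross-hybridisation, and beta
heteroscedasticity near the interval ends beyond simple clipping. Passing
tests therefore demonstrate the statistical machinery under idealised
replicate noise, not robustness to array artefacts.

With two replicates per arm, Δβ has standard deviation equal to the
per-replicate noise sd (σ²/2 + σ²/2), so at sd 0.03 the expected absolute
error of a called probe's Δβ is 0.03·√(2/π) ≈ 0.024; three replicates per
arm or sd ≤ 0.025 bring it under 0.02. `truth_evaluation` reports
sensitivity above a level floor (the threshold regime cannot see levels
below its cutoff), the fraction of calls on truly 5hmC-free probes, and
the bias/MAE/RMSE of Δβ against true 5hmC over called probes.

## Pipeline and determinism

`run_all` executes simulate/load → filter → QC → per-group calling →
enrichment → truth evaluation from one YAML config; every artifact is
plain text with fixed numeric formats (betas at 6 decimals), every random
draw flows from the config seed through `numpy.random.default_rng`, and a
rerun with the same config is byte-identical. Stage failures surface as
stage-named errors with stage-specific exit codes. Default problem sizes
in the test suite (8,000–50,000 probes; one full 485,000 × 12 run) were
chosen so the whole suite exercises array scale while staying quick on a
laptop.

## Known limitations

* Exact reproduction of published probe counts from real cohorts is out of
  reach by design: those depend on the undeposited arrays and on the
  upstream pipeline's internal test; this implementation's t-test is a
  documented, reproducible stand-in for that unnamed test.
* The empirical FDR is an aggregate estimate; it does not identify which
  positive calls are false.
* With exactly two replicates per arm the FDR regime is underpowered
  (df = 2); that is a property of the design, and the threshold regime
  exists precisely for it.
* Missing betas drop a probe from the affected group's calling entirely
  rather than using the remaining replicates.
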