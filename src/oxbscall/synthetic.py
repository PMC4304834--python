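"""Synthetic paired BS/oxBS datasets with known per-probe ground truth.

The generator emulates the data-generating assumptions of the paired
conversion design: for each probe a true 5mC fraction and (for a subset of
probes) a true 5hmC fraction are drawn, the expected BS beta is
5mC + 5hmC, the expected oxBS beta is 5mC, and replicate measurements are
independent normal perturbations clipped to [0, 1].  Per-measurement
detection p-values are generated with a configurable failure rate, a
fraction of probes is placed on the X/Y chromosomes, and every probe gets a
gene-feature category and a CpG-island relation, so the filtering, calling,
QC and enrichment stages can all be exercised against known truth.

The defaults describe a brain-like tissue: 15% of probes carry 5hmC, at
levels spanning 0.04-0.59 with mean 0.18 (a right-skewed scaled-Beta
profile); the 5mC background is bimodal (unmethylated mode near 0,
methylated mode near 0.8); replicate noise sd is 0.03 on the beta scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    CGI_CATEGORIES,
    FEATURE_CATEGORIES,
    BetaMatrix,
    HmcCallTable,
    OxbsValidationError,
    ProbeAnnotation,
    SampleSheet,
)

log = logging.getLogger(__name__)

#: Gene-feature proportions approximating the post-filter composition of a
#: 450K array (gene body and intergenic dominate; promoter windows,
#: 5'UTR/1st-exon and 3'UTR make up the rest).
DEFAULT_FEATURE_PROPORTIONS = {
    "TSS200": 0.13,
    "TSS1500": 0.14,
    "UTR5": 0.12,
    "EXON1": 0.05,
    "BODY": 0.31,
    "UTR3": 0.04,
    "IGR": 0.21,
}

#: CpG-island relation proportions (450K-like: roughly a third on islands).
DEFAULT_CGI_PROPORTIONS = {
    "ISLAND": 0.31,
    "SHORE": 0.23,
    "SHELF": 0.10,
    "OPEN_SEA": 0.36,
}


#: Brain-like relative 5hmC propensities: enriched in gene bodies and the
#: open sea, depleted at proximal promoters, first exons and CpG islands.
BRAIN_FEATURE_WEIGHTS = {
    "BODY": 1.8,
    "IGR": 1.2,
    "UTR3": 1.2,
    "TSS1500": 0.8,
    "UTR5": 0.6,
    "EXON1": 0.45,
    "TSS200": 0.35,
}
BRAIN_CGI_WEIGHTS = {"ISLAND": 0.3, "SHORE": 0.7, "SHELF": 1.2, "OPEN_SEA": 1.5}


@dataclass
class GroupProfile:
    """Global 5hmC profile of one simulated tissue group.

    ``hmc_level_shape`` are Beta-distribution shape parameters rescaled onto
    [hmc_level_low, hmc_level_high]; the default (1.4, 4.1) gives mean 0.18
    over the range 0.04-0.59.  Set it to None for a uniform level
    distribution on the same range.
    """

    name: str
    hmc_fraction: float = 0.15
    hmc_level_low: float = 0.04
    hmc_level_high: float = 0.59
    hmc_level_shape: tuple[float, float] | None = (1.4, 4.1)
    #: Optional relative propensity of carrying 5hmC per gene-feature /
    #: CpG-island category (renormalised so the overall fraction stays
    #: hmc_fraction).  None means 5hmC placement is independent of
    #: annotation; brain-like presets weight gene bodies up and
    #: promoters/islands down, as observed in neural tissue.
    feature_weights: dict | None = None
    cgi_weights: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hmc_fraction <= 1.0):
            raise OxbsValidationError("hmc_fraction must lie in [0, 1]")
        if not (0.0 <= self.hmc_level_low <= self.hmc_level_high <= 1.0):
            raise OxbsValidationError("5hmC level range must satisfy 0 <= low <= high <= 1")
        for weights in (self.feature_weights, self.cgi_weights):
            if weights is not None and any(w < 0 for w in weights.values()):
                raise OxbsValidationError("annotation weights must be non-negative")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paired BS/oxBS experiment."""

    n_probes: int = 20000
    groups: tuple[GroupProfile, ...] = (GroupProfile("brain1"),)
    replicates: int = 2  # per conversion arm
    noise_sd: float = 0.03  # replicate measurement sd on the beta scale
    detection_failure_rate: float = 0.001  # per measurement
    sex_probe_fraction: float = 0.024
    mc_high_fraction: float = 0.4  # weight of the methylated 5mC mode
    mc_low_shape: tuple[float, float] = (1.5, 15.0)  # Beta, mode near 0
    mc_high_shape: tuple[float, float] = (12.0, 3.0)  # Beta, mode near 0.8
    feature_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PROPORTIONS)
    )
    cgi_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CGI_PROPORTIONS))
    oxidation_efficiency: float = 1.0  # fraction of 5hmC actually oxidised
    bisulfite_efficiency: float = 1.0  # fraction of unmodified C converted
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise OxbsValidationError("n_probes must be positive")
        if self.replicates < 2:
            raise OxbsValidationError("need >= 2 replicates per arm for calling")
        if not self.groups:
            raise OxbsValidationError("at least one group profile is required")
        for frac in (
            self.detection_failure_rate,
            self.sex_probe_fraction,
            self.mc_high_fraction,
            self.oxidation_efficiency,
            self.bisulfite_efficiency,
        ):
            if not (0.0 <= frac <= 1.0):
                raise OxbsValidationError("all fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise OxbsValidationError("noise_sd must be non-negative")


@dataclass
class SimulatedDataset:
    """A simulated experiment plus its per-probe, per-group ground truth."""

    matrix: BetaMatrix  # includes detection_p
    sheet: SampleSheet
    annotation: ProbeAnnotation
    truth: pd.DataFrame  # columns probe_id, group, true_mc, true_hmc, feature


def _draw_levels(rng: np.random.Generator, profile: GroupProfile, n: int) -> np.ndarray:
    lo, hi = profile.hmc_level_low, profile.hmc_level_high
    if profile.hmc_level_shape is None:
        return rng.uniform(lo, hi, size=n)
    a, b = profile.hmc_level_shape
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def _draw_mc(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    high = rng.random(n) < cfg.mc_high_fraction
    mc = np.empty(n)
    mc[~high] = rng.beta(*cfg.mc_low_shape, size=int((~high).sum()))
    mc[high] = rng.beta(*cfg.mc_high_shape, size=int(high.sum()))
    return mc


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate a paired BS/oxBS dataset with known truth.

    ``seed`` overrides ``config.seed``; with a fixed seed the output is
    byte-identical across runs.  Per probe and group, expected BS beta =
    5mC + 5hmC and expected oxBS beta = 5mC (modulated by the conversion
    efficiencies); replicate betas are independent N(truth, noise_sd) draws
    clipped to [0, 1].  Probes where a drawn 5mC would violate
    5mC + 5hmC <= 1 have their 5mC redrawn (up to 100 rounds, then set to
    1 - 5hmC).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id")

    # -- annotation ---------------------------------------------------------
    chrom = rng.choice([str(c) for c in range(1, 23)], size=n)
    sex_mask = rng.random(n) < config.sex_probe_fraction
    chrom[sex_mask] = rng.choice(["X", "Y"], size=int(sex_mask.sum()), p=[2 / 3, 1 / 3])
    feat_names = list(config.feature_proportions)
    feat_p = np.asarray(list(config.feature_proportions.values()), dtype=float)
    features = rng.choice(feat_names, size=n, p=feat_p / feat_p.sum())
    cgi_names = list(config.cgi_proportions)
    cgi_p = np.asarray(list(config.cgi_proportions.values()), dtype=float)
    cgi = rng.choice(cgi_names, size=n, p=cgi_p / cgi_p.sum())
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {"chromosome": chrom, "feature": features, "cgi_relation": cgi},
            index=probe_ids,
        )
    )

    # -- truth and measurements --------------------------------------------
    eff_ox = config.oxidation_efficiency
    eff_bs = config.bisulfite_efficiency
    columns: dict[str, np.ndarray] = {}
    detection: dict[str, np.ndarray] = {}
    sheet_rows = []
    truth_frames = []
    for profile in config.groups:
        prob = np.full(n, profile.hmc_fraction)
        if profile.feature_weights or profile.cgi_weights:
            w = np.ones(n)
            if profile.feature_weights:
                w *= np.vectorize(lambda f: profile.feature_weights.get(f, 1.0))(features)
            if profile.cgi_weights:
                w *= np.vectorize(lambda c: profile.cgi_weights.get(c, 1.0))(cgi)
            prob = np.clip(profile.hmc_fraction * w / w.mean(), 0.0, 1.0)
        hmc_mask = rng.random(n) < prob
        hmc = np.zeros(n)
        hmc[hmc_mask] = _draw_levels(rng, profile, int(hmc_mask.sum()))
        mc = _draw_mc(config, rng, n)
        for _ in range(100):
            bad = mc + hmc > 1.0
            if not bad.any():
                break
            mc[bad] = _draw_mc(config, rng, int(bad.sum()))
        else:
            mc = np.minimum(mc, 1.0 - hmc)

        unmod = 1.0 - mc - hmc
        true_bs = mc + hmc + unmod * (1.0 - eff_bs)
        true_ox = mc + hmc * (1.0 - eff_ox) + unmod * (1.0 - eff_bs)
        for treatment, expectation in (("BS", true_bs), ("oxBS", true_ox)):
            for rep in range(1, config.replicates + 1):
                sid = f"{profile.name}_{treatment}_r{rep}"
                noisy = expectation + rng.normal(0.0, config.noise_sd, size=n)
                columns[sid] = np.clip(noisy, 0.0, 1.0)
                fail = rng.random(n) < config.detection_failure_rate
                dp = rng.uniform(0.0, 0.005, size=n)
                dp[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))
                detection[sid] = dp
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "group": profile.name,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
        truth_frames.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "group": profile.name,
                    "true_mc": mc,
                    "true_hmc": hmc,
                    "feature": features,
                }
            )
        )

    matrix = BetaMatrix(
        pd.DataFrame(columns, index=probe_ids),
        pd.DataFrame(detection, index=probe_ids),
    )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = pd.concat(truth_frames, ignore_index=True)
    log.info(
        "simulated %d probes x %d samples (%d groups, %d replicates/arm, seed %s)",
        n,
        len(columns),
        len(config.groups),
        config.replicates,
        seed,
    )
    return SimulatedDataset(matrix=matrix, sheet=sheet, annotation=annotation, truth=truth)


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["true_mc"] = out["true_mc"].map(lambda v: f"{v:.6f}")
    out["true_hmc"] = out["true_hmc"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "group": str, "feature": str})
    df["true_mc"] = df["true_mc"].astype(float)
    df["true_hmc"] = df["true_hmc"].astype(float)
    return df


@dataclass
class EvaluationMetrics:
    """Recovery metrics of a call table against simulation ground truth."""

    n_truth: int  # probes truly hydroxymethylated at >= level_floor
    n_called: int
    sensitivity: float
    false_call_rate: float  # fraction of calls on probes with true 5hmC == 0
    delta_bias: float  # mean(delta - true 5hmC) over called probes
    delta_rmse: float
    delta_mae: float

    def as_dict(self) -> dict:
        import math

        return {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in self.__dict__.items()
        }


def truth_evaluation(
    calls: HmcCallTable, truth: pd.DataFrame, level_floor: float = 0.0
) -> EvaluationMetrics:
    """Sensitivity, false-call rate and delta-beta accuracy against truth.

    Sensitivity is computed over probes whose true 5hmC is positive and at
    least ``level_floor`` (restricting to well-hydroxymethylated probes
    matters for the conservative threshold regime, which by construction
    cannot see levels below its delta cutoff).  Bias/RMSE/MAE compare the
    estimated delta-beta with the true 5hmC level over called probes.
    """
    if "group" in truth.columns:
        groups = truth["group"].unique()
        if calls.group is not None and calls.group in groups:
            truth = truth[truth["group"] == calls.group]
        elif len(groups) > 1:
            raise OxbsValidationError(
                "truth table covers several groups; pass the slice matching the call table"
            )
    truth_idx = pd.Index(truth["probe_id"].astype(str))
    call_universe = calls.data.index
    if len(truth_idx.intersection(call_universe)) == 0:
        raise OxbsValidationError("call table and truth table share no probes")
    t = truth.set_index(truth_idx)
    t = t.loc[t.index.intersection(call_universe)]

    true_hmc = t["true_hmc"]
    positives = t.index[(true_hmc > 0) & (true_hmc >= level_floor)]
    called = calls.called_probe_ids.intersection(t.index)
    n_truth = len(positives)
    sensitivity = (
        len(positives.intersection(called)) / n_truth if n_truth else float("nan")
    )
    if len(called):
        false_calls = int((true_hmc.loc[called] == 0).sum())
        err = calls.data.loc[called, "delta_beta"] - true_hmc.loc[called]
        metrics = (
            false_calls / len(called),
            float(err.mean()),
            float(np.sqrt((err**2).mean())),
            float(err.abs().mean()),
        )
    else:
        metrics = (float("nan"),) * 4
    return EvaluationMetrics(
        n_truth=n_truth,
        n_called=len(called),
        sensitivity=sensitivity,
        false_call_rate=metrics[0],
        delta_bias=metrics[1],
        delta_rmse=metrics[2],
        delta_mae=metrics[3],
    )
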