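"""Permutation enrichment of 5hmC calls over genomic feature categories.

The null model draws probe sets of the same size as the call set from the
post-filter background without replacement and counts probes per category.
Because only the per-category counts of such a draw matter, each permutation
is drawn directly from the corresponding multivariate hypergeometric
distribution -- exactly the distribution of counting a uniform
without-replacement sample -- which makes very large permutation numbers
cheap.  Reported per category: observed count, null mean/sd, percent
enrichment 100 * (observed - null_mean) / null_mean, and add-one-corrected
one-sided permutation p-values for enrichment and depletion (the smaller
one, doubled and capped at 1, is the two-sided p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CGI_CATEGORIES,
    FEATURE_CATEGORIES,
    OxbsValidationError,
    ProbeAnnotation,
)

log = logging.getLogger(__name__)

_CATEGORY_SETS = {"feature": FEATURE_CATEGORIES, "cgi_relation": CGI_CATEGORIES}


@dataclass
class EnrichmentResult:
    """Per-category enrichment table plus the permutation run metadata."""

    table: pd.DataFrame  # index category; observed, null_mean, null_sd,
    # percent_enrichment, p_enriched, p_depleted, p_two_sided, direction
    column: str
    n_permutations: int
    seed: int | None
    n_background: int
    n_calls: int


def feature_distribution(
    probe_ids, annotation: ProbeAnnotation, column: str = "feature"
) -> pd.DataFrame:
    """Counts and proportions of probes per category (proportions sum to 1)."""
    counts = _category_counts(probe_ids, annotation, column)
    total = int(counts.sum())
    if total == 0:
        raise OxbsValidationError("no annotated probes in the given set")
    return pd.DataFrame({"count": counts, "proportion": counts / total})


def _category_counts(probe_ids, annotation: ProbeAnnotation, column: str) -> pd.Series:
    if column not in _CATEGORY_SETS:
        raise OxbsValidationError(f"unknown annotation column {column!r}")
    cats = annotation.categories_of(probe_ids, column)
    order = [c for c in _CATEGORY_SETS[column] if c in set(cats)] or list(
        _CATEGORY_SETS[column]
    )
    counts = cats.value_counts().reindex(order, fill_value=0)
    counts.index.name = column
    return counts.astype(int)


def permutation_enrichment(
    call_set,
    background,
    annotation: ProbeAnnotation,
    n_permutations: int = 1000,
    seed: int | None = None,
    column: str = "feature",
) -> EnrichmentResult:
    """Permutation enrichment of ``call_set`` against ``background``.

    ``call_set`` must be a subset of ``background``.  Probes without
    annotation are excluded from both sets (logged).  P-values use the
    add-one correction (#{null as or more extreme} + 1) / (B + 1), so they
    are never zero.
    """
    call_idx = pd.Index(call_set)
    bg_idx = pd.Index(background)
    if not call_idx.isin(bg_idx).all():
        raise OxbsValidationError("call set is not a subset of the background")
    if n_permutations < 1:
        raise OxbsValidationError("n_permutations must be >= 1")

    bg_counts = _category_counts(bg_idx, annotation, column)
    # observed counts on the same category axis as the background
    obs_cats = annotation.categories_of(call_idx, column)
    observed = obs_cats.value_counts().reindex(bg_counts.index, fill_value=0).astype(int)
    n_calls = int(observed.sum())
    n_background = int(bg_counts.sum())
    if n_calls == 0:
        raise OxbsValidationError("no annotated probes in the call set")

    rng = np.random.default_rng(seed)
    null = rng.multivariate_hypergeometric(
        bg_counts.to_numpy(), n_calls, size=n_permutations
    )  # (B, n_categories): category counts of drawing n_calls probes w/o replacement

    obs = observed.to_numpy()
    p_enr = ((null >= obs).sum(axis=0) + 1) / (n_permutations + 1)
    p_dep = ((null <= obs).sum(axis=0) + 1) / (n_permutations + 1)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_enr, p_dep))
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(len(obs))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(null_mean > 0, 100.0 * (obs - null_mean) / null_mean, np.nan)
    direction = np.where(obs >= null_mean, "enriched", "depleted")

    table = pd.DataFrame(
        {
            "observed": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "percent_enrichment": pct,
            "p_enriched": p_enr,
            "p_depleted": p_dep,
            "p_two_sided": p_two,
            "direction": direction,
        },
        index=bg_counts.index,
    )
    return EnrichmentResult(
        table=table,
        column=column,
        n_permutations=n_permutations,
        seed=seed,
        n_background=n_background,
        n_calls=n_calls,
    )


def cgi_enrichment(
    call_set,
    background,
    annotation: ProbeAnnotation,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Enrichment over CpG-island relation categories."""
    return permutation_enrichment(
        call_set,
        background,
        annotation,
        n_permutations=n_permutations,
        seed=seed,
        column="cgi_relation",
    )


def write_enrichment(result: EnrichmentResult, path) -> None:
    """Write an enrichment table TSV with '#'-prefixed run metadata lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# column: {result.column}\n")
        fh.write(f"# n_permutations: {result.n_permutations}\n")
        fh.write(f"# seed: {result.seed}\n")
        fh.write(f"# n_background: {result.n_background}\n")
        fh.write(f"# n_calls: {result.n_calls}\n")
        out = result.table.copy()
        for col in ("null_mean", "null_sd", "percent_enrichment"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
        for col in ("p_enriched", "p_depleted", "p_two_sided"):
            out[col] = out[col].map(lambda v: f"{v:.6e}")
        out.to_csv(fh, sep="\t", index_label="category")


def read_enrichment(path) -> pd.DataFrame:
    """Read the per-category table back (metadata lines are skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
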