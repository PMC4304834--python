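"""Core data types and plain-text I/O for paired BS/oxBS methylation-array analysis.

The central objects are a beta-value matrix (probes x samples, values on
[0, 1]), a sample sheet describing the paired bisulfite-only (BS) and
oxidative-bisulfite (oxBS) conversion design, a per-probe genomic
annotation, and the per-probe 5hmC call table produced by the calling
stage.  All tables are read and written as UTF-8 TSV/CSV so that every
artifact of a run is diffable and reproducible.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Gene-feature categories used to classify each probe.  TSS200/TSS1500 are
#: the 200 bp / 1500 bp windows upstream of a transcription start site.
FEATURE_CATEGORIES = ("TSS200", "TSS1500", "UTR5", "EXON1", "BODY", "UTR3", "IGR")

#: Precedence used to collapse multi-valued gene-group annotations down to a
#: single feature per probe (promoter-proximal categories win); IGR is the
#: fallback when a probe has no gene annotation at all.
FEATURE_PRECEDENCE = ("TSS200", "TSS1500", "UTR5", "EXON1", "BODY", "UTR3")

#: CpG-island relation categories.  SHORE/SHELF inputs may be collapsed to
#: NON_ISLAND by callers that only care about the island / non-island split.
CGI_CATEGORIES = ("ISLAND", "SHORE", "SHELF", "OPEN_SEA", "NON_ISLAND")

SEX_CHROMOSOMES = frozenset({"X", "Y"})

TREATMENT_BS = "BS"
TREATMENT_OXBS = "oxBS"

CALL_HMC = "HMC"
CALL_NEG_SIG = "NEG_SIG"
CALL_NOT_CALLED = "NOT_CALLED"

#: Decimal places used when writing beta values; fixed for reproducibility.
BETA_DECIMALS = 6

_FEATURE_ALIASES = {
    "TSS200": "TSS200",
    "TSS1500": "TSS1500",
    "UTR5": "UTR5",
    "5'UTR": "UTR5",
    "5UTR": "UTR5",
    "EXON1": "EXON1",
    "1STEXON": "EXON1",
    "FIRSTEXON": "EXON1",
    "BODY": "BODY",
    "GENEBODY": "BODY",
    "UTR3": "UTR3",
    "3'UTR": "UTR3",
    "3UTR": "UTR3",
    "IGR": "IGR",
    "INTERGENIC": "IGR",
}

_CGI_ALIASES = {
    "ISLAND": "ISLAND",
    "CGI": "ISLAND",
    "SHORE": "SHORE",
    "N_SHORE": "SHORE",
    "S_SHORE": "SHORE",
    "SHELF": "SHELF",
    "N_SHELF": "SHELF",
    "S_SHELF": "SHELF",
    "OPEN_SEA": "OPEN_SEA",
    "OPENSEA": "OPEN_SEA",
    "SEA": "OPEN_SEA",
    "NON_ISLAND": "NON_ISLAND",
    "NONISLAND": "NON_ISLAND",
}

_TREATMENT_ALIASES = {
    "BS": TREATMENT_BS,
    "BSONLY": TREATMENT_BS,
    "BS-ONLY": TREATMENT_BS,
    "BS_ONLY": TREATMENT_BS,
    "OXBS": TREATMENT_OXBS,
}


class OxbsValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def _check_unique(labels: Iterable, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise OxbsValidationError(f"duplicate {what}: {dups}")


def normalise_chromosome(label: str) -> str:
    """Normalise chromosome dialects ('chrX', 'x', '23') to a bare label."""
    s = str(label).strip()
    s = re.sub(r"^chr", "", s, flags=re.IGNORECASE)
    s = s.upper()
    if s == "23":
        s = "X"
    elif s == "24":
        s = "Y"
    return s


def normalise_treatment(label: str) -> str:
    key = str(label).strip().upper()
    if key not in _TREATMENT_ALIASES:
        raise OxbsValidationError(
            f"unknown treatment label {label!r}; expected one of BS, oxBS"
        )
    return _TREATMENT_ALIASES[key]


def collapse_feature(label: str, precedence: Sequence[str] = FEATURE_PRECEDENCE) -> str:
    """Collapse a (possibly multi-valued) gene-group annotation to one feature.

    Multi-valued inputs such as ``"TSS1500;Body"`` arise because a probe may
    be annotated against several transcripts; the first category in
    ``precedence`` that occurs wins.  A probe with no gene category maps to
    ``IGR`` (intergenic).
    """
    tokens = [t.strip().upper().replace(" ", "") for t in re.split(r"[;,|]", str(label))]
    cats = set()
    for tok in tokens:
        if not tok or tok == "NA":
            continue
        if tok not in _FEATURE_ALIASES:
            raise OxbsValidationError(f"unknown gene-feature category {tok!r}")
        cats.add(_FEATURE_ALIASES[tok])
    if not cats or cats == {"IGR"}:
        return "IGR"
    for cat in precedence:
        if cat in cats:
            return cat
    return "IGR"


def normalise_cgi(label: str) -> str:
    key = str(label).strip().upper().replace(" ", "_")
    if key not in _CGI_ALIASES:
        raise OxbsValidationError(f"unknown CpG-island relation {label!r}")
    return _CGI_ALIASES[key]


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values on [0, 1].

    ``values`` is indexed by probe id with one column per sample.  Missing
    measurements are NaN (never silently zero).  ``detection_p`` is an
    optional matrix of identical shape and ordering holding per-measurement
    detection p-values.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        self._check_bounds(self.values, "beta")
        if self.detection_p is not None:
            dp = pd.DataFrame(self.detection_p).astype(float)
            if not dp.index.equals(self.values.index) or not dp.columns.equals(
                self.values.columns
            ):
                raise OxbsValidationError(
                    "detection-p matrix does not match the beta matrix "
                    f"(shape {dp.shape} vs {self.values.shape}, or ordering differs)"
                )
            self._check_bounds(dp, "detection p")
            self.detection_p = dp

    @staticmethod
    def _check_bounds(frame: pd.DataFrame, what: str) -> None:
        arr = frame.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0) | np.isinf(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise OxbsValidationError(
                f"{what} value {arr[i, j]!r} out of [0, 1] at probe "
                f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_probes(self, probe_ids: Sequence) -> "BetaMatrix":
        """Restrict to ``probe_ids`` (must all be present), preserving order."""
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise OxbsValidationError(f"unknown probe ids: {missing.tolist()[:5]}")
        dp = None if self.detection_p is None else self.detection_p.loc[idx]
        return BetaMatrix(self.values.loc[idx], dp)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Per-sample metadata defining the paired BS/oxBS replicate design."""

    data: pd.DataFrame  # columns: sample_id, group, treatment, replicate

    REQUIRED = ("sample_id", "group", "treatment", "replicate")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise OxbsValidationError(f"sample sheet missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["group"] = df["group"].astype(str)
        df["treatment"] = df["treatment"].map(normalise_treatment)
        try:
            df["replicate"] = df["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise OxbsValidationError(f"non-integer replicate index: {exc}") from exc
        if (df["replicate"] < 1).any():
            raise OxbsValidationError("replicate indices must be positive integers")
        _check_unique(df["sample_id"], "sample ids")
        triple = df[["group", "treatment", "replicate"]].apply(tuple, axis=1)
        _check_unique(triple, "(group, treatment, replicate) triples")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    def validate_matrix(self, matrix: BetaMatrix) -> None:
        """Every matrix sample must appear exactly once in the sheet."""
        missing = matrix.sample_ids.difference(self.sample_ids)
        if len(missing):
            raise OxbsValidationError(
                f"samples in beta matrix absent from sample sheet: {missing.tolist()[:5]}"
            )
        extra = self.sample_ids.difference(matrix.sample_ids)
        if len(extra):
            log.warning(
                "%d sheet samples not present in the beta matrix: %s",
                len(extra),
                extra.tolist()[:5],
            )

    def arms(self, group: str) -> tuple[list[str], list[str]]:
        """Return (BS sample ids, oxBS sample ids) for one group."""
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise OxbsValidationError(f"group {group!r} not present in sample sheet")
        bs = sub.loc[sub["treatment"] == TREATMENT_BS, "sample_id"].tolist()
        ox = sub.loc[sub["treatment"] == TREATMENT_OXBS, "sample_id"].tolist()
        return bs, ox


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Per-probe chromosome, gene-feature category and CpG-island relation."""

    data: pd.DataFrame  # index: probe_id; columns: chromosome, feature, cgi_relation

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        if "probe_id" in df.columns:
            df = df.set_index("probe_id")
        df.index = df.index.astype(str)
        _check_unique(df.index, "annotation probe ids")
        for col in ("chromosome", "feature", "cgi_relation"):
            if col not in df.columns:
                raise OxbsValidationError(f"annotation missing column {col!r}")
        df["chromosome"] = df["chromosome"].map(normalise_chromosome)
        df["feature"] = df["feature"].map(collapse_feature)
        df["cgi_relation"] = df["cgi_relation"].map(normalise_cgi)
        self.data = df[["chromosome", "feature", "cgi_relation"]]

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def sex_probes(self) -> pd.Index:
        mask = self.data["chromosome"].isin(SEX_CHROMOSOMES)
        return self.data.index[mask]

    def categories_of(self, probe_ids: Sequence, column: str = "feature") -> pd.Series:
        """Category per probe; probes absent from the annotation are dropped
        with a logged count (they are excluded from enrichment only)."""
        idx = pd.Index(probe_ids)
        known = idx.intersection(self.data.index)
        n_unknown = len(idx) - len(known)
        if n_unknown:
            log.warning("%d probes lack annotation and are excluded", n_unknown)
        return self.data.loc[known, column]


# ---------------------------------------------------------------------------
# Call configuration and results
# ---------------------------------------------------------------------------

MODE_THRESHOLD = "threshold"
MODE_FDR = "fdr"


@dataclass
class CallConfig:
    """Thresholds for probe filtering and 5hmC calling.

    ``threshold`` mode calls a probe hydroxymethylated when
    delta-beta >= ``delta_threshold`` with nominal p < ``nominal_p_threshold``
    (the conservative two-replicate regime); ``fdr`` mode calls on the
    Benjamini-Hochberg adjusted p-value alone (q < ``q_threshold``).
    """

    mode: str = MODE_THRESHOLD
    delta_threshold: float = 0.30
    nominal_p_threshold: float = 0.05
    q_threshold: float = 0.05
    detection_p_threshold: float = 0.01
    drop_sex_chromosomes: bool = True
    filter_detection: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (MODE_THRESHOLD, MODE_FDR):
            raise OxbsValidationError(
                f"call mode must be {MODE_THRESHOLD!r} or {MODE_FDR!r}, got {self.mode!r}"
            )
        for name in (
            "delta_threshold",
            "nominal_p_threshold",
            "q_threshold",
            "detection_p_threshold",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise OxbsValidationError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class CallSummary:
    """Run-level summary of a call table.

    ``empirical_fdr`` is the fraction of all significant probes whose
    delta-beta is negative -- a chemically impossible direction that can only
    be noise, so it estimates the false-discovery rate of the positive calls.
    NaN when there are no significant probes at all.
    """

    n_probes: int
    n_called: int
    n_neg_sig: int
    empirical_fdr: float
    mean_called_delta: float
    min_called_delta: float
    max_called_delta: float

    def as_dict(self) -> dict:
        return {
            "n_probes": self.n_probes,
            "n_called": self.n_called,
            "n_neg_sig": self.n_neg_sig,
            "empirical_fdr": None if math.isnan(self.empirical_fdr) else self.empirical_fdr,
            "mean_called_delta": None
            if math.isnan(self.mean_called_delta)
            else self.mean_called_delta,
            "min_called_delta": None
            if math.isnan(self.min_called_delta)
            else self.min_called_delta,
            "max_called_delta": None
            if math.isnan(self.max_called_delta)
            else self.max_called_delta,
        }


@dataclass
class HmcCallTable:
    """Per-probe delta-beta, test statistic, p, q and call status."""

    data: pd.DataFrame  # index probe_id; delta_beta, stat, p_value, q_value, call
    summary: CallSummary
    group: str | None = None
    mode: str | None = None

    COLUMNS = ("delta_beta", "stat", "p_value", "q_value", "call")

    @property
    def called_probe_ids(self) -> pd.Index:
        return self.data.index[self.data["call"] == CALL_HMC]

    @property
    def neg_sig_probe_ids(self) -> pd.Index:
        return self.data.index[self.data["call"] == CALL_NEG_SIG]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe ids, header sample ids).

    Empty cells and ``NA`` are recorded as missing, not zero.  Values outside
    [0, 1] raise an error naming the offending probe and sample.
    """
    values = _read_matrix_tsv(path)
    detection = _read_matrix_tsv(detection_path) if detection_path is not None else None
    return BetaMatrix(values, detection)


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise OxbsValidationError(f"non-numeric value in {path}: {exc}") from exc
    return df


def write_beta_matrix(matrix: BetaMatrix, path, detection_path=None) -> None:
    fmt = f"%.{BETA_DECIMALS}f"
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format=fmt, na_rep="NA")
    if detection_path is not None:
        if matrix.detection_p is None:
            raise OxbsValidationError("matrix has no detection-p component to write")
        matrix.detection_p.to_csv(
            detection_path, sep="\t", index_label="probe_id", float_format=fmt, na_rep="NA"
        )


def read_sample_sheet(path) -> SampleSheet:
    """Read a CSV sample sheet with header ``sample_id,group,treatment,replicate``."""
    return SampleSheet(pd.read_csv(path, dtype=str))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False)


def read_annotation(path) -> ProbeAnnotation:
    """Read a TSV annotation with header ``probe_id chromosome feature cgi_relation``."""
    return ProbeAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.data.to_csv(path, sep="\t", index_label="probe_id")


def write_call_table(table: HmcCallTable, path) -> None:
    """Write a call table TSV: ``probe_id delta_beta stat p_value q_value call``."""
    df = table.data.copy()
    df["delta_beta"] = df["delta_beta"].map(lambda v: f"{v:.6f}")
    df["stat"] = df["stat"].map(lambda v: f"{v:.6g}")
    for col in ("p_value", "q_value"):
        df[col] = df[col].map(lambda v: f"{v:.6e}")
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_call_table(path) -> pd.DataFrame:
    """Read a call table back as a DataFrame indexed by probe id."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"call": str})
    df.index = df.index.astype(str)
    for col in ("delta_beta", "stat", "p_value", "q_value"):
        df[col] = df[col].astype(float)
    return df
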