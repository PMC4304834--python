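"""Probe filtering applied before any 5hmC calling.

Two removal rules, applied in a fixed order so that the report counts are
disjoint: (1) detection failure -- a probe fails when its detection p-value
exceeds the threshold in ANY sample of the analysis set (the stricter of the
common readings, switchable to an all-samples rule); (2) sex-chromosome
removal, on by default because mixed male/female sample sets make X/Y betas
uninterpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    SEX_CHROMOSOMES,
    BetaMatrix,
    CallConfig,
    OxbsValidationError,
    ProbeAnnotation,
)

log = logging.getLogger(__name__)

DETECTION_RULE_ANY = "any"
DETECTION_RULE_ALL = "all"


@dataclass
class FilterReport:
    """Disjoint accounting of probe removals (detection rule applied first)."""

    n_input_probes: int
    n_failed_detection: int
    n_sex_chromosome: int
    n_retained: int
    retained_probe_ids: pd.Index

    def as_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_failed_detection": self.n_failed_detection,
            "n_sex_chromosome": self.n_sex_chromosome,
            "n_retained": self.n_retained,
        }


def filter_probes(
    matrix: BetaMatrix,
    annotation: ProbeAnnotation,
    config: CallConfig,
    detection_rule: str = DETECTION_RULE_ANY,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove detection-failed and (optionally) sex-chromosome probes.

    Returns the restricted matrix (probe order preserved) and a report whose
    removal counts are disjoint: a probe failing detection on chrY is counted
    once, under detection.  Probes absent from the annotation cannot be
    assigned a chromosome and are retained with a logged count.
    """
    if detection_rule not in (DETECTION_RULE_ANY, DETECTION_RULE_ALL):
        raise OxbsValidationError(f"unknown detection rule {detection_rule!r}")

    n_input = len(matrix.probe_ids)
    failed = pd.Index([])
    if config.filter_detection:
        if matrix.detection_p is None:
            raise OxbsValidationError(
                "detection filtering requested but the matrix has no detection-p values"
            )
        exceed = matrix.detection_p.to_numpy() > config.detection_p_threshold
        mask = exceed.any(axis=1) if detection_rule == DETECTION_RULE_ANY else exceed.all(axis=1)
        failed = matrix.probe_ids[mask]

    remaining = matrix.probe_ids[~matrix.probe_ids.isin(failed)]

    sex = pd.Index([])
    if config.drop_sex_chromosomes:
        annotated = remaining[remaining.isin(annotation.probe_ids)]
        n_unannotated = len(remaining) - len(annotated)
        if n_unannotated:
            log.warning(
                "%d probes lack annotation; retained (chromosome unknown)", n_unannotated
            )
        chrom = annotation.data.loc[annotated, "chromosome"]
        sex = annotated[chrom.isin(SEX_CHROMOSOMES).to_numpy()]

    drop = failed.union(sex)
    retained = matrix.probe_ids[~matrix.probe_ids.isin(drop)]
    report = FilterReport(
        n_input_probes=n_input,
        n_failed_detection=len(failed),
        n_sex_chromosome=len(sex),
        n_retained=len(retained),
        retained_probe_ids=retained,
    )
    log.info(
        "probe filter: %d input, %d failed detection, %d on X/Y, %d retained",
        n_input,
        report.n_failed_detection,
        report.n_sex_chromosome,
        report.n_retained,
    )
    return matrix.select_probes(retained), report
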