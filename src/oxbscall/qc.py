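"""Replicate-quality diagnostics: beta-value densities and replicate R^2.

A well-behaved array run shows a bimodal beta density per sample (an
unmethylated peak near 0 and a methylated peak near 1); because oxBS
conversion strips the 5hmC contribution from the signal, the oxBS arms of a
tissue carrying 5hmC show a methylated peak shifted left of the paired BS
arms.  Technical replicates of the same (group, treatment) should correlate
with R^2 well above 0.95 on modern conversion protocols.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BetaMatrix, OxbsValidationError, SampleSheet

log = logging.getLogger(__name__)

#: Number of grid points of the fixed beta-density grid on [0, 1].
DENSITY_GRID_POINTS = 101


@dataclass
class QcReport:
    """Per-sample densities and per-replicate-pair squared correlations."""

    densities: pd.DataFrame  # grid (101 bin centres) x samples
    modes: pd.Series  # per sample, grid position of the density maximum
    methylated_modes: pd.Series  # density maximum restricted to beta >= 0.5
    pair_r2: pd.DataFrame  # group, treatment, sample_a, sample_b, r_squared, flagged
    r2_floor: float

    def as_dict(self) -> dict:
        return {
            "r2_floor": self.r2_floor,
            "modes": {k: float(v) for k, v in self.modes.items()},
            "methylated_modes": {k: float(v) for k, v in self.methylated_modes.items()},
            "pair_r2": self.pair_r2.to_dict(orient="records"),
        }


def beta_density(matrix: BetaMatrix) -> pd.DataFrame:
    """Histogram density of beta values per sample on a fixed 101-bin grid.

    The grid is 101 equal bins on [0, 1]; values are a proper density
    (sum(density) * bin_width == 1) indexed by bin centre.  Histogram rather
    than kernel density, so there is no bandwidth choice.
    """
    if matrix.values.empty:
        raise OxbsValidationError("beta matrix is empty")
    edges = np.linspace(0.0, 1.0, DENSITY_GRID_POINTS + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    cols = {}
    for sample in matrix.sample_ids:
        v = matrix.values[sample].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        counts, _ = np.histogram(v, bins=edges, density=True)
        cols[sample] = counts
    return pd.DataFrame(cols, index=pd.Index(centres, name="beta"))


def r_squared(x, y) -> float:
    """Squared Pearson correlation over shared non-missing entries.

    Returns NaN (with a warning) if either vector is constant after removing
    missing values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant beta vector: replicate R^2 undefined", stacklevel=2)
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def replicate_correlation(
    matrix: BetaMatrix, sheet: SampleSheet, r2_floor: float = 0.95
) -> QcReport:
    """QC report: densities plus pairwise replicate R^2 within (group, treatment).

    Every (group, treatment) present in the sheet and the matrix must have at
    least two replicates.  Pairs with R^2 below ``r2_floor`` are flagged.
    """
    sheet.validate_matrix(matrix)
    present = sheet.data[sheet.data["sample_id"].isin(matrix.sample_ids)]
    rows = []
    for (group, treatment), sub in present.groupby(["group", "treatment"], sort=True):
        ids = sorted(sub["sample_id"])
        if len(ids) < 2:
            raise OxbsValidationError(
                f"({group}, {treatment}) has {len(ids)} replicate(s); need >= 2 for QC"
            )
        for a, b in itertools.combinations(ids, 2):
            r2 = r_squared(matrix.values[a], matrix.values[b])
            rows.append(
                {
                    "group": group,
                    "treatment": treatment,
                    "sample_a": a,
                    "sample_b": b,
                    "r_squared": r2,
                    "flagged": bool(r2 < r2_floor) if not np.isnan(r2) else True,
                }
            )
    pair_r2 = pd.DataFrame(rows)
    densities = beta_density(matrix)
    modes = densities.idxmax()
    methylated = densities[densities.index >= 0.5]
    methylated_modes = methylated.idxmax()
    n_flagged = int(pair_r2["flagged"].sum())
    if n_flagged:
        log.warning("%d replicate pair(s) below the R^2 floor %.3f", n_flagged, r2_floor)
    return QcReport(
        densities=densities,
        modes=modes,
        methylated_modes=methylated_modes,
        pair_r2=pair_r2,
        r2_floor=r2_floor,
    )
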