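"""Dual-marker immunofluorescence mutual-exclusivity analysis.

Per-cell HER2 and CK5 (basal cytokeratin) intensities are dichotomized at
the median computed over all quantified cells, cross-tabulated, and tested
for association with Fisher's exact test; mutual exclusivity of the two
markers shows up as an odds ratio below 1 together with a negative
intensity correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusivityResult",
    "dichotomize",
    "exclusivity_table",
    "fisher_exact",
    "intensity_correlation",
    "exclusivity_analysis",
]

REQUIRED_COLUMNS = ["cell_id", "tumor_id", "her2_intensity", "ck5_intensity"]


@dataclass
class ExclusivityResult:
    """2x2 contingency outcome of the HER2/CK5 dichotomization."""

    table: np.ndarray  # rows: HER2 hi/lo; cols: CK5 hi/lo
    odds_ratio: float  # ad/bc; inf when bc = 0 and ad > 0
    p_value: float
    pearson_r: float
    pearson_p: float
    her2_median: float
    ck5_median: float
    labels: pd.DataFrame  # per-cell hi/lo labels


def dichotomize(intensities, median: "float | None" = None) -> np.ndarray:
    """HI/LO labels at the median of all cells; ties at the median are LO.

    Returns a boolean array (True = HI).  Supplying ``median`` supports
    per-tumor dichotomization against an externally computed cutoff.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("dichotomization requires at least 2 cells")
    if not np.isfinite(x).all() or (x < 0).any():
        raise ValueError("intensities must be finite and non-negative")
    cut = float(np.median(x)) if median is None else float(median)
    return x > cut


def exclusivity_table(her2_hi: np.ndarray, ck5_hi: np.ndarray) -> np.ndarray:
    """Counts [[HER2hi&CK5hi, HER2hi&CK5lo], [HER2lo&CK5hi, HER2lo&CK5lo]]."""
    a = np.asarray(her2_hi, dtype=bool)
    b = np.asarray(ck5_hi, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("label vectors must be aligned")
    return np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )


def fisher_exact(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided p by the probability-mass method: the sum of hypergeometric
    probabilities of all tables (at the observed margins) no more probable
    than the observed one.  The reported odds ratio is the sample odds ratio
    ad/bc (infinite when bc = 0 and ad > 0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() < 1:
        raise ValueError("table must contain at least one observation")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def intensity_correlation(her2, ck5) -> tuple[float, float]:
    """Pearson correlation of the raw intensities with t-based two-sided p."""
    x = np.asarray(her2, dtype=float)
    y = np.asarray(ck5, dtype=float)
    if x.size < 3:
        raise ValueError("correlation requires at least 3 cells")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in an intensity channel")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def exclusivity_analysis(
    cells: pd.DataFrame,
    per_tumor_median: bool = False,
) -> ExclusivityResult:
    """Full HER2/CK5 exclusivity analysis on a per-cell intensity table.

    By default the dichotomization cutoffs are the medians over all cells
    pooled across tumors; ``per_tumor_median`` dichotomizes each tumor
    against its own medians before pooling the labels.
    """
    for col in REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table missing column {col!r}")
    her2 = cells["her2_intensity"].astype(float).values
    ck5 = cells["ck5_intensity"].astype(float).values
    if per_tumor_median:
        her2_hi = np.zeros(len(cells), dtype=bool)
        ck5_hi = np.zeros(len(cells), dtype=bool)
        for _, idx in cells.groupby("tumor_id").indices.items():
            her2_hi[idx] = dichotomize(her2[idx])
            ck5_hi[idx] = dichotomize(ck5[idx])
        her2_median = math.nan
        ck5_median = math.nan
    else:
        her2_hi = dichotomize(her2)
        ck5_hi = dichotomize(ck5)
        her2_median = float(np.median(her2))
        ck5_median = float(np.median(ck5))
    table = exclusivity_table(her2_hi, ck5_hi)
    odds, p = fisher_exact(table)
    r, rp = intensity_correlation(her2, ck5)
    labels = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].values,
            "tumor_id": cells["tumor_id"].values,
            "her2_label": np.where(her2_hi, "HI", "LO"),
            "ck5_label": np.where(ck5_hi, "HI", "LO"),
        }
    )
    return ExclusivityResult(
        table=table,
        odds_ratio=odds,
        p_value=p,
        pearson_r=r,
        pearson_p=rp,
        her2_median=her2_median,
        ck5_median=ck5_median,
        labels=labels,
    )
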