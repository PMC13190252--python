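"""Immune-correlate statistics: multiplex-immunofluorescence densities,
tumor-infiltrating-lymphocyte categories, Pearson correlations and
rank-based group comparisons.

Marker-positive cell counts from multiplex immunofluorescence are normalized
to the stromal cell count of the same region, giving comparable per-sample
densities.  Densities and genomic scores are related by product-moment
correlation; density differences between clinical groups (e.g. longer versus
shorter progression-free survival) reuse the exact rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ctdna import RankSumResult, wilcoxon_rank_sum

__all__ = [
    "PearsonResult",
    "TIL_HIGH_CUT",
    "normalize_mif",
    "mif_density_table",
    "til_category",
    "pearson_r",
    "compare_density_groups",
]

#: Ordinal H&E TIL score at or above which a tumor is called TIL-high.
TIL_HIGH_CUT = 3


@dataclass(frozen=True)
class PearsonResult:
    r: float
    pvalue: float
    n: int


def normalize_mif(positive_cells: int, stromal_cells: int) -> float:
    """Marker-positive cells per stromal cell."""
    if stromal_cells <= 0:
        raise ValueError("stromal cell denominator must be positive")
    if positive_cells < 0:
        raise ValueError("negative cell count")
    return positive_cells / stromal_cells


def mif_density_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a ``density`` column (positive per stromal cell) to an mIF count
    table with columns sample_id, marker_combo, compartment, positive_cells,
    stromal_cells."""
    df = counts.copy()
    df["density"] = [
        normalize_mif(int(p), int(s))
        for p, s in zip(df["positive_cells"], df["stromal_cells"])
    ]
    return df


def til_category(score: float, cut: float = TIL_HIGH_CUT) -> str:
    """'high' at or above the declared ordinal cut, else 'low'."""
    return "high" if score >= cut else "low"


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation with the two-sided t-distribution p-value
    t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), pvalue=float(res.pvalue), n=int(x.size))


def compare_density_groups(values, labels, mode: str = "auto") -> RankSumResult:
    """Rank-sum comparison of densities between two labelled groups (e.g.
    'long' versus 'short' PFS); delegates to the shared exact Wilcoxon
    implementation."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    return wilcoxon_rank_sum(values[labels == groups[0]], values[labels == groups[1]], mode=mode)
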