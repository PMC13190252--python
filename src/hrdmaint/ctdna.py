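"""Circulating tumor DNA dynamics: per-sample mean VAF, longitudinal deltas,
molecular residual disease (mRD) classification and the exact rank-sum
comparison across progression-free-survival groups.

Liquid-biopsy panels with matched white-blood-cell sequencing flag each
variant as somatic, clonal-hematopoiesis-derived, or germline.  Only somatic
non-clonal-hematopoiesis variants describe the tumor fraction, so the mean
variant allele fraction (VAF) of a plasma sample averages over exactly those
rows; a sample with no qualifying variants is "undetected" and carries mean
VAF 0 rather than missing.  Samples that fail quality control are
non-evaluable for deltas and mRD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleVAFSummary",
    "RankSumResult",
    "MRD_THRESHOLD",
    "mean_vaf",
    "delta_mean_vaf",
    "classify_mrd",
    "wilcoxon_rank_sum",
]

#: Mean-VAF cut below which a sample is called mRD-negative.  Sits above
#: published near-undetectable values (~1e-4) and below the assay floor (1e-3).
MRD_THRESHOLD = 0.0005


@dataclass(frozen=True)
class SampleVAFSummary:
    """Per-sample mean VAF over qualifying (somatic, non-CH, non-germline)
    variants, with detection and QC status."""

    sample_id: str
    mean_vaf: float
    detected: bool
    qc_pass: bool

    def __post_init__(self) -> None:
        if not self.detected and self.mean_vaf != 0.0:
            raise ValueError("undetected sample must carry mean_vaf = 0")


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U for the first group
    pvalue: float
    method: str  # "exact" or "approximate"


def mean_vaf(observations: pd.DataFrame) -> SampleVAFSummary:
    """Arithmetic mean VAF over somatic, non-clonal-hematopoiesis,
    non-germline rows of one sample; 0 / undetected when no row qualifies."""
    ids = observations["sample_id"].unique()
    if len(ids) != 1:
        raise ValueError("observations must come from a single sample")
    qc = bool(observations["qc_pass"].all())
    qual = observations[
        observations["somatic"].astype(bool)
        & ~observations["ch"].astype(bool)
        & ~observations["germline"].astype(bool)
    ]
    if (observations["vaf"] < 0).any() or (observations["vaf"] > 1).any():
        raise ValueError("vaf outside [0, 1]")
    if len(qual):
        return SampleVAFSummary(str(ids[0]), float(qual["vaf"].mean()), True, qc)
    return SampleVAFSummary(str(ids[0]), 0.0, False, qc)


def delta_mean_vaf(t1: SampleVAFSummary, t2: SampleVAFSummary) -> float | None:
    """On-treatment minus baseline mean VAF; ``None`` (non-evaluable, not
    zero) when either sample failed QC."""
    if not (t1.qc_pass and t2.qc_pass):
        return None
    return t2.mean_vaf - t1.mean_vaf


def classify_mrd(summary: SampleVAFSummary, threshold: float = MRD_THRESHOLD) -> str:
    """'negative' below the threshold, 'positive' at or above, 'qc_fail' for
    samples that failed quality control."""
    if not summary.qc_pass:
        return "qc_fail"
    return "negative" if summary.mean_vaf < threshold else "positive"


def wilcoxon_rank_sum(group_x, group_y, mode: str = "auto") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``exact`` enumerates the full permutation distribution of the rank sum
    (the default under ``auto`` when m + n <= 20 and there are no ties);
    ``approximate`` uses the normal form with tie-corrected variance and a
    continuity correction.  Two identical groups yield p = 1 by convention.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "approximate", "auto"):
        raise ValueError("mode must be exact, approximate or auto")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return RankSumResult(statistic=float(x.size * y.size / 2.0), pvalue=1.0,
                             method="degenerate")
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 20 and not has_ties) else "approximate"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires untied data")
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(statistic=float(u), pvalue=float(p), method="exact")
    u, p = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(statistic=float(u), pvalue=float(min(p, 1.0)), method="approximate")
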