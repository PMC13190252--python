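"""Affinity-weighted neoantigen burden from MHC-I binding prediction tables.

Candidate neoantigens are peptides of 8-11 residues with predicted binding
affinity IC50 <= 500 nM (both bounds inclusive).  The per-sample burden sums
the inverse affinity 1/IC50 over all retained peptides, so strong binders
dominate; duplicate peptide rows are kept by default (an explicit dedupe
option collapses to unique sample/peptide/allele rows).  Samples are ranked
into cohort-relative quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NeoantigenBurden",
    "MIN_LENGTH",
    "MAX_LENGTH",
    "IC50_CUTOFF_NM",
    "filter_candidates",
    "weighted_burden",
    "burden_table",
    "assign_quartiles",
]

MIN_LENGTH = 8
MAX_LENGTH = 11
IC50_CUTOFF_NM = 500.0


@dataclass(frozen=True)
class NeoantigenBurden:
    """Per-sample candidate count and affinity-weighted burden (nM^-1)."""

    sample_id: str
    candidate_count: int
    weighted_burden: float


def _with_length(predictions: pd.DataFrame) -> pd.DataFrame:
    df = predictions.copy()
    if "length" not in df.columns:
        df["length"] = df["peptide"].str.len()
    elif (df["length"] != df["peptide"].str.len()).any():
        raise ValueError("length column disagrees with peptide residues")
    return df


def filter_candidates(predictions: pd.DataFrame) -> pd.DataFrame:
    """Keep peptides with 8 <= length <= 11 and IC50 <= 500 nM (inclusive)."""
    df = _with_length(predictions)
    if (df["ic50"] <= 0).any():
        raise ValueError("non-positive ic50")
    keep = df["length"].between(MIN_LENGTH, MAX_LENGTH) & (df["ic50"] <= IC50_CUTOFF_NM)
    return df[keep].reset_index(drop=True)


def weighted_burden(candidates: pd.DataFrame, sample_id: str | None = None) -> NeoantigenBurden:
    """Sum of 1/IC50 over the filtered candidates of one sample.

    Rows violating the candidate filter are rejected rather than silently
    dropped so the caller's filtering intent stays explicit.
    """
    df = _with_length(candidates)
    if sample_id is None:
        ids = df["sample_id"].unique() if "sample_id" in df.columns else []
        if len(ids) > 1:
            raise ValueError("candidates span multiple samples; pass sample_id")
        sample_id = str(ids[0]) if len(ids) else ""
    if len(df):
        if (df["ic50"] <= 0).any():
            raise ValueError("non-positive ic50")
        bad = ~(df["length"].between(MIN_LENGTH, MAX_LENGTH) & (df["ic50"] <= IC50_CUTOFF_NM))
        if bad.any():
            raise ValueError("unfiltered rows present; run filter_candidates first")
    return NeoantigenBurden(
        sample_id=sample_id,
        candidate_count=int(len(df)),
        weighted_burden=float((1.0 / df["ic50"]).sum()) if len(df) else 0.0,
    )


def burden_table(predictions: pd.DataFrame, dedupe: bool = False) -> pd.DataFrame:
    """Filter, optionally deduplicate (sample, peptide, allele), and score
    every sample; returns sample_id, candidate_count, weighted_burden and
    cohort-relative quartile (when >= 4 samples)."""
    cand = filter_candidates(predictions)
    if dedupe:
        cand = cand.drop_duplicates(subset=["sample_id", "peptide", "allele"])
    rows = []
    for sid in predictions["sample_id"].unique():
        b = weighted_burden(cand[cand["sample_id"] == sid], sample_id=sid)
        rows.append({"sample_id": sid, "candidate_count": b.candidate_count,
                     "weighted_burden": b.weighted_burden})
    out = pd.DataFrame(rows)
    if len(out) >= 4:
        out["quartile"] = assign_quartiles(out["weighted_burden"])
    return out


def assign_quartiles(values: pd.Series | np.ndarray) -> pd.Series:
    """Rank-based quartile labels 1-4; ties share the lowest applicable
    quartile (rank method 'min')."""
    v = pd.Series(values).reset_index(drop=True)
    n = len(v)
    if n < 4:
        raise ValueError("need at least 4 samples for quartiles")
    ranks = v.rank(method="min")
    q = 1 + np.floor(4 * (ranks - 1) / n).astype(int)
    q.index = pd.Series(values).index
    return q.rename("quartile")
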