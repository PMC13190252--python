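"""Best-overall-response classification and ORR/DCR summaries.

Response is classified from the best percent change in the sum of target
lesions under the solid-tumor response criteria (RECIST v1.1): progressive
disease (PD) on a new lesion or a >= +20% increase that is also >= 5 mm in
absolute terms; complete response (CR) on disappearance of all target
lesions; partial response (PR) at <= -30%; stable disease (SD) otherwise.

The objective response rate (ORR, CR+PR) and disease control rate (DCR,
CR+PR+SD) are summarized over the measurable population with exact binomial
intervals.  An exploratory mode additionally counts patients who entered with
non-measurable "undefined" disease (deep responses to prior platinum
chemotherapy) but remained progression free beyond four months, over the full
cohort denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import ProportionInterval, clopper_pearson_ci

__all__ = ["ResponseSummary", "classify_bor", "classify_bor_table", "summarize_response"]

RESPONDER_LABELS = frozenset({"CR", "PR"})
DISEASE_CONTROL_LABELS = frozenset({"CR", "PR", "SD"})


@dataclass(frozen=True)
class ResponseSummary:
    """ORR and DCR with exact intervals and their counts."""

    orr: ProportionInterval
    dcr: ProportionInterval
    n_responders: int
    n_disease_control: int
    n_denominator: int
    exploratory: bool


def classify_bor(
    best_target_change: float,
    new_lesion: bool = False,
    absolute_increase_mm: float = 0.0,
    target_sum_zero: bool = False,
) -> str:
    """Classify best overall response (CR/PR/SD/PD) from target-lesion change.

    PD dominates: a new lesion forces PD regardless of target change, as does
    a >= +20% increase that is also >= 5 mm absolute.
    """
    if best_target_change is None or pd.isna(best_target_change):
        raise ValueError("best_target_change is required for measurable disease")
    if best_target_change < -100:
        raise ValueError("best_target_change cannot be below -100%")
    if new_lesion or (best_target_change >= 20 and absolute_increase_mm >= 5):
        return "PD"
    if target_sum_zero:
        return "CR"
    if best_target_change <= -30:
        return "PR"
    return "SD"


def classify_bor_table(patients: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_bor` over a patient table.

    Expects columns ``measurable``, ``best_change_pct``, ``new_lesion``,
    ``abs_increase_mm`` and optionally ``target_sum_zero``; non-measurable
    patients get a missing label.
    """
    out = []
    for _, row in patients.iterrows():
        if not bool(row["measurable"]):
            out.append(pd.NA)
            continue
        out.append(
            classify_bor(
                row["best_change_pct"],
                bool(row.get("new_lesion", False)),
                float(row.get("abs_increase_mm", 0.0)),
                bool(row.get("target_sum_zero", False)),
            )
        )
    return pd.Series(out, index=patients.index, name="bor")


def summarize_response(
    patients: pd.DataFrame,
    include_durable_undefined: bool = False,
    level: float = 0.95,
) -> ResponseSummary:
    """Summarize ORR and DCR with exact binomial intervals.

    Primary mode restricts the denominator to measurable patients; numerators
    are CR+PR (ORR) and CR+PR+SD (DCR) from the ``bor`` column.  Patients lost
    to follow-up without a documented response carry a missing/``PD`` label and
    count as non-responders.  Exploratory mode widens the denominator to all
    patients and adds ``durable_undefined`` patients (non-measurable at
    baseline, progression free beyond the durability window) to both
    numerators.
    """
    if "bor" not in patients.columns:
        raise ValueError("patients table must carry a 'bor' column")
    measurable = patients["measurable"].astype(bool)
    bor = patients["bor"]
    responders = bor.isin(RESPONDER_LABELS) & measurable
    controlled = bor.isin(DISEASE_CONTROL_LABELS) & measurable

    if include_durable_undefined:
        durable = patients.get("durable_undefined")
        if durable is None:
            raise ValueError("exploratory mode requires a 'durable_undefined' column")
        durable = durable.fillna(False).astype(bool) & ~measurable
        denom = len(patients)
        n_resp = int((responders | durable).sum())
        n_ctrl = int((controlled | durable).sum())
    else:
        denom = int(measurable.sum())
        n_resp = int(responders.sum())
        n_ctrl = int(controlled.sum())

    if denom == 0:
        raise ValueError("empty response denominator")
    return ResponseSummary(
        orr=clopper_pearson_ci(n_resp, denom, level),
        dcr=clopper_pearson_ci(n_ctrl, denom, level),
        n_responders=n_resp,
        n_disease_control=n_ctrl,
        n_denominator=denom,
        exploratory=include_durable_undefined,
    )
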