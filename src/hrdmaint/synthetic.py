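"""Synthetic cohort generator for every pipeline stage.

Emulates the data structures of a three-cohort biomarker-stratified
maintenance trial: clinical response/survival tables, allele-specific
copy-number segments with planted scar events, MHC-binding prediction
tables, longitudinal ctDNA variant tables and multiplex-immunofluorescence
cell counts.  Defaults mirror the study conditions: cohort sizes 33/15/15;
true objective response rates 0.35/0.08/0.14; exponential progression-free
survival with medians 8.3/4.8/3.3 months and overall survival with medians
28/18/10 months; measurable-at-baseline fractions 20/33, 12/15 and 14/15.

Scar events are planted into disjoint, per-chromosome slots of a simplified
genome so the generator knows the exact scores its segments imply: each
telomeric-imbalance plant is short enough (3-8 Mb) never to create a
large-scale transition, each transition plant abuts the centromere so it
creates exactly one countable breakpoint, and each interstitial >=15 Mb LOH
plant creates exactly two (both flanks >= 10 Mb by construction), so the
truth manifest records ``lst = n_lst_plants + 2 * n_loh_plants``.

Every operation is deterministic for a fixed (config, seed) pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import GenomeBuild, simplified_build

__all__ = [
    "CohortConfig",
    "SCAR_RATES",
    "generate_clinical",
    "generate_survival_with_covariate",
    "generate_segments",
    "generate_peptides",
    "generate_ctdna",
    "generate_mif",
    "simulate_all",
]

LN2 = math.log(2.0)

#: Planted-event Poisson rates per genome by scar class (ntai, lst, loh).
SCAR_RATES = {"high": (6.0, 5.0, 3.0), "low": (1.5, 1.0, 0.5)}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the generator (see module docstring)."""

    sizes: dict = field(default_factory=lambda: {"A": 33, "B": 15, "C": 15})
    true_orr: dict = field(default_factory=lambda: {"A": 0.35, "B": 0.08, "C": 0.14})
    pfs_median: dict = field(default_factory=lambda: {"A": 8.3, "B": 4.8, "C": 3.3})
    os_median: dict = field(default_factory=lambda: {"A": 28.0, "B": 18.0, "C": 10.0})
    measurable_fraction: dict = field(
        default_factory=lambda: {"A": 20 / 33, "B": 12 / 15, "C": 14 / 15}
    )
    censoring_rate: float = 0.15
    durable_window_months: float = 4.0
    mrd_negative_fraction_long_pfs: float = 0.8
    qc_fail_rate: float = 0.05
    log_ic50_mean: float = math.log(400.0)
    log_ic50_sd: float = 1.6

    def __post_init__(self) -> None:
        for d in (self.true_orr, self.measurable_fraction):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")
        for d in (self.pfs_median, self.os_median):
            for v in d.values():
                if v <= 0:
                    raise ValueError("medians must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


def _censored_exponential(rng, n: int, median: float, censoring_rate: float):
    """Event/censoring pairs: exponential event times with the given median;
    independent exponential censoring with rate chosen so the marginal
    probability of censoring equals ``censoring_rate``."""
    rate = LN2 / median
    t_event = rng.exponential(1.0 / rate, size=n)
    if censoring_rate == 0.0:
        return t_event, np.ones(n, dtype=int)
    c_rate = rate * censoring_rate / (1.0 - censoring_rate)
    t_cens = rng.exponential(1.0 / c_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def generate_clinical(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level response table and survival table for the three cohorts.

    Best overall response is drawn per cohort-true ORR among measurable
    patients; PFS/OS are exponential with the configured medians and
    independent censoring.  Non-measurable patients with PFS beyond the
    durability window are flagged ``durable_undefined``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    pat_rows, surv_rows = [], []
    for cohort in sorted(config.sizes):
        n = config.sizes[cohort]
        pfs_t, pfs_e = _censored_exponential(
            rng, n, config.pfs_median[cohort], config.censoring_rate
        )
        os_t, os_e = _censored_exponential(
            rng, n, config.os_median[cohort], config.censoring_rate
        )
        measurable = rng.random(n) < config.measurable_fraction[cohort]
        responders = rng.random(n) < config.true_orr[cohort]
        for i in range(n):
            pid = f"{cohort}{i + 1:03d}"
            if measurable[i]:
                if responders[i]:
                    if rng.random() < 0.05:
                        bor, change, tsz = "CR", -100.0, True
                    else:
                        bor, change, tsz = "PR", float(rng.uniform(-85, -31)), False
                    new_lesion, inc = False, 0.0
                elif rng.random() < 0.7:
                    bor, change, tsz = "SD", float(rng.uniform(-29, 19)), False
                    new_lesion, inc = False, 0.0
                else:
                    bor, change, tsz = "PD", float(rng.uniform(20, 60)), False
                    new_lesion, inc = bool(rng.random() < 0.5), float(rng.uniform(5, 20))
            else:
                bor, change, tsz = pd.NA, np.nan, False
                new_lesion, inc = False, 0.0
            durable = (not measurable[i]) and pfs_t[i] > config.durable_window_months
            pat_rows.append(
                {
                    "patient_id": pid,
                    "cohort": cohort,
                    "measurable": bool(measurable[i]),
                    "bor": bor,
                    "best_change_pct": change,
                    "new_lesion": new_lesion,
                    "abs_increase_mm": inc,
                    "target_sum_zero": tsz,
                    "durable_undefined": durable,
                }
            )
            surv_rows.append(
                {
                    "patient_id": pid,
                    "cohort": cohort,
                    "pfs_months": float(pfs_t[i]),
                    "pfs_event": int(pfs_e[i]),
                    "os_months": float(os_t[i]),
                    "os_event": int(os_e[i]),
                }
            )
    return pd.DataFrame(pat_rows), pd.DataFrame(surv_rows)


def generate_survival_with_covariate(
    n: int,
    baseline_median: float,
    log_hr: float,
    seed: int = 0,
    censoring_rate: float = 0.15,
    n_strata: int = 1,
) -> pd.DataFrame:
    """Proportional-hazards cohort with one continuous covariate.

    Covariate x ~ N(0, 10^2) (a marker-like scale); hazard multiplied by
    exp(log_hr * x); optional equal-size strata with distinct baseline rates.
    Used for Cox parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 10.0, size=n)
    strata = np.repeat(np.arange(n_strata), math.ceil(n / n_strata))[:n]
    base_rate = LN2 / baseline_median
    stratum_scale = 1.0 + 0.5 * strata
    rate = base_rate * stratum_scale * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        c_rate = base_rate * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    return pd.DataFrame(
        {"time": time, "event": event, "x": x, "stratum": strata.astype(str)}
    )


# Slot geometry for planted scar events (fractions of arm positions are
# absolute coordinates on the simplified 200 Mb metacentric chromosome).
_NTAI_LEN = (3_000_000, 8_000_000)
_LST_LEN = (11_000_000, 14_000_000)
_LOH_LEN = (16_000_000, 25_000_000)
_LOH_OFFSET = 30_000_000  # gap between centromere end and LOH start


def generate_segments(
    scar_class: str = "high",
    seed: int = 0,
    genome: GenomeBuild | None = None,
    rates: tuple[float, float, float] | None = None,
    sample: str = "S1",
) -> tuple[pd.DataFrame, dict]:
    """Allele-specific segments with planted scar events and their exact
    implied scores.

    Returns the segment table (columns sample, chrom, start, end, major_cn,
    minor_cn) and a truth dict with the planted counts and the scores they
    imply under the default thresholds.
    """
    if rates is None:
        if scar_class not in SCAR_RATES:
            raise ValueError(f"scar_class must be one of {sorted(SCAR_RATES)}")
        rates = SCAR_RATES[scar_class]
    genome = genome or simplified_build()
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chrom_lengths, key=lambda c: int(c))

    ntai_slots = [(c, arm) for c in chroms for arm in ("p", "q")]
    lst_slots = [(c, arm) for c in chroms for arm in ("p", "q")]
    loh_slots = [(c, "q") for c in chroms]

    def draw(rate: float, capacity: int) -> int:
        return min(int(rng.poisson(rate)), capacity)

    n_ntai = draw(rates[0], len(ntai_slots))
    n_lst = draw(rates[1], len(lst_slots))
    n_loh = draw(rates[2], len(loh_slots))

    def pick(slots: list, k: int) -> list:
        idx = rng.choice(len(slots), size=k, replace=False)
        return [slots[i] for i in sorted(idx)]

    events: dict[str, list] = {c: [] for c in chroms}
    for c, arm in pick(ntai_slots, n_ntai):
        length = int(rng.integers(_NTAI_LEN[0], _NTAI_LEN[1] + 1))
        chrom_len = genome.chrom_lengths[c]
        if arm == "p":
            events[c].append((1, length, 2, 1))
        else:
            events[c].append((chrom_len - length + 1, chrom_len, 2, 1))
    for c, arm in pick(lst_slots, n_lst):
        length = int(rng.integers(_LST_LEN[0], _LST_LEN[1] + 1))
        cs, ce = genome.centromeres[c]
        if arm == "p":
            events[c].append((cs - length, cs - 1, 3, 1))
        else:
            events[c].append((ce + 1, ce + length, 3, 1))
    for c, _arm in pick(loh_slots, n_loh):
        length = int(rng.integers(_LOH_LEN[0], _LOH_LEN[1] + 1))
        _cs, ce = genome.centromeres[c]
        start = ce + _LOH_OFFSET + 1
        events[c].append((start, start + length - 1, 1, 0))

    rows = []
    for c in chroms:
        pos = 1
        chrom_len = genome.chrom_lengths[c]
        for start, end, major, minor in sorted(events[c]):
            if start > pos:
                rows.append((sample, c, pos, start - 1, 1, 1))
            rows.append((sample, c, start, end, major, minor))
            pos = end + 1
        if pos <= chrom_len:
            rows.append((sample, c, pos, chrom_len, 1, 1))
    seg = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
    )
    truth = {
        "planted_ntai": n_ntai,
        "planted_lst": n_lst,
        "planted_loh": n_loh,
        "ntai": n_ntai,
        "lst": n_lst + 2 * n_loh,
        "hrd_loh": n_loh,
        "hrd_sum": n_ntai + (n_lst + 2 * n_loh) + n_loh,
        "wgd": False,
    }
    return seg, truth


_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_ALLELES = ("HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02", "HLA-C*07:01")


def generate_peptides(
    n_samples: int,
    seed: int = 0,
    n_per_sample: int = 150,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Per-sample MHC-I binding prediction rows: random peptides of 7-12
    residues (straddling both sides of the 8-11 filter) with log-normal IC50
    affinities."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_samples):
        sid = f"S{s + 1:03d}"
        lengths = rng.integers(7, 13, size=n_per_sample)
        ic50 = np.exp(rng.normal(config.log_ic50_mean, config.log_ic50_sd, n_per_sample))
        for ln, a in zip(lengths, ic50):
            pep = "".join(rng.choice(_AMINO_ACIDS, size=int(ln)))
            rows.append(
                {
                    "sample_id": sid,
                    "peptide": pep,
                    "allele": _ALLELES[int(rng.integers(len(_ALLELES)))],
                    "ic50": float(a),
                }
            )
    return pd.DataFrame(rows)


def generate_ctdna(
    survival: pd.DataFrame,
    config: CohortConfig | None = None,
    seed: int = 0,
    n_patients: int = 30,
    pfs_cut_months: float = 6.0,
) -> pd.DataFrame:
    """Longitudinal ctDNA variant tables (baseline T1 and on-treatment T2).

    Patients with PFS beyond the cut are mRD-negative with the configured
    probability (near-undetectable VAFs at both timepoints); short-PFS
    patients receive positive VAF deltas.  Clonal-hematopoiesis and germline
    rows are interleaved to exercise exclusion rules; a small fraction of
    samples fail QC.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    genes = ("KRAS", "TP53", "SMAD4", "CDKN2A", "ARID1A")
    chosen = survival.head(n_patients)
    rows = []
    for _, pat in chosen.iterrows():
        long_pfs = pat["pfs_months"] > pfs_cut_months
        mrd_negative = long_pfs and rng.random() < config.mrd_negative_fraction_long_pfs
        if mrd_negative:
            t1_target = float(rng.uniform(0.0, 2.0e-4))
            t2_target = float(rng.uniform(0.0, 2.0e-4))
        else:
            t1_target = float(np.exp(rng.normal(np.log(0.002), 0.7)))
            delta = (
                float(rng.uniform(0.001, 0.013))
                if not long_pfs
                else float(rng.normal(0.0, 0.0008))
            )
            t2_target = max(t1_target + delta, 1e-5)
        for tp, target in (("T1", t1_target), ("T2", t2_target)):
            sid = f"{pat['patient_id']}-{tp}"
            qc_pass = bool(rng.random() >= config.qc_fail_rate)
            detected = target > 5e-5 or rng.random() < 0.5
            k = int(rng.integers(2, 6)) if detected else 0
            for j in range(k):
                rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": pat["patient_id"],
                        "timepoint": tp,
                        "gene": genes[int(rng.integers(len(genes)))],
                        "variant_id": f"v{j + 1}",
                        "vaf": float(min(max(target * rng.uniform(0.5, 1.5), 0.0), 1.0)),
                        "somatic": True,
                        "ch": False,
                        "germline": False,
                        "qc_pass": qc_pass,
                    }
                )
            # clonal-hematopoiesis and germline rows must never move the mean
            for j in range(int(rng.integers(0, 3))):
                rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": pat["patient_id"],
                        "timepoint": tp,
                        "gene": "DNMT3A",
                        "variant_id": f"ch{j + 1}",
                        "vaf": float(rng.uniform(0.001, 0.05)),
                        "somatic": True,
                        "ch": True,
                        "germline": False,
                        "qc_pass": qc_pass,
                    }
                )
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pat["patient_id"],
                    "timepoint": tp,
                    "gene": "BRCA2",
                    "variant_id": "g1",
                    "vaf": float(rng.uniform(0.4, 0.6)),
                    "somatic": False,
                    "ch": False,
                    "germline": True,
                    "qc_pass": qc_pass,
                }
            )
    return pd.DataFrame(rows)


_MARKERS = ("CD3+CD8+", "CD3+CD8-", "CD68+", "PD-L1+")
_BASE_DENSITY = {"CD3+CD8+": 0.02, "CD3+CD8-": 0.03, "CD68+": 0.05, "PD-L1+": 0.01}


def generate_mif(
    sample_classes: dict[str, bool] | list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """mIF cell-count tables; samples flagged HRD get ~2.5x higher cytotoxic
    T cell (CD3+CD8+) density.

    ``sample_classes`` maps sample_id -> is_hrd (a list of sample ids means
    all non-HRD).
    """
    if isinstance(sample_classes, list):
        sample_classes = {s: False for s in sample_classes}
    rng = np.random.default_rng(seed)
    rows = []
    for sid, is_hrd in sample_classes.items():
        for compartment in ("tumor", "stroma"):
            stromal = int(rng.integers(800, 3000))
            for marker in _MARKERS:
                dens = _BASE_DENSITY[marker]
                if marker == "CD3+CD8+" and is_hrd:
                    dens *= 2.5
                rows.append(
                    {
                        "sample_id": sid,
                        "marker_combo": marker,
                        "compartment": compartment,
                        "positive_cells": int(rng.poisson(dens * stromal)),
                        "stromal_cells": stromal,
                    }
                )
    return pd.DataFrame(rows)


def simulate_all(config: CohortConfig | None = None, seed: int = 0, outdir: str | Path | None = None):
    """Generate all six tables plus a truth manifest; optionally write them.

    Child seeds are spawned deterministically from ``seed`` so the tables are
    mutually independent but jointly reproducible.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    patients, survival = generate_clinical(config, seeds[0])
    seg_high, truth_high = generate_segments("high", seeds[1])
    seg_low, truth_low = generate_segments("low", seeds[2], sample="S2")
    segments = pd.concat([seg_high, seg_low], ignore_index=True)
    peptides = generate_peptides(n_samples=8, seed=seeds[3], config=config)
    ctdna = generate_ctdna(survival, config, seeds[4])
    hrd_flags = {f"M{i + 1:02d}": i < 6 for i in range(12)}
    mif = generate_mif(hrd_flags, seeds[5])
    truth = {
        "seed": seed,
        "scar_truth": {"S1": truth_high, "S2": truth_low},
        "mif_hrd_samples": [s for s, f in hrd_flags.items() if f],
    }
    tables = {
        "clinical": patients,
        "survival": survival,
        "segments": segments,
        "peptides": peptides,
        "ctdna": ctdna,
        "mif": mif,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from . import io as hio

        for name, df in tables.items():
            if name == "segments":
                hio.write_seg(df, outdir / "segments.seg")
            else:
                hio.write_table(df, outdir / f"{name}.csv")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return tables, truth
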