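"""Genomic-scar metrics on hand-built and planted-event genomes."""

import numpy as np
import pandas as pd
import pytest

from hrdmaint import synthetic
from hrdmaint.scar import (
    call_wgd,
    compute_hrd_loh,
    compute_lst,
    compute_ntai,
    merge_segments,
    scar_scores,
)

MB = 1_000_000


def seg(chrom, start, end, major, minor):
    return {"chrom": chrom, "start": start, "end": end, "major_cn": major, "minor_cn": minor}


def frame(*rows):
    return pd.DataFrame(rows)


def balanced(toy_len=100 * MB):
    return frame(seg("1", 1, toy_len, 1, 1))


def test_merge_adjacent_identical_states():
    out = merge_segments(frame(seg("1", 1, 10, 2, 1), seg("1", 11, 20, 2, 1)))
    assert len(out) == 1 and out.loc[0, "end"] == 20
    out = merge_segments(frame(seg("1", 1, 10, 2, 1), seg("1", 11, 20, 2, 0)))
    assert len(out) == 2
    five = frame(
        seg("1", 1, 10, 1, 1), seg("1", 11, 20, 2, 1), seg("1", 21, 30, 2, 1),
        seg("1", 31, 40, 1, 0), seg("2", 1, 10, 1, 1),
    )
    assert len(merge_segments(five)) == 4


def test_merge_rejects_overlap():
    with pytest.raises(ValueError):
        merge_segments(frame(seg("1", 1, 10, 1, 1), seg("1", 5, 20, 2, 1)))


def test_ntai_telomeric_rule(toy_genome):
    # AI from position 1 to 30 Mb, centromere 45-55 Mb: telomeric, no crossing
    df = frame(seg("1", 1, 30 * MB, 2, 1), seg("1", 30 * MB + 1, 100 * MB, 1, 1))
    assert compute_ntai(df, toy_genome) == 1
    # whole-chromosome AI crosses the centromere: excluded
    assert compute_ntai(frame(seg("1", 1, 100 * MB, 2, 1)), toy_genome) == 0
    assert compute_ntai(balanced(), toy_genome) == 0
    # interstitial AI does not reach a telomere
    df = frame(
        seg("1", 1, 10 * MB, 1, 1), seg("1", 10 * MB + 1, 30 * MB, 2, 1),
        seg("1", 30 * MB + 1, 100 * MB, 1, 1),
    )
    assert compute_ntai(df, toy_genome) == 0


def test_ntai_minimum_size(toy_genome):
    small = frame(seg("1", 1, 500_000, 2, 1), seg("1", 500_001, 100 * MB, 1, 1))
    assert compute_ntai(small, toy_genome) == 0
    assert compute_ntai(small, toy_genome, min_size=100_000) == 1


def test_ntai_unknown_chromosome(toy_genome):
    with pytest.raises(ValueError):
        compute_ntai(frame(seg("7", 1, 10 * MB, 2, 1)), toy_genome)


def test_lst_breakpoint_rules(toy_genome):
    # two adjacent 12 Mb segments with different states on the q arm
    df = frame(
        seg("1", 1, 55 * MB + 10, 1, 1),
        seg("1", 55 * MB + 11, 67 * MB, 2, 1),
        seg("1", 67 * MB + 1, 79 * MB, 3, 1),
        seg("1", 79 * MB + 1, 100 * MB, 1, 1),
    )
    # the leading background contributes only a 10 bp sliver to the q arm
    # (smoothed away), so the countable breakpoints are at 67M and 79M,
    # each flanked by >= 10 Mb
    assert compute_lst(df, toy_genome) == 2
    # 2 Mb interstitial piece is smoothed away, transition still counted
    df2 = frame(
        seg("1", 1, 55 * MB + 10, 1, 1),
        seg("1", 55 * MB + 11, 67 * MB, 2, 1),
        seg("1", 67 * MB + 1, 69 * MB, 1, 0),
        seg("1", 69 * MB + 1, 81 * MB, 3, 1),
        seg("1", 81 * MB + 1, 100 * MB, 1, 1),
    )
    assert compute_lst(df2, toy_genome) == 2
    assert compute_lst(balanced(), toy_genome) == 0


def test_lst_needs_both_flanks_large(toy_genome):
    # 5 Mb flank on one side: breakpoint at 60M does not count
    df = frame(
        seg("1", 55 * MB + 1, 60 * MB, 2, 1),
        seg("1", 60 * MB + 1, 100 * MB, 1, 1),
    )
    assert compute_lst(df, toy_genome) == 0


def test_hrd_loh_size_and_whole_chromosome(toy_genome):
    interstitial = frame(
        seg("1", 10 * MB, 30 * MB - 1, 1, 0), seg("1", 30 * MB, 100 * MB, 1, 1)
    )
    assert compute_hrd_loh(interstitial, toy_genome) == 1
    short = frame(seg("1", 10 * MB, 20 * MB - 1, 1, 0), seg("1", 20 * MB, 100 * MB, 1, 1))
    assert compute_hrd_loh(short, toy_genome) == 0
    whole = frame(seg("1", 1, 100 * MB, 1, 0))
    assert compute_hrd_loh(whole, toy_genome) == 0


def test_wgd_fraction_and_boundary(toy_genome):
    assert call_wgd(frame(seg("1", 1, 100 * MB, 2, 2)), toy_genome) == (True, 1.0)
    assert call_wgd(frame(seg("1", 1, 100 * MB, 1, 1)), toy_genome) == (False, 0.0)
    half = frame(seg("1", 1, 50 * MB, 2, 1), seg("1", 50 * MB + 1, 100 * MB, 1, 1))
    wgd, frac = call_wgd(half, toy_genome)
    assert frac == pytest.approx(0.5) and wgd is False  # strict inequality


def test_scar_scores_composite(toy_genome):
    from hrdmaint.genomes import GenomeBuild

    genome = GenomeBuild(
        name="toy3",
        chrom_lengths={c: 100 * MB for c in "123"},
        centromeres={c: (45 * MB, 55 * MB) for c in "123"},
    )
    # chr1: one telomeric AI (8 Mb flank, too short for an LST);
    # chr2: one 12 Mb altered block abutting the centromere on q -> 1 LST;
    # chr3: one 19 Mb interstitial LOH on p whose distal flank (1 Mb) is
    # smoothed away -> 1 LOH plus 1 LST at its proximal breakpoint
    df = frame(
        seg("1", 1, 8 * MB, 2, 1), seg("1", 8 * MB + 1, 100 * MB, 1, 1),
        seg("2", 1, 55 * MB, 1, 1), seg("2", 55 * MB + 1, 67 * MB, 2, 1),
        seg("2", 67 * MB + 1, 100 * MB, 1, 1),
        seg("3", 1, 25 * MB - 1, 1, 1), seg("3", 25 * MB, 44 * MB, 1, 0),
        seg("3", 44 * MB + 1, 100 * MB, 1, 1),
    )
    s = scar_scores(df, genome)
    assert (s.ntai, s.lst, s.hrd_loh) == (1, 2, 1)
    assert s.hrd_sum == 4
    assert s.wgd is False


def test_balanced_genome_all_zero(toy_genome):
    s = scar_scores(balanced(), toy_genome)
    assert (s.ntai, s.lst, s.hrd_loh, s.hrd_sum, s.wgd) == (0, 0, 0, 0, False)


def test_scores_invariant_to_segment_splitting(sim_genome):
    segs, _ = synthetic.generate_segments("high", seed=11)
    segs = segs.drop(columns=["sample"])
    base = scar_scores(segs, sim_genome)
    rng = np.random.default_rng(0)
    rows = []
    for _, row in segs.iterrows():
        if row["end"] - row["start"] > 2 and rng.random() < 0.5:
            mid = int(rng.integers(row["start"] + 1, row["end"]))
            a, b = dict(row), dict(row)
            a["end"], b["start"] = mid, mid + 1
            rows.extend([a, b])
        else:
            rows.append(dict(row))
    split = scar_scores(pd.DataFrame(rows), sim_genome)
    assert split == base


def test_scores_invariant_to_input_order(sim_genome):
    segs, _ = synthetic.generate_segments("high", seed=4)
    segs = segs.drop(columns=["sample"])
    shuffled = segs.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert scar_scores(shuffled, sim_genome) == scar_scores(segs, sim_genome)


def test_planted_truth_matches_computed_scores(sim_genome):
    for seed in range(50):
        for cls in ("high", "low"):
            segs, truth = synthetic.generate_segments(cls, seed=seed)
            s = scar_scores(segs.drop(columns=["sample"]), sim_genome)
            assert (s.ntai, s.lst, s.hrd_loh) == (
                truth["ntai"], truth["lst"], truth["hrd_loh"]
            ), f"{cls} seed {seed}"
            assert s.hrd_sum == s.ntai + s.lst + s.hrd_loh


def test_generator_monotone_in_scar_rate(sim_genome):
    high = [
        scar_scores(
            synthetic.generate_segments("high", seed=s)[0].drop(columns=["sample"]),
            sim_genome,
        ).hrd_sum
        for s in range(25)
    ]
    low = [
        scar_scores(
            synthetic.generate_segments("low", seed=s)[0].drop(columns=["sample"]),
            sim_genome,
        ).hrd_sum
        for s in range(25)
    ]
    assert np.mean(high) > np.mean(low)
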