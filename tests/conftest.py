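import numpy as np
import pandas as pd
import pytest

from hrdmaint import design as design_mod
from hrdmaint.genomes import simplified_build


@pytest.fixture(scope="session")
def design():
    return design_mod.default_design()


@pytest.fixture(scope="session")
def toy_genome():
    """One 100 Mb metacentric chromosome (centromere 45-55 Mb)."""
    from hrdmaint.genomes import GenomeBuild

    return GenomeBuild(
        name="toy1",
        chrom_lengths={"1": 100_000_000},
        centromeres={"1": (45_000_000, 55_000_000)},
    )


@pytest.fixture(scope="session")
def sim_genome():
    return simplified_build()


@pytest.fixture()
def cohort_a_patients():
    """A cohort mirroring the measurable/undefined bookkeeping of the primary
    cohort: 20 measurable (7 PR, 9 SD, 4 PD) plus 13 non-measurable of whom
    10 are durably progression free."""
    rows = []
    bors = ["PR"] * 7 + ["SD"] * 9 + ["PD"] * 4
    for i, bor in enumerate(bors):
        rows.append(
            {
                "patient_id": f"A{i:03d}",
                "cohort": "A",
                "measurable": True,
                "bor": bor,
                "durable_undefined": False,
            }
        )
    for i in range(13):
        rows.append(
            {
                "patient_id": f"A9{i:02d}",
                "cohort": "A",
                "measurable": False,
                "bor": pd.NA,
                "durable_undefined": i < 10,
            }
        )
    return pd.DataFrame(rows)


def brute_force_two_stage(n1, n2, continue_min, final_min, p):
    """Independent double-loop enumeration of the single-endpoint two-stage
    rule using only math.comb (no scipy)."""
    from math import comb

    def pmf(k, n):
        return comb(n, k) * p**k * (1 - p) ** (n - k)

    total = 0.0
    for k1 in range(continue_min, n1 + 1):
        for k2 in range(0, n2 + 1):
            if k1 + k2 >= final_min:
                total += pmf(k1, n1) * pmf(k2, n2)
    return total


@pytest.fixture(scope="session")
def two_stage_oracle():
    return brute_force_two_stage


def enumerate_rank_sum_p(x, y):
    """Two-sided exact Wilcoxon p by full enumeration of all C(m+n, m)
    assignments of the pooled ranks to group x (untied data only)."""
    import itertools

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    assert len(np.unique(pooled)) == pooled.size, "oracle requires untied data"
    ranks = pooled.argsort().argsort() + 1
    m = len(x)
    w_obs = ranks[:m].sum()
    lo = hi = total = 0
    for combo in itertools.combinations(range(pooled.size), m):
        w = sum(ranks[i] for i in combo)
        total += 1
        lo += w <= w_obs
        hi += w >= w_obs
    return min(1.0, 2.0 * min(lo, hi) / total)


@pytest.fixture(scope="session")
def rank_sum_oracle():
    return enumerate_rank_sum_p
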