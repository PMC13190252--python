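"""Two-stage dual-endpoint design: decisions, exact enumeration, intervals."""

import numpy as np
import pytest
from math import comb

from hrdmaint.design import (
    TwoStageDualDesign,
    clopper_pearson_ci,
    default_design,
    early_termination_prob,
    evaluate_final,
    evaluate_stage1,
    joint_outcome_mc,
    marginal_two_stage_prob,
    operating_characteristics,
    proportion_margin_of_error,
)


@pytest.mark.parametrize(
    "responses,pfs,expected",
    [(7, 10, "continue"), (5, 13, "stop"), (0, 14, "continue"), (6, 0, "continue"), (5, 14, "continue")],
)
def test_stage1_continues_on_either_endpoint(design, responses, pfs, expected):
    assert evaluate_stage1(responses, pfs, design) == expected


@pytest.mark.parametrize(
    "responses,pfs,expected",
    [(12, 0, "active"), (11, 22, "inactive"), (0, 23, "active")],
)
def test_final_activity_on_either_endpoint(design, responses, pfs, expected):
    assert evaluate_final(responses, pfs, design) == expected


def test_decision_inputs_validated(design):
    with pytest.raises(ValueError):
        evaluate_stage1(-1, 0, design)
    with pytest.raises(ValueError):
        evaluate_stage1(21, 0, design)
    with pytest.raises(ValueError):
        evaluate_final(34, 0, design)


def test_invalid_design_rejected():
    with pytest.raises(ValueError):
        TwoStageDualDesign(20, 13, 25, 14, 12, 23, 0.2, 0.53, 0.43, 0.77)
    with pytest.raises(ValueError):
        TwoStageDualDesign(20, 13, 6, 14, 12, 23, 0.5, 0.53, 0.43, 0.77)  # p0 > p1


@pytest.mark.parametrize(
    "n1,n2,c,f",
    [(20, 13, 14, 23), (20, 13, 6, 12), (10, 5, 3, 6), (25, 25, 10, 30), (5, 0, 2, 3)],
)
@pytest.mark.parametrize("p", [0.0, 0.1, 0.2, 0.43, 0.53, 0.77, 0.9, 1.0])
def test_marginal_prob_equals_double_loop_oracle(two_stage_oracle, n1, n2, c, f, p):
    got = marginal_two_stage_prob(n1, n2, c, f, p)
    assert got == pytest.approx(two_stage_oracle(n1, n2, c, f, p), abs=1e-12)


def test_marginal_prob_monotone_in_p(design):
    grid = np.linspace(0, 1, 41)
    vals = [
        marginal_two_stage_prob(design.n1, design.n2, design.pfs_continue_min,
                                design.pfs_final_min, p)
        for p in grid
    ]
    assert np.all(np.diff(vals) >= -1e-12)


def test_marginal_prob_zero_when_continuation_impossible():
    assert marginal_two_stage_prob(20, 13, 1, 12, 0.0) == 0.0


def test_early_termination_complement_is_continue_probability(design):
    # P(stop) + P(continue) = 1 with P(continue) = 1 - prod of stage-1 stop
    # probabilities; verified against an independent double sum over the
    # joint stage-1 outcome lattice.
    p_orr, p_pfs = 0.2, 0.53

    def pmf(k, n, p):
        return comb(n, k) * p**k * (1 - p) ** (n - k)

    p_stop = sum(
        pmf(r, design.n1, p_orr) * pmf(s, design.n1, p_pfs)
        for r in range(design.orr_continue_min)
        for s in range(design.pfs_continue_min)
    )
    assert early_termination_prob(design, p_orr, p_pfs) == pytest.approx(p_stop, abs=1e-12)
    assert early_termination_prob(design, 0, 0) == 1.0
    assert early_termination_prob(design, 1, 1) == 0.0


def test_operating_characteristics_consistency(design):
    oc = operating_characteristics(design)
    assert oc.alpha_sum == pytest.approx(oc.alpha_orr + oc.alpha_pfs)
    # p0 = p1 collapses power onto alpha
    flat = TwoStageDualDesign(20, 13, 6, 14, 12, 23, 0.3, 0.5, 0.3, 0.5)
    oc_flat = operating_characteristics(flat)
    assert oc_flat.alpha_orr == pytest.approx(oc_flat.power_orr)
    assert oc_flat.alpha_pfs == pytest.approx(oc_flat.power_pfs)


def test_joint_mc_degenerate_and_deterministic(design):
    est = joint_outcome_mc(design, 0.0, 0.0, n_sims=1000, seed=1)
    assert est.p_early_stop == 1.0 and est.p_active == 0.0
    a = joint_outcome_mc(design, 0.3, 0.6, n_sims=5000, seed=42)
    b = joint_outcome_mc(design, 0.3, 0.6, n_sims=5000, seed=42)
    assert a == b


def test_joint_mc_agrees_with_exact_marginals(design):
    est = joint_outcome_mc(design, design.p0_orr, design.p0_pfs, n_sims=1_000_000, seed=7)
    exact = early_termination_prob(design, design.p0_orr, design.p0_pfs)
    assert abs(est.p_early_stop - exact) <= 3 * est.se_early_stop
    # OR rule dominates each marginal rule under the alternatives
    est_alt = joint_outcome_mc(design, design.p1_orr, design.p1_pfs, n_sims=1_000_000, seed=8)
    oc = operating_characteristics(design)
    assert est_alt.p_active >= max(oc.power_orr, oc.power_pfs) - 3 * est_alt.se_active


@pytest.mark.parametrize(
    "x,n,lo_pct,hi_pct",
    [(7, 20, 15, 59), (2, 14, 2, 43), (1, 12, 0, 38)],
)
def test_clopper_pearson_examples(x, n, lo_pct, hi_pct):
    ci = clopper_pearson_ci(x, n, 0.95)
    assert round(100 * ci.lower) == lo_pct
    assert round(100 * ci.upper) == hi_pct
    assert ci.lower <= ci.point <= ci.upper


def test_clopper_pearson_boundaries_and_errors():
    assert clopper_pearson_ci(0, 12).lower == 0.0
    assert clopper_pearson_ci(12, 12).upper == 1.0
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 4)


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for x, n in [(3, 10), (7, 20), (0, 5), (5, 5), (17, 33)]:
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        ci = clopper_pearson_ci(x, n, 0.95)
        assert ci.lower == pytest.approx(float(lo), abs=1e-10)
        assert ci.upper == pytest.approx(float(hi), abs=1e-10)


def test_clopper_pearson_exact_coverage():
    # exact coverage >= nominal for all x-summed binomial configurations
    level = 0.95
    for n in (5, 12, 20, 30):
        for p in np.arange(0.1, 0.91, 0.1):
            cover = 0.0
            for x in range(n + 1):
                ci = clopper_pearson_ci(x, n, level)
                if ci.lower <= p <= ci.upper:
                    cover += comb(n, x) * p**x * (1 - p) ** (n - x)
            assert cover >= level - 1e-12


def test_margin_of_error():
    assert proportion_margin_of_error(15, 0.95, 0.5) == pytest.approx(0.253, abs=5e-4)
    assert proportion_margin_of_error(100, 0.95, 0.5) == pytest.approx(0.098, abs=5e-4)
    assert proportion_margin_of_error(50, 0.95, 0.0) == 0.0
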