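"""Dual-endpoint two-stage phase 2 design and its exact operating characteristics.

The design enrolls ``n1`` patients in a first stage and continues to a second
stage of ``n2`` patients if *either* the number of objective responses or the
number of six-month progression-free (PFS) successes reaches its continuation
threshold.  At the end of the trial the regimen is declared active if either
endpoint reaches its final threshold.  Because the decision rule is an OR over
the two endpoints, each endpoint's type I error and power can be computed
marginally by exact binomial enumeration of the corresponding single-endpoint
two-stage rule; joint quantities (which depend on the cross-endpoint
continuation path) are available by Monte Carlo via :func:`joint_outcome_mc`.

Exact binomial (Clopper–Pearson) interval estimation for response proportions
and the normal-approximation planning margin of error live here as well, since
they are part of the same design/analysis toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TwoStageDualDesign",
    "OperatingCharacteristics",
    "ProportionInterval",
    "JointOutcomeEstimate",
    "default_design",
    "evaluate_stage1",
    "evaluate_final",
    "marginal_two_stage_prob",
    "early_termination_prob",
    "operating_characteristics",
    "joint_outcome_mc",
    "clopper_pearson_ci",
    "proportion_margin_of_error",
]


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class TwoStageDualDesign:
    """A two-stage design with OR-combined objective-response and PFS rules.

    Parameters
    ----------
    n1, n2
        Stage-1 and stage-2 sample sizes (patients).
    orr_continue_min, pfs_continue_min
        Minimum stage-1 responses / six-month-PFS successes to continue.
    orr_final_min, pfs_final_min
        Minimum total successes (over ``n1 + n2`` patients) to declare the
        regimen active.
    p0_orr, p0_pfs
        Null (uninteresting) per-patient success probabilities.
    p1_orr, p1_pfs
        Alternative (target) per-patient success probabilities.
    """

    n1: int
    n2: int
    orr_continue_min: int
    pfs_continue_min: int
    orr_final_min: int
    pfs_final_min: int
    p0_orr: float
    p0_pfs: float
    p1_orr: float
    p1_pfs: float

    def __post_init__(self) -> None:
        if self.n1 <= 0:
            raise ValueError("n1 must be positive")
        if self.n2 < 0:
            raise ValueError("n2 must be non-negative")
        for name in ("orr_continue_min", "pfs_continue_min"):
            v = getattr(self, name)
            if not 0 <= v <= self.n1:
                raise ValueError(f"{name} must lie in [0, n1]")
        n_total = self.n1 + self.n2
        for name in ("orr_final_min", "pfs_final_min"):
            if not 0 <= getattr(self, name) <= n_total:
                raise ValueError(f"{name} must lie in [0, n1 + n2]")
        for ep in ("orr", "pfs"):
            p0, p1 = getattr(self, f"p0_{ep}"), getattr(self, f"p1_{ep}")
            _check_prob(f"p0_{ep}", p0)
            _check_prob(f"p1_{ep}", p1)
            if p0 > p1:
                raise ValueError(f"p0_{ep} must not exceed p1_{ep}")

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2


def default_design() -> TwoStageDualDesign:
    """The cohort-A maintenance design: 20 + 13 patients, continue on >=6
    responses or >=14 six-month-PFS successes, active on >=12 responses or
    >=23/33 PFS successes.

    The null six-month PFS rate is the historical maintenance benchmark 0.53.
    The null ORR ships as 0.20, the value consistent with the design's stated
    marginal type I error (0.02) and early-termination probability (0.73); the
    historical benchmark 0.23 can be selected explicitly but reproduces
    neither.  Alternatives are 0.43 (ORR) and 0.77 (six-month PFS).
    """
    return TwoStageDualDesign(
        n1=20,
        n2=13,
        orr_continue_min=6,
        pfs_continue_min=14,
        orr_final_min=12,
        pfs_final_min=23,
        p0_orr=0.20,
        p0_pfs=0.53,
        p1_orr=0.43,
        p1_pfs=0.77,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Marginal error/power summary of a :class:`TwoStageDualDesign`."""

    alpha_orr: float
    alpha_pfs: float
    power_orr: float
    power_pfs: float
    pet_null: float
    alpha_sum: float


@dataclass(frozen=True)
class ProportionInterval:
    """A point estimate with a two-sided confidence interval for a proportion."""

    point: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"interval must satisfy 0 <= lower <= point <= upper <= 1, got "
                f"({self.lower}, {self.point}, {self.upper})"
            )


@dataclass(frozen=True)
class JointOutcomeEstimate:
    """Monte Carlo estimate of joint trial outcome probabilities."""

    p_active: float
    p_early_stop: float
    se_active: float
    se_early_stop: float
    n_sims: int


def evaluate_stage1(
    responses: int, pfs_successes: int, design: TwoStageDualDesign
) -> str:
    """Stage-1 decision: ``"continue"`` iff either endpoint reaches its
    continuation threshold, else ``"stop"``."""
    for name, v in (("responses", responses), ("pfs_successes", pfs_successes)):
        if not 0 <= v <= design.n1:
            raise ValueError(f"{name} must lie in [0, n1={design.n1}], got {v}")
    ok = (
        responses >= design.orr_continue_min
        or pfs_successes >= design.pfs_continue_min
    )
    return "continue" if ok else "stop"


def evaluate_final(
    responses_total: int, pfs_total: int, design: TwoStageDualDesign
) -> str:
    """Final decision: ``"active"`` iff either endpoint reaches its final
    threshold, else ``"inactive"``."""
    n = design.n_total
    for name, v in (("responses_total", responses_total), ("pfs_total", pfs_total)):
        if not 0 <= v <= n:
            raise ValueError(f"{name} must lie in [0, n1+n2={n}], got {v}")
    ok = responses_total >= design.orr_final_min or pfs_total >= design.pfs_final_min
    return "active" if ok else "inactive"


def marginal_two_stage_prob(
    n1: int, n2: int, continue_min: int, final_min: int, p: float
) -> float:
    """P(pass stage 1 AND total successes >= final_min) for one endpoint alone.

    Exact enumeration: sum over stage-1 success counts ``k`` from
    ``continue_min`` to ``n1`` of ``BinomPMF(k; n1, p) * P(S2 >= final_min - k)``
    with ``S2 ~ Binom(n2, p)``.  At a null ``p`` this is the endpoint's
    marginal type I error; at an alternative it is the marginal power.  No
    normal approximation is involved.
    """
    if n1 <= 0 or n2 < 0:
        raise ValueError("require n1 > 0 and n2 >= 0")
    if not 0 <= continue_min <= n1:
        raise ValueError("continue_min must lie in [0, n1]")
    if final_min > n1 + n2:
        raise ValueError("final_min cannot exceed n1 + n2")
    _check_prob("p", p)
    k = np.arange(continue_min, n1 + 1)
    # sf(final_min - k - 1) = P(S2 >= final_min - k); negative arguments give 1
    return float(
        np.sum(stats.binom.pmf(k, n1, p) * stats.binom.sf(final_min - k - 1, n2, p))
    )


def early_termination_prob(
    design: TwoStageDualDesign, p_orr: float, p_pfs: float
) -> float:
    """Probability the trial stops after stage 1, assuming the two endpoint
    outcomes are independent: both stage-1 counts fall below their
    continuation thresholds."""
    _check_prob("p_orr", p_orr)
    _check_prob("p_pfs", p_pfs)
    return float(
        stats.binom.cdf(design.orr_continue_min - 1, design.n1, p_orr)
        * stats.binom.cdf(design.pfs_continue_min - 1, design.n1, p_pfs)
    )


def operating_characteristics(design: TwoStageDualDesign) -> OperatingCharacteristics:
    """Exact marginal operating characteristics of the dual-endpoint design.

    Marginal alphas/powers evaluate each endpoint's two-stage rule in
    isolation (continuation and final thresholds for that endpoint only); the
    early-termination probability is the independence product of the two
    stage-1 stopping probabilities at the nulls.  ``alpha_sum`` is the
    Bonferroni-style bound on the overall type I error of the OR rule.
    """
    a_orr = marginal_two_stage_prob(
        design.n1, design.n2, design.orr_continue_min, design.orr_final_min, design.p0_orr
    )
    a_pfs = marginal_two_stage_prob(
        design.n1, design.n2, design.pfs_continue_min, design.pfs_final_min, design.p0_pfs
    )
    pw_orr = marginal_two_stage_prob(
        design.n1, design.n2, design.orr_continue_min, design.orr_final_min, design.p1_orr
    )
    pw_pfs = marginal_two_stage_prob(
        design.n1, design.n2, design.pfs_continue_min, design.pfs_final_min, design.p1_pfs
    )
    pet = early_termination_prob(design, design.p0_orr, design.p0_pfs)
    return OperatingCharacteristics(
        alpha_orr=a_orr,
        alpha_pfs=a_pfs,
        power_orr=pw_orr,
        power_pfs=pw_pfs,
        pet_null=pet,
        alpha_sum=a_orr + a_pfs,
    )


def joint_outcome_mc(
    design: TwoStageDualDesign,
    p_orr: float,
    p_pfs: float,
    n_sims: int,
    seed: int,
) -> JointOutcomeEstimate:
    """Monte Carlo estimate of P(declared active) and P(early stop) under the
    full OR rule, with independent per-patient Bernoulli outcomes.

    The joint rule allows an endpoint that failed its own continuation
    threshold to reach its final threshold because the *other* endpoint kept
    the trial alive; these composite probabilities have no simple closed form
    and are estimated by simulation.  Deterministic for a fixed seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    _check_prob("p_orr", p_orr)
    _check_prob("p_pfs", p_pfs)
    rng = np.random.default_rng(seed)
    # Stage counts are sums of independent per-patient Bernoulli draws.
    r1 = rng.binomial(design.n1, p_orr, size=n_sims)
    s1 = rng.binomial(design.n1, p_pfs, size=n_sims)
    cont = (r1 >= design.orr_continue_min) | (s1 >= design.pfs_continue_min)
    r2 = rng.binomial(design.n2, p_orr, size=n_sims)
    s2 = rng.binomial(design.n2, p_pfs, size=n_sims)
    active = cont & (
        (r1 + r2 >= design.orr_final_min) | (s1 + s2 >= design.pfs_final_min)
    )
    p_active = float(active.mean())
    p_stop = float((~cont).mean())
    se = lambda p: float(np.sqrt(p * (1 - p) / n_sims))  # noqa: E731
    return JointOutcomeEstimate(
        p_active=p_active,
        p_early_stop=p_stop,
        se_active=se(p_active),
        se_early_stop=se(p_stop),
        n_sims=n_sims,
    )


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95) -> ProportionInterval:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval.

    Lower bound is the ``(1-level)/2`` quantile of Beta(successes,
    n - successes + 1) (exactly 0 when successes = 0); upper bound is the
    ``(1+level)/2`` quantile of Beta(successes + 1, n - successes) (exactly 1
    when successes = n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(a, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1.0 - a, successes + 1, n - successes))
    return ProportionInterval(point=successes / n, lower=lower, upper=upper, level=level)


def proportion_margin_of_error(n: int, level: float = 0.95, p_planning: float = 0.5) -> float:
    """Normal-approximation half-width z * sqrt(p(1-p)/n) used for planning
    descriptive cohorts (e.g. +/-25% at n=15, level 0.95, p=0.5)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    _check_prob("p_planning", p_planning)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(z * np.sqrt(p_planning * (1.0 - p_planning) / n))
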