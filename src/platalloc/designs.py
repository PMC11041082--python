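"""Platform-trial designs and the closed-form variance engine.

The trial evaluated here has two experimental arms (1 and 2) and a shared
control (0).  Arm 1 recruits from the start; arm 2 enters later and may
finish after arm 1 does.  This partitions the trial into up to three
periods with active-arm sets ``I1={0,1}``, ``I2={0,1,2}``, ``I3={0,2}``.
A design is described by the total sample size ``N``, the period fractions
``r = (r1, r2, r3)`` and the within-period allocation probabilities
``p[s][i]``.

Treatment effects are estimated by period-stratified estimators: the
treatment-control mean difference is computed per period and combined with
inverse-variance weights.  Stratification makes the estimators unbiased
under additive time trends that affect all arms equally, which is the
reason this analysis is recommended whenever allocation ratios change over
time.  For arm ``i`` the relevant periods are ``i`` and ``i+1``.

All variance formulas here work on *expected* (real-valued) group sizes
``n_{i,s} = N * r_s * p_{i,s}``; integer rounding is the business of
:mod:`platalloc.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ARM_SETS",
    "DesignError",
    "InestimableEffectError",
    "PlatformDesign",
    "VarianceReport",
    "period_effect_variance",
    "stratification_weights",
    "var_stratified_cc",
    "var_ncc",
    "rho_coefficient",
]

#: Active arms per period (period index 1..3 maps to position 0..2).
ARM_SETS = (frozenset({0, 1}), frozenset({0, 1, 2}), frozenset({0, 2}))

_TOL = 1e-12


class DesignError(ValueError):
    """Raised when a design violates the simplex/positivity invariants."""


class InestimableEffectError(RuntimeError):
    """Raised when a period effect cannot be estimated (a group is empty).

    This is distinct from :class:`DesignError`: the design itself is valid,
    but the requested quantity does not exist for it.
    """


def _g(a: float, b: float) -> float:
    """Harmonic-mean-type precision kernel ``a*b/(a+b)``.

    ``g(a, 0) = g(0, b) = 0``: a period in which one of the two groups gets
    no patients contributes no information to the comparison.
    """
    if a <= 0.0 or b <= 0.0:
        return 0.0
    return a * b / (a + b)


@dataclass(frozen=True)
class PlatformDesign:
    """A two-experimental-arm platform trial design with a shared control.

    Parameters
    ----------
    N:
        Total sample size (a positive count; real values are accepted
        because the variance algebra treats sample sizes as continuous).
    r:
        Period fractions ``(r1, r2, r3)``, nonnegative, summing to 1.
    p:
        Allocation probabilities as three rows (one per period) of three
        entries ``(control, arm1, arm2)``.  Each row sums to 1 and arms
        outside the period's active set must have probability 0.
    sigma:
        Per-arm response standard deviations ``(sigma0, sigma1, sigma2)``.
    """

    N: float
    r: tuple[float, float, float]
    p: tuple[tuple[float, float, float], ...]
    sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", tuple(float(x) for x in self.r))
        object.__setattr__(
            self, "p", tuple(tuple(float(x) for x in row) for row in self.p)
        )
        object.__setattr__(self, "sigma", tuple(float(x) for x in self.sigma))
        if not self.N > 0:
            raise DesignError(f"N must be positive, got {self.N}")
        if len(self.r) != 3 or any(x < -_TOL for x in self.r):
            raise DesignError(f"period fractions must be >= 0, got {self.r}")
        if abs(sum(self.r) - 1.0) > _TOL:
            raise DesignError(f"period fractions must sum to 1, got {self.r}")
        if len(self.p) != 3 or any(len(row) != 3 for row in self.p):
            raise DesignError("p must be a 3x3 matrix (periods x arms)")
        for s, row in enumerate(self.p, start=1):
            if any(x < -_TOL for x in row):
                raise DesignError(f"allocation probabilities in period {s} must be >= 0")
            if abs(sum(row) - 1.0) > _TOL:
                raise DesignError(
                    f"allocation probabilities in period {s} must sum to 1, got {row}"
                )
            for i in range(3):
                if i not in ARM_SETS[s - 1] and row[i] > _TOL:
                    raise DesignError(
                        f"arm {i} is not active in period {s} but has p={row[i]}"
                    )
        if len(self.sigma) != 3 or any(x <= 0 for x in self.sigma):
            raise DesignError(f"sigma must be positive, got {self.sigma}")

    # -- convenience accessors -------------------------------------------------

    def n(self, arm: int, period: int) -> float:
        """Expected group size ``N * r_s * p_{i,s}`` (real-valued)."""
        return self.N * self.r[period - 1] * self.p[period - 1][arm]

    @property
    def equal_sigmas(self) -> bool:
        s0 = self.sigma[0]
        return all(abs(s - s0) <= 1e-12 * s0 for s in self.sigma)

    def variance_ratio(self, arm: int) -> float:
        """``sigma_i^2 / sigma_0^2`` for experimental arm ``i``."""
        return (self.sigma[arm] / self.sigma[0]) ** 2

    def arm_periods(self, arm: int) -> tuple[int, int]:
        """The two periods in which experimental arm ``i`` is active."""
        if arm not in (1, 2):
            raise ValueError(f"experimental arm must be 1 or 2, got {arm}")
        return (arm, arm + 1)


@dataclass
class VarianceReport:
    """Closed-form variances of the two treatment-effect estimators.

    ``per_period_var`` holds ``sigma_{i,s}^2``, the variance of the period-s
    mean difference for arm ``i``; ``weights`` the inverse-variance weights
    used to combine them (they sum to 1 per arm).  ``var_arm1`` and
    ``var_arm2`` are the resulting effect-estimator variances; an arm with
    no allocation anywhere is flagged with an infinite variance rather than
    an exception.
    """

    per_period_var: dict[tuple[int, int], float]
    weights: dict[tuple[int, int], float]
    var_arm1: float
    var_arm2: float
    analysis_mode: str = "concurrent-only"
    notes: dict = field(default_factory=dict)

    def var(self, arm: int) -> float:
        return self.var_arm1 if arm == 1 else self.var_arm2


def period_effect_variance(design: PlatformDesign, arm: int, period: int) -> float:
    """Variance of the period-``s`` mean difference for experimental ``arm``.

    Returns ``sigma_i^2 / n_{i,s} + sigma_0^2 / n_{0,s}`` on expected group
    sizes.  Raises :class:`InestimableEffectError` if either group is empty.
    """
    if period not in design.arm_periods(arm):
        raise ValueError(f"arm {arm} is not active in period {period}")
    n_i = design.n(arm, period)
    n_0 = design.n(0, period)
    if n_i <= 0 or n_0 <= 0:
        raise InestimableEffectError(
            f"inestimable period effect: empty group in period {period} "
            f"(n_arm={n_i}, n_control={n_0})"
        )
    return design.sigma[arm] ** 2 / n_i + design.sigma[0] ** 2 / n_0


def stratification_weights(var_a: float, var_b: float) -> tuple[float, float]:
    """Inverse-variance weights for combining two period-wise estimates.

    ``w_a = (1/var_a) / (1/var_a + 1/var_b)``.  An infinite variance gets
    weight 0 (the arm is absent from that period); two infinite variances
    mean the arm was never dosed and no weights exist.
    """
    inf_a = math.isinf(var_a)
    inf_b = math.isinf(var_b)
    if inf_a and inf_b:
        raise ValueError("arm absent from both periods: no weights defined")
    if inf_a:
        return (0.0, 1.0)
    if inf_b:
        return (1.0, 0.0)
    if var_a <= 0 or var_b <= 0:
        raise ValueError("period variances must be positive")
    inv_a, inv_b = 1.0 / var_a, 1.0 / var_b
    return (inv_a / (inv_a + inv_b), inv_b / (inv_a + inv_b))


def _period_var_or_inf(design: PlatformDesign, arm: int, period: int) -> float:
    try:
        return period_effect_variance(design, arm, period)
    except InestimableEffectError:
        return math.inf


def _cc_precision(design: PlatformDesign, arm: int) -> float:
    """Scaled precision of the stratified estimator for ``arm``.

    In units of ``N / sigma_0^2``:
    ``sum_s r_s * p_{i,s} p_{0,s} / (p_{i,s} + (sigma_i^2/sigma_0^2) p_{0,s})``.
    For equal variances the summand reduces to ``r_s * g(p_{i,s}, p_{0,s})``.
    """
    rho = design.variance_ratio(arm)
    total = 0.0
    for s in design.arm_periods(arm):
        a = design.p[s - 1][arm]
        b = design.p[s - 1][0]
        if a > 0.0 and b > 0.0:
            total += design.r[s - 1] * a * b / (a + rho * b)
    return total


def var_stratified_cc(design: PlatformDesign) -> VarianceReport:
    """Variances of both stratified estimators using concurrent controls only.

    For equal variances the arm-``i`` variance is
    ``sigma^2/N * [ r_i g(p_{i,i}, p_{0,i}) + r_{i+1} g(p_{i,i+1}, p_{0,i+1}) ]^{-1}``
    with ``g(a,b) = ab/(a+b)``; unequal per-arm variances generalize the
    kernel to ``a*b/(a + (sigma_i^2/sigma_0^2) b)`` with a ``sigma_0^2``
    prefactor.  This is identical to combining the per-period variances with
    the inverse-variance stratification weights.
    """
    per_period: dict[tuple[int, int], float] = {}
    weights: dict[tuple[int, int], float] = {}
    variances = {}
    for arm in (1, 2):
        s_a, s_b = design.arm_periods(arm)
        v_a = _period_var_or_inf(design, arm, s_a)
        v_b = _period_var_or_inf(design, arm, s_b)
        per_period[(arm, s_a)] = v_a
        per_period[(arm, s_b)] = v_b
        prec = _cc_precision(design, arm)
        if prec > 0.0:
            w_a, w_b = stratification_weights(v_a, v_b)
            weights[(arm, s_a)] = w_a
            weights[(arm, s_b)] = w_b
            variances[arm] = design.sigma[0] ** 2 / (design.N * prec)
        else:
            # Arm never dosed together with a control: flagged, not raised.
            weights[(arm, s_a)] = math.nan
            weights[(arm, s_b)] = math.nan
            variances[arm] = math.inf
    return VarianceReport(
        per_period_var=per_period,
        weights=weights,
        var_arm1=variances[1],
        var_arm2=variances[2],
        analysis_mode="concurrent-only",
    )


def _ncc_precision(r: tuple[float, float, float], p) -> float:
    """Scaled precision (units ``N/sigma^2``) of the arm-2 estimator when
    non-concurrent controls are used via the period-adjusted regression.

    ``r3*q_{2,3} + r2*q_{2,2} - r2^2 p_{1,2}^2 p_{2,2}^2 /
    (r1*q_{1,1} + r2*q_{1,2})`` with ``q_{i,s} = p_{i,s}(1-p_{i,s})``.
    The subtracted term is the price of estimating the period-2 effect; it
    vanishes when arm 1 is absent from period 2.
    """
    q = lambda x: x * (1.0 - x)  # noqa: E731
    r1, r2, r3 = r
    base = r3 * q(p[2][2]) + r2 * q(p[1][2])
    num = r2**2 * p[1][1] ** 2 * p[1][2] ** 2
    if num > 0.0:
        den = r1 * q(p[0][1]) + r2 * q(p[1][1])
        base -= num / den
    return base


def var_ncc(design: PlatformDesign) -> VarianceReport:
    """Variances when arm 2 is analyzed with non-concurrent controls.

    Arm 2 borrows the pre-entry (period-1) control data through the
    period-adjusted regression on all three periods; its variance has the
    closed form implemented in :func:`_ncc_precision` and always satisfies
    ``Var(arm 2, ncc) <= Var(arm 2, concurrent-only)``.  Arm 1 is evaluated
    when its recruitment ends, so it keeps the concurrent-only analysis.

    The formula is derived for a common response variance; unequal
    ``sigma`` is refused.  Requires ``r1 > 0`` (otherwise there are no
    non-concurrent controls and the concurrent analysis applies).
    """
    if not design.equal_sigmas:
        raise DesignError(
            "non-concurrent-control variance formulas require equal variances "
            f"across arms, got sigma={design.sigma}"
        )
    if design.r[0] <= 0.0:
        raise DesignError(
            "non-concurrent-control analysis requires r1 > 0; with r1 = 0 "
            "there are no non-concurrent controls"
        )
    cc = var_stratified_cc(design)
    prec2 = _ncc_precision(design.r, design.p)
    var2 = design.sigma[0] ** 2 / (design.N * prec2) if prec2 > 0.0 else math.inf
    return VarianceReport(
        per_period_var=cc.per_period_var,
        weights={k: w for k, w in cc.weights.items() if k[0] == 1},
        var_arm1=cc.var_arm1,
        var_arm2=var2,
        analysis_mode="non-concurrent",
        notes={"var_arm2_concurrent_only": cc.var_arm2},
    )


def rho_coefficient(n01: float, n02: float, n11: float, n12: float) -> float:
    """Weight of the between-period correction in the two-period NCC estimator.

    In a two-period design the regression-based arm-2 estimator can be
    written as ``theta2_tilde = theta_hat_{2,2} + rho * (theta_hat_{1,1} -
    theta_hat_{1,2})`` where ``rho = n_{0,2}^{-1} / (n_{0,1}^{-1} +
    n_{0,2}^{-1} + n_{1,1}^{-1} + n_{1,2}^{-1})``: the arm-1 effect measured
    twice calibrates the period effect, and the correction matters in
    proportion to how noisy the period-2 control mean is.
    """
    counts = (n01, n02, n11, n12)
    if any(c <= 0 for c in counts):
        raise ValueError(f"all four group sizes must be positive, got {counts}")
    inv = [1.0 / c for c in counts]
    return inv[1] / sum(inv)
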