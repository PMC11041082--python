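"""Minmax-optimal allocation solvers for the three design cases.

The objective is ``max(Var(theta1_hat), Var(theta2_hat))`` — minimize the
worse of the two effect-estimator variances, which (for equal targeted
effects) maximizes the minimum marginal power.  Where the minmax solution
is not unique, the solution with the smallest *minimum* variance is
returned (secondary criterion); in practice this pins equal allocation in
the periods where only one experimental arm recruits.

Cases
-----
1. free entry/exit times: optimize ``r1, r2`` and the allocations;
2. entry time of arm 2 fixed (``r1`` given): optimize ``r2`` and allocations;
3. entry and exit times fixed (``r1, r2`` given): optimize allocations only.

In every case the optimal allocation in periods 1 and 3 is equal split
(1:1 between the single active arm and control), so the real work is the
period-2 allocation.  Interior optima equalize the two variances; for the
concurrent-controls analysis the Lagrange conditions further give the
stationarity relation ``p_{0,2}^2 = p_{1,2}^2 + p_{2,2}^2``, which reduces
the problem to a univariate root-find.  With non-concurrent controls no
closed-form stationarity is available and a constrained sequential
quadratic programming search (with deterministic multi-starts) is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sopt

from .designs import (
    DesignError,
    PlatformDesign,
    _cc_precision,
    _g,
    _ncc_precision,
    var_ncc,
    var_stratified_cc,
)

__all__ = [
    "AllocationSolution",
    "SQRT_K_CONTROL_SHARE",
    "optimize_case1",
    "optimize_case2_cc",
    "optimize_case3_cc",
    "optimize_case2_ncc",
    "optimize_case3_ncc",
    "optimize_unequal_variances",
    "optimize_sum_of_variances",
]

#: Control share of the classical 1:1:sqrt(2) many-to-one allocation.
SQRT_K_CONTROL_SHARE = 1.0 / (1.0 + math.sqrt(2.0))

_EQUAL_SPLIT_1 = (0.5, 0.5, 0.0)  # period 1: control / arm 1
_EQUAL_SPLIT_3 = (0.5, 0.0, 0.5)  # period 3: control / arm 2

SCENARIO_INTERIOR = "interior"
SCENARIO_LARGE_R1 = "r1>=1/2"
SCENARIO_SMALL_HEAD = "r1+r2<1/2"


@dataclass
class AllocationSolution:
    """An optimized design together with solver diagnostics.

    ``objective`` is the minimized maximum variance in units of
    ``sigma0^2/N`` (or the variance *sum* for the sum criterion);
    ``variance_gap`` is ``|Var1 - Var2|`` in the same units, which is
    ~0 for interior solutions.
    """

    design: PlatformDesign
    objective: float
    case: int
    scenario: str
    analysis_mode: str
    converged: bool = True
    variance_gap: float = 0.0
    trace: dict = field(default_factory=dict)

    @property
    def period2(self) -> tuple[float, float, float]:
        """Period-2 allocation ``(p_{0,2}, p_{1,2}, p_{2,2})``."""
        return self.design.p[1]


def _report(design: PlatformDesign, analysis_mode: str):
    if analysis_mode == "ncc" and design.r[0] > 0.0 and design.r[1] > 0.0:
        return var_ncc(design)
    return var_stratified_cc(design)


def _finish(design, case, scenario, analysis_mode, trace, converged=True):
    rep = _report(design, analysis_mode)
    scale = design.N / design.sigma[0] ** 2
    v1, v2 = rep.var_arm1 * scale, rep.var_arm2 * scale
    return AllocationSolution(
        design=design,
        objective=max(v1, v2),
        case=case,
        scenario=scenario,
        analysis_mode=analysis_mode,
        converged=converged,
        variance_gap=abs(v1 - v2),
        trace=trace,
    )


def _make_design(r, p2, sigma=(1.0, 1.0, 1.0), p1=_EQUAL_SPLIT_1, p3=_EQUAL_SPLIT_3):
    return PlatformDesign(N=1.0, r=tuple(r), p=(p1, tuple(p2), p3), sigma=sigma)


def _check_r(r1, r2=None):
    if not 0.0 < r1 < 1.0:
        raise DesignError(f"r1 must be in (0, 1), got {r1}")
    if r2 is not None and not (0.0 <= r2 <= 1.0 - r1 + 1e-12):
        raise DesignError(f"r2 must be in [0, 1-r1], got r2={r2} with r1={r1}")


# ---------------------------------------------------------------------------
# Concurrent-controls solvers
# ---------------------------------------------------------------------------

def _stationary_p02(p22: float) -> float:
    """Control share on the interior stationarity curve, given ``p_{2,2}``.

    Solves ``p_{0,2}^2 = p_{1,2}^2 + p_{2,2}^2`` with
    ``p_{1,2} = 1 - p_{0,2} - p_{2,2}``.
    """
    return ((1.0 - p22) ** 2 + p22**2) / (2.0 * (1.0 - p22))


def _case3_cc_period2(r1: float, r2: float):
    """Interior period-2 allocation for fixed period fractions.

    Root-find on ``p_{2,2}`` along the stationarity curve for the
    equal-variance condition; the precision difference is monotone in
    ``p_{2,2}`` and changes sign on ``(0, 1/2)`` exactly in the interior
    regime ``r1 < 1/2 <= r1 + r2``.
    """
    r3 = 1.0 - r1 - r2

    def gap(p22: float) -> float:
        p02 = _stationary_p02(p22)
        p12 = 1.0 - p02 - p22
        return (r1 / 4.0 + r2 * _g(p12, p02)) - (r3 / 4.0 + r2 * _g(p22, p02))

    lo, hi = 1e-12, 0.5 - 1e-12
    if gap(lo) <= 0.0:  # boundary of the interior regime: arm 2 gets nothing
        return (0.5, 0.5, 0.0), {"method": "stationarity-root", "boundary": "p22=0"}
    p22, info = sopt.brentq(gap, lo, hi, xtol=1e-15, full_output=True)
    p02 = _stationary_p02(p22)
    p12 = max(1.0 - p02 - p22, 0.0)
    trace = {
        "method": "stationarity-root",
        "iterations": info.iterations,
        "xtol": 1e-15,
        "residual_gap": gap(p22),
    }
    return (p02, p12, p22), trace


def optimize_case1(analysis_mode: str = "cc") -> AllocationSolution:
    """Free entry/exit times: the one-period many-to-one trial is optimal.

    All patients are recruited in a single period shared by both arms
    (``r = (0, 1, 0)``) with the classical square-root-of-k allocation
    ``control : arm1 : arm2 = sqrt(2) : 1 : 1``.  With a single period
    there are no non-concurrent controls, so the solution is the same for
    both analysis modes.
    """
    c = SQRT_K_CONTROL_SHARE
    t = (1.0 - c) / 2.0  # = 1 - 1/sqrt(2)
    design = _make_design((0.0, 1.0, 0.0), (c, t, t))
    return _finish(design, 1, SCENARIO_INTERIOR, analysis_mode,
                   trace={"method": "closed-form"})


def optimize_case3_cc(r1: float, r2: float) -> AllocationSolution:
    """Optimal allocation with both period fractions fixed (concurrent only).

    Scenarios: (i) ``r1 >= 1/2``: period 1 already dominates, everything
    afterwards goes 1:1 to arm 2 and control; (ii) ``r1 + r2 < 1/2``:
    period 3 dominates, period 2 goes 1:1 to arm 1 and control;
    (iii) otherwise an interior solution equalizing the two variances,
    found on the stationarity curve ``p_{0,2}^2 = p_{1,2}^2 + p_{2,2}^2``.
    At ``r1 = r3`` the interior solution is the square-root-of-k rule.
    """
    _check_r(r1, r2)
    if r1 >= 0.5:
        design = _make_design((r1, r2, 1.0 - r1 - r2), (0.5, 0.0, 0.5))
        return _finish(design, 3, SCENARIO_LARGE_R1, "cc",
                       trace={"method": "boundary"})
    if r1 + r2 < 0.5:
        design = _make_design((r1, r2, 1.0 - r1 - r2), (0.5, 0.5, 0.0))
        return _finish(design, 3, SCENARIO_SMALL_HEAD, "cc",
                       trace={"method": "boundary"})
    p2, trace = _case3_cc_period2(r1, r2)
    design = _make_design((r1, r2, 1.0 - r1 - r2), p2)
    return _finish(design, 3, SCENARIO_INTERIOR, "cc", trace)


def optimize_case2_cc(r1: float) -> AllocationSolution:
    """Optimal allocation and period-2 size with only ``r1`` fixed.

    For ``r1 >= 1/2`` the optimum degenerates to two separate consecutive
    trials (``r2 = 0``); otherwise arm 1 is kept open to the end
    (``r2 = 1 - r1``) and the period-2 allocation is the interior Case-3
    solution with ``r3 = 0``.
    """
    _check_r(r1)
    if r1 >= 0.5:
        design = _make_design((r1, 0.0, 1.0 - r1), (0.5, 0.0, 0.5))
        return _finish(design, 2, SCENARIO_LARGE_R1, "cc",
                       trace={"method": "boundary", "r2": 0.0})
    r2 = 1.0 - r1
    p2, trace = _case3_cc_period2(r1, r2)
    trace["r2"] = r2
    design = _make_design((r1, r2, 0.0), p2)
    return _finish(design, 2, SCENARIO_INTERIOR, "cc", trace)


# ---------------------------------------------------------------------------
# Non-concurrent-controls solvers
# ---------------------------------------------------------------------------

def _ncc_interior_period2(r1: float, r2: float):
    """Interior period-2 allocation when arm 2 uses non-concurrent controls.

    Minimizes ``Var(theta1_hat)`` in ``(p_{1,2}, p_{2,2})`` subject to the
    equal-variance constraint, via SLSQP from five deterministic starts
    (vertices and centroid of the feasible triangle).  The winning point is
    polished by a bracketed root-find on the constraint so the reported
    variance gap is at rounding level.
    """
    r = (r1, r2, 1.0 - r1 - r2)

    def prec1(x):
        p12, p22 = x
        return r1 / 4.0 + r2 * _g(p12, 1.0 - p12 - p22)

    def gap(x):
        p = ((0.5, 0.5, 0.0), (1.0 - x[0] - x[1], x[0], x[1]), (0.5, 0.0, 0.5))
        return prec1(x) - _ncc_precision(r, p)

    starts = [(0.25, 0.25), (0.1, 0.4), (0.4, 0.1), (0.15, 0.15), (0.3, 0.3)]
    attempts = []
    best = None
    for x0 in starts:
        res = sopt.minimize(
            lambda x: -prec1(x),
            x0,
            method="SLSQP",
            bounds=[(1e-9, 1.0 - 1e-9)] * 2,
            constraints=[
                {"type": "eq", "fun": gap},
                {"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1] - 1e-9},
            ],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        attempts.append({"x0": x0, "success": bool(res.success), "fun": float(res.fun)})
        if res.success and abs(gap(res.x)) < 1e-6:
            if best is None or -res.fun > -best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"NCC interior optimization failed to converge from all starts: {attempts}"
        )
    p12, p22 = float(best.x[0]), float(best.x[1])
    # Polish feasibility: re-solve the constraint exactly in p12 near the optimum.
    f = lambda v: gap((v, p22))  # noqa: E731
    lo = max(p12 - 0.05, 1e-12)
    hi = min(p12 + 0.05, 1.0 - p22 - 1e-12)
    if f(lo) * f(hi) < 0.0:
        p12 = sopt.brentq(f, lo, hi, xtol=1e-15)
    p02 = 1.0 - p12 - p22
    trace = {"method": "slsqp-multistart", "starts": attempts,
             "residual_gap": gap((p12, p22))}
    return (p02, p12, p22), trace


def optimize_case3_ncc(r1: float, r2: float) -> AllocationSolution:
    """Case 3 when arm 2 also uses the pre-entry controls.

    The boundary scenarios coincide with the concurrent-only ones (in (i)
    and (ii) the borrowing cannot change which arm has the larger
    variance); in the interior the optimum allocates *less* to control
    than the concurrent-only design at the same period fractions.
    """
    _check_r(r1, r2)
    if r1 >= 0.5:
        design = _make_design((r1, r2, 1.0 - r1 - r2), (0.5, 0.0, 0.5))
        return _finish(design, 3, SCENARIO_LARGE_R1, "ncc",
                       trace={"method": "boundary"})
    if r1 + r2 < 0.5:
        design = _make_design((r1, r2, 1.0 - r1 - r2), (0.5, 0.5, 0.0))
        return _finish(design, 3, SCENARIO_SMALL_HEAD, "ncc",
                       trace={"method": "boundary"})
    p2, trace = _ncc_interior_period2(r1, r2)
    design = _make_design((r1, r2, 1.0 - r1 - r2), p2)
    return _finish(design, 3, SCENARIO_INTERIOR, "ncc", trace)


def optimize_case2_ncc(r1: float) -> AllocationSolution:
    """Case 2 with non-concurrent controls: ``r2 = 1 - r1`` when ``r1 < 1/2``.

    For ``r1 >= 1/2`` the two-consecutive-trials design is again optimal;
    the regression is then fitted without a period-2 effect and the
    non-concurrent controls cannot improve the arm-2 estimate (only the
    control arm spans both periods).
    """
    _check_r(r1)
    if r1 >= 0.5:
        design = _make_design((r1, 0.0, 1.0 - r1), (0.5, 0.0, 0.5))
        return _finish(design, 2, SCENARIO_LARGE_R1, "ncc",
                       trace={"method": "boundary", "r2": 0.0,
                              "note": "period-2 effect not estimable; "
                                      "non-concurrent controls do not contribute"})
    r2 = 1.0 - r1
    p2, trace = _ncc_interior_period2(r1, r2)
    trace["r2"] = r2
    design = _make_design((r1, r2, 0.0), p2)
    return _finish(design, 2, SCENARIO_INTERIOR, "ncc", trace)


# ---------------------------------------------------------------------------
# Variants: unequal variances; sum-of-variances criterion
# ---------------------------------------------------------------------------

def _neyman_split(sigma_arm: float, sigma0: float, arm: int):
    """Single-arm-period allocation proportional to the standard deviations."""
    share = sigma_arm / (sigma_arm + sigma0)
    row = [1.0 - share, 0.0, 0.0]
    row[arm] = share
    return tuple(row)


def optimize_unequal_variances(
    r1: float, r2: float, sigma: tuple[float, float, float]
) -> AllocationSolution:
    """Minmax allocation with per-arm response variances (concurrent only).

    Periods 1 and 3 get the Neyman allocation ``p_{i,s} : p_{0,s} =
    sigma_i : sigma_0``.  Period 2 is solved numerically: maximize the
    smaller of the two scaled precisions (epigraph form) with SLSQP
    multi-starts, then a secondary pass maximizes the other precision among
    near-minmax points.  Reduces to :func:`optimize_case3_cc` when all
    sigmas are equal.
    """
    _check_r(r1, r2)
    sigma = tuple(float(s) for s in sigma)
    if any(s <= 0 for s in sigma):
        raise DesignError(f"sigma must be positive, got {sigma}")
    if max(sigma) - min(sigma) <= 1e-12 * sigma[0]:
        sol = optimize_case3_cc(r1, r2)
        design = PlatformDesign(N=1.0, r=sol.design.r, p=sol.design.p, sigma=sigma)
        return _finish(design, 3, sol.scenario, "cc", sol.trace)

    r3 = 1.0 - r1 - r2
    rho1 = (sigma[1] / sigma[0]) ** 2
    rho2 = (sigma[2] / sigma[0]) ** 2
    p1 = _neyman_split(sigma[1], sigma[0], 1)
    p3 = _neyman_split(sigma[2], sigma[0], 2)

    def f(a, b, rho):
        return a * b / (a + rho * b) if a > 0 and b > 0 else 0.0

    head1 = r1 * f(p1[1], p1[0], rho1)
    tail2 = r3 * f(p3[2], p3[0], rho2)

    def precisions(x):
        p12, p22 = x
        p02 = 1.0 - p12 - p22
        return (head1 + r2 * f(p12, p02, rho1), tail2 + r2 * f(p22, p02, rho2))

    def neg_min_prec(z):
        return -z[2]

    cons = [
        {"type": "ineq", "fun": lambda z: precisions(z[:2])[0] - z[2]},
        {"type": "ineq", "fun": lambda z: precisions(z[:2])[1] - z[2]},
        {"type": "ineq", "fun": lambda z: 1.0 - z[0] - z[1] - 1e-9},
    ]
    starts = [(0.25, 0.25), (0.1, 0.4), (0.4, 0.1), (0.45, 0.05), (0.05, 0.45)]
    best, attempts = None, []
    for x0 in starts:
        z0 = np.array([x0[0], x0[1], min(precisions(x0))])
        res = sopt.minimize(
            neg_min_prec, z0, method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0), (0.0, None)],
            constraints=cons, options={"ftol": 1e-14, "maxiter": 500},
        )
        attempts.append({"x0": x0, "success": bool(res.success), "fun": float(res.fun)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"unequal-variance minmax optimization failed from all starts: {attempts}"
        )
    m_star = -best.fun
    # Secondary criterion: among near-minmax points, also maximize the total
    # precision (pushes the slack arm's variance down where non-unique).
    res2 = sopt.minimize(
        lambda x: -sum(precisions(x)),
        best.x[:2],
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 2,
        constraints=[
            {"type": "ineq", "fun": lambda x: min(precisions(x)) - m_star + 1e-12},
            {"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1] - 1e-9},
        ],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    x = res2.x if res2.success and min(precisions(res2.x)) >= m_star - 1e-9 else best.x[:2]
    p12, p22 = (max(float(v), 0.0) for v in x)
    design = _make_design((r1, r2, r3), (1.0 - p12 - p22, p12, p22),
                          sigma=sigma, p1=p1, p3=p3)
    interior = p12 > 1e-6 and p22 > 1e-6
    scenario = SCENARIO_INTERIOR if interior else (
        SCENARIO_LARGE_R1 if p12 <= 1e-6 else SCENARIO_SMALL_HEAD
    )
    return _finish(design, 3, scenario, "cc",
                   trace={"method": "slsqp-epigraph", "starts": attempts})


def optimize_sum_of_variances(r1: float, r2: float) -> AllocationSolution:
    """Minimize ``Var1 + Var2`` instead of the maximum (concurrent only).

    The Lagrange conditions for the sum criterion lead to the same interior
    stationarity curve ``p_{0,2}^2 = p_{1,2}^2 + p_{2,2}^2`` as the minmax
    problem, so the search reduces to a univariate minimization of the sum
    along that curve, compared against the two single-arm boundary
    candidates.  At ``r1 = r3`` both criteria give the square-root-of-k
    allocation; away from symmetry the sum criterion shifts patients from
    the arm with the larger own-period share toward the other arm relative
    to the minmax optimum.
    """
    _check_r(r1, r2)
    r3 = 1.0 - r1 - r2

    def total_var(p02, p12, p22):
        prec1 = r1 / 4.0 + r2 * _g(p12, p02)
        prec2 = r3 / 4.0 + r2 * _g(p22, p02)
        v1 = 1.0 / prec1 if prec1 > 0 else math.inf
        v2 = 1.0 / prec2 if prec2 > 0 else math.inf
        return v1 + v2

    def on_curve(p22):
        p02 = _stationary_p02(p22)
        return total_var(p02, 1.0 - p02 - p22, p22)

    res = sopt.minimize_scalar(on_curve, bounds=(1e-9, 0.5 - 1e-9),
                               method="bounded", options={"xatol": 1e-12})
    candidates = []
    p22 = float(res.x)
    p02 = _stationary_p02(p22)
    candidates.append(((p02, 1.0 - p02 - p22, p22), float(res.fun), "interior"))
    candidates.append(((0.5, 0.5, 0.0), total_var(0.5, 0.5, 0.0), SCENARIO_SMALL_HEAD))
    candidates.append(((0.5, 0.0, 0.5), total_var(0.5, 0.0, 0.5), SCENARIO_LARGE_R1))
    p2, obj, scenario = min(candidates, key=lambda c: c[1])
    design = _make_design((r1, r2, r3), p2)
    rep = var_stratified_cc(design)
    scale = design.N / design.sigma[0] ** 2
    v1, v2 = rep.var_arm1 * scale, rep.var_arm2 * scale
    return AllocationSolution(
        design=design,
        objective=v1 + v2,
        case=3,
        scenario=scenario,
        analysis_mode="cc",
        converged=bool(res.success) if scenario == "interior" else True,
        variance_gap=abs(v1 - v2),
        trace={"method": "stationarity-curve-scalar", "objective": "sum"},
    )
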