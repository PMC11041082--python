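"""Independent oracles used across the test suite.

These deliberately avoid the package's own code paths: variances come from
brute-force inversion of the OLS information matrix on expected cell
counts, and optima from dense grid searches of the raw minmax objective.
"""

from __future__ import annotations

import numpy as np

ARM_SETS = ({0, 1}, {0, 1, 2}, {0, 2})


def g(a: float, b: float) -> float:
    return a * b / (a + b) if a > 0 and b > 0 else 0.0


def info_matrix_variance(r, p, arm: int, full_model: bool = False,
                         sigma=(1.0, 1.0, 1.0)) -> float:
    """Variance (units sigma0^2/N at N=1) of the treatment coefficient from
    the weighted least-squares information matrix on expected cell counts.

    ``full_model=False`` fits the two-period model for the requested arm
    (periods 1-2 for arm 1, periods 2-3 for arm 2); ``full_model=True``
    fits the all-periods model used with non-concurrent controls.
    Inestimable period effects (no data in a period) are dropped.
    """
    if full_model:
        periods = [s for s in (1, 2, 3) if r[s - 1] > 0]
    else:
        periods = [s for s in (arm, arm + 1) if r[s - 1] > 0]
    ref = periods[0]
    rows = []
    for s in periods:
        for i in ARM_SETS[s - 1]:
            n = r[s - 1] * p[s - 1][i]
            if n <= 0:
                continue
            x = [1.0, float(i == 1), float(i == 2)]
            x += [float(s == t) for t in periods if t != ref]
            w = n / sigma[i] ** 2
            rows.append((w, np.array(x)))
    keep = [j for j in range(len(rows[0][1]))
            if any(abs(x[j]) > 0 for _, x in rows)]
    M = sum(w * np.outer(x[keep], x[keep]) for w, x in rows)
    Minv = np.linalg.inv(M)
    col = keep.index(arm)  # columns 1, 2 are the arm indicators
    return float(Minv[col, col])


def random_design_params(rng, min_frac=0.02):
    """Random period fractions and allocations bounded away from zero."""
    r = min_frac + rng.dirichlet([1.0, 1.0, 1.0]) * (1 - 3 * min_frac)
    p1 = min_frac + rng.dirichlet([1.0, 1.0]) * (1 - 2 * min_frac)
    p2 = min_frac + rng.dirichlet([1.0, 1.0, 1.0]) * (1 - 3 * min_frac)
    p3 = min_frac + rng.dirichlet([1.0, 1.0]) * (1 - 2 * min_frac)
    p = (
        (p1[0], p1[1], 0.0),
        (p2[0], p2[1], p2[2]),
        (p3[0], 0.0, p3[1]),
    )
    return tuple(r), p


def _minmax_objective(r1, r2, P02, P22):
    """Vectorized max-variance surface over period-2 allocations."""
    r3 = 1.0 - r1 - r2
    P12 = 1.0 - P02 - P22
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = np.where(P12 > 0, P12 * P02 / (P12 + P02), 0.0)
        g2 = np.where(P22 > 0, P22 * P02 / (P22 + P02), 0.0)
        prec1 = r1 / 4.0 + r2 * g1
        prec2 = r3 / 4.0 + r2 * g2
        obj = np.maximum(1.0 / prec1, 1.0 / prec2)
    obj = np.where((P12 < 0) | (P02 <= 0), np.inf, obj)
    return obj


def grid_minmax_cc(r1, r2, step=0.002):
    """Brute-force search of the raw concurrent-controls minmax objective.

    A dense 2-D grid locates the basin; because the objective is kinked
    and nearly flat along the equal-variance ridge, the raw grid argmin
    wobbles by a few grid steps, so the coarse point is polished by a
    profile search: exact scalar minimization over ``p22`` inside a scalar
    minimization over ``p02``.  No solver internals (stationarity curve,
    Lagrange relations) are used.
    """
    from scipy import optimize as sopt

    p02 = np.arange(step, 1.0, step)
    p22 = np.arange(0.0, 1.0, step)
    P02, P22 = np.meshgrid(p02, p22, indexing="ij")
    obj = _minmax_objective(r1, r2, P02, P22)
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    c02 = p02[i]

    def profile(c):
        res = sopt.minimize_scalar(
            lambda t: _minmax_objective(r1, r2, np.array(c), np.array(t)).item(),
            bounds=(1e-9, 1.0 - c - 1e-9), method="bounded",
            options={"xatol": 1e-13},
        )
        return res.fun, res.x

    outer = sopt.minimize_scalar(
        lambda c: profile(c)[0],
        bounds=(max(c02 - 5 * step, step), min(c02 + 5 * step, 1.0 - step)),
        method="bounded", options={"xatol": 1e-10},
    )
    c02 = float(outer.x)
    c22 = float(profile(c02)[1])
    return c02, 1.0 - c02 - c22, c22
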