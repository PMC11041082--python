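"""Period-adjusted estimation and testing on patient-level trial data.

Arm ``i`` is compared with control through a linear model with a treatment
factor and a period factor, fitted on the periods in which arm ``i``
recruits (periods 1-2 for arm 1, periods 2-3 for arm 2).  The treatment
coefficient of that model *is* the period-stratified estimator: the
inverse-variance-weighted combination of per-period mean differences.
Adjusting for period keeps the estimate unbiased under additive time
trends shared by all arms.

When non-concurrent controls are used for arm 2, the same model is fitted
on all three periods, so the period-1 control data sharpen the period
effect and, through it, the arm-2 contrast.

Hypotheses are one-sided, ``H_i: theta_i <= 0`` tested at level 0.025 by
default, alongside a two-sided 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import ARM_SETS

__all__ = [
    "TrialData",
    "EffectEstimate",
    "estimate_stratified_cc",
    "estimate_ncc",
    "stratified_combination",
    "test_and_ci",
]

_COLUMNS = ["patient", "period", "arm", "y"]


@dataclass
class TrialData:
    """Patient-level records ``(patient, period, arm, y)``.

    Patients are ordered by period (period 1 first, then 2, then 3) and
    arms must respect the per-period active sets.  Arm 0 is the control.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trial data is missing columns {missing}")
        df = self.df.loc[:, _COLUMNS].reset_index(drop=True)
        periods = df["period"].to_numpy()
        if len(periods) and np.any(np.diff(periods) < 0):
            raise ValueError("periods must form contiguous blocks in patient order")
        if not set(np.unique(periods)).issubset({1, 2, 3}):
            raise ValueError("period must be 1, 2 or 3")
        for s in (1, 2, 3):
            arms = set(df.loc[df["period"] == s, "arm"].unique().tolist())
            if not arms.issubset(ARM_SETS[s - 1]):
                raise ValueError(
                    f"arms {sorted(arms - ARM_SETS[s - 1])} are not active in period {s}"
                )
        self.df = df

    @property
    def n(self) -> int:
        return len(self.df)

    def counts(self) -> np.ndarray:
        """3x3 matrix of realized group sizes (rows periods, cols arms)."""
        out = np.zeros((3, 3), dtype=int)
        for (s, i), grp in self.df.groupby(["period", "arm"]):
            out[int(s) - 1, int(i)] = len(grp)
        return out

    @classmethod
    def read_csv(cls, path) -> "TrialData":
        """Read ``patient,period,arm,y`` records (arm 0 = control)."""
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class EffectEstimate:
    """A treatment-control effect estimate with its test and interval."""

    arm: int
    estimate: float
    std_error: float
    df: float  # residual degrees of freedom; inf for the known-sigma z analysis
    analysis_mode: str = "cc"
    statistic: float | None = None
    p_one_sided: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    reject: bool | None = None
    metadata: dict = field(default_factory=dict)


def _model_frame(data: TrialData, periods: tuple[int, ...]):
    """Design matrix for the period-adjusted model on the given periods.

    Control is the reference arm and the earliest period present is the
    reference period.  Indicator columns without variation (an arm or a
    period absent from the data) are dropped and recorded.
    """
    sub = data.df[data.df["period"].isin(periods)]
    if sub.empty:
        raise ValueError(f"no data in periods {periods}")
    cols = {"const": np.ones(len(sub))}
    dropped = []
    for arm in (1, 2):
        ind = (sub["arm"] == arm).to_numpy(float)
        if ind.any():
            cols[f"arm{arm}"] = ind
        else:
            dropped.append(f"arm{arm}")
    present = sorted(sub["period"].unique().tolist())
    for s in present[1:]:
        cols[f"period{s}"] = (sub["period"] == s).to_numpy(float)
    for s in periods:
        if s not in present:
            dropped.append(f"period{s}")
    X = pd.DataFrame(cols, index=sub.index)
    return sub["y"].to_numpy(float), X, dropped


def _fit(y, X, coef: str, known_sigma: float | None):
    model = sm.OLS(y, X)
    res = model.fit()
    if coef not in X.columns:
        raise ValueError(f"{coef} has no observations; effect is inestimable")
    est = float(res.params[coef])
    if known_sigma is None:
        se = float(res.bse[coef])
        df = float(res.df_resid)
    else:
        xtx_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
        j = list(X.columns).index(coef)
        se = known_sigma * math.sqrt(xtx_inv[j, j])
        df = math.inf
    return est, se, df, res


def estimate_stratified_cc(
    data: TrialData,
    arm: int,
    known_sigma: float | None = None,
    alpha: float = 0.025,
) -> EffectEstimate:
    """Stratified (period-adjusted) estimate of arm ``i`` vs control.

    Fits the period-adjusted linear model on the two periods in which the
    arm recruits; the treatment coefficient equals the inverse-variance
    weighted combination of the per-period mean differences (see
    :func:`stratified_combination`).  The standard error comes from the
    residual variance (t analysis) or from ``known_sigma`` (z analysis).
    """
    if arm not in (1, 2):
        raise ValueError(f"experimental arm must be 1 or 2, got {arm}")
    periods = (arm, arm + 1)
    y, X, dropped = _model_frame(data, periods)
    est, se, df, _ = _fit(y, X, f"arm{arm}", known_sigma)
    out = EffectEstimate(
        arm=arm, estimate=est, std_error=se, df=df, analysis_mode="cc",
        metadata={"periods": periods, "dropped_terms": dropped},
    )
    return test_and_ci(out, alpha=alpha)


def estimate_ncc(
    data: TrialData,
    known_sigma: float | None = None,
    alpha: float = 0.025,
) -> EffectEstimate:
    """Arm-2 estimate using concurrent *and* non-concurrent controls.

    Fits the period-adjusted model on all observed periods; the arm-2
    coefficient borrows the pre-entry control data through the period
    effects.  Period effects that cannot be estimated (no data in a
    period) are dropped and recorded in the estimate's metadata.  In a
    two-period trial the result equals the explicit correction form
    ``theta_hat_{2,2} + rho * (theta_hat_{1,1} - theta_hat_{1,2})`` with
    :func:`platalloc.designs.rho_coefficient`.
    """
    y, X, dropped = _model_frame(data, (1, 2, 3))
    est, se, df, _ = _fit(y, X, "arm2", known_sigma)
    out = EffectEstimate(
        arm=2, estimate=est, std_error=se, df=df, analysis_mode="ncc",
        metadata={"periods": (1, 2, 3), "dropped_terms": dropped},
    )
    return test_and_ci(out, alpha=alpha)


def stratified_combination(data: TrialData, arm: int) -> tuple[float, dict]:
    """Directly combine per-period mean differences with realized-count
    inverse-variance weights.

    This is the textbook form of the stratified estimator; it equals the
    regression coefficient returned by :func:`estimate_stratified_cc` and
    is exposed for transparency and cross-checking.  Weights are
    proportional to ``(1/n_{i,s} + 1/n_{0,s})^{-1}``; a period in which
    either group is empty gets weight 0.
    """
    if arm not in (1, 2):
        raise ValueError(f"experimental arm must be 1 or 2, got {arm}")
    diffs, invvars, used = {}, {}, []
    for s in (arm, arm + 1):
        sub = data.df[data.df["period"] == s]
        y_t = sub.loc[sub["arm"] == arm, "y"]
        y_c = sub.loc[sub["arm"] == 0, "y"]
        if len(y_t) and len(y_c):
            diffs[s] = float(y_t.mean() - y_c.mean())
            invvars[s] = 1.0 / (1.0 / len(y_t) + 1.0 / len(y_c))
            used.append(s)
    if not used:
        raise ValueError(f"arm {arm} absent from both of its periods")
    total = sum(invvars.values())
    weights = {s: invvars[s] / total for s in used}
    estimate = sum(weights[s] * diffs[s] for s in used)
    return estimate, {"weights": weights, "period_diffs": diffs}


def test_and_ci(est: EffectEstimate, alpha: float = 0.025) -> EffectEstimate:
    """Complete an estimate with the one-sided test and two-sided 95% CI.

    The one-sided p-value is the upper tail of the reference distribution
    (Student t with the estimate's residual df, or standard normal when
    the variance is known) at ``statistic = estimate / std_error``.
    """
    if not est.std_error > 0:
        raise ValueError("standard error must be positive")
    dist = stats.norm if math.isinf(est.df) else stats.t(est.df)
    est.statistic = est.estimate / est.std_error
    est.p_one_sided = float(dist.sf(est.statistic))
    crit = float(dist.ppf(0.975))
    est.ci_low = est.estimate - crit * est.std_error
    est.ci_high = est.estimate + crit * est.std_error
    est.reject = bool(est.p_one_sided < alpha)
    est.metadata.setdefault("alpha", alpha)
    return est
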