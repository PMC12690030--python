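"""Statistical surface: summaries, HC3-robust regressions, subgroup contrasts.

Outcomes (vasoactive-support hours, ventilation days) are analyzed on the
linear scale by ordinary least squares with Huber–White HC3 standard errors,

    V = (XᵀX)⁻¹ Xᵀ diag(eᵢ²/(1−hᵢᵢ)²) X (XᵀX)⁻¹,

confidence intervals and p-values using the t distribution with n−p degrees
of freedom by default (switchable to normal quantiles).  R² is reported in
percent.  Missing data are handled by listwise deletion per model and every
result carries its own n.  Post-hoc subgroup contrasts are reported
unadjusted for multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateLeverageError,
    SampleSizeError,
    SingularDesignError,
)
from .indices import DCCO2_CUTOFF_ML_DL, RATIO_CUTOFF


# ---------------------------------------------------------------- summaries

@dataclass(frozen=True)
class Summary:
    """Median/IQR summary with an optional exceedance proportion."""

    n: int
    median: float
    q25: float
    q75: float
    n_above: int | None = None
    pct_above: float | None = None

    @property
    def empty(self) -> bool:
        return self.n == 0


def summarize(values, threshold: float | None = None) -> Summary:
    """Median, IQR (linear-interpolation quantiles) and, if a threshold is
    given, the strict-exceedance proportion among non-missing values."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        return Summary(0, math.nan, math.nan, math.nan)
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    n_above = pct = None
    if threshold is not None:
        n_above = int(np.sum(v > threshold))
        pct = 100.0 * n_above / v.size
    return Summary(int(v.size), float(med), float(q25), float(q75), n_above, pct)


# ------------------------------------------------------------- OLS and HC3

@dataclass
class OLSFit:
    """Least-squares fit with leverages and the underlying statsmodels result."""

    params: np.ndarray
    resid: np.ndarray
    leverage: np.ndarray
    r2: float
    n: int
    k: int
    _sm: object

    @property
    def df_resid(self) -> int:
        return self.n - self.k


def ols_fit(design, outcome) -> OLSFit:
    """Fit y on a design matrix that already includes its intercept column."""
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    n, k = X.shape
    if n <= k:
        raise SampleSizeError(f"n={n} observations for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    leverage = res.get_influence().hat_matrix_diag
    # centered R² when an intercept (any constant column) is present,
    # matching the usual 1 − RSS/TSS definition
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(res.resid**2) / tss if tss > 0 else 0.0
    return OLSFit(res.params, res.resid, leverage, float(r2), n, k, res)


def hc3_covariance(fit: OLSFit) -> np.ndarray:
    """HC3 sandwich covariance of the coefficients."""
    if np.any(fit.leverage >= 1.0 - 1e-12):
        raise DegenerateLeverageError("leverage of 1: HC3 weight undefined")
    return np.asarray(fit._sm.cov_HC3)


# ------------------------------------------------------------ associations

@dataclass(frozen=True)
class RegressionResult:
    """One association: slope, robust 95% CI, R² (percent), p, and its n."""

    coefficient: float
    ci95_low: float
    ci95_high: float
    robust_se: float
    r2_pct: float
    p_value: float
    n: int


def _ci_multiplier(df_resid: int, ci_dist: str) -> float:
    from scipy import stats

    if ci_dist == "t":
        return float(stats.t.ppf(0.975, df_resid))
    if ci_dist == "normal":
        return 1.959963984540054
    raise ValueError(f"unknown ci_dist {ci_dist!r}")


def _p_value(tstat: float, df_resid: int, ci_dist: str) -> float:
    from scipy import stats

    if ci_dist == "t":
        return float(2 * stats.t.sf(abs(tstat), df_resid))
    return float(2 * stats.norm.sf(abs(tstat)))


def _slope_result(fit: OLSFit, index: int, ci_dist: str) -> RegressionResult:
    V = hc3_covariance(fit)
    se = math.sqrt(V[index, index])
    coef = float(fit.params[index])
    mult = _ci_multiplier(fit.df_resid, ci_dist)
    if se > 0:
        p = _p_value(coef / se, fit.df_resid, ci_dist)
    else:
        p = 0.0 if coef != 0 else 1.0
    return RegressionResult(
        coefficient=coef,
        ci95_low=coef - mult * se,
        ci95_high=coef + mult * se,
        robust_se=se,
        r2_pct=100.0 * fit.r2,
        p_value=p,
        n=fit.n,
    )


def _complete_cases(*arrays) -> tuple[np.ndarray, ...]:
    cols = [np.asarray(pd.Series(a), dtype=float) for a in arrays]
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    return tuple(c[mask] for c in cols)


def univariate_association(
    outcome, predictor, *, n_floor: int = 10, ci_dist: str = "t"
) -> RegressionResult:
    """Slope of outcome on one predictor with HC3 CI/p and R² in percent."""
    y, x = _complete_cases(outcome, predictor)
    if y.size < n_floor:
        raise SampleSizeError(
            f"only {y.size} complete observations; floor is {n_floor}"
        )
    X = np.column_stack([np.ones_like(x), x])
    fit = ols_fit(X, y)
    return _slope_result(fit, 1, ci_dist)


@dataclass(frozen=True)
class IncrementalR2:
    """R² of the base model, the augmented model, and their difference."""

    r2_base: float
    r2_full: float
    delta_r2: float
    n: int


def incremental_r2(outcome, base: pd.DataFrame, added) -> IncrementalR2:
    """Gain in R² from one extra predictor over a base predictor set.

    Both models are fit on the same complete cases (listwise deletion on the
    union of all variables).  A zero-variance added predictor contributes
    nothing by definition and yields delta_r2 = 0 without refitting.
    """
    base = pd.DataFrame(base)
    arrays = [outcome] + [base[c] for c in base.columns] + [added]
    cc = _complete_cases(*arrays)
    y, base_cols, a = cc[0], cc[1:-1], cc[-1]
    Xb = np.column_stack([np.ones_like(y), *base_cols])
    fit_b = ols_fit(Xb, y)
    if np.ptp(a) == 0:
        return IncrementalR2(fit_b.r2, fit_b.r2, 0.0, fit_b.n)
    fit_f = ols_fit(np.column_stack([Xb, a]), y)
    return IncrementalR2(fit_b.r2, fit_f.r2, fit_f.r2 - fit_b.r2, fit_b.n)


@dataclass(frozen=True)
class SubgroupResult:
    """Indicator-coded group model (reference I) with pairwise contrasts.

    ``overall`` is the ordinal-coded single-slope variant (group as 1–4);
    ``contrasts`` maps each non-reference group to its I-vs-group contrast.
    Contrast p-values are unadjusted post-hoc comparisons.
    """

    overall: RegressionResult | None
    contrasts: dict[str, RegressionResult]
    r2_pct: float
    n: int
    small_groups: tuple[str, ...]


_GROUP_ORDER = ("I", "II", "III", "IV")


def subgroup_association(
    outcome, groups, *, reference: str = "I", ci_dist: str = "t"
) -> SubgroupResult:
    """Outcome vs four-group factor: categorical contrasts plus ordinal slope."""
    df = pd.DataFrame({"y": outcome, "g": list(groups)}).dropna()
    levels = [g for g in _GROUP_ORDER if g in set(df["g"])]
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} empty")
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    small = tuple(g for g in levels if (df["g"] == g).sum() < 2)
    # a singleton group has leverage 1 in the indicator model, so its HC3
    # weight is undefined; non-reference singletons are flagged and excluded,
    # a singleton reference leaves no valid baseline to contrast against
    if reference in small:
        raise SampleSizeError(
            f"reference group {reference!r} has a single member; "
            "HC3 contrasts are undefined"
        )
    dropped = [g for g in small if g != reference]
    if dropped:
        df = df[~df["g"].isin(dropped)]

    y = df["y"].to_numpy(dtype=float)
    others = [g for g in levels if g != reference and g not in dropped]
    X = np.column_stack(
        [np.ones(len(df))] + [(df["g"] == g).to_numpy(float) for g in others]
    )
    fit = ols_fit(X, y)
    contrasts = {
        g: _slope_result(fit, i + 1, ci_dist) for i, g in enumerate(others)
    }

    # ordinal variant: group coded 1..4, single slope
    code = df["g"].map({g: i + 1 for i, g in enumerate(_GROUP_ORDER)})
    overall = None
    if code.nunique() > 1:
        fit_o = ols_fit(
            np.column_stack([np.ones(len(df)), code.to_numpy(float)]), y
        )
        overall = _slope_result(fit_o, 1, ci_dist)

    return SubgroupResult(overall, contrasts, 100.0 * fit.r2, fit.n, small)


# ------------------------------------------------------ dynamic predictors

def predictor_transforms(
    series: dict[str, float] | pd.Series,
    *,
    threshold: float | None = None,
) -> dict[str, float]:
    """H0-anchored predictor set for one index tracked over H0..H24.

    Returns the H0 level, its exceedance flag (if a threshold is given), and
    the H6/H0 and H24/H0 ratios; ratios are NaN when H0 is missing or zero.
    """
    s = dict(pd.Series(series).items())
    h0 = s.get("H0", math.nan)
    out: dict[str, float] = {"h0": h0}
    if threshold is not None:
        out["h0_high"] = math.nan if math.isnan(h0) else float(h0 > threshold)
    for tp in ("H6", "H24"):
        later = s.get(tp, math.nan)
        if math.isnan(h0) or h0 == 0 or math.isnan(later):
            out[f"ratio_{tp.lower()}_h0"] = math.nan
        else:
            out[f"ratio_{tp.lower()}_h0"] = later / h0
    return out


DEFAULT_THRESHOLDS = {"dcco2": DCCO2_CUTOFF_ML_DL, "ratio": RATIO_CUTOFF}
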