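"""Statistical layer: subject-table summaries, correlations, least-squares
fits against horn radius, equidistant wall sampling, and the Welch test
comparing stretch at lesion-positive vs lesion-negative wall points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .markers import WallProfile

__all__ = [
    "FitResult",
    "WallSampleTest",
    "pearson",
    "fit_linear",
    "fit_reciprocal",
    "welch_ttest",
    "sample_wall_points",
    "summarize_table1",
]


@dataclass
class FitResult:
    model: str              # "linear" or "reciprocal"
    coefficients: tuple[float, float]   # (a, b) of a*x + b  or  a/x + b
    r_squared: float
    pearson_r: float        # of the raw (regressor, response) pair
    p_value: float

    def predict(self, x):
        a, b = self.coefficients
        x = np.asarray(x, float)
        return a * x + b if self.model == "linear" else a / x + b


@dataclass
class WallSampleTest:
    n_positive: int
    n_negative: int
    t_statistic: float
    df: float               # Welch-Satterthwaite, unrounded
    p_value: float


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value
    (t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _ols_1d(z, y):
    """OLS of y on [z, 1]; returns (a, b) and R^2 on the original scale."""
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    X = np.c_[z, np.ones_like(z)]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (float(coef[0]), float(coef[1])), r2


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares y = a*x + b with intercept."""
    x = np.asarray(x, float)
    if np.std(x) == 0:
        raise ValueError("degenerate design: regressor is constant")
    coef, r2 = _ols_1d(x, y)
    if np.std(np.asarray(y, float)) == 0:
        return FitResult("linear", coef, r2, 0.0, 1.0)
    r, p = pearson(x, y)
    return FitResult("linear", coef, r2, r, p)


def fit_reciprocal(r_values, y) -> FitResult:
    """OLS on the transformed regressor 1/r: y = a/r + b; R^2 on the
    original scale."""
    r_values = np.asarray(r_values, float)
    if np.any(r_values <= 0):
        raise ValueError("reciprocal fit requires strictly positive radii")
    z = 1.0 / r_values
    if np.std(z) == 0:
        raise ValueError("degenerate design: 1/r is constant")
    coef, r2 = _ols_1d(z, y)
    if np.std(np.asarray(y, float)) == 0:
        return FitResult("reciprocal", coef, r2, 0.0, 1.0)
    rr, p = pearson(z, y)
    return FitResult("reciprocal", coef, r2, rr, p)


def welch_ttest(a, b) -> WallSampleTest:
    """Welch's unequal-variance two-sample t-test with Welch-Satterthwaite
    degrees of freedom (reported unrounded)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WallSampleTest(len(a), len(b), 0.0, float(len(a) + len(b) - 2), 1.0)
        raise ValueError("degenerate variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return WallSampleTest(
        n_positive=len(a),
        n_negative=len(b),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
    )


def sample_wall_points(profile: WallProfile, lesion_flags, n_points: int = 30):
    """Sample lambda_t at ``n_points`` equidistant arclength positions
    starting from the wall origin.

    ``lesion_flags`` is a boolean array on the wall nodes (True where the
    node abuts a segmented lesion component); each sample point inherits
    the flag of its nearest wall node.  Returns (values, flags).
    """
    lesion_flags = np.asarray(lesion_flags, bool)
    if len(lesion_flags) != len(profile.lambda_t):
        raise ValueError("lesion_flags must align with wall nodes")
    L = profile.total_length
    s_samples = np.arange(n_points) * L / n_points
    sa = profile.arclength
    lt = profile.lambda_t
    n = len(sa)
    values = np.interp(s_samples, np.append(sa, L), np.append(lt, lt[0]))
    flags = np.empty(n_points, bool)
    for i, s in enumerate(s_samples):
        d = np.minimum(np.abs(sa - s), L - np.abs(sa - s))
        flags[i] = lesion_flags[int(np.argmin(d))]
    return values, flags


def summarize_table1(table: pd.DataFrame) -> dict:
    """Means, sample standard deviations (1/(n-1)), ranges, and the
    male/female subgroup means for the subject table."""
    out = {}
    for col in ("age", "vCSF", "vLV", "vWMH"):
        v = table[col].to_numpy(float)
        out[col] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    male = table[table["sex"] == "M"]["vWMH"].to_numpy(float)
    female = table[table["sex"] == "F"]["vWMH"].to_numpy(float)
    out["vWMH_male_mean"] = float(male.mean())
    out["vWMH_female_mean"] = float(female.mean())
    out["vWMH_male_female_ratio"] = float(male.mean() / female.mean())
    return out
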