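"""Two-wave temporal stability of mid-sleep, and cross-method correspondence.

The per-person stability metric is Asendorpf's individual rank-order
stability coefficient

    i12 = 1 - (z1 - z2)^2 / 2,

where z1 and z2 are the wave-wise z-standardized mid-sleep scores. Its
population mean equals the retest correlation r12. Because i12 is strongly
left-skewed, regression analyses use the de-skewing piecewise logarithmic
transform

    T(i) = 0.5 * ln[(1.001 + i) / (1.001 - i)]   for 0 <= i <= 1,
    T(i) = ln[1 / (1 - i)]                        for i < 0,

which is continuous at 0 and strictly increasing (T(1) ~ 3.8, T(0.99) ~ 2.6).

Age-dependence is summarized three ways: retest Pearson correlations in
fixed age strata, an OLS quadratic of the transformed coefficients on age,
and a hierarchical regression entering retest interval before age and age
squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AGE_GROUPS",
    "INTERVAL_GROUPS",
    "standardize_wave",
    "asendorpf_i12",
    "t_transform",
    "t_transform_inverse",
    "score_stability",
    "StabilityScorer",
    "retest_correlations",
    "quadratic_age_fit",
    "QuadraticAgeFit",
    "hierarchical_regression",
    "steiger_z_nonoverlapping",
    "correspondence",
    "paired_t",
]

AGE_GROUPS = ((18, 25), (26, 35), (36, 45), (46, 55), (56, 65), (66, 87))
# retest intervals in whole years; participants retested within the same
# year are merged into the 1-year group
INTERVAL_GROUPS = ((0, 1), (2, 2), (3, 3), (4, 4), (5, 5))

MEASURE_COLUMNS = {
    "msf": ("msf_t1", "msf_t2"),
    "msw": ("msw_t1", "msw_t2"),
    "msfsc": ("msfsc_t1", "msfsc_t2"),
}


def standardize_wave(values) -> np.ndarray:
    """z-standardize one measurement wave across the full sample (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValueError("standardization needs at least 2 distinct values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero variance in wave")
    return (x - np.mean(x)) / sd


def asendorpf_i12(z1, z2):
    """Individual stability coefficient ``1 - (z1 - z2)^2 / 2`` (<= 1)."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    out = 1.0 - (z1 - z2) ** 2 / 2.0
    return float(out) if out.ndim == 0 else out


def t_transform(i12):
    """De-skewing transform of i12; log-ratio branch on [0, 1], log branch below 0."""
    i = np.asarray(i12, dtype=float)
    if np.any(i > 1.0 + 1e-12):
        raise ValueError("i12 cannot exceed 1")
    i = np.minimum(i, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # both branches are evaluated elementwise; each is only *used* on
        # its own domain
        pos = 0.5 * np.log((1.001 + i) / (1.001 - i))
        neg = np.log(1.0 / (1.0 - i))
    out = np.where(i >= 0, pos, neg)
    return float(out) if out.ndim == 0 else out


def t_transform_inverse(t12):
    """Inverse of :func:`t_transform` (valid for t >= 0, i.e. i12 in [0, 1])."""
    t = np.asarray(t12, dtype=float)
    if np.any(t < 0):
        raise ValueError("inverse defined for t >= 0 only")
    out = 1.001 * np.tanh(t)
    return float(out) if out.ndim == 0 else out


def score_stability(panel: pd.DataFrame, measure: str = "msf") -> pd.DataFrame:
    """Per-participant stability scores for one mid-sleep measure.

    Standardizes each wave across the analysis sample, then computes i12
    and its t-transform. Returns a table with participant_id, z1, z2, i12,
    t12, age_t1, interval_years.
    """
    c1, c2 = MEASURE_COLUMNS[measure]
    data = panel.dropna(subset=[c1, c2])
    z1 = standardize_wave(data[c1])
    z2 = standardize_wave(data[c2])
    i12 = asendorpf_i12(z1, z2)
    out = pd.DataFrame(
        {
            "participant_id": data["participant_id"].to_numpy(),
            "variable": measure.upper(),
            "z1": z1,
            "z2": z2,
            "i12": i12,
            "t12": t_transform(i12),
        }
    )
    for col in ("age_t1", "interval_years"):
        if col in data.columns:
            out[col] = data[col].to_numpy()
    return out


class StabilityScorer(BaseEstimator, TransformerMixin):
    """Transformer wrapper: panel table in, per-person stability scores out."""

    def __init__(self, measure: str = "msf"):
        self.measure = measure

    def fit(self, X, y=None):
        c1, c2 = MEASURE_COLUMNS[self.measure]
        data = X.dropna(subset=[c1, c2])
        self.n_ = len(data)
        self.mean_ = (float(data[c1].mean()), float(data[c2].mean()))
        self.sd_ = (float(data[c1].std(ddof=1)), float(data[c2].std(ddof=1)))
        return self

    def transform(self, X):
        return score_stability(X, self.measure)


def _interval_group(years) -> np.ndarray:
    y = np.asarray(years, dtype=float)
    g = np.clip(np.round(y), 1, 5)  # 0 merged into the 1-year group
    return g.astype(int)


def retest_correlations(
    panel: pd.DataFrame,
    measure: str = "msf",
    stratifier: str = "none",
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson retest correlation of a measure, optionally stratified.

    ``stratifier``: ``"none"`` (full sample), ``"age_group"`` (fixed strata
    18-25 ... 66-87 on age at T1), or ``"interval_group"`` (0-1, 2, 3, 4, 5
    years between waves). Strata with fewer than ``min_n`` complete pairs
    are reported with a missing correlation.
    """
    c1, c2 = MEASURE_COLUMNS[measure]
    data = panel.dropna(subset=[c1, c2])
    rows = []

    def corr(sub):
        if len(sub) < min_n:
            return np.nan
        return float(np.corrcoef(sub[c1], sub[c2])[0, 1])

    if stratifier == "none":
        rows.append({"stratum": "all", "r": corr(data), "n": len(data)})
    elif stratifier == "age_group":
        for lo, hi in AGE_GROUPS:
            sub = data[(data["age_t1"] >= lo) & (data["age_t1"] <= hi)]
            rows.append({"stratum": f"{lo}-{hi}", "r": corr(sub), "n": len(sub)})
    elif stratifier == "interval_group":
        groups = _interval_group(data["interval_years"])
        for lo, hi in INTERVAL_GROUPS:
            sub = data[(groups >= lo) & (groups <= hi)]
            label = "0-1" if hi == 1 else str(hi)
            rows.append({"stratum": label, "r": corr(sub), "n": len(sub)})
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    out = pd.DataFrame(rows)
    if out["r"].isna().any():
        import warnings

        warnings.warn("some strata have fewer pairs than min_n; reported as missing",
                      stacklevel=2)
    return out


@dataclass
class QuadraticAgeFit:
    """OLS summaries of t-transformed stability on age and age squared."""

    coef_age2: float
    coef_age: float
    intercept: float
    r2_quadratic_pct: float
    r2_linear_pct: float
    vertex_age: float
    n: int


def _ols(Xd: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise ValueError("collinear design matrix")
    fitted = Xd @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return beta, fitted, r2, ss_res


def quadratic_age_fit(t12, ages) -> QuadraticAgeFit:
    """Fit ``t12 ~ age + age^2`` (and ``~ age``) by OLS; R^2 as percentages.

    Age enters uncentered so coefficients are directly comparable with a
    printed curve equation; conditioning is unproblematic at double
    precision for ages below ~100.
    """
    t12 = np.asarray(t12, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(t12) < 4:
        raise ValueError("need at least 4 points")
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    Xq = np.column_stack([np.ones_like(ages), ages, ages ** 2])
    beta_q, _, r2_q, _ = _ols(Xq, t12)
    Xl = np.column_stack([np.ones_like(ages), ages])
    _, _, r2_l, _ = _ols(Xl, t12)
    a2, a1 = float(beta_q[2]), float(beta_q[1])
    vertex = -a1 / (2 * a2) if a2 != 0 else np.nan
    return QuadraticAgeFit(
        coef_age2=a2,
        coef_age=a1,
        intercept=float(beta_q[0]),
        r2_quadratic_pct=100.0 * r2_q,
        r2_linear_pct=100.0 * r2_l,
        vertex_age=float(vertex),
        n=len(t12),
    )


def hierarchical_regression(y, blocks: list) -> list:
    """Blockwise OLS with incremental R^2 and F-change tests.

    ``blocks`` is a list of DataFrames (or 2-D arrays) of predictors added
    cumulatively; an intercept is always included. For each cumulative
    model the summary holds R^2, delta R^2 against the previous block, the
    F-change statistic with its p-value, and per-coefficient t-test
    p-values.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    names = ["intercept"]
    summaries = []
    prev_r2, prev_p = 0.0, 1
    for block in blocks:
        B = pd.DataFrame(block)
        X = np.column_stack([X, B.to_numpy(dtype=float)])
        names = names + [str(c) for c in B.columns]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(f"rank-deficient design after adding block {list(B.columns)}")
        beta, fitted, r2, ss_res = _ols(X, y)
        p = X.shape[1]
        df_res = n - p
        delta_r2 = r2 - prev_r2
        df_change = p - prev_p
        if df_res > 0 and r2 < 1.0:
            f_change = (delta_r2 / df_change) / ((1.0 - r2) / df_res)
            p_change = float(stats.f.sf(f_change, df_change, df_res))
        else:
            f_change, p_change = np.inf, 0.0
        sigma2 = ss_res / df_res if df_res > 0 else np.nan
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_res) if df_res > 0 else np.full(p, np.nan)
        summaries.append(
            {
                "predictors": list(names[1:]),
                "r2": float(r2),
                "delta_r2": float(delta_r2),
                "f_change": float(f_change),
                "df_change": int(df_change),
                "df_res": int(df_res),
                "p_change": p_change,
                "coef": {nm: float(b) for nm, b in zip(names, beta)},
                "coef_p": {nm: float(pv) for nm, pv in zip(names, pvals)},
            }
        )
        prev_r2, prev_p = r2, p
    return summaries


def steiger_z_nonoverlapping(R: np.ndarray, n: int, idx1=(0, 1), idx2=(2, 3)):
    """Steiger's Z for two dependent correlations with no variable in common.

    ``R`` is the 4x4 (or larger) correlation matrix of the variables;
    ``idx1``/``idx2`` select the two correlations being compared. Uses
    Fisher-transformed correlations with the Pearson-Filon covariance
    evaluated at the pooled correlation. Returns ``(z, p)`` two-sided.
    """
    j, k = idx1
    h, m = idx2
    r_jk, r_hm = R[j, k], R[h, m]
    rbar = 0.5 * (r_jk + r_hm)
    psi = (
        0.5 * rbar * rbar * (R[j, h] ** 2 + R[j, m] ** 2 + R[k, h] ** 2 + R[k, m] ** 2)
        + R[j, h] * R[k, m]
        + R[j, m] * R[k, h]
        - rbar * (R[j, h] * R[j, m] + R[k, h] * R[k, m]
                  + R[j, h] * R[k, h] + R[j, m] * R[k, m])
    )
    c = psi / (1.0 - rbar * rbar) ** 2
    c = float(np.clip(c, -0.999999, 0.999999))
    z1 = np.arctanh(np.clip(r_jk, -0.999999, 0.999999))
    z2 = np.arctanh(np.clip(r_hm, -0.999999, 0.999999))
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def correspondence(free_a, free_b, work_a, work_b) -> dict:
    """Agreement between two mid-sleep measurement methods, free vs workdays.

    ``free_a``/``free_b`` are one method pair on free days (say MCTQ recall
    vs diary average), ``work_a``/``work_b`` the corresponding workday pair.
    Complete cases only. Returns the two Pearson correlations and the
    Steiger z/p for their difference (dependent, non-overlapping, using all
    six intercorrelations of the four series).
    """
    data = pd.DataFrame(
        {"free_a": free_a, "free_b": free_b, "work_a": work_a, "work_b": work_b}
    ).dropna()
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 complete cases")
    R = np.corrcoef(data.to_numpy().T)
    r_free = float(R[0, 1])
    r_work = float(R[2, 3])
    z, p = steiger_z_nonoverlapping(R, n, idx1=(0, 1), idx2=(2, 3))
    return {"r_free": r_free, "r_work": r_work, "z": z, "p": p, "n": n}


def paired_t(x, y):
    """Classical paired t-test; returns ``(t, df, p)`` with df = n - 1."""
    data = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(data) < 2:
        raise ValueError("need at least 2 complete pairs")
    d = data["x"].to_numpy() - data["y"].to_numpy()
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(data["x"], data["y"])
    return float(res.statistic), len(data) - 1, float(res.pvalue)
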