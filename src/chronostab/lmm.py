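"""From-scratch REML estimation of Gaussian mixed models with one grouping factor.

The model is

    y = X beta + Z_i b_i + e,   b_i ~ N(0, Sigma_b),   e ~ N(0, sigma^2 I),

with independent random-effect vectors ``b_i`` per participant. The
between-participant covariance is parameterized through its *relative*
Cholesky factor Lambda, ``Sigma_b = sigma^2 Lambda Lambda'`` (the lme4
convention), and the REML criterion is profiled over beta and sigma^2 so the
numerical search runs only over the entries of Lambda. Per-group linear
algebra is reduced once to the sufficient statistics Z'Z, Z'X, Z'y, which
makes one criterion evaluation O(groups * q^3) regardless of the number of
observations.

Two-level factors use sum-to-zero coding (+0.5 for a free day, -0.5 for a
workday), so fixed effects read as main effects (free-minus-work contrasts)
and interactions are products of the main-effect columns.

A fit is flagged *singular* when the estimated covariance sits on the
boundary of its parameter space: a relative-Cholesky diagonal entry
collapses to ~0, a between-term correlation reaches +-1, or the relative
scale diverges (the residual-variance-to-zero boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "LmmSpec",
    "LmmFit",
    "DesignError",
    "build_design",
    "fit_reml",
    "fit_with_ladder",
    "wald_fixed_tests",
    "MixedLMM",
]

INTERCEPT = "intercept"


class DesignError(ValueError):
    """The model specification cannot be built from the data."""


@dataclass(frozen=True)
class LmmSpec:
    """Specification of response, fixed terms, and per-participant random terms.

    Terms are factor column names, ``"a:b"`` for an interaction, or
    ``"intercept"``. ``ladder`` lists random terms to drop, in order, when a
    fit is singular.
    """

    response: str
    fixed: tuple = ()
    random: tuple = (INTERCEPT,)
    correlated: bool = True
    ladder: tuple = ()

    def __post_init__(self):
        valid = set(self.fixed) | {INTERCEPT}
        for term in self.random:
            if term not in valid:
                raise DesignError(
                    f"random term {term!r} is not the intercept or a fixed term"
                )
        for term in self.ladder:
            if term not in self.random:
                raise DesignError(f"ladder term {term!r} is not a random term")


@dataclass
class LmmFit:
    """REML estimates: fixed effects, variance components, diagnostics."""

    beta: np.ndarray
    beta_cov: np.ndarray
    fe_names: list
    sigma2_within: float
    cov_between: np.ndarray
    corr_between: np.ndarray
    re_names: list
    reml_deviance: float
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    theta: np.ndarray = field(default=None, repr=False)
    ladder_history: list = field(default_factory=list)

    @property
    def var_between(self) -> float:
        """Random-intercept variance (the interindividual variance)."""
        if INTERCEPT not in self.re_names:
            raise ValueError("fit has no random intercept")
        i = self.re_names.index(INTERCEPT)
        return float(self.cov_between[i, i])

    def to_dict(self) -> dict:
        return {
            "beta": {n: float(b) for n, b in zip(self.fe_names, self.beta)},
            "sigma2_within": self.sigma2_within,
            "cov_between": self.cov_between.tolist(),
            "re_names": list(self.re_names),
            "reml_deviance": self.reml_deviance,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "ladder_history": list(self.ladder_history),
        }


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Sum-to-zero column for a term: +0.5 free / -0.5 workday for boolean
    day-type factors, the product of parts for interactions, raw values for
    numeric covariates."""
    if term == INTERCEPT:
        return np.ones(len(df))
    if ":" in term:
        parts = term.split(":")
        col = np.ones(len(df))
        for part in parts:
            col = col * _term_column(df, part)
        return col
    if term not in df.columns:
        raise DesignError(f"term {term!r} not found in data")
    values = df[term]
    if values.dtype == bool or str(values.dtype) == "boolean" or set(values.dropna().unique()) <= {0, 1, True, False}:
        observed = values.dropna().unique()
        if len(observed) < 2:
            raise DesignError(f"factor {term!r} has a single observed level")
        # workday=True -> -0.5, free day -> +0.5
        return np.where(values.to_numpy(dtype=bool), -0.5, 0.5)
    return values.to_numpy(dtype=float)


def build_design(df: pd.DataFrame, spec: LmmSpec, group_col: str = "participant_id"):
    """Assemble (y, X, Z, groups) for a spec; drop rows missing a used term.

    Rows with a missing value in the response or in any column a fixed or
    random term uses are dropped (so the lagged day-type factor removes
    first nights only from models that include it).
    """
    used_cols = {spec.response}
    for term in set(spec.fixed) | set(spec.random):
        if term == INTERCEPT:
            continue
        used_cols.update(term.split(":"))
    used_cols &= set(df.columns)
    data = df.dropna(subset=sorted(used_cols))
    if data.empty:
        raise DesignError("no complete rows for the requested terms")
    y = data[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] + [_term_column(data, t) for t in spec.fixed])
    fe_names = [INTERCEPT] + list(spec.fixed)
    Z = np.column_stack([_term_column(data, t) for t in spec.random])
    codes, uniques = pd.factorize(data[group_col])
    return y, X, Z, codes, fe_names, list(spec.random), len(uniques)


class _ProfiledREML:
    """Profiled REML criterion over the relative Cholesky factor.

    Precomputes per-group Z'Z, Z'X, Z'y once; each evaluation solves a
    batched q x q system per group via the Woodbury identity.
    """

    def __init__(self, y, X, Z, groups):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.g = int(groups.max()) + 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sufficient statistics
        q, p, g = self.q, self.p, self.g
        self.C = np.zeros((g, q, q))
        self.A = np.zeros((g, q, p))
        self.b = np.zeros((g, q))
        np.add.at(self.C, groups, Z[:, :, None] * Z[:, None, :])
        np.add.at(self.A, groups, Z[:, :, None] * X[:, None, :])
        np.add.at(self.b, groups, Z * y[:, None])
        self.counts = np.bincount(groups, minlength=g)

    def lam(self, theta: np.ndarray, correlated: bool) -> np.ndarray:
        L = np.zeros((self.q, self.q))
        if correlated:
            L[np.tril_indices(self.q)] = theta
        else:
            L[np.diag_indices(self.q)] = theta
        return L

    def n_theta(self, correlated: bool) -> int:
        return self.q * (self.q + 1) // 2 if correlated else self.q

    def theta_bounds(self, correlated: bool):
        bounds = []
        if correlated:
            for i in range(self.q):
                for j in range(i + 1):
                    bounds.append((0.0, 1e6) if i == j else (-1e6, 1e6))
        else:
            bounds = [(0.0, 1e6)] * self.q
        return bounds

    def _pieces(self, L):
        q, p = self.q, self.p
        T = np.einsum("ab,gbc,cd->gad", L.T, self.C, L)
        M = T + np.eye(q)[None]
        chol = np.linalg.cholesky(M)
        logdetV = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum()
        U = np.einsum("ab,gbp->gap", L.T, self.A)
        v = np.einsum("ab,gb->ga", L.T, self.b)
        G = np.concatenate([U, v[:, :, None]], axis=2)  # (g, q, p + 1)
        S = np.linalg.solve(M, G)
        block = np.einsum("gai,gaj->ij", G, S)
        XtViX = self.XtX - block[:p, :p]
        XtViy = self.Xty - block[:p, p]
        ytViy = self.yty - block[p, p]
        return logdetV, XtViX, XtViy, ytViy

    def deviance(self, theta, correlated=True):
        L = self.lam(np.asarray(theta, dtype=float), correlated)
        logdetV, XtViX, XtViy, ytViy = self._pieces(L)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        r2 = ytViy - XtViy @ beta
        dof = self.n - self.p
        if not np.isfinite(r2) or r2 <= 0:
            return np.inf
        return logdetV + logdetXtViX + dof * (1.0 + np.log(2.0 * np.pi * r2 / dof))

    def estimates(self, theta, correlated=True):
        L = self.lam(np.asarray(theta, dtype=float), correlated)
        logdetV, XtViX, XtViy, ytViy = self._pieces(L)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
            XtViX_inv = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            # boundary pathologies (residual variance ~ 0) can degenerate
            # the GLS normal matrix; fall back to the pseudo-inverse
            XtViX_inv = np.linalg.pinv(XtViX)
            beta = XtViX_inv @ XtViy
        r2 = ytViy - XtViy @ beta
        dof = self.n - self.p
        sigma2 = max(float(r2), 0.0) / dof
        cov_rel = L @ L.T
        cov_between = sigma2 * cov_rel
        beta_cov = sigma2 * XtViX_inv
        return beta, beta_cov, sigma2, cov_between, L


def _mom_start(y, X, Z, groups, q, correlated, profiled):
    """Method-of-moments starting point: one-way ANOVA on OLS residuals for
    the intercept component, a conservative positive value for slopes."""
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    g = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=g).astype(float)
    sums = np.bincount(groups, weights=resid, minlength=g)
    means = sums / np.maximum(counts, 1.0)
    within = resid - means[groups]
    dof_w = max(len(y) - g, 1)
    s2_w = float(within @ within) / dof_w
    m_bar = counts.mean()
    s2_b = max(float(np.var(means, ddof=1)) - s2_w / m_bar, 0.01 * s2_w) if g > 1 else 0.1
    rel_int = np.sqrt(s2_b / max(s2_w, 1e-12))
    diag = np.full(q, 0.3)
    diag[0] = max(rel_int, 1e-2)
    L = np.diag(diag)
    if correlated:
        return L[np.tril_indices(q)]
    return diag


def fit_reml(
    y,
    X,
    Z,
    groups,
    fe_names=None,
    re_names=None,
    correlated: bool = True,
    n_starts: int = 5,
    tol: float = 1e-8,
    singular_tol: float = 1e-4,
    max_corr: float = 0.9999,
    random_state: int = 0,
) -> LmmFit:
    """Maximize the profiled REML criterion; return an :class:`LmmFit`.

    The search runs ``n_starts`` local optimizations from a
    method-of-moments start and jittered copies of it (L-BFGS-B with a
    Nelder-Mead polish of the best candidate; exact bounded scalar search
    when there is a single parameter), keeping the best deviance. The
    ``converged`` flag is honest: it reports whether any start terminated
    successfully and the polish changed the deviance by less than ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.ndim == 1:
        Z = Z[:, None]
    groups = np.asarray(groups)
    n, p = X.shape
    q = Z.shape[1]
    g = int(groups.max()) + 1
    if g < 2:
        raise DesignError("need at least 2 groups")
    if n <= p:
        raise DesignError("need more observations than fixed-effect columns")
    if np.var(y) == 0:
        raise DesignError("response has zero variance")
    fe_names = list(fe_names) if fe_names is not None else [f"x{j}" for j in range(p)]
    re_names = list(re_names) if re_names is not None else [f"z{j}" for j in range(q)]

    # center the response for numerical stability; the profiled criterion is
    # shift-invariant, and the shift is restored on the intercept column
    ybar = float(np.mean(y))
    yc = y - ybar
    ones_col = next((j for j in range(p) if np.all(X[:, j] == 1.0)), None)

    prof = _ProfiledREML(yc, X, Z, groups)
    dim = prof.n_theta(correlated)
    rng = np.random.default_rng(random_state)
    start0 = _mom_start(y, X, Z, groups, q, correlated, prof)

    best_theta, best_dev, converged = None, np.inf, False
    if dim == 1:
        res = optimize.minimize_scalar(
            lambda t: prof.deviance([t], correlated),
            bounds=(0.0, 1e6),
            method="bounded",
            options={"xatol": 1e-10},
        )
        # noise-robust parabolic refinement of the interior solution: the
        # vertex of a wide-step parabola is insensitive to float-level
        # wiggle in the profiled deviance
        x = float(res.x)
        h = 1e-4 * max(1.0, x)
        if x - h > 0:
            f0 = prof.deviance([x], correlated)
            fp = prof.deviance([x + h], correlated)
            fm = prof.deviance([x - h], correlated)
            denom = fp - 2.0 * f0 + fm
            if denom > 0:
                x_ref = x - h * (fp - fm) / (2.0 * denom)
                if 0.0 < x_ref and prof.deviance([x_ref], correlated) <= f0 + 1e-9:
                    x = x_ref
        # the boundary itself can be the optimum
        cand = [(x, prof.deviance([x], correlated)),
                (0.0, prof.deviance([0.0], correlated))]
        theta_best, best_dev = min(cand, key=lambda c: c[1])
        best_theta = np.array([theta_best])
        converged = bool(res.success)
    else:
        bounds = prof.theta_bounds(correlated)
        for s in range(n_starts):
            theta0 = start0 if s == 0 else start0 * np.exp(rng.normal(0, 0.4, dim)) + rng.normal(0, 0.02, dim)
            theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = optimize.minimize(
                prof.deviance,
                theta0,
                args=(correlated,),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            if res.fun < best_dev:
                best_dev, best_theta = res.fun, res.x
                converged = bool(res.success)
        if best_theta is None:
            # criterion infinite everywhere explored (residual variance at
            # its zero boundary): report the MoM start, unconverged; the
            # divergence check below flags the fit as singular
            best_theta = np.clip(start0, [b[0] for b in bounds], [b[1] for b in bounds])
            converged = False
        polish = optimize.minimize(
            prof.deviance,
            best_theta,
            args=(correlated,),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 400 * dim, "maxfev": 400 * dim},
        )
        if np.isfinite(polish.fun) and polish.fun <= best_dev:
            converged = converged or abs(best_dev - polish.fun) < max(tol, 1e-8) * (1 + abs(polish.fun))
            best_dev, best_theta = polish.fun, polish.x
        best_theta = np.clip(best_theta, [b[0] for b in bounds], [b[1] for b in bounds])
        best_dev = prof.deviance(best_theta, correlated)

    beta, beta_cov, sigma2, cov_between, L = prof.estimates(best_theta, correlated)
    if ones_col is not None:
        beta = beta.copy()
        beta[ones_col] += ybar
    singular, corr = _check_singular(L, cov_between, singular_tol, max_corr)
    return LmmFit(
        beta=beta,
        beta_cov=beta_cov,
        fe_names=fe_names,
        sigma2_within=sigma2,
        cov_between=cov_between,
        corr_between=corr,
        re_names=re_names,
        reml_deviance=float(best_dev),
        converged=converged,
        singular=singular,
        n_obs=n,
        n_groups=g,
        theta=np.asarray(best_theta, dtype=float),
    )


def _check_singular(L, cov_between, singular_tol, max_corr):
    """Boundary detection on the relative Cholesky factor and correlations."""
    diag = np.abs(np.diag(L))
    scale = max(1.0, float(diag.max()) if diag.size else 1.0)
    singular = bool(diag.size and (diag.min() < singular_tol * scale or diag.max() > 1e4))
    q = cov_between.shape[0]
    corr = np.eye(q)
    sd = np.sqrt(np.maximum(np.diag(cov_between), 0.0))
    for i in range(q):
        for j in range(q):
            if i != j:
                denom = sd[i] * sd[j]
                corr[i, j] = cov_between[i, j] / denom if denom > 0 else np.nan
    off = corr[~np.eye(q, dtype=bool)]
    if off.size and np.any(np.abs(off[np.isfinite(off)]) > max_corr):
        singular = True
    return singular, corr


def fit_from_frame(df, spec: LmmSpec, group_col="participant_id", **kwargs) -> LmmFit:
    y, X, Z, groups, fe_names, re_names, _ = build_design(df, spec, group_col)
    return fit_reml(
        y, X, Z, groups, fe_names=fe_names, re_names=re_names,
        correlated=spec.correlated, **kwargs,
    )


def fit_with_ladder(df, spec: LmmSpec, group_col="participant_id", **kwargs):
    """Fit the maximal spec; while singular, drop the next ladder term and refit.

    Returns ``(fit, fitted_spec)`` — the first non-singular fit, or the last
    fit (still flagged singular) when the ladder is exhausted. The fit's
    ``ladder_history`` records each step as ``(dropped_terms, singular)``.
    """
    history = []
    current = spec
    ladder = list(spec.ladder)
    dropped = []
    fit = fit_from_frame(df, current, group_col, **kwargs)
    history.append({"dropped": list(dropped), "singular": fit.singular})
    while fit.singular and ladder:
        drop = ladder.pop(0)
        dropped.append(drop)
        current = replace(
            current,
            random=tuple(t for t in current.random if t != drop),
            ladder=tuple(ladder),
        )
        fit = fit_from_frame(df, current, group_col, **kwargs)
        history.append({"dropped": list(dropped), "singular": fit.singular})
    fit.ladder_history = history
    return fit, current


def wald_fixed_tests(fit: LmmFit) -> pd.DataFrame:
    """Wald chi-square test per fixed term (asymptotic, *not* Satterthwaite).

    The statistic is beta_j^2 / Var(beta_j) on 1 df with an asymptotic
    chi-square p-value; with singular fits the tests are suppressed
    (returned as NaN) with a warning, since boundary estimates invalidate
    the asymptotics.
    """
    stats_rows = []
    se = np.sqrt(np.diag(fit.beta_cov))
    suppress = fit.singular
    if suppress:
        warnings.warn("singular fit: Wald tests suppressed", stacklevel=2)
    for j, name in enumerate(fit.fe_names):
        if suppress:
            stat = p = np.nan
        else:
            stat = float(fit.beta[j] ** 2 / fit.beta_cov[j, j])
            p = float(stats.chi2.sf(stat, df=1))
        stats_rows.append({"term": name, "estimate": float(fit.beta[j]),
                           "se": float(se[j]), "wald_chi2": stat, "df": 1, "p": p})
    return pd.DataFrame(stats_rows)


class MixedLMM(BaseEstimator):
    """Scikit-learn style wrapper around the REML engine.

    Parameters mirror :class:`LmmSpec`; ``fit(X, y, groups)`` takes a
    DataFrame of factor/covariate columns, the response, and the grouping
    labels. Fitted attributes follow the trailing-underscore convention.
    """

    def __init__(
        self,
        fixed=(),
        random=(INTERCEPT,),
        correlated=True,
        ladder=(),
        n_starts=5,
        tol=1e-8,
        singular_tol=1e-4,
        max_corr=0.9999,
        random_state=0,
    ):
        self.fixed = fixed
        self.random = random
        self.correlated = correlated
        self.ladder = ladder
        self.n_starts = n_starts
        self.tol = tol
        self.singular_tol = singular_tol
        self.max_corr = max_corr
        self.random_state = random_state

    def fit(self, X, y, groups):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        df = X.copy()
        df["__y__"] = np.asarray(y, dtype=float)
        df["__group__"] = np.asarray(groups)
        spec = LmmSpec(
            response="__y__",
            fixed=tuple(self.fixed),
            random=tuple(self.random),
            correlated=self.correlated,
            ladder=tuple(self.ladder),
        )
        kwargs = dict(
            n_starts=self.n_starts,
            tol=self.tol,
            singular_tol=self.singular_tol,
            max_corr=self.max_corr,
            random_state=self.random_state,
        )
        if spec.ladder:
            fit, fitted_spec = fit_with_ladder(df, spec, group_col="__group__", **kwargs)
        else:
            fit, fitted_spec = fit_from_frame(df, spec, group_col="__group__", **kwargs), spec
        self.result_ = fit
        self.spec_ = fitted_spec
        self.beta_ = fit.beta
        self.fe_names_ = fit.fe_names
        self.sigma2_within_ = fit.sigma2_within
        self.cov_between_ = fit.cov_between
        self.re_names_ = fit.re_names
        self.singular_ = fit.singular
        self.converged_ = fit.converged
        self.reml_deviance_ = fit.reml_deviance
        self.n_obs_ = fit.n_obs
        self.n_groups_ = fit.n_groups
        return self

    def predict(self, X):
        """Population-level (fixed-effects only) predictions."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        design = np.column_stack(
            [np.ones(len(X))] + [_term_column(X, t) for t in self.spec_.fixed]
        )
        return design @ self.beta_
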