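"""Group-level inference: random-intercept mixed models and logistic prediction.

The mixed model is the single-variance-component linear model
``y = X beta + Z u + e`` with one random intercept per subject, estimated by
REML with the likelihood profiled over the variance ratio (closed-form GLS
via Sherman-Morrison per subject). Fixed effects are tested with a
Satterthwaite-style degrees-of-freedom approximation computed from the
numerical REML information matrix, and explained variance is summarized by
Nakagawa's marginal/conditional R-squared.

Models used downstream:
  - DTR ~ condition + (1|subject)                (engagement by condition)
  - DTR ~ trial * condition + (1|subject)        (habituation)
  - beta ~ condition + (1|subject)               (condition responses)
  - beta ~ -1 + cond + cond:TraitAnxiety + (1|subject)  (anxiety coupling)
  - clinical ~ unexpected right-mPFC response     (logistic)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import optimize, stats

STAI_CLINICAL_CUTOFF = 40.0


# ---------------------------------------------------------------------------
# random-intercept REML machinery
# ---------------------------------------------------------------------------

def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    idx = pd.Series(np.arange(len(groups))).groupby(pd.Series(groups), sort=False).apply(lambda s: s.to_numpy())
    return list(idx)


def _gls_pieces(y, X, slices, theta):
    """Weighted cross-products under V = sigma2_e * (I + theta * 1 1') per group."""
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    for sl in slices:
        Xj, yj = X[sl], y[sl]
        nj = len(sl)
        c = theta / (1.0 + theta * nj)
        sx = Xj.sum(axis=0)
        sy = yj.sum()
        XtWX += Xj.T @ Xj - c * np.outer(sx, sx)
        XtWy += Xj.T @ yj - c * sx * sy
    return XtWX, XtWy


def _profiled_fit(y, X, slices, theta, reml=True):
    n, p = X.shape
    XtWX, XtWy = _gls_pieces(y, X, slices, theta)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = 0.0
    logdet_v_unit = 0.0
    for sl in slices:
        rj = y[sl] - X[sl] @ beta
        nj = len(sl)
        c = theta / (1.0 + theta * nj)
        rss += rj @ rj - c * rj.sum() ** 2
        logdet_v_unit += np.log1p(theta * nj)
    denom = (n - p) if reml else n
    sigma2_e = rss / denom
    sigma2_e = max(sigma2_e, 1e-300)
    if reml:
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(sigma2_e) + logdet_v_unit + logdet_xwx + (n - p))
    else:
        ll = -0.5 * (n * np.log(sigma2_e) + logdet_v_unit + n)
    return beta, sigma2_e, ll, XtWX


def _reml_loglik_full(y, X, slices, sigma2_u, sigma2_e, reml=True):
    """REML (or ML) log-likelihood at explicit variance components, up to const."""
    if sigma2_e <= 0 or sigma2_u < 0:
        return -np.inf
    n, p = X.shape
    theta = sigma2_u / sigma2_e
    XtWX, XtWy = _gls_pieces(y, X, slices, theta)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = 0.0
    logdet_v = 0.0
    for sl in slices:
        rj = y[sl] - X[sl] @ beta
        nj = len(sl)
        c = theta / (1.0 + theta * nj)
        rss += rj @ rj - c * rj.sum() ** 2
        logdet_v += nj * np.log(sigma2_e) + np.log1p(theta * nj)
    ll = -0.5 * (logdet_v + rss / sigma2_e)
    if reml:
        sign, logdet_xwx = np.linalg.slogdet(XtWX / sigma2_e)
        ll -= 0.5 * logdet_xwx
    return ll


@dataclass
class MixedFitResult:
    """Fixed effects with Satterthwaite-style tests plus variance components."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    dof: pd.Series
    pvalues: pd.Series
    sigma2_subject: float
    sigma2_resid: float
    loglik: float
    r2_marginal: float
    r2_conditional: float
    cov_params: pd.DataFrame
    boundary: bool = False
    method: str = "reml"
    n_obs: int = 0
    n_groups: int = 0
    fitted_fixed: np.ndarray = field(default_factory=lambda: np.array([]))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "t": self.tvalues, "dof": self.dof, "p": self.pvalues}
        )

    def __getitem__(self, name: str) -> float:
        return float(self.params[name])


def fit_random_intercept(
    table: pd.DataFrame,
    response: str,
    fixed: str = "condition",
    groups: str = "subject",
    reml: bool = True,
) -> MixedFitResult:
    """REML fit of ``response ~ fixed + (1|groups)``.

    ``fixed`` is a patsy right-hand side (e.g. ``"condition"``,
    ``"trial * condition"``, ``"0 + condition + condition:trait_anxiety"``).
    The likelihood is profiled over the variance ratio; a zero
    between-subject variance is reported as a boundary fit.
    """
    data = table.dropna(subset=[response]).reset_index(drop=True)
    if data[groups].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    dm = dmatrix(fixed, data, return_type="dataframe")
    X = dm.to_numpy()
    names = list(dm.columns)
    y = data[response].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    slices = _group_slices(data[groups].to_numpy())
    n, p = X.shape

    obj = lambda log_theta: -_profiled_fit(y, X, slices, np.exp(log_theta), reml)[2]
    res = optimize.minimize_scalar(obj, bounds=(-14.0, 14.0), method="bounded", options={"xatol": 1e-8})
    theta = float(np.exp(res.x))
    # compare against the boundary theta -> 0
    _, _, ll0, _ = _profiled_fit(y, X, slices, 0.0, reml)
    beta, sigma2_e, ll, XtWX = _profiled_fit(y, X, slices, theta, reml)
    boundary = False
    if ll0 >= ll - 1e-10 or theta < 1e-10:
        theta, boundary = 0.0, True
        beta, sigma2_e, ll, XtWX = _profiled_fit(y, X, slices, 0.0, reml)
        warnings.warn("between-subject variance estimated at the zero boundary")
    sigma2_u = theta * sigma2_e
    cov = sigma2_e * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se

    dof = np.array([_satterthwaite_dof(y, X, slices, sigma2_u, sigma2_e, _unit(p, j), reml) for j in range(p)])
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    fitted = X @ beta
    var_f = float(np.var(fitted))
    denom = var_f + sigma2_u + sigma2_e
    r2m = var_f / denom if denom > 0 else np.nan
    r2c = (var_f + sigma2_u) / denom if denom > 0 else np.nan
    idx = pd.Index(names)
    return MixedFitResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        dof=pd.Series(dof, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma2_subject=float(sigma2_u),
        sigma2_resid=float(sigma2_e),
        loglik=float(ll),
        r2_marginal=float(r2m),
        r2_conditional=float(r2c),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        boundary=boundary,
        method="reml" if reml else "ml",
        n_obs=n,
        n_groups=len(slices),
        fitted_fixed=fitted,
    )


def _unit(p: int, j: int) -> np.ndarray:
    c = np.zeros(p)
    c[j] = 1.0
    return c


def _satterthwaite_dof(y, X, slices, sigma2_u, sigma2_e, c, reml=True) -> float:
    """Satterthwaite dof for contrast c: nu = 2 g^2 / (grad g' A grad g).

    g(theta) = c' Cov(beta) c; A is the inverse numerical REML information in
    (sigma2_u, sigma2_e). Falls back to the residual dof when the
    information matrix is not usable (e.g. at the variance boundary).
    """
    n, p = X.shape
    fallback = max(n - p, 1.0)

    def g(s2u, s2e):
        th = max(s2u, 0.0) / s2e
        XtWX, _ = _gls_pieces(y, X, slices, th)
        return s2e * (c @ np.linalg.solve(XtWX, c))

    g0 = g(sigma2_u, sigma2_e)
    if sigma2_u <= 0:
        return fallback
    try:
        h_u = max(1e-8, 1e-4 * sigma2_u)
        h_e = max(1e-8, 1e-4 * sigma2_e)
        grad = np.array(
            [
                (g(sigma2_u + h_u, sigma2_e) - g(sigma2_u - h_u, sigma2_e)) / (2 * h_u),
                (g(sigma2_u, sigma2_e + h_e) - g(sigma2_u, sigma2_e - h_e)) / (2 * h_e),
            ]
        )
        H = _num_hessian(
            lambda v: _reml_loglik_full(y, X, slices, v[0], v[1], reml),
            np.array([sigma2_u, sigma2_e]),
            np.array([h_u * 10, h_e * 10]),
        )
        A = np.linalg.inv(-H)
        denom = grad @ A @ grad
        if denom <= 0:
            return fallback
        nu = 2.0 * g0**2 / denom
        return float(np.clip(nu, 1.0, fallback * 10))
    except np.linalg.LinAlgError:
        return fallback


def _num_hessian(f, x0, h):
    k = len(x0)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# the study's specific models
# ---------------------------------------------------------------------------

def fit_anxiety_interaction(table: pd.DataFrame, response: str = "beta") -> MixedFitResult:
    """Fit ``beta ~ -1 + cond + cond:TraitAnxiety + (1|subject)``.

    No global intercept: per-condition intercepts and per-condition trait-
    anxiety slopes. The slope for the unexpected condition is the quantity
    of interest. Rows with missing trait anxiety are dropped with a count
    logged.
    """
    n_before = len(table)
    data = table.dropna(subset=["trait_anxiety", response])
    if len(data) < n_before:
        warnings.warn(f"dropped {n_before - len(data)} rows with missing anxiety or response")
    return fit_random_intercept(
        data, response=response, fixed="0 + C(condition) + C(condition):trait_anxiety"
    )


def unexpected_anxiety_slope(fit: MixedFitResult) -> tuple[float, float, float, float]:
    """(estimate, se, t, p) of the trait-anxiety slope for unexpected events."""
    name = [n for n in fit.params.index if "unexpected" in n and "trait_anxiety" in n]
    if not name:
        raise KeyError("no unexpected:trait_anxiety term in fit")
    n = name[0]
    return float(fit.params[n]), float(fit.se[n]), float(fit.tvalues[n]), float(fit.pvalues[n])


@dataclass
class LogisticFitResult:
    slope: float
    se: float
    z: float
    p: float
    intercept: float
    separated: bool = False
    n: int = 0


def fit_logistic_clinical(
    table: pd.DataFrame,
    predictor: str = "beta",
    cutoff: float = STAI_CLINICAL_CUTOFF,
    roi: str = "R_mPFC",
    condition: str = "unexpected",
    chromophore: str = "HbO",
) -> LogisticFitResult:
    """Logistic regression of clinical anxiety (STAI > cutoff) on ROI response.

    Uses each subject's unexpected-event response in the right mPFC by
    default. Perfect separation is flagged rather than reported as a finite
    estimate.
    """
    sel = table
    for col, val in (("roi", roi), ("condition", condition), ("chromophore", chromophore)):
        if col in sel.columns:
            sel = sel[sel[col] == val]
    sel = sel.dropna(subset=[predictor])
    if "clinical" in sel.columns:
        yflag = sel["clinical"].astype(bool)
    else:
        yflag = sel["trait_anxiety"] > cutoff
    x = sel[predictor].to_numpy(dtype=float)
    y = yflag.to_numpy()
    if y.all() or not y.any():
        raise ValueError("degenerate outcome: only one class present")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
        except Exception:
            return LogisticFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, separated=True, n=len(y))
    separated = bool(np.any(np.abs(res.params) > 1e3) or not np.all(np.isfinite(res.bse)))
    return LogisticFitResult(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        z=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        separated=separated,
        n=len(y),
    )


def r2_nakagawa(fit: MixedFitResult) -> tuple[float, float]:
    """Marginal and conditional R-squared of a random-intercept fit.

    R2m = var_fixed / (var_fixed + var_subject + var_resid);
    R2c = (var_fixed + var_subject) / same denominator; var_fixed is the
    variance of the fixed-effect predictions over the rows.
    """
    var_f = float(np.var(fit.fitted_fixed))
    denom = var_f + fit.sigma2_subject + fit.sigma2_resid
    if denom == 0:
        return 1.0, 1.0
    return var_f / denom, (var_f + fit.sigma2_subject) / denom
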