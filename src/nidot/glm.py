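"""Design matrices and AR-prewhitened robust GLM fitting.

The design couples condition regressors (FIR bins or canonical-HRF sticks)
with a single trial-by-trial engagement modulator: scaled dwell-time ratios
placed as stick heights at event onsets and convolved with the canonical
infant HRF, applied across all trials irrespective of condition.

Fitting follows the AR(P)IRLS idea: the noise is prewhitened with an
autoregressive model whose order is chosen by BIC, and the regression is made
robust to motion-related outliers with Tukey bisquare reweighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .containers import CONDITIONS, TrialSchedule

DEFAULT_N_BINS = 28
COLLINEARITY_WARN_COND = 1e6


def canonical_hrf(t: np.ndarray, peak_s: float = 4.0, shape: float = 6.0) -> np.ndarray:
    """Canonical infant hemodynamic response: single gamma, unit peak.

    h(t) = (t/peak)^k * exp(k * (1 - t/peak)) with shape k; h(peak) = 1 and
    h(0) = 0. The 4 s time-to-peak reflects the faster infant response.
    """
    if peak_s <= 0:
        raise ValueError("peak_s must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / peak_s
    out[pos] = tp**shape * np.exp(shape * (1.0 - tp))
    return out


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_times, n_regressors)
    names: list[str]
    rate_hz: float
    bin_map: dict[tuple[str, int], int] = field(default_factory=dict)
    basis: str = "fir"
    n_bins: int = DEFAULT_N_BINS
    t0_s: float = 0.0

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


def _hrf_kernel(rate_hz: float, peak_s: float = 4.0, dur_s: float = 20.0) -> np.ndarray:
    return canonical_hrf(np.arange(0.0, dur_s, 1.0 / rate_hz), peak_s=peak_s)


def build_design(
    schedule: TrialSchedule,
    dtr_scaled: np.ndarray,
    basis: str = "fir",
    rate_hz: float = 4.0,
    n_times: int | None = None,
    t0_s: float = 0.0,
    n_bins: int = DEFAULT_N_BINS,
    include_modulator: bool = True,
    hrf_peak_s: float = 4.0,
) -> DesignMatrix:
    """Build the GLM design for one session.

    Events are time-locked to the outcome (stimulus-window) onset of each
    trial. Trials with missing (NaN) scaled DTR are excluded from every event
    regressor; the engagement modulator is a single column of DTR-height
    sticks convolved with the canonical HRF, shared across conditions.
    Intercept and linear-drift nuisance columns are always appended.
    """
    if basis not in ("fir", "canonical"):
        raise ValueError(f"unknown basis {basis!r}")
    dtr_scaled = np.asarray(dtr_scaled, dtype=float)
    if len(dtr_scaled) != schedule.n_trials:
        raise ValueError("dtr_scaled must align with schedule trials")
    usable = ~np.isnan(dtr_scaled)
    if not usable.any():
        raise ValueError("no usable trials (all DTR missing)")
    if n_times is None:
        n_times = int(np.ceil((schedule.session_end_s - t0_s) * rate_hz))
    onset_idx = np.round((schedule.stim_onsets - t0_s) * rate_hz).astype(int)
    types = schedule.types

    cols: list[np.ndarray] = []
    names: list[str] = []
    bin_map: dict[tuple[str, int], int] = {}
    kern = _hrf_kernel(rate_hz, peak_s=hrf_peak_s)

    for cond in CONDITIONS:
        sel = usable & (types == cond)
        if basis == "fir":
            for b in range(n_bins):
                col = np.zeros(n_times)
                idx = onset_idx[sel] + b
                idx = idx[(idx >= 0) & (idx < n_times)]
                np.add.at(col, idx, 1.0)
                bin_map[(cond, b + 1)] = len(cols)
                cols.append(col)
                names.append(f"{cond}:bin{b + 1:02d}")
        else:
            stick = np.zeros(n_times)
            idx = onset_idx[sel]
            idx = idx[(idx >= 0) & (idx < n_times)]
            np.add.at(stick, idx, 1.0)
            cols.append(np.convolve(stick, kern)[:n_times])
            names.append(cond)

    if include_modulator:
        stick = np.zeros(n_times)
        for i in np.flatnonzero(usable):
            if 0 <= onset_idx[i] < n_times:
                stick[onset_idx[i]] += dtr_scaled[i]
        cols.append(np.convolve(stick, kern)[:n_times])
        names.append("modulator")

    cols.append(np.ones(n_times))
    names.append("intercept")
    drift = np.linspace(-0.5, 0.5, n_times)
    cols.append(drift)
    names.append("drift")

    X = np.column_stack(cols)
    keep = X.any(axis=0)
    if not keep.all():
        X = X[:, keep]
        dropped = [n for n, k in zip(names, keep) if not k]
        names = [n for n, k in zip(names, keep) if k]
        bin_map = {k: names.index(f"{k[0]}:bin{k[1]:02d}") for k in bin_map if f"{k[0]}:bin{k[1]:02d}" in names}
        warnings.warn(f"dropped all-zero design columns: {dropped}")
    cond_num = np.linalg.cond(X)
    if cond_num > COLLINEARITY_WARN_COND:
        warnings.warn(
            f"design matrix nearly collinear (condition number {cond_num:.3g}); "
            "the engagement modulator may be indistinguishable from the "
            "condition regressors",
        )
    return DesignMatrix(X=X, names=names, rate_hz=rate_hz, bin_map=bin_map, basis=basis, n_bins=n_bins, t0_s=t0_s)


@dataclass
class GLMFit:
    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    dof: float
    ar_order: int
    ar_coeffs: np.ndarray
    weights: np.ndarray
    residuals: np.ndarray
    converged: bool
    basis: str
    bin_map: dict[tuple[str, int], int]
    rate_hz: float

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def __getitem__(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


def _levinson_pev(acov: np.ndarray, max_order: int) -> np.ndarray:
    """Prediction-error variance for AR orders 0..max_order (Levinson-Durbin)."""
    pev = np.empty(max_order + 1)
    pev[0] = acov[0]
    a = np.zeros(max_order + 1)
    for k in range(1, max_order + 1):
        acc = acov[k] - np.dot(a[1:k], acov[1:k][::-1])
        refl = acc / pev[k - 1]
        a_new = a.copy()
        a_new[k] = refl
        a_new[1:k] = a[1:k] - refl * a[1:k][::-1]
        a = a_new
        pev[k] = pev[k - 1] * (1.0 - refl**2)
    return np.maximum(pev, 1e-300)


def _select_ar(
    resid: np.ndarray, max_order: int, weights: np.ndarray | None = None
) -> tuple[int, np.ndarray]:
    """AR order by BIC on the residuals; Yule-Walker coefficients.

    The autocovariance is estimated with the robust regression weights
    (products w_t * w_{t+k}) so that outliers — already removed from the fit
    — do not bias the noise-correlation estimate toward whiteness, which
    would under-whiten and understate the betas' standard errors.
    """
    n = len(resid)
    max_order = int(min(max_order, n // 4))
    if max_order <= 0 or np.allclose(resid, resid[0]):
        return 0, np.array([])
    x = resid - resid.mean()
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    acov = np.empty(max_order + 1)
    for k in range(max_order + 1):
        ww = w[: n - k] * w[k:]
        tot = ww.sum()
        acov[k] = (ww * x[: n - k] * x[k:]).sum() / tot if tot > 0 else 0.0
    if acov[0] <= 0:
        return 0, np.array([])
    pev = _levinson_pev(acov, max_order)
    bic = n * np.log(pev) + np.arange(max_order + 1) * np.log(n)
    order = int(np.argmin(bic))
    if order == 0:
        return 0, np.array([])
    R = np.array([[acov[abs(i - j)] for j in range(order)] for i in range(order)])
    coeffs = np.linalg.solve(R, acov[1 : order + 1])
    return order, coeffs


def _tukey_raw_weights(r: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare weights of raw residuals around their median (MAD scale)."""
    med = np.median(r)
    s = 1.4826 * np.median(np.abs(r - med))
    if s == 0:
        return np.ones_like(r)
    u = (r - med) / (c * s)
    return np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)


def _whiten(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    if len(coeffs) == 0:
        return x
    filt = np.r_[1.0, -coeffs]
    return signal.lfilter(filt, [1.0], x, axis=0)[len(coeffs):]


def ar_irls_fit(
    y: np.ndarray,
    design: DesignMatrix,
    max_ar_order: int | None = None,
    tukey_c: float = 4.685,
    robust: bool = True,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> GLMFit:
    """Fit one timeseries with AR-prewhitened (optionally robust) regression.

    Iterates: (1) fit on the currently whitened model, robustly (Tukey
    bisquare, 95%-efficiency constant 4.685) or by least squares; (2)
    estimate the AR order of the unwhitened residuals by BIC over
    0..max_ar_order via Yule-Walker; (3) re-whiten y and every design column
    with the AR filter. Stops when the relative beta change falls below
    ``tol`` or after ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y length must match design rows")
    if max_ar_order is None:
        max_ar_order = int(np.ceil(4 * design.rate_hz))
    if n <= p + max_ar_order:
        raise ValueError("timeseries too short for design + AR order")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        d = np.abs(np.diag(R))
        bad = [design.names[i] for i in np.where(d < d.max() * 1e-10)[0]]
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")

    ar_coeffs = np.array([])
    ar_order = 0
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid0 = y - X @ beta
    if resid0.std() <= 1e-12 * (np.abs(y).max() + 1e-30):
        # exact fit: robust reweighting and AR estimation are degenerate
        cov = np.zeros((p, p))
        return GLMFit(
            beta=beta, cov=cov, names=list(design.names), dof=float(n - p),
            ar_order=0, ar_coeffs=np.array([]), weights=np.ones(n),
            residuals=resid0, converged=True, basis=design.basis,
            bin_map=dict(design.bin_map), rate_hz=design.rate_hz,
        )
    converged = False
    res_obj = None
    for _ in range(max_iter):
        yw = _whiten(y, ar_coeffs)
        Xw = _whiten(X, ar_coeffs)
        if robust:
            res_obj = sm.RLM(yw, Xw, M=sm.robust.norms.TukeyBiweight(c=tukey_c)).fit()
            beta_new = np.asarray(res_obj.params)
        else:
            res_obj = sm.OLS(yw, Xw).fit()
            beta_new = np.asarray(res_obj.params)
        resid = y - X @ beta_new
        w_raw = _tukey_raw_weights(resid, tukey_c) if robust else None
        ar_order, ar_coeffs = _select_ar(resid, max_ar_order, weights=w_raw)
        delta = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta_new), 1e-30)
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("AR-IRLS did not converge; returning last iterate")

    yw = _whiten(y, ar_coeffs)
    Xw = _whiten(X, ar_coeffs)
    if robust:
        res_obj = sm.RLM(yw, Xw, M=sm.robust.norms.TukeyBiweight(c=tukey_c)).fit()
        beta = np.asarray(res_obj.params)
        cov = np.asarray(res_obj.bcov_scaled)
        weights = np.asarray(res_obj.weights)
    else:
        res_obj = sm.OLS(yw, Xw).fit()
        beta = np.asarray(res_obj.params)
        cov = np.asarray(res_obj.cov_params())
        weights = np.ones(len(yw))
    dof = float(len(yw) - p)
    return GLMFit(
        beta=beta,
        cov=cov,
        names=list(design.names),
        dof=dof,
        ar_order=ar_order,
        ar_coeffs=ar_coeffs,
        weights=weights,
        residuals=y - X @ beta,
        converged=converged,
        basis=design.basis,
        bin_map=dict(design.bin_map),
        rate_hz=design.rate_hz,
    )


def bins_to_window(bin_lo: int, bin_hi: int, rate_hz: float, labeled: bool = True) -> tuple[float, float]:
    """Post-onset time window covered by a labeled bin range.

    Bin b covers [(b-1)/rate, b/rate) post-onset. Under the default labeled
    convention the range (12, 24) resolves internally to bins 13..24, i.e.
    the window [3.00, 6.00) s at 4 Hz matching the "3 to 6 s" description.
    """
    lo = bin_lo + 1 if labeled else bin_lo
    return ((lo - 1) / rate_hz, bin_hi / rate_hz)


@dataclass
class BinSummary:
    """Per-condition average of FIR betas over a bin range."""

    estimates: dict[str, float]
    cov: np.ndarray  # across conditions, order of `conditions`
    conditions: list[str]
    dof: float
    bins_used: tuple[int, int]
    window_s: tuple[float, float]


def average_bins(
    fit: GLMFit,
    bin_lo: int = 12,
    bin_hi: int = 24,
    labeled: bool = True,
) -> BinSummary:
    """Average FIR betas over a bin range, per condition, with covariance.

    ``bin_lo``/``bin_hi`` are the labeled indices (default 12-24, the typical
    infant HRF peak, 3-6 s post-stimulus); see :func:`bins_to_window` for the
    labeled-index convention.
    """
    if fit.basis != "fir":
        raise ValueError("average_bins requires an FIR-basis fit")
    lo = bin_lo + 1 if labeled else bin_lo
    conds = sorted({c for c, _ in fit.bin_map})
    conds = [c for c in CONDITIONS if c in conds]
    vecs = []
    for cond in conds:
        a = np.zeros(len(fit.beta))
        cols = [fit.bin_map[(cond, b)] for b in range(lo, bin_hi + 1) if (cond, b) in fit.bin_map]
        if not cols:
            raise ValueError(f"no FIR bins in range for condition {cond}")
        a[cols] = 1.0 / len(cols)
        vecs.append(a)
    A = np.vstack(vecs)
    est = A @ fit.beta
    cov = A @ fit.cov @ A.T
    return BinSummary(
        estimates={c: float(e) for c, e in zip(conds, est)},
        cov=cov,
        conditions=conds,
        dof=fit.dof,
        bins_used=(lo, bin_hi),
        window_s=bins_to_window(bin_lo, bin_hi, fit.rate_hz, labeled=labeled),
    )


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    t: float
    dof: float
    p: float
    p_adjusted: float | None = None


def contrast(fit: "GLMFit | BinSummary", weights: dict[str, float], label: str | None = None) -> ContrastResult:
    """Linear contrast of betas (GLMFit columns or BinSummary conditions)."""
    if isinstance(fit, BinSummary):
        names, beta, cov, dof = fit.conditions, np.array([fit.estimates[c] for c in fit.conditions]), fit.cov, fit.dof
    else:
        names, beta, cov, dof = fit.names, fit.beta, fit.cov, fit.dof
    missing = [k for k in weights if k not in names]
    if missing:
        raise KeyError(f"unknown labels in contrast: {missing}")
    w = np.zeros(len(names))
    for k, v in weights.items():
        w[names.index(k)] = v
    est = float(w @ beta)
    var = float(w @ cov @ w)
    se = float(np.sqrt(max(var, 0.0)))
    t = est / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), dof) if se > 0 else 1.0
    if label is None:
        label = "+".join(f"{v:+g}*{k}" for k, v in weights.items())
    return ContrastResult(label=label, estimate=est, se=se, t=float(t), dof=float(dof), p=float(p))


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags).

    The main analysis pools 6 ROIs x 2 contrasts = 12 comparisons at q=0.05.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject
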