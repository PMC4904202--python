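"""PLS1 regression of process outcomes on the four hydrolysis factors.

A single-response NIPALS implementation with:

* leave-one-out cross-validation (RMSECV, relative RMSE%, correlation
  between predicted and measured, RPD = sd(y)/RMSECV);
* the four-band RPD interpretation scale (1.5 / 2.0 / 2.5 boundaries);
* a Martens-style jackknife uncertainty test on the regression
  coefficients using the LOO segments;
* an optional log10-with-floor response transform for the heavily
  right-skewed concentration outcomes.

Predictors are autoscaled (centered, unit variance) before component
extraction; coefficients are reported both on the autoscaled and on the
raw predictor scale.  With as many components as (full-rank) predictors
PLS1 coincides with ordinary least squares, which the tests use as an
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

RPD_BANDS = (
    (1.5, "unusable"),
    (2.0, "distinguish high/low"),
    (2.5, "quantitative prediction possible"),
    (math.inf, "excellent"),
)


@dataclass
class PLSFit:
    """A fitted PLS1 model (autoscaled predictors, centered response)."""

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x a
    x_loadings: np.ndarray   # p x a
    y_loadings: np.ndarray   # a
    coef_scaled: np.ndarray  # coefficients on autoscaled predictors
    coef_raw: np.ndarray     # coefficients on raw predictors
    intercept: float
    dropped: list[int] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef_raw


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    dropped = [j for j in range(X.shape[1]) if scale[j] == 0]
    safe = np.where(scale == 0, 1.0, scale)
    Xs = (X - mean) / safe
    Xs[:, dropped] = 0.0
    return Xs, mean, safe, dropped


def fit_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSFit:
    """Fit a PLS1 model by sequential NIPALS component extraction.

    Components maximise covariance between predictor scores and the
    (deflated) response; extraction is deterministic.  Zero-variance
    predictors are dropped (coefficient 0) and the requested component
    count is truncated at the effective predictor rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if n_components < 1:
        raise ValueError("need at least one component")
    Xs, x_mean, x_scale, dropped = _autoscale(X)
    y_mean = float(y.mean())
    a_max = int(np.linalg.matrix_rank(Xs))
    a = min(n_components, max(a_max, 1))

    E, f = Xs.copy(), (y - y_mean).astype(float)
    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    for k in range(a):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            a = k
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            a = k
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        pk = E.T @ t / tt
        qk = float(f @ t / tt)
        E = E - np.outer(t, pk)
        f = f - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk
    if a == 0:
        coef_scaled = np.zeros(p)
    else:
        # b = W (P'W)^-1 q  on the autoscaled predictors
        coef_scaled = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    coef_raw = coef_scaled / x_scale
    coef_raw[dropped] = 0.0
    intercept = y_mean - float(x_mean @ coef_raw)
    return PLSFit(
        n_components=a,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W[:, :a],
        x_loadings=P[:, :a],
        y_loadings=q[:a],
        coef_scaled=coef_scaled,
        coef_raw=coef_raw,
        intercept=intercept,
        dropped=dropped,
    )


def rpd_band(rpd: float) -> str:
    """Interpretation band of an RPD value (boundaries closed on the left)."""
    if rpd <= 0:
        raise ValueError("RPD must be positive")
    for upper, label in RPD_BANDS:
        if rpd < upper:
            return label
    return RPD_BANDS[-1][1]  # pragma: no cover


@dataclass
class CVReport:
    """Leave-one-out cross-validation diagnostics."""

    predictions: np.ndarray
    rmsecv: float
    rmse_pct: float
    r: float
    rpd: float
    band: str
    n_components: int
    skipped_folds: int = 0


def loo_cv(X: np.ndarray, y: np.ndarray, n_components: int) -> CVReport:
    """Leave-one-out cross-validation of a PLS1 model.

    RMSECV = sqrt(mean (ŷ_(-i) − y_i)²); RMSE% expresses it relative to
    the response mean; RPD = sd(y, n−1)/RMSECV.  A constant response is
    degenerate (RPD is 0/0) and rejected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    sd_y = float(y.std(ddof=1))
    if sd_y == 0:
        raise ValueError("degenerate response")
    preds = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        keep = np.arange(n) != i
        try:
            fit = fit_pls1(X[keep], y[keep], n_components)
            preds[i] = fit.predict(X[i : i + 1])[0]
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    ok = ~np.isnan(preds)
    resid = preds[ok] - y[ok]
    rmsecv = float(np.sqrt(np.mean(resid**2)))
    mean_y = float(np.mean(y[ok]))
    rmse_pct = float("inf") if mean_y == 0 else abs(rmsecv / mean_y) * 100.0
    if rmsecv == 0:
        rpd, band = float("inf"), RPD_BANDS[-1][1]
    else:
        rpd = sd_y / rmsecv
        band = rpd_band(rpd)
    r = float(np.corrcoef(preds[ok], y[ok])[0, 1]) if ok.sum() > 1 else float("nan")
    return CVReport(
        predictions=preds,
        rmsecv=rmsecv,
        rmse_pct=rmse_pct,
        r=r,
        rpd=rpd,
        band=band,
        n_components=n_components,
        skipped_folds=skipped,
    )


def select_components(X: np.ndarray, y: np.ndarray, max_components: int = 4) -> int:
    """Component count minimising RMSECV over 1..max_components."""
    scores = {a: loo_cv(X, y, a).rmsecv for a in range(1, max_components + 1)}
    return min(scores, key=scores.get)


@dataclass
class MUTReport:
    """Jackknife coefficient-uncertainty (Martens-style) test results."""

    coef: np.ndarray
    jackknife_sd: np.ndarray
    t_values: np.ndarray
    significant: np.ndarray
    alpha: float


def martens_uncertainty(
    X: np.ndarray, y: np.ndarray, n_components: int, alpha: float = 0.05
) -> MUTReport:
    """Coefficient significance from the spread of LOO-segment refits.

    For each left-out sample the model is refit and its (autoscaled)
    coefficient vector stored; the jackknife variance of coefficient j is

        s_j² = (n−1)/n · Σ_i (b_j − b_j^(−i))²

    and predictor j is significant when |b_j| / s_j exceeds the
    two-sided t critical value at `alpha` with n−1 degrees of freedom.
    Deterministic for a fixed segment (sample) order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    full = fit_pls1(X, y, n_components)
    B = np.zeros((n, p))
    for i in range(n):
        keep = np.arange(n) != i
        B[i] = fit_pls1(X[keep], y[keep], n_components).coef_scaled
    dev = full.coef_scaled[None, :] - B
    s = np.sqrt((n - 1) / n * np.sum(dev**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, np.abs(full.coef_scaled) / s, np.inf)
    t[np.abs(full.coef_scaled) == 0] = 0.0
    crit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return MUTReport(
        coef=full.coef_scaled,
        jackknife_sd=s,
        t_values=t,
        significant=t > crit,
        alpha=alpha,
    )


def log10_transform(
    y: np.ndarray, floor: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """log10 of the response with values below `floor` clamped first.

    Returns the transformed response and a boolean mask of the clamped
    entries (so the flooring is reportable/invertible).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    y = np.asarray(y, dtype=float)
    floored = y < floor
    return np.log10(np.maximum(y, floor)), floored
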