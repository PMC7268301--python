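"""PLS1 regression (NIPALS), prediction, leave-one-out CV and fit metrics.

The single-response NIPALS algorithm operates on column-centred X and
centred y. Per component: the weight vector w is proportional to X'y and
normalised to unit length; scores t = Xw; X-loadings p = X't/(t't) and
y-loading q = y't/(t't); X and y are then deflated by the rank-one
approximations t p' and q t. The regression vector on centred data is
b = W (P'W)^-1 q. Columns are centred but not variance-scaled, the usual
choice for spectra where variance carries signal.

The number of latent variables is chosen by leave-one-out cross-validation
with a parsimony rule: the smallest component count whose RMSECV is within
2% of the global minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError

#: relative parsimony band for LV choice: accept the smallest LV count whose
#: RMSECV is within this fraction of the global minimum
PARSIMONY_REL = 0.02

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """Fitted PLS1 model: centring constants, factorisation and coefficients.

    ``coef`` maps centred X to centred y; training scores ``scores`` are
    retained for score plots. ``n_lv`` is the number of components actually
    extracted (may be fewer than requested if deflation exhausts X, in
    which case ``early_stopped`` is set).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x n_lv
    x_loadings: np.ndarray    # p x n_lv
    y_loadings: np.ndarray    # n_lv
    coef: np.ndarray          # p
    scores: np.ndarray        # n x n_lv
    early_stopped: bool = False
    wavenumbers: np.ndarray | None = None  # axis the model was fitted on, if known


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary."""

    rmsecv_per_lv: np.ndarray   # index k-1 holds RMSECV at k components
    chosen_lv: int
    cv_predictions: np.ndarray  # LOO predictions at chosen_lv


@dataclass
class FitMetrics:
    r2: float
    rmse: float


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Run NIPALS on centred data; returns (W, P, q, T, early_stopped)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    scale = max(np.abs(Xc).max(initial=0.0), 1.0)
    k = 0
    for k in range(n_lv):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= 1e3 * _EPS * scale * max(np.abs(y).max(initial=0.0), 1.0):
            return W[:, :k], P[:, :k], q[:k], T[:, :k], True
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt <= (1e3 * _EPS * scale) ** 2 * n:
            return W[:, :k], P[:, :k], q[:k], T[:, :k], True
        pk = X.T @ t / tt
        qk = float(y @ t) / tt
        X = X - np.outer(t, pk)
        y = y - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
    return W, P, q, T, False


def _coef(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int | None = None) -> np.ndarray:
    """Regression vector using the first k components: b = W (P'W)^-1 q."""
    if k is None:
        k = W.shape[1]
    if k == 0:
        return np.zeros(W.shape[0])
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int,
             wavenumbers: np.ndarray | None = None) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    Extraction stops early (with a warning recorded on the model) if
    deflation exhausts the covariance before ``n_lv`` components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"y has {y.size} entries for {n} rows of X")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ConfigError(f"n_lv must be in [1, {min(n - 1, p)}] (got {n_lv})")
    if np.ptp(y) == 0:
        raise ValidationError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T, stopped = _nipals(X - x_mean, y - y_mean, n_lv)
    if stopped:
        warnings.warn(
            f"NIPALS stopped after {W.shape[1]} of {n_lv} requested components "
            "(X exhausted)", stacklevel=2,
        )
    return PLSModel(
        n_lv=W.shape[1], x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q,
        coef=_coef(W, P, q), scores=T, early_stopped=stopped,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
    )


def predict(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response: y_hat = (X_new - x_mean) b + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValidationError(
            f"X has {X_new.shape[1]} columns; model expects {m.x_mean.size}"
        )
    return (X_new - m.x_mean) @ m.coef + m.y_mean


def transform(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new spectra onto the model's score space (n x n_lv)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValidationError(
            f"X has {X_new.shape[1]} columns; model expects {m.x_mean.size}"
        )
    # scores for new data use the weights in original X space: T = Xc W (P'W)^-1
    R = m.weights @ np.linalg.inv(m.x_loadings.T @ m.weights)
    return (X_new - m.x_mean) @ R


def loo_cv(X: np.ndarray, y: np.ndarray, max_lv: int = 20) -> CVResult:
    """Leave-one-out cross-validation over 1..max_lv components.

    Each fold re-centres and refits on the remaining n-1 samples. The
    chosen component count is the smallest whose RMSECV lies within 2% of
    the global minimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ConfigError(f"leave-one-out needs n >= 3 (got {n})")
    cap = min(n - 2, p)
    if max_lv > cap:
        warnings.warn(f"max_lv {max_lv} clipped to {cap}", stacklevel=2)
        max_lv = cap
    if max_lv < 1:
        raise ConfigError("max_lv must be >= 1")

    preds = np.zeros((n, max_lv))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        xm = Xi.mean(axis=0)
        ym = yi.mean()
        W, P, q, _, _ = _nipals(Xi - xm, yi - ym, max_lv)
        got = W.shape[1]
        xc = X[i] - xm
        for k in range(1, max_lv + 1):
            b = _coef(W, P, q, min(k, got))
            preds[i, k - 1] = xc @ b + ym
        mask[i] = True

    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    best = float(rmsecv.min())
    chosen = int(np.flatnonzero(rmsecv <= (1.0 + PARSIMONY_REL) * best)[0]) + 1
    return CVResult(rmsecv_per_lv=rmsecv, chosen_lv=chosen,
                    cv_predictions=preds[:, chosen - 1].copy())


def metrics(y: np.ndarray, y_hat: np.ndarray) -> FitMetrics:
    """R^2 (about the mean of y) and RMSE."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size or y.size < 2:
        raise ValidationError("y and y_hat must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("R^2 undefined: response has zero variance")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return FitMetrics(r2=1.0 - ss_res / ss_tot, rmse=float(np.sqrt(np.mean((y - y_hat) ** 2))))
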