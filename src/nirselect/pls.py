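"""PLS1 regression engine, calibration metrics, and MCCV latent-variable
selection.

The regression core is NIPALS PLS1 with deflation of X only: successive
weight vectors are extracted from the covariance of the (deflated)
spectral matrix with the response, giving mutually orthogonal score
vectors.  At full rank (n_lv = min(n-1, p)) the predictions coincide with
ordinary least squares.  The latent-variable count — the model's single
complexity parameter — is chosen by Monte Carlo cross-validation: the
smallest count whose pooled validation RMSE attains the curve minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .partition import MCCVPlan, mccv_splits

__all__ = ["PLSModel", "MetricReport", "fit_pls", "predict", "rmse",
           "r_squared", "rmsecv", "select_lv_mccv"]


@dataclass
class PLSModel:
    """Fitted PLS1 model on (optionally masked) spectral channels.

    ``b`` is the regression coefficient vector on centred data, one entry
    per selected channel; prediction is y_mean + (X - x_mean) @ b.
    ``n_lv_eff`` can fall below ``n_lv`` if X deflates to numerical zero.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray     # p_sel x n_lv_eff
    x_loadings: np.ndarray  # p_sel x n_lv_eff
    y_loadings: np.ndarray  # n_lv_eff
    b: np.ndarray           # p_sel
    channel_mask: Optional[np.ndarray] = None
    n_lv_eff: int = 0


def _as_mask(mask, p: int) -> np.ndarray:
    if mask is None:
        return np.ones(p, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype != bool:
        m = np.zeros(p, dtype=bool)
        m[mask] = True
        return m
    return mask.copy()


def _pls1_core(E: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 inner loop on pre-centred data.

    Returns (W, P, q, a) with a = effective component count.  ``E`` is
    consumed (deflated in place); pass a copy.  Kept lean: the selector
    fitness loops call this tens of thousands of times.
    """
    n, p = E.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    a = 0
    for k in range(n_lv):
        w = E.T @ yc
        nw = np.sqrt(w @ w)
        if nw < 1e-13:
            break  # X (or its covariance with y) exhausted
        w /= nw
        t = E @ w
        tt = t @ t
        if tt < 1e-26:
            break
        W[:, k] = w
        pk = E.T @ t
        pk /= tt
        P[:, k] = pk
        q[k] = (yc @ t) / tt
        E -= t[:, None] * pk
        a = k + 1
    return W[:, :a], P[:, :a], q[:a], a


def _pls1_coef(Xtr: np.ndarray, ytr: np.ndarray, n_lv: int):
    """Centre, run NIPALS, return (x_mean, y_mean, b) — fast path, no
    validation."""
    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    W, P, q, a = _pls1_core(Xtr - x_mean, ytr - y_mean, n_lv)
    if a == 0:
        raise ValueError("no usable covariance between X and y")
    b = W @ np.linalg.solve(P.T @ W, q)
    return x_mean, y_mean, b


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            mask=None) -> PLSModel:
    """NIPALS PLS1 on column-centred X and centred y.

    ``mask`` restricts the fit to a channel subset (boolean vector or
    index array); the returned coefficients refer to those channels only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m = _as_mask(mask, X.shape[1])
    Xs = X[:, m]
    n, p = Xs.shape
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > min(n - 1, p):
        raise ValueError(
            f"n_lv={n_lv} exceeds min(n_samples-1, n_channels)="
            f"{min(n - 1, p)}")
    if np.isnan(Xs).any() or np.isnan(y).any():
        raise ValueError("NaN in input")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")

    x_mean = Xs.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, a = _pls1_core(Xs - x_mean, y - y_mean, n_lv)
    if a == 0:
        raise ValueError("no usable covariance between X and y")
    # b = W (P^T W)^{-1} q ; P^T W is unit upper triangular for NIPALS PLS1
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, weights=W,
                    x_loadings=P, y_loadings=q, b=b, channel_mask=m,
                    n_lv_eff=a)


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response: y_mean + (X - x_mean) @ b.

    ``X`` may carry either all original channels (the model's mask is
    applied) or exactly the model's selected channels.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p_sel = model.b.shape[0]
    if X.shape[1] == p_sel:
        Xs = X
    elif model.channel_mask is not None and X.shape[1] == model.channel_mask.shape[0]:
        Xs = X[:, model.channel_mask]
    else:
        raise ValueError(
            f"X has {X.shape[1]} channels; model expects {p_sel} selected "
            f"(or the full {model.channel_mask.shape[0]})")
    return model.y_mean + (Xs - model.x_mean) @ model.b


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error; RMSEP when y is the prediction set."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant response; R^2 undefined")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def rmsecv(X: np.ndarray, y: np.ndarray, n_lv: int, plan: MCCVPlan,
           mask=None, splits=None) -> float:
    """Pooled validation RMSE over the plan's Monte Carlo splits.

    The model is refit per repeat on the calibration subset restricted to
    ``mask``.  ``splits`` allows reusing a precomputed split sequence (the
    selectors evaluate thousands of masks against one shared plan, making
    subset comparisons paired).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m = _as_mask(mask, X.shape[1])
    if int(m.sum()) < n_lv:
        raise ValueError(f"mask selects {int(m.sum())} < n_lv={n_lv} channels")
    if splits is None:
        splits = mccv_splits(X.shape[0], plan)
    Xs = X[:, m]
    sq, cnt = 0.0, 0
    for sp in splits:
        x_mean, y_mean, b = _pls1_coef(Xs[sp.train_idx], y[sp.train_idx], n_lv)
        r = y[sp.test_idx] - (y_mean + (Xs[sp.test_idx] - x_mean) @ b)
        sq += float(r @ r)
        cnt += r.size
    return float(np.sqrt(sq / cnt))


def select_lv_mccv(X: np.ndarray, y: np.ndarray, max_lv: int,
                   plan: MCCVPlan) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by MCCV.

    Returns (best_n_lv, curve) where curve[k-1] is the pooled RMSECV at k
    latent variables, k = 1..max_lv.  The smallest count within 1e-12 of
    the curve minimum wins (parsimony tie-break).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    bound = min(n - 1, X.shape[1])
    if not 1 <= max_lv <= bound:
        raise ValueError(f"max_lv must be in [1, {bound}], got {max_lv}")
    splits = mccv_splits(n, plan)
    cal_bound = min(len(splits[0].train_idx) - 1, X.shape[1])
    if max_lv > cal_bound:
        raise ValueError(
            f"max_lv={max_lv} infeasible for calibration size "
            f"{len(splits[0].train_idx)}")
    curve = np.array([rmsecv(X, y, k, plan, splits=splits)
                      for k in range(1, max_lv + 1)])
    best = int(np.flatnonzero(curve <= curve.min() + 1e-12)[0]) + 1
    return best, curve


@dataclass(frozen=True)
class MetricReport:
    """The study's three figures of merit plus model size."""
    rmsecv: float
    rmsep: float
    r2: float
    n_variables: int

    def __post_init__(self):
        if self.rmsecv < 0 or self.rmsep < 0:
            raise ValueError("rmse values must be nonnegative")
        if self.r2 > 1:
            raise ValueError("r2 cannot exceed 1")
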