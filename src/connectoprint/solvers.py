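"""Proximal-gradient (FISTA) solver for mixed-penalty linear classifiers.

Minimizes, over weights ``w`` and unpenalized intercept ``b``,

    (1/n) sum_i loss(y_i, b + x_i . w)
        + lam * (alpha * ||w||_1 + (1 - alpha) / 2 * ||w||_2^2)

— the glmnet parameterization, where ``alpha`` is the L1 share of the
penalty.  Two losses are supported:

* ``logistic`` — log(1 + exp(-y z)), the binomial deviance;
* ``huber_hinge`` — the huberized (quadratically smoothed) hinge of
  HHSVM/gcdnet, which behaves like the SVM hinge but has a Lipschitz
  gradient so accelerated first-order methods apply.

The L1 part enters through the soft-threshold proximal operator (giving
exact zeros, hence well-defined retained-edge sets); the L2 part stays in
the smooth term.  Warm starts across a decreasing lambda path make dense
paths cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_enet", "fit_enet_path"]


def _logistic_value_grad(margin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Loss value and d loss / d margin for margins y*z (labels +/-1)."""
    # stable log(1 + exp(-m)) and -sigmoid(-m)
    val = np.logaddexp(0.0, -margin)
    dm = -1.0 / (1.0 + np.exp(margin))
    return val, dm


def _huber_hinge_value_grad(margin: np.ndarray, delta: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    val = np.zeros_like(margin)
    dm = np.zeros_like(margin)
    quad = (margin > 1 - delta) & (margin <= 1)
    lin = margin <= 1 - delta
    val[quad] = (1 - margin[quad]) ** 2 / (2 * delta)
    dm[quad] = -(1 - margin[quad]) / delta
    val[lin] = 1 - margin[lin] - delta / 2
    dm[lin] = -1.0
    return val, dm


def _spectral_norm_sq(x: np.ndarray, n_iter: int = 30, seed: int = 0) -> float:
    """Largest squared singular value of [X 1] by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(x.shape[1] + 1)
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        u = x @ v[:-1] + v[-1]
        v_new = np.concatenate([x.T @ u, [u.sum()]])
        nrm = np.linalg.norm(v_new)
        if nrm == 0:
            return 1.0
        v = v_new / nrm
    u = x @ v[:-1] + v[-1]
    return float(u @ u)


def _objective(x, y, w, b, lam, alpha, loss, delta):
    margin = y * (x @ w + b)
    if loss == "logistic":
        val, _ = _logistic_value_grad(margin)
    else:
        val, _ = _huber_hinge_value_grad(margin, delta)
    pen = lam * (alpha * np.abs(w).sum() + (1 - alpha) / 2 * w @ w)
    return val.mean() + pen


def fit_enet(x: np.ndarray, y: np.ndarray, lam: float, alpha: float = 0.1,
             loss: str = "logistic", delta: float = 1.0,
             w0: np.ndarray | None = None, b0: float = 0.0,
             max_iter: int = 1000, tol: float = 1e-8,
             lipschitz: float | None = None) -> tuple[np.ndarray, float]:
    """Solve one mixed-penalty problem; returns (weights, intercept).

    ``y`` may be boolean/0-1 or +/-1.  ``tol`` is the relative objective
    decrease below which iteration stops (checked with FISTA restart on
    objective increase).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    ypm = np.where(y > 0, 1.0, -1.0)
    n, p = x.shape
    if loss not in ("logistic", "huber_hinge"):
        raise ValueError(f"unknown loss {loss!r}")
    curv = 0.25 if loss == "logistic" else 1.0 / delta
    if lipschitz is None:
        lipschitz = _spectral_norm_sq(x)
    step = 1.0 / (curv * lipschitz / n + lam * (1 - alpha) + 1e-12)

    w = np.zeros(p) if w0 is None else w0.astype(float).copy()
    b = float(b0)
    wv, bv = w.copy(), b   # FISTA extrapolation point
    t_k = 1.0
    obj_prev = _objective(x, ypm, w, b, lam, alpha, loss, delta)
    thr = step * lam * alpha
    for _ in range(max_iter):
        margin = ypm * (x @ wv + bv)
        if loss == "logistic":
            _, dm = _logistic_value_grad(margin)
        else:
            _, dm = _huber_hinge_value_grad(margin, delta)
        gz = ypm * dm / n                 # d loss / d z, averaged
        grad_w = x.T @ gz + lam * (1 - alpha) * wv
        grad_b = gz.sum()
        w_new = wv - step * grad_w
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - thr, 0.0)
        b_new = bv - step * grad_b

        obj = _objective(x, ypm, w_new, b_new, lam, alpha, loss, delta)
        if obj > obj_prev:               # restart acceleration
            t_k = 1.0
            wv, bv = w.copy(), b
            continue
        t_next = (1 + np.sqrt(1 + 4 * t_k**2)) / 2
        beta = (t_k - 1) / t_next
        wv = w_new + beta * (w_new - w)
        bv = b_new + beta * (b_new - b)
        w, b, t_k = w_new, b_new, t_next
        if obj_prev - obj < tol * (abs(obj_prev) + 1e-12):
            obj_prev = obj
            break
        obj_prev = obj
    return w, b


def fit_enet_path(x: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                  alpha: float = 0.1, loss: str = "logistic",
                  delta: float = 1.0, max_iter: int = 1000,
                  tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started solutions along a decreasing lambda path.

    Returns (coefs, intercepts): one row of ``coefs`` per lambda.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda path must be non-increasing")
    lips = _spectral_norm_sq(x)
    coefs = np.empty((lambdas.size, x.shape[1]))
    intercepts = np.empty(lambdas.size)
    w, b = None, 0.0
    for i, lam in enumerate(lambdas):
        w, b = fit_enet(x, y, lam, alpha=alpha, loss=loss, delta=delta,
                        w0=w, b0=b, max_iter=max_iter, tol=tol,
                        lipschitz=lips)
        coefs[i] = w
        intercepts[i] = b
    return coefs, intercepts
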