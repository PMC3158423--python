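"""Partial least squares regression by NIPALS latent-component extraction.

Components are extracted iteratively: each one pairs an X-score direction
with the response residual so as to maximize their covariance, the matrices
are deflated, and the next component works on the residuals. The response
may have any number of columns (PLS2); with a single response column each
component's inner loop converges in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateResponseError


@dataclass
class PLSModel:
    """Fitted PLS state: centering vectors and the regression coefficients
    assembled from the extracted weights/loadings."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # W  (p, k)
    x_loadings: np.ndarray  # P  (p, k)
    y_loadings: np.ndarray  # Q  (q, k)
    coef: np.ndarray  # B  (p, q)
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit PLS with ``n_components`` latent components.

    ``n_components`` must lie in [1, nAttr - 1] where nAttr is the number of
    feature columns. Raises :class:`DegenerateResponseError` when the
    response has zero variance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, p = X.shape
    q = Y.shape[1]
    if not 1 <= n_components <= p - 1:
        raise ValueError(
            f"n_components must be in [1, {p - 1}] for {p} features, got {n_components}"
        )
    if np.allclose(Y.var(axis=0), 0.0):
        raise DegenerateResponseError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xr = X - x_mean
    Yr = Y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))

    k_used = 0
    for k in range(n_components):
        # start u from the residual response column with the largest variance
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        if np.allclose(Yr, 0.0) or np.allclose(Xr, 0.0):
            break  # nothing left to model
        w = np.zeros(p)
        for _ in range(max_iter):
            denom = float(u @ u)
            if denom == 0.0:
                break
            w_new = Xr.T @ u / denom
            norm = float(np.linalg.norm(w_new))
            if norm == 0.0:
                break
            w_new /= norm
            t = Xr @ w_new
            tt = float(t @ t)
            if tt == 0.0:
                break
            c = Yr.T @ t / tt
            cc = float(c @ c)
            u_new = Yr @ c / cc if cc else u
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            u = u_new
        t = Xr @ w
        tt = float(t @ t)
        if tt == 0.0:
            break
        p_load = Xr.T @ t / tt
        q_load = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q_load)
        W[:, k], P[:, k], Q[:, k] = w, p_load, q_load
        k_used += 1

    W, P, Q = W[:, :k_used], P[:, :k_used], Q[:, :k_used]
    if k_used:
        # B = W (P'W)^-1 Q'
        coef = W @ np.linalg.solve(P.T @ W, Q.T)
    else:
        coef = np.zeros((p, q))
    return PLSModel(x_mean, y_mean, W, P, Q, coef, k_used)
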