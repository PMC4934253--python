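"""PLS regression core, PRESS-based factor selection, RMSEP / RMSECV metrics.

The regression engine is a deterministic sequential PLS2: both blocks are
mean-centered, each factor's X-weight is the dominant left singular vector of
X_d^T Y_d (computed from the small q x q eigenproblem, so extraction is exact
and iteration-free), and both residual blocks are deflated by the extracted
score.  All factor counts 1..kmax are available from a single pass, which the
leave-one-out loops exploit.

Factor-count selection follows the first-upturn PRESS rule: the smallest
k - 1 such that PRESS_k / PRESS_{k-1} > 1, falling back to kmax when the
trace never turns up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """Fitted centered bilinear factor model.

    ``weights`` (p x k), ``x_loadings`` (p x k) and ``y_loadings`` (q x k)
    suffice to predict new spectra; ``coef`` caches the (p x q) regression
    matrix at ``n_factors``.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    press_trace: np.ndarray | None = None
    trained_on: tuple | None = None

    def predict(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        """Predict responses for spectra ``X`` (rows)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = self.n_factors if n_factors is None else n_factors
        if not 1 <= k <= self.weights.shape[1]:
            raise ValueError(f"n_factors must lie in [1, {self.weights.shape[1]}]")
        Xd = X - self.x_mean[None, :]
        Y = np.tile(self.y_mean, (X.shape[0], 1)).astype(float)
        for a in range(k):
            t = Xd @ self.weights[:, a]
            Xd = Xd - np.outer(t, self.x_loadings[:, a])
            Y += np.outer(t, self.y_loadings[:, a])
        return Y

    def to_text(self) -> str:
        """Plain-text key-value serialization for provenance records."""
        lines = [f"n_factors: {self.n_factors}"]
        for name in ("x_mean", "y_mean"):
            vec = getattr(self, name)
            lines.append(f"{name}: " + " ".join(repr(float(v)) for v in vec))
        for name in ("weights", "x_loadings", "y_loadings", "coef"):
            mat = getattr(self, name)
            lines.append(f"{name}:")
            for row in mat:
                lines.append("  " + " ".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"


def _extract_factors(X: np.ndarray, Y: np.ndarray, kmax: int):
    """Sequential factor extraction on centered blocks.

    Returns (W, P, Q, k_eff); extraction stops early when the residual
    cross-covariance or score norm underflows (rank exhausted).
    """
    m, p = X.shape
    q = Y.shape[1]
    W = np.zeros((p, kmax))
    P = np.zeros((p, kmax))
    Q = np.zeros((q, kmax))
    Xd = X.copy()
    Yd = Y.copy()
    scale = max(float(np.abs(X).max()), 1.0) * max(float(np.abs(Y).max()), 1.0)
    tol = (scale + 1.0) * 1e-13 * max(m, p)
    k_eff = 0
    for a in range(kmax):
        S = Xd.T @ Yd  # (p, q)
        if q == 1:
            w = S[:, 0].copy()
        else:
            evals, evecs = np.linalg.eigh(S.T @ S)
            w = S @ evecs[:, -1]
        nw = np.linalg.norm(w)
        if nw <= tol:
            break
        w /= nw
        if w[np.argmax(np.abs(w))] < 0:  # deterministic sign
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol**2:
            break
        p_load = (Xd.T @ t) / tt
        q_load = (Yd.T @ t) / tt
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, q_load)
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q_load
        k_eff = a + 1
    return W[:, :k_eff], P[:, :k_eff], Q[:, :k_eff], k_eff


def fit_pls(X: np.ndarray, Y: np.ndarray, n_factors: int, trained_on: tuple | None = None) -> PLSModel:
    """Fit a PLS2 model with ``n_factors`` latent variables.

    Rank deficiency below the requested count triggers a warning and the
    model is truncated to the extractable factors.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    m, p = X.shape
    if Y.shape[0] != m:
        raise ValueError("X and Y row counts differ")
    if m < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= n_factors <= min(m - 1, p):
        raise ValueError(f"n_factors must lie in [1, {min(m - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, P, Q, k_eff = _extract_factors(X - x_mean, Y - y_mean, n_factors)
    if k_eff == 0:
        # no extractable covariance: constant model at the mean
        W = np.zeros((p, 1))
        P = np.zeros((p, 1))
        Q = np.zeros((Y.shape[1], 1))
        coef = np.zeros((p, Y.shape[1]))
        k_eff = 1
    else:
        if k_eff < n_factors:
            warnings.warn(
                f"rank supports only {k_eff} of {n_factors} requested factors",
                RuntimeWarning,
            )
        # B_k = W (P^T W)^{-1} Q^T  (triangular system)
        R = np.linalg.solve(P.T @ W, np.eye(k_eff))
        coef = W @ R @ Q.T
    return PLSModel(
        n_factors=k_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        coef=coef,
        trained_on=trained_on,
    )


def _loo_residual_cube(X: np.ndarray, Y: np.ndarray, kmax: int) -> np.ndarray:
    """Leave-one-out residuals for every factor count.

    Returns an (m, q, kmax) array of held-out residuals; factor counts beyond
    a fold's extractable rank repeat the deepest available prediction.
    """
    m, p = X.shape
    q = Y.shape[1]
    res = np.zeros((m, q, kmax))
    mask = np.ones(m, dtype=bool)
    for j in range(m):
        mask[j] = False
        Xt, Yt = X[mask], Y[mask]
        xm = Xt.mean(axis=0)
        ym = Yt.mean(axis=0)
        W, P, Q, k_eff = _extract_factors(Xt - xm, Yt - ym, kmax)
        xd = X[j] - xm
        yhat = ym.copy()
        for a in range(kmax):
            if a < k_eff:
                t = float(xd @ W[:, a])
                xd = xd - t * P[:, a]
                yhat = yhat + t * Q[:, a]
            res[j, :, a] = Y[j] - yhat
        mask[j] = True
    return res


def press_trace(X: np.ndarray, Y: np.ndarray, kmax: int) -> np.ndarray:
    """Leave-one-out PRESS_k for k = 1..kmax, pooled over all responses."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    m, p = X.shape
    if m < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if not 1 <= kmax <= min(m - 2, p):
        raise ValueError(f"kmax must lie in [1, {min(m - 2, p)}]")
    res = _loo_residual_cube(X, Y, kmax)
    return (res**2).sum(axis=(0, 1))


def select_factors(press: np.ndarray, ratio_threshold: float = 1.0) -> int:
    """First-upturn PRESS rule: smallest k-1 with PRESS_k/PRESS_{k-1} > 1.

    A zero PRESS_{k-1} counts as an upturn (growth stops); if the trace never
    turns up the deepest count is returned.  Never returns 0.

    ``ratio_threshold`` is the critical ratio of the F-test-style variant:
    raising it slightly above 1 (e.g. 1.05) ignores sub-noise upturns.
    """
    press = np.asarray(press, dtype=float).ravel()
    if press.size == 0:
        raise ValueError("empty PRESS trace")
    if np.any(press < 0):
        raise ValueError("PRESS values must be non-negative")
    if ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must be >= 1")
    for k in range(2, press.size + 1):
        if press[k - 2] == 0.0 or press[k - 1] > ratio_threshold * press[k - 2]:
            return k - 1
    return press.size


def rmsep(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Root mean square error of prediction, per analyte (column)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if yhat.ndim == 1:
        yhat = yhat[:, None]
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    return np.sqrt(((y - yhat) ** 2).mean(axis=0))


def rmsecv_loo(
    X: np.ndarray,
    Y: np.ndarray,
    kmax: int | None = None,
    factor_rule: str = "pooled_press",
    ratio_threshold: float = 1.0,
) -> float:
    """Leave-one-out RMSECV with PRESS-rule factor selection.

    factor_rule
        ``"pooled_press"`` (default): one factor count for all folds, chosen
        by the first-upturn rule on the pooled LOO PRESS trace; RMSECV is the
        root mean squared held-out residual at that count.
        ``"per_fold"``: each fold selects its own count from an inner
        leave-one-out PRESS trace on its training samples (nested LOO).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    m, p = X.shape
    if m < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if kmax is None:
        kmax = min(m - 2, p, 15)
    kmax = max(1, min(kmax, m - 2, p))
    if factor_rule == "pooled_press":
        res = _loo_residual_cube(X, Y, kmax)
        press = (res**2).sum(axis=(0, 1))
        k = select_factors(press, ratio_threshold)
        return float(np.sqrt((res[:, :, k - 1] ** 2).mean()))
    if factor_rule == "per_fold":
        sq = []
        mask = np.ones(m, dtype=bool)
        for j in range(m):
            mask[j] = False
            Xt, Yt = X[mask], Y[mask]
            inner_kmax = max(1, min(kmax, Xt.shape[0] - 2, p))
            if Xt.shape[0] < 3:
                mask[j] = True
                raise ValueError("too few samples for nested leave-one-out")
            k = select_factors(press_trace(Xt, Yt, inner_kmax), ratio_threshold)
            model = fit_pls(Xt, Yt, k)
            sq.append((Y[j] - model.predict(X[j][None, :])[0]) ** 2)
            mask[j] = True
        return float(np.sqrt(np.mean(sq)))
    raise ValueError(f"unknown factor_rule {factor_rule!r}")
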