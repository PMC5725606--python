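"""Fixed-X knockoff filter for FDR-controlled variable selection.

Implements the original fixed-design knockoff construction of Barber &
Candes: equicorrelated knockoff copies of the (column-normalized) design, the
Lasso signed-max path statistic, and the knockoff+ selection threshold that
controls the false-discovery rate at a user level ``q``.  Written against the
procedure's defining linear-algebra identities (Gram matrix preserved,
cross-correlations reduced by ``s``) and verified by those identities in the
test suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import lasso_path

__all__ = [
    "equicorrelated_knockoffs",
    "lasso_signed_max_stats",
    "knockoff_threshold",
    "knockoff_select",
]


def _normalize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=0)
    norms_safe = np.where(norms > 0, norms, 1.0)
    return X / norms_safe, norms


def equicorrelated_knockoffs(
    X: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Equicorrelated fixed-X knockoff copy of a column-normalized design.

    Requires ``n >= 2p``.  With Gram matrix ``G = X'X`` (unit diagonal) and
    ``s = min(2 lambda_min(G), 1)``, returns ``Xt`` satisfying
    ``Xt'Xt = G`` and ``X'Xt = G - s I``.
    """
    n, p = X.shape
    if n < 2 * p:
        raise ValueError(f"fixed-X knockoffs need n >= 2p (n={n}, p={p})")
    if rng is None:
        rng = np.random.default_rng()
    G = X.T @ X
    evals = np.linalg.eigvalsh(G)
    lam_min = max(float(evals[0]), 0.0)
    s = min(2.0 * lam_min, 1.0)
    if s <= 0:
        # singular design: knockoffs collapse onto X (zero power, valid FDR)
        return X.copy()
    Ginv = np.linalg.pinv(G, hermitian=True)
    # C'C = 2 s I - s^2 Ginv, PSD by construction of s
    mat = 2.0 * s * np.eye(p) - (s * s) * Ginv
    w, V = np.linalg.eigh(mat)
    C = np.sqrt(np.clip(w, 0.0, None))[:, None] * V.T
    # orthonormal basis orthogonal to col(X)
    Q, _ = np.linalg.qr(X, mode="complete")
    U = Q[:, p : 2 * p]
    return X @ (np.eye(p) - s * Ginv) + U @ C


def lasso_signed_max_stats(
    X: np.ndarray, Xt: np.ndarray, y: np.ndarray, n_alphas: int = 200
) -> np.ndarray:
    """Signed-max Lasso path statistics ``W_j``.

    ``Z_j`` is the largest penalty at which feature ``j`` enters the Lasso
    path of ``y`` on the augmented design ``[X, Xt]``;
    ``W_j = max(Z_j, Zt_j) * sign(Z_j - Zt_j)``.  Large positive ``W_j`` is
    evidence the original feature beats its knockoff.
    """
    p = X.shape[1]
    Xa = np.hstack([X, Xt])
    alphas, coefs, _ = lasso_path(Xa, y, alphas=n_alphas, eps=1e-4)
    nonzero = coefs != 0  # (2p, n_alphas); alphas descend along the path
    entered = nonzero.any(axis=1)
    first = nonzero.argmax(axis=1)
    Z = np.where(entered, alphas[np.minimum(first, len(alphas) - 1)], 0.0)
    Zo, Zk = Z[:p], Z[p:]
    return np.maximum(Zo, Zk) * np.sign(Zo - Zk)


def knockoff_threshold(W: np.ndarray, q: float, offset: int = 1) -> float:
    """Knockoff(+) data-dependent threshold controlling FDR at level ``q``.

    ``offset=1`` gives the knockoff+ variant (exact FDR control); the smallest
    ``t`` with ``(offset + #{W_j <= -t}) / max(1, #{W_j >= t}) <= q``, or
    ``inf`` when no threshold qualifies (select nothing).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    candidates = np.sort(np.unique(np.abs(W[W != 0])))
    for t in candidates:
        fdp = (offset + np.sum(W <= -t)) / max(1, np.sum(W >= t))
        if fdp <= q:
            return float(t)
    return np.inf


def knockoff_select(
    X: np.ndarray,
    y: np.ndarray,
    q: float,
    rng: np.random.Generator | None = None,
    n_alphas: int = 200,
) -> np.ndarray:
    """Full fixed-X knockoff+ selection on a raw design.

    Centers ``y`` and the columns of ``X``, normalizes columns, augments with
    zero rows (and residual-scale noise on ``y``) when ``p <= n < 2p``, builds
    equicorrelated knockoffs, and returns the boolean selection mask over the
    ``p`` original features.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Xn, norms = _normalize_columns(Xc)
    usable = norms > 1e-12  # constant columns can never be selected
    Xn = Xn[:, usable]
    p_use = Xn.shape[1]
    if p_use == 0:
        return np.zeros(p, dtype=bool)
    if n < p_use:
        raise ValueError(f"knockoff construction infeasible: n={n} < p={p_use}")
    if n < 2 * p_use:
        # row augmentation: zero design rows, y rows at the residual scale
        beta, *_ = np.linalg.lstsq(Xn, yc, rcond=None)
        resid = yc - Xn @ beta
        dof = max(n - p_use, 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        extra = 2 * p_use - n
        Xn = np.vstack([Xn, np.zeros((extra, p_use))])
        yc = np.concatenate([yc, rng.normal(0.0, sigma, size=extra)])
    Xt = equicorrelated_knockoffs(Xn, rng=rng)
    W = lasso_signed_max_stats(Xn, Xt, yc, n_alphas=n_alphas)
    T = knockoff_threshold(W, q)
    selected = np.zeros(p, dtype=bool)
    selected[np.flatnonzero(usable)] = W >= T
    return selected
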