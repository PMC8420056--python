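"""Single-kernel linear mixed model machinery.

Implements the spectral (eigendecomposition) route to REML for the model

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with the variance ratio delta = se2/sg2 profiled out on the restricted
likelihood. Both the association scan (P3D: variance components estimated
once under the null, then each marker tested by GLS at the fixed ratio) and
the ridge-regression BLUP predictor (K = M M') are thin layers over this
module.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_DELTA_RANGE = (-10.0, 10.0)


class MixedModelContext:
    """Precomputed spectral quantities for repeated REML fits sharing (K, X).

    Parameters
    ----------
    K : (n, n) symmetric PSD covariance kernel (e.g. kinship).
    X : (n, q) full-rank fixed-effect design (intercept + covariates).
    """

    def __init__(self, K: np.ndarray, X: np.ndarray):
        K = np.asarray(K, dtype=float)
        X = np.asarray(X, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n):
            raise ValueError("K must be square")
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError("X must be n x q")
        self.n, self.q = n, X.shape[1]
        self.X = X
        # full spectrum of K, for whitening
        d, U = np.linalg.eigh(K)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        # restricted spectrum: eigenpairs of S(K+I)S with S the projector off
        # X; adding I keeps the complement-of-X eigenspace strictly positive
        # even for rank-deficient K, so its eigenvectors stay orthogonal to X
        Q, _ = np.linalg.qr(X)
        K1 = K + np.eye(n)
        SKS = K1 - Q @ (Q.T @ K1)
        SKS = SKS - (SKS @ Q) @ Q.T
        SKS = 0.5 * (SKS + SKS.T)
        lam, Ur = np.linalg.eigh(SKS)
        order = np.argsort(lam)[::-1][: n - self.q]
        self.lam = np.clip(lam[order] - 1.0, 0.0, None)
        self.Ur = Ur[:, order]
        self._Q = Q

    # -- REML ---------------------------------------------------------------

    def _restricted_ll(self, log_delta: float, xi2: np.ndarray) -> float:
        delta = np.exp(log_delta)
        nq = self.n - self.q
        denom = self.lam + delta
        s = float(np.sum(xi2 / denom))
        return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(s))
                      - float(np.sum(np.log(denom))))

    def reml(self, y: np.ndarray) -> tuple[float, float, float]:
        """REML variance components for trait ``y``.

        Returns ``(delta, sg2, se2)`` with delta = se2/sg2. The restricted
        likelihood is unimodal in log-delta for almost all data; a coarse
        grid seeds a bounded Brent refinement to be safe.
        """
        y = np.asarray(y, dtype=float)
        xi = self.Ur.T @ y
        xi2 = xi**2
        grid = np.linspace(*_LOG_DELTA_RANGE, 41)
        lls = [self._restricted_ll(g, xi2) for g in grid]
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(lambda g: -self._restricted_ll(g, xi2),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        delta = float(np.exp(res.x))
        nq = self.n - self.q
        sg2 = float(np.sum(xi2 / (self.lam + delta))) / nq
        se2 = delta * sg2
        return delta, sg2, se2

    # -- whitening and GLS --------------------------------------------------

    def whiten(self, A: np.ndarray, delta: float) -> np.ndarray:
        """Decorrelate columns of ``A``: multiply by (K + delta I)^(-1/2).

        The overall sg2 scalar is omitted; it cancels in every Wald
        statistic and variance ratio computed downstream.
        """
        scale = 1.0 / np.sqrt(self.d + delta)
        return self.U @ (scale[:, None] * (self.U.T @ A))

    def rotate(self, A: np.ndarray) -> np.ndarray:
        """One-time rotation U'A so per-trait whitening is a diagonal scale."""
        return self.U.T @ A


def gls_marker_scan(y_star: np.ndarray, X_star: np.ndarray,
                    G_star: np.ndarray) -> dict[str, np.ndarray]:
    """Per-marker GLS on pre-whitened data.

    For each column g of ``G_star``, fits y* = X* b + g beta + eps by OLS
    (valid because whitening made errors iid) via Frisch-Waugh projection
    off X*, and returns beta, se, two-sided t-test p (df = n - q - 1) and
    pve = beta^2 var(g*)/var(y*) on the whitened scale.
    """
    from scipy import stats

    n, q = X_star.shape
    Q, _ = np.linalg.qr(X_star)
    y_r = y_star - Q @ (Q.T @ y_star)
    G_r = G_star - Q @ (Q.T @ G_star)
    gg = np.einsum("ij,ij->j", G_r, G_r)
    ok = gg > 1e-12
    gy = G_r.T @ y_r
    beta = np.full(G_star.shape[1], np.nan)
    se = np.full_like(beta, np.nan)
    p = np.full_like(beta, np.nan)
    pve = np.full_like(beta, np.nan)
    df = n - q - 1
    beta[ok] = gy[ok] / gg[ok]
    rss = float(y_r @ y_r) - np.where(ok, beta**2 * gg, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / df
        se[ok] = np.sqrt(sigma2[ok] / gg[ok])
        t = beta / se
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
        pve[ok] = (beta[ok] ** 2 * np.var(G_star[:, ok], axis=0)
                   / np.var(y_star))
    # p-values of exactly 0 are numerically impossible under t; clamp to tiny
    p = np.where(p == 0.0, np.nextafter(0, 1), p)
    return {"beta": beta, "se": se, "p": p, "pve": np.clip(pve, 0.0, 1.0 - 1e-12),
            "df": df, "tested": ok}
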