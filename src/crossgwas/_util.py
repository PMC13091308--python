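"""Shared numerical helpers: seed derivation, block jackknife, weighted regression."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, layer: str) -> int:
    """Derive a per-layer seed from the single global seed.

    Hash-based so adding a layer never shifts the streams of the others.
    Result is always in [0, 2**31).
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{layer}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def block_bounds(m: int, n_blocks: int) -> np.ndarray:
    """Boundaries of ``n_blocks`` contiguous, near-equal-count index blocks."""
    n_blocks = min(n_blocks, m)
    return np.linspace(0, m, n_blocks + 1).round().astype(int)


class JackknifeWLS:
    """Weighted least squares with delete-one-block jackknife machinery.

    Accumulates per-block sufficient statistics (X'WX, X'Wy) so that each
    delete-one-block fit is a small solve rather than a refit over all rows.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, w: np.ndarray, bounds: np.ndarray):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        self.k = x.shape[1]
        self.bounds = bounds
        g = len(bounds) - 1
        self.xtx_b = np.zeros((g, self.k, self.k))
        self.xty_b = np.zeros((g, self.k))
        for i in range(g):
            sl = slice(bounds[i], bounds[i + 1])
            xw = x[sl] * w[sl, None]
            self.xtx_b[i] = xw.T @ x[sl]
            self.xty_b[i] = xw.T @ y[sl]
        self.xtx = self.xtx_b.sum(axis=0)
        self.xty = self.xty_b.sum(axis=0)

    @property
    def n_blocks(self) -> int:
        return len(self.bounds) - 1

    def fit(self) -> np.ndarray:
        return np.linalg.solve(self.xtx, self.xty)

    def delete_one(self) -> np.ndarray:
        """Coefficients with each block deleted in turn; shape (g, k)."""
        g = self.n_blocks
        out = np.empty((g, self.k))
        for i in range(g):
            out[i] = np.linalg.solve(self.xtx - self.xtx_b[i], self.xty - self.xty_b[i])
        return out


def jackknife_se(estimates: np.ndarray) -> float:
    """Block-jackknife standard error from delete-one estimates."""
    est = np.asarray(estimates, dtype=float)
    g = est.shape[0]
    mean = est.mean(axis=0)
    return float(np.sqrt((g - 1) / g * np.sum((est - mean) ** 2, axis=0)))
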