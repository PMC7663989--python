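"""Variable ranking by PCA vector length in the plane of the first two axes.

Habitat variables span wildly different units (metres, percentages,
counts), so the PCA is run on the correlation matrix (variables z-scored
first). Loadings are eigenvectors scaled by the square root of their
eigenvalue, so a variable's vector length in the axis-1/axis-2 plane
reflects how much of the leading variance it carries; the top-k longest
vectors are selected for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaRanking", "pca_rank", "select_top_k"]


@dataclass
class PcaRanking:
    """Per-variable loadings on the first two axes and the resulting ranks."""

    table: pd.DataFrame          # columns: l1, l2, length, rank (index = variable)
    variance_fractions: np.ndarray  # explained variance of every axis, non-increasing

    @property
    def variables_by_rank(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def pca_rank(features: pd.DataFrame) -> PcaRanking:
    """Correlation-matrix PCA of a feature table, ranking variables by
    vector length in the plane of the first two axes.

    Requires >= 2 variables, >= 3 rows, no missing values. Constant
    variables are rejected by name (z-scoring would divide by zero).
    Eigenvector signs are fixed by orienting each axis so its
    largest-magnitude element is positive; ties in length are broken by
    input column order.
    """
    if features.shape[1] < 2 or features.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 rows")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains missing/non-finite values")
    sds = X.std(axis=0, ddof=1)
    # a truly constant column can leave an O(eps) residual sd
    tol = 1e-10 * (np.abs(X).max(axis=0) + 1.0)
    constant = [n for n, s, t in zip(features.columns, sds, tol) if s <= t]
    if constant:
        raise ValueError(f"zero-variance variable(s): {constant}")
    Z = (X - X.mean(axis=0)) / sds
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 0, None), eigvecs[:, order]
    # sign convention: largest-|element| of each eigenvector positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(len(eigvals))])
    eigvecs = eigvecs * np.where(flip == 0, 1.0, flip)
    loadings = eigvecs * np.sqrt(eigvals)
    l1, l2 = loadings[:, 0], loadings[:, 1]
    length = np.hypot(l1, l2)
    # stable sort on -length => ties broken by input order
    rank = np.empty(len(length), dtype=int)
    rank[np.argsort(-length, kind="stable")] = np.arange(1, len(length) + 1)
    table = pd.DataFrame(
        {"l1": l1, "l2": l2, "length": length, "rank": rank},
        index=pd.Index(features.columns, name="variable"))
    return PcaRanking(table, eigvals / eigvals.sum())


def select_top_k(ranking: PcaRanking, k: int) -> list[str]:
    """Names of the k longest vectors, in rank order."""
    n = len(ranking.table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return ranking.variables_by_rank[:k]
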