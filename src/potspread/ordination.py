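"""Correspondence analysis of site × trait contingency tables.

Standard (symmetric) CA of a two-way nonnegative table: with correspondence
matrix ``P = N / n``, row and column masses ``r`` and ``c``, the matrix of
standardized residuals

    S = D_r^{−1/2} (P − r cᵀ) D_c^{−1/2}

is decomposed by SVD; principal row coordinates are ``D_r^{−1/2} U Σ`` and
total inertia ``Σ σ_k² = χ²/n``.  Axis signs are fixed so the
largest-magnitude row loading on each axis is positive, making scores
reproducible across platforms (orientation carries no information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import logger


@dataclass
class CAResult:
    """Correspondence-analysis decomposition of a contingency table."""

    row_scores: pd.DataFrame      # principal coordinates, axes as columns
    col_scores: pd.DataFrame
    singular_values: np.ndarray
    inertia_per_axis: np.ndarray  # singular values squared
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame, n_axes: int = 2) -> CAResult:
    """Correspondence analysis of a nonnegative two-way table.

    All-zero rows/columns are dropped (logged).  Raises on tables that are
    degenerate after dropping (fewer than 2 rows or columns).
    """
    N = table.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("contingency table must be nonnegative")
    keep_r = N.sum(axis=1) > 0
    keep_c = N.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.info("CA: dropping %d all-zero rows, %d all-zero columns",
                    int((~keep_r).sum()), int((~keep_c).sum()))
    N = N[np.ix_(keep_r, keep_c)]
    row_ids = list(table.index[keep_r])
    col_ids = list(table.columns[keep_c])
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise ValueError(f"degenerate table after dropping zeros: shape {N.shape}")

    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)

    rank = min(N.shape) - 1  # centring removes one dimension
    s = s[:rank]
    U, Vt = U[:, :rank], Vt[:rank]
    total_inertia = float((s ** 2).sum())

    k = min(n_axes, rank)
    F = (U[:, :k] * s[:k]) / np.sqrt(r)[:, None]
    G = (Vt[:k].T * s[:k]) / np.sqrt(c)[:, None]
    # deterministic orientation: largest |row loading| positive per axis
    for j in range(k):
        i_max = int(np.argmax(np.abs(F[:, j])))
        if F[i_max, j] < 0:
            F[:, j] *= -1
            G[:, j] *= -1
    axes = [f"axis{j + 1}" for j in range(k)]
    return CAResult(
        row_scores=pd.DataFrame(F, index=row_ids, columns=axes),
        col_scores=pd.DataFrame(G, index=col_ids, columns=axes),
        singular_values=s,
        inertia_per_axis=s ** 2,
        total_inertia=total_inertia,
    )


def plot_ca_biplot(result: CAResult, ax=None, show_columns: bool = False):
    """Quick biplot of row (and optionally column) scores on the first two axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    F = result.row_scores
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.scatter(F.iloc[:, 0], F.iloc[:, 1], s=18)
    for lab, (x, y) in F.iloc[:, :2].iterrows():
        ax.annotate(lab, (x, y), fontsize=7, xytext=(2, 2), textcoords="offset points")
    if show_columns:
        G = result.col_scores
        ax.scatter(G.iloc[:, 0], G.iloc[:, 1], s=10, marker="^", color="firebrick")
    share = result.inertia_per_axis / result.total_inertia
    ax.set_xlabel(f"axis 1 ({100 * share[0]:.1f}% inertia)")
    if len(share) > 1:
        ax.set_ylabel(f"axis 2 ({100 * share[1]:.1f}% inertia)")
    return ax
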