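"""Pseudotime-ordered expression smoothing and heatmap cell ordering.

Cells are ordered by branch, then cluster emergence (rank of the cluster's
median pseudotime), then pseudotime. For display, per-gene z-scores
(population standard deviation) are averaged over a centered window of
neighboring cells in that ordering; the window truncates symmetrically at
the ends and never crosses branch boundaries.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .io import CountMatrix


def order_cells(
    pseudotime,
    branch,
    cluster_labels,
    barcodes=None,
    branch_order=None,
) -> np.ndarray:
    """Permutation ordering cells by (branch, cluster emergence, pseudotime).

    Cluster emergence is the rank of each cluster's median pseudotime.
    Remaining ties are broken by barcode, making the ordering invariant to
    the input cell permutation.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    if np.isnan(pseudotime).any():
        bad = np.flatnonzero(np.isnan(pseudotime))
        raise ValueError(f"missing pseudotime for cells {bad.tolist()}")
    branch = np.asarray(branch, dtype=object)
    cluster_labels = np.asarray(cluster_labels)
    n = len(pseudotime)
    if barcodes is None:
        barcodes = np.array([f"{i:09d}" for i in range(n)], dtype=object)
    barcodes = np.asarray(barcodes, dtype=object)

    if branch_order is None:
        branch_order = sorted(set(branch), key=str)
    branch_rank = {b: i for i, b in enumerate(branch_order)}
    b_key = np.array([branch_rank[b] for b in branch])

    emergence = {
        c: np.median(pseudotime[cluster_labels == c])
        for c in set(cluster_labels.tolist())
    }
    ranked = sorted(emergence, key=lambda c: (emergence[c], str(c)))
    cluster_rank = {c: i for i, c in enumerate(ranked)}
    c_key = np.array([cluster_rank[c] for c in cluster_labels])

    return np.lexsort((barcodes, pseudotime, c_key, b_key))


@dataclasses.dataclass
class OrderedExpression:
    ordering: np.ndarray       # permutation of cell indices
    z_scores: np.ndarray       # genes x cells, in display order
    smoothed: np.ndarray       # genes x cells, in display order
    window: int
    constant_genes: np.ndarray  # zero-variance genes (z set to 0)


def _window_bounds(i: int, lo: int, hi: int, window: int) -> tuple[int, int]:
    """Centered window [a, b] of nominal width ``window`` around position i,
    truncated symmetrically within segment [lo, hi]."""
    r_lo = (window - 1) // 2
    r_hi = window // 2
    deficit = max(0, lo - (i - r_lo), (i + r_hi) - hi)
    return i - max(0, r_lo - deficit), i + max(0, r_hi - deficit)


def smooth_expression(
    matrix,
    ordering,
    window: int = 10,
    branch=None,
) -> OrderedExpression:
    """Z-score genes, then moving-average along the ordering.

    Z-scores use the population standard deviation (denominator n);
    zero-variance genes are set to 0 and flagged. The moving average is
    centered with symmetric truncation at segment ends; when ``branch`` is
    given, smoothing is applied within contiguous branch segments of the
    ordering and never crosses a branch boundary.
    """
    if isinstance(matrix, CountMatrix):
        values = matrix.values
    else:
        values = np.asarray(matrix, dtype=float)
    ordering = np.asarray(ordering)
    n = values.shape[1]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds {n} cells")

    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # ddof 0
    constant = np.flatnonzero(sd[:, 0] == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant, :] = 0.0
    z = z[:, ordering]

    if branch is None:
        segments = [(0, n - 1)]
    else:
        b = np.asarray(branch, dtype=object)[ordering]
        starts = [0] + [i for i in range(1, n) if b[i] != b[i - 1]]
        segments = [
            (s, (starts[idx + 1] - 1) if idx + 1 < len(starts) else n - 1)
            for idx, s in enumerate(starts)
        ]

    smoothed = np.empty_like(z)
    cum = np.concatenate(
        [np.zeros((z.shape[0], 1)), np.cumsum(z, axis=1)], axis=1
    )
    for lo, hi in segments:
        for i in range(lo, hi + 1):
            a, b_ = _window_bounds(i, lo, hi, window)
            smoothed[:, i] = (cum[:, b_ + 1] - cum[:, a]) / (b_ - a + 1)
    return OrderedExpression(
        ordering=ordering,
        z_scores=z,
        smoothed=smoothed,
        window=window,
        constant_genes=constant,
    )
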