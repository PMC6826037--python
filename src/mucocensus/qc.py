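"""Per-cell QC metrics, distribution-relative filtering, normalization and
highly-variable-gene selection.

Cells are filtered on the empirical 5th/95th percentiles of three metrics
(expressed features, dropout percentage, library size) plus the 95th
percentile of the mitochondrial fraction; genes must be detected (>= 1 UMI)
in at least five cells. Normalization is a two-pass scheme: a median-library
scale factor first, then an optional cluster-guided median-ratio refinement.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

CELL_FILTER_REASONS = (
    "feat_low", "feat_high", "dropout_low", "dropout_high",
    "libsize_low", "libsize_high", "mito_high",
)

MIN_CELLS_PER_GENE = 5


def compute_qc(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell metrics: expressed features, dropout %, library size, mito %.

    dropout_pct = 1 - n_features / n_genes; mito_pct is the fraction of UMI
    on mitochondrial genes (0 for an all-zero cell).
    """
    if matrix.layer_tag != "raw":
        raise ValueError("QC metrics are defined on the raw layer")
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty matrix")
    values = matrix.values
    n_features = (values > 0).sum(axis=0)
    library_size = values.sum(axis=0)
    mito_counts = values[matrix.is_mito, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(library_size > 0, mito_counts / library_size, 0.0)
    return pd.DataFrame(
        {
            "n_features": n_features.astype(int),
            "dropout_pct": 1.0 - n_features / matrix.n_genes,
            "library_size": library_size.astype(int),
            "mito_pct": mito_pct,
        },
        index=matrix.barcodes,
    )


@dataclasses.dataclass
class FilterReport:
    kept_cells: np.ndarray
    removed_cells: np.ndarray
    reasons: pd.DataFrame          # removed barcodes x reason flags
    thresholds: dict               # metric -> applied quantile value(s)

    def __post_init__(self) -> None:
        assert set(self.reasons.columns) <= set(CELL_FILTER_REASONS)


def filter_cells(
    matrix: CountMatrix, metrics: pd.DataFrame
) -> tuple[CountMatrix, FilterReport]:
    """Remove distribution-extreme cells.

    A cell is removed when strictly above the 95th or strictly below the 5th
    empirical percentile of n_features, dropout_pct or library_size, or
    strictly above the 95th percentile of mito_pct. All four rules are
    evaluated jointly on the unfiltered distributions; a cell may carry
    several reasons. Fully tied distributions remove nobody (strict
    inequalities).
    """
    if matrix.n_cells < 20:
        warnings.warn(
            f"only {matrix.n_cells} cells: percentile filtering is noisy",
            stacklevel=2,
        )
    thresholds = {}
    flags = {}
    for metric in ("n_features", "dropout_pct", "library_size"):
        x = metrics[metric].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [0.05, 0.95])
        thresholds[metric] = (lo, hi)
        short = {"n_features": "feat", "dropout_pct": "dropout",
                 "library_size": "libsize"}[metric]
        flags[f"{short}_low"] = x < lo
        flags[f"{short}_high"] = x > hi
    mito = metrics["mito_pct"].to_numpy(dtype=float)
    mito_hi = np.quantile(mito, 0.95)
    thresholds["mito_pct"] = (None, mito_hi)
    flags["mito_high"] = mito > mito_hi

    reason_frame = pd.DataFrame(flags, index=metrics.index)
    removed_mask = reason_frame.any(axis=1).to_numpy()
    kept_idx = np.flatnonzero(~removed_mask)
    removed_idx = np.flatnonzero(removed_mask)
    report = FilterReport(
        kept_cells=matrix.barcodes[kept_idx],
        removed_cells=matrix.barcodes[removed_idx],
        reasons=reason_frame.loc[removed_mask],
        thresholds=thresholds,
    )
    return matrix.subset_cells(kept_idx), report


def filter_genes(
    matrix: CountMatrix, min_cells: int = MIN_CELLS_PER_GENE
) -> CountMatrix:
    """Keep genes detected (>= 1 UMI) in at least ``min_cells`` cells."""
    detected = (matrix.values > 0).sum(axis=1)
    return matrix.subset_genes(np.flatnonzero(detected >= min_cells))


def normalize(
    matrix: CountMatrix,
    labels: np.ndarray | None = None,
    min_cluster_size: int = 3,
    n_ratio_bins: int = 20,
) -> CountMatrix:
    """Two-pass cell-level normalization.

    Pass 1 (unsupervised): scale factor = library size / median library size.
    Pass 2 (cluster-guided, when ``labels`` is given): each cluster defines
    a per-gene mean reference of pass-1 values; each cell's residual factor
    is the median over expression bins of the cell/reference ratio of
    binned sums, rescaled to mean 1. Ratios are taken over gene bins rather
    than single genes because per-gene ratios conditioned on detection are
    biased by dropout on sparse counts; binned sums keep the median-ratio
    estimator well defined at single-cell depth. Clusters with fewer than
    ``min_cluster_size`` cells fall back to the pass-1 factor. Returns a
    ``normalized`` layer.
    """
    if matrix.layer_tag != "raw":
        raise ValueError("normalize expects the raw layer")
    raw = matrix.values.astype(float)
    libsize = raw.sum(axis=0)
    median_lib = np.median(libsize)
    if median_lib <= 0:
        raise ValueError("median library size is zero")
    f1 = libsize / median_lib
    f1[f1 == 0] = 1.0
    pass1 = raw / f1[None, :]

    factor = f1.copy()
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != matrix.n_cells:
            raise ValueError("labels must cover every cell")
        f2 = np.ones(matrix.n_cells)
        for cluster in np.unique(labels):
            members = np.flatnonzero(labels == cluster)
            if members.size < min_cluster_size:
                logger.warning(
                    "cluster %r has %d cells; keeping pass-1 factors",
                    cluster, members.size,
                )
                continue
            reference = pass1[:, members].mean(axis=1)
            detected = np.flatnonzero(reference > 0)
            order = detected[np.argsort(-reference[detected], kind="stable")]
            bins = np.array_split(order, min(n_ratio_bins, order.size))
            ref_sums = np.array([reference[b].sum() for b in bins])
            cell_sums = np.vstack(
                [pass1[b, :][:, members].sum(axis=0) for b in bins]
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios = cell_sums / ref_sums[:, None]
            f2[members] = np.median(ratios, axis=0)
        f2[f2 <= 0] = 1.0
        f2 /= f2.mean()
        factor = f1 * f2

    out = matrix.copy()
    out.values = raw / factor[None, :]
    out.layer_tag = "normalized"
    return out


def select_hvg(matrix: CountMatrix, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Highly variable genes by binned dispersion z-score.

    Genes are placed into ``n_bins`` equal-occupancy mean-expression bins;
    dispersion = variance / mean is z-scored within each bin; the ``n_top``
    genes by z-score are returned (ties broken by gene id). Constant genes
    are never selected.
    """
    if matrix.layer_tag == "raw":
        raise ValueError("select_hvg expects a normalized layer")
    if n_top > matrix.n_genes:
        raise ValueError(
            f"n_top={n_top} exceeds the {matrix.n_genes} available genes"
        )
    values = matrix.values
    mean = values.mean(axis=1)
    var = values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)

    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.full(matrix.n_genes, -np.inf)
    for bin_idx in bins:
        if bin_idx.size == 0:
            continue
        d = dispersion[bin_idx]
        sd = d.std()
        z[bin_idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf  # constant genes are never variable

    if n_top == matrix.n_genes:
        return np.arange(matrix.n_genes)
    ranked = sorted(
        range(matrix.n_genes), key=lambda i: (-z[i], str(matrix.gene_ids[i]))
    )
    return np.asarray(ranked[:n_top], dtype=int)
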