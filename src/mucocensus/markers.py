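"""Marker-gene detection and ranking-robustness tools.

One-vs-all marker detection uses a Wilcoxon rank-sum test per gene
(tie-corrected normal approximation with continuity correction; exact
enumeration for small tie-free samples) with Benjamini-Hochberg adjustment
within each cluster. The pooled design re-tests markers on repeated balanced
pools of cells, and rank-rank hypergeometric overlap (RRHO) quantifies the
agreement of two ranked gene lists over a grid of rank thresholds.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 12
RRHO_CLIP = 320.0


def _exact_rank_sum_p(n1: int, n2: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W of group 1, tie-free ranks.

    Counts subsets of {1..N} of size n1 by rank sum with a dynamic program
    (number-partition convolution), then sums the tail as extreme as
    ``w_obs`` on both sides of the mean n1(N+1)/2.
    """
    n = n1 + n2
    max_sum = n1 * n + 10
    # counts[j][s] = subsets of size j with rank sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0][0] = 1.0
    for rank in range(1, n + 1):
        for j in range(min(rank, n1), 0, -1):
            counts[j][rank:] += counts[j - 1][:-rank]
    dist = counts[n1]
    total = dist.sum()
    mu = n1 * (n + 1) / 2.0
    delta = abs(w_obs - mu)
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mu) >= delta - 1e-9
    return float(dist[extreme].sum() / total)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum statistic of group ``x``. The
    p-value is exact (full enumeration of rank splits) when the pooled
    sample has at most 12 tie-free observations, otherwise a normal
    approximation with tie correction and 0.5 continuity correction.
    Identical values in both groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n <= EXACT_MAX_N:
        return w, _exact_rank_sum_p(n1, n2, w)

    mu = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return w, 1.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def _rank_sum_genewise(
    values: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected normal-approximation test per gene (rows).

    Same statistic and correction as :func:`wilcoxon_rank_sum`'s
    large-sample path, applied to every row at once.
    """
    n1 = int(in_mask.sum())
    n2 = values.shape[1] - n1
    n = n1 + n2
    ranks = rankdata(values, axis=1)
    w = ranks[:, in_mask].sum(axis=1)
    mu = n1 * (n + 1) / 2.0

    sorted_vals = np.sort(values, axis=1)
    changes = np.diff(sorted_vals, axis=1) != 0
    # tie correction: sum t^3 - t over runs of equal values, per gene
    tie_term = np.empty(values.shape[0])
    for g in range(values.shape[0]):
        idx = np.flatnonzero(changes[g])
        run_lengths = np.diff(np.concatenate([[-1], idx, [n - 1]]))
        tie_term[g] = float(np.sum(run_lengths**3 - run_lengths))
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (
        12.0 * n * (n - 1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    return w, np.minimum(p, 1.0)


def _marker_frame(
    values: np.ndarray,
    gene_ids: np.ndarray,
    in_mask: np.ndarray,
    cluster,
    min_pct: float,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest marker statistics for one cluster."""
    inside = values[:, in_mask]
    outside = values[:, ~in_mask]
    pct_in = (inside > 0).mean(axis=1)
    pct_out = (outside > 0).mean(axis=1)
    tested = np.flatnonzero(np.maximum(pct_in, pct_out) >= min_pct)
    mean_in = inside[tested].mean(axis=1)
    mean_out = outside[tested].mean(axis=1)
    log_fc = np.log(mean_in + pseudocount) - np.log(mean_out + pseudocount)
    u, p = _rank_sum_genewise(values[tested], in_mask)
    fdr = multipletests(p, method="fdr_bh")[1] if p.size else p
    frame = pd.DataFrame(
        {
            "gene": gene_ids[tested],
            "cluster": cluster,
            "mean_in": mean_in,
            "mean_out": mean_out,
            "log_fc": log_fc,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "U": u,
            "p": p,
            "fdr": fdr,
        }
    )
    frame["abs_log_fc"] = frame["log_fc"].abs()
    frame = frame.sort_values(
        ["fdr", "abs_log_fc"], ascending=[True, False]
    )
    return frame.drop(columns="abs_log_fc")


def find_all_markers(
    matrix, labels, min_pct: float = 0.1, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-all Wilcoxon marker table for every cluster.

    Genes must be detected in at least ``min_pct`` of the cluster or of the
    rest to be tested; BH adjustment is applied within each cluster over the
    tested genes. The table is sorted by (cluster, fdr, -log_fc).
    """
    from .io import CountMatrix

    if isinstance(matrix, CountMatrix):
        values, gene_ids = matrix.values, matrix.gene_ids
    else:
        values = np.asarray(matrix, dtype=float)
        gene_ids = np.arange(values.shape[0])
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least two clusters")
    frames = []
    for cluster in clusters:
        in_mask = labels == cluster
        if in_mask.sum() < min_cells:
            warnings.warn(
                f"cluster {cluster!r} has {int(in_mask.sum())} cells; skipped",
                stacklevel=2,
            )
            continue
        frames.append(
            _marker_frame(values, gene_ids, in_mask, cluster, min_pct)
        )
    if not frames:
        raise ValueError(
            f"no cluster has >= {min_cells} cells; check the labels"
        )
    out = pd.concat(frames, ignore_index=True)
    out["abs_log_fc"] = out["log_fc"].abs()
    out = out.sort_values(
        ["cluster", "fdr", "abs_log_fc"], ascending=[True, True, False]
    ).drop(columns="abs_log_fc")
    return out.reset_index(drop=True)


def _mixture_shares(sizes: dict, pool_size: int) -> dict:
    """Balanced mixture with round-robin remainder, in cluster order."""
    clusters = sorted(sizes, key=str)
    base = pool_size // len(clusters)
    rem = pool_size - base * len(clusters)
    shares = {}
    for i, c in enumerate(clusters):
        shares[c] = base + (1 if i < rem else 0)
        if shares[c] > sizes[c]:
            raise ValueError(
                f"cluster {c!r} has {sizes[c]} cells but the mixture "
                f"needs {shares[c]}"
            )
    return shares


def pooled_de(
    matrix,
    labels,
    target,
    pool_size: int = 100,
    reps: int = 10,
    seed: int = 0,
    other: object | None = None,
    min_pct: float = 0.1,
) -> list[pd.DataFrame]:
    """Pooled differential expression for one cluster.

    Per repetition, ``pool_size`` cells are sampled from the target cluster
    and compared against either an equal mixture of all other clusters
    (one-vs-all; balanced shares, remainder round-robin) or a same-size pool
    of one ``other`` cluster (one-vs-one). Returns one ranked marker table
    per repetition; fully deterministic from ``seed``.
    """
    from .io import CountMatrix

    if isinstance(matrix, CountMatrix):
        values, gene_ids = matrix.values, matrix.gene_ids
    else:
        values = np.asarray(matrix, dtype=float)
        gene_ids = np.arange(values.shape[0])
    labels = np.asarray(labels)
    target_idx = np.flatnonzero(labels == target)
    if target_idx.size < pool_size:
        raise ValueError(
            f"target cluster has {target_idx.size} cells; needs {pool_size}"
        )
    if other is None:
        sizes = {
            c: int((labels == c).sum())
            for c in np.unique(labels) if c != target
        }
        if sum(sizes.values()) < pool_size:
            raise ValueError(
                f"other clusters hold {sum(sizes.values())} cells; "
                f"needs {pool_size}"
            )
        shares = _mixture_shares(sizes, pool_size)
    else:
        other_idx = np.flatnonzero(labels == other)
        if other_idx.size < pool_size:
            raise ValueError(
                f"cluster {other!r} has {other_idx.size} cells; "
                f"needs {pool_size}"
            )
        shares = None

    tables = []
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        )
        pool_a = rng.choice(target_idx, size=pool_size, replace=False)
        if shares is not None:
            parts = [
                rng.choice(
                    np.flatnonzero(labels == c), size=share, replace=False
                )
                for c, share in shares.items()
            ]
            pool_b = np.concatenate(parts)
        else:
            pool_b = rng.choice(
                np.flatnonzero(labels == other), size=pool_size,
                replace=False,
            )
        cols = np.concatenate([pool_a, pool_b])
        sub = values[:, cols]
        in_mask = np.zeros(cols.size, dtype=bool)
        in_mask[: pool_a.size] = True
        table = _marker_frame(sub, gene_ids, in_mask, target, min_pct)
        table.insert(0, "rep", rep)
        tables.append(table.reset_index(drop=True))
    return tables


@dataclasses.dataclass
class RRHOMap:
    """-log10 hypergeometric tail p-values over rank-threshold pairs."""

    grid: np.ndarray
    thresholds: np.ndarray
    step: int
    universe_size: int


def rrho(ranked_a, ranked_b, step: int | None = None) -> RRHOMap:
    """Rank-rank hypergeometric overlap of two ranked gene lists.

    Both lists must be permutations of the same universe of N genes. For
    rank thresholds i, j on a step grid, the overlap k of the top-i of list
    a with the top-j of list b is scored by the exact upper hypergeometric
    tail P[X >= k] (population N, i successes, j draws); entries are
    -log10(P), clipped at 320. ``rrho(a, b)`` is the transpose of
    ``rrho(b, a)``.
    """
    a = np.asarray(ranked_a, dtype=object)
    b = np.asarray(ranked_b, dtype=object)
    if len(a) != len(b) or set(a) != set(b):
        raise ValueError("lists must rank the same gene universe")
    if len(set(a)) != len(a):
        raise ValueError("ranked lists must not contain duplicates")
    n = len(a)
    if step is None:
        step = max(1, n // 50)
    thresholds = np.arange(step, n + 1, step)
    rank_in_b = {g: r for r, g in enumerate(b)}
    pos_a_in_b = np.array([rank_in_b[g] for g in a])

    grid = np.zeros((len(thresholds), len(thresholds)))
    for ii, i in enumerate(thresholds):
        b_ranks = np.sort(pos_a_in_b[:i])
        for jj, j in enumerate(thresholds):
            k = int(np.searchsorted(b_ranks, j, side="left"))
            p = float(hypergeom.sf(k - 1, n, i, j))
            grid[ii, jj] = min(-np.log10(max(p, 0.0)) if p > 0 else np.inf,
                               RRHO_CLIP)
    return RRHOMap(grid=grid, thresholds=thresholds, step=step,
                   universe_size=n)
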