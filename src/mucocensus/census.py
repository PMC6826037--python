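"""Clustering-robustness census.

The census measures how stable a clustering of cells is under perturbation
of the dataset. For each candidate number of clusters k, the cells are
re-clustered many times on random subsets (by default 10 subsets with 10% of
cells removed, 10 differently seeded runs each). The runs are pooled into an
n x n *stability matrix* S whose entry (i, j) is the frequency with which
cells i and j were clustered together among the runs where both were
present. A consensus partition is obtained by average-linkage hierarchical
clustering of the Euclidean distances between rows of S; intra- and
inter-cluster stability summarize the partition, the elbow of the
intra-stability curve over k selects the number of clusters, and cells whose
own-cluster stability falls below 70% are labeled unassigned.

The base clusterer is pluggable; the default is log1p -> top-30 PCA ->
k-means. The census itself, not the base clusterer, is the method.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import CountMatrix

#: stability value assigned to pairs never co-present in any run
NEVER_COPRESENT_PRIOR = 0.5

#: per-cell stability below which a cell is labeled unassigned
UNASSIGNED_THRESHOLD = 0.70


@dataclasses.dataclass
class PerturbationPlan:
    """Perturbation schedule of the census."""

    k_range: Sequence[int] = tuple(range(2, 10))
    n_subsets: int = 10
    drop_fraction: float = 0.10
    runs_per_subset: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in (0, 1)")
        if min(self.k_range) < 2:
            raise ValueError("k must be at least 2")
        if self.n_subsets < 1 or self.runs_per_subset < 1:
            raise ValueError("need at least one subset and one run")

    def validate_for(self, n_cells: int) -> None:
        if max(self.k_range) > n_cells - 1:
            raise ValueError("k_range exceeds n_cells - 1")


def derive_seed(seed: int, *key: int) -> int:
    """Stable, platform-independent derived seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def base_cluster(expr: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Default base clusterer: log layer -> top-30 PCs -> k-means.

    ``expr`` is a normalized genes x cells submatrix. Any callable with
    this signature can replace it — e.g. a wrapper around an external
    clusterer such as SIMLR.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    expr = np.asarray(expr, dtype=float)
    n_cells = expr.shape[1]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds {n_cells} cells")
    x = np.log1p(expr).T  # cells x genes
    n_comp = min(30, x.shape[0] - 1, x.shape[1])
    x = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(x)


def run_perturbations(
    expr: np.ndarray,
    plan: PerturbationPlan,
    k: int,
    base_clusterer: Callable = base_cluster,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All perturbed clustering runs for one k.

    For each subset, ``drop_fraction`` of the cells is removed uniformly
    without replacement (subset seed derived from ``plan.seed``), and the
    base clusterer runs ``runs_per_subset`` times with distinct derived
    seeds. Returns ``n_subsets * runs_per_subset`` pairs of (present cell
    indices, labels), fully reproducible from ``plan.seed``.
    """
    expr = np.asarray(expr, dtype=float)
    n_cells = expr.shape[1]
    n_drop = int(round(plan.drop_fraction * n_cells))
    runs = []
    for s in range(plan.n_subsets):
        rng = np.random.default_rng(derive_seed(plan.seed, k, s))
        dropped = rng.choice(n_cells, size=n_drop, replace=False)
        present = np.setdiff1d(np.arange(n_cells), dropped)
        sub = expr[:, present]
        for r in range(plan.runs_per_subset):
            labels = base_clusterer(sub, k, derive_seed(plan.seed, k, s, r))
            runs.append((present, np.asarray(labels)))
    return runs


@dataclasses.dataclass
class StabilityMatrix:
    """Pairwise co-clustering frequencies pooled over runs."""

    co_cluster: np.ndarray     # runs where i, j present and clustered together
    co_present: np.ndarray     # runs where i, j both present
    S: np.ndarray              # co_cluster / co_present, diagonal 1
    never_copresent: np.ndarray  # pairs with co_present == 0 (prior applied)

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]


def build_stability_matrix(runs, n_cells: int) -> StabilityMatrix:
    """Pool runs into co-clustering counts and the frequency matrix S.

    Pairs never co-present get S = 0.5 (uninformative prior) and are
    flagged; the diagonal is 1.
    """
    co_cluster = np.zeros((n_cells, n_cells), dtype=np.int32)
    co_present = np.zeros((n_cells, n_cells), dtype=np.int32)
    for present, labels in runs:
        present = np.asarray(present)
        if len(labels) != len(present):
            raise ValueError("labels length does not match present set")
        ix = np.ix_(present, present)
        co_present[ix] += 1
        same = (labels[:, None] == labels[None, :]).astype(np.int32)
        co_cluster[ix] += same
    never = co_present == 0
    np.fill_diagonal(never, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(co_present > 0, co_cluster / co_present, 0.0)
    S[never] = NEVER_COPRESENT_PRIOR
    np.fill_diagonal(S, 1.0)
    return StabilityMatrix(co_cluster, co_present, S, never)


def consensus_partition(stability: StabilityMatrix, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of the rows of S, cut at k."""
    n = stability.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds {n} cells")
    dist = pdist(stability.S, metric="euclidean")
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=k, criterion="maxclust") - 1
    return labels.astype(int)


def stability_scores(
    stability: StabilityMatrix, labels: np.ndarray
) -> tuple[np.ndarray, dict, float]:
    """Per-cell, intra- and inter-cluster stability for a partition.

    per_cell(i) = mean S[i, j] over co-members j != i (singleton -> 1);
    intra(c) = mean S over within-cluster pairs, averaged unweighted over
    clusters; inter = mean S over all between-cluster pairs.
    """
    S = stability.S
    labels = np.asarray(labels)
    n = len(labels)
    per_cell = np.ones(n)
    intra = {}
    clusters = np.unique(labels)
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if members.size == 1:
            intra[c] = 1.0  # singleton convention
            continue
        block = S[np.ix_(members, members)]
        m = members.size
        per_cell[members] = (block.sum(axis=1) - 1.0) / (m - 1)
        intra[c] = (block.sum() - m) / (m * (m - 1))
    between = labels[:, None] != labels[None, :]
    inter = float(S[between].mean()) if between.any() else 0.0
    intra["average"] = float(np.mean([intra[c] for c in clusters]))
    return per_cell, intra, inter


def select_k(intra_by_k: dict) -> tuple[int, str | None]:
    """Sharpest elbow of the average intra-stability curve.

    The intra-stability curve peaks at the supported number of clusters:
    fewer clusters force merges that the perturbed runs resolve
    inconsistently, more clusters force splits that they place
    inconsistently, and both depress within-cluster co-clustering. The
    selected k is therefore the interior maximum of average intra-stability
    (the point the eye picks on the elbow plot); ties go to the smaller k
    and the curve endpoints are never selected automatically. A featureless
    (flat or linear) curve yields the smallest interior k and a warning.
    The full curves are always reported so the choice can be overridden.
    """
    ks = sorted(intra_by_k)
    if len(ks) < 3:
        raise ValueError(
            "need at least 3 evaluated k values; choose k manually"
        )
    y = np.array([intra_by_k[k] for k in ks])
    note = None
    if np.allclose(np.diff(y), np.diff(y)[0]):
        note = "no elbow in the intra-stability curve; smallest interior k"
        warnings.warn(note, stacklevel=2)
        return ks[1], note
    interior = y[1:-1]
    return ks[1 + int(np.argmax(interior))], note


def label_unassigned(
    per_cell_stability: np.ndarray, threshold: float = UNASSIGNED_THRESHOLD
) -> np.ndarray:
    """Flag cells whose stability is strictly below ``threshold``."""
    scores = np.asarray(per_cell_stability, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("stability scores must lie in [0, 1]")
    return scores < threshold


@dataclasses.dataclass
class CensusResults:
    """Fitted census: consensus labels, stability diagnostics, curves."""

    selected_k: int
    labels: np.ndarray
    per_cell_stability: np.ndarray
    unassigned: np.ndarray
    intra_stability: dict            # selected k: cluster -> intra + average
    inter_stability: float           # selected k
    intra_curve: dict                # k -> average intra-stability
    inter_curve: dict                # k -> inter-stability
    labels_by_k: dict
    stability_matrix: StabilityMatrix
    plan: PerturbationPlan
    threshold: float = UNASSIGNED_THRESHOLD
    selection_note: str | None = None

    @property
    def mean_stability(self) -> float:
        return float(self.per_cell_stability.mean())

    def to_frame(self, barcodes=None):
        import pandas as pd

        index = barcodes if barcodes is not None else np.arange(
            len(self.labels)
        )
        return pd.DataFrame(
            {
                "cluster": self.labels,
                "stability": self.per_cell_stability,
                "unassigned": self.unassigned,
            },
            index=index,
        )

    def summary(self) -> str:
        lines = [
            "Clustering-robustness census",
            "=" * 60,
            f"cells: {len(self.labels)}    "
            f"runs/k: {self.plan.n_subsets * self.plan.runs_per_subset}    "
            f"drop fraction: {self.plan.drop_fraction:.2f}",
            f"selected k: {self.selected_k}"
            + (f"    ({self.selection_note})" if self.selection_note else ""),
            "",
            f"{'k':>3} {'intra':>8} {'inter':>8}",
        ]
        for k in sorted(self.intra_curve):
            mark = " *" if k == self.selected_k else ""
            lines.append(
                f"{k:>3} {self.intra_curve[k]:>8.4f} "
                f"{self.inter_curve[k]:>8.4f}{mark}"
            )
        lines += [
            "",
            f"mean per-cell stability (k={self.selected_k}): "
            f"{self.mean_stability:.4f}",
            f"unassigned (< {self.threshold:.0%}): "
            f"{int(self.unassigned.sum())} cells",
        ]
        return "\n".join(lines)


class ClusterStabilityCensus:
    """Model object for the perturbation census.

    Parameters
    ----------
    data : CountMatrix (normalized layer) or genes x cells array.
    plan : PerturbationPlan, optional.
    base_clusterer : callable ``(expr, k, seed) -> labels``, optional.
    """

    def __init__(
        self,
        data,
        plan: PerturbationPlan | None = None,
        base_clusterer: Callable = base_cluster,
    ) -> None:
        if isinstance(data, CountMatrix):
            if data.layer_tag == "raw":
                raise ValueError("census expects a normalized layer")
            self.barcodes = data.barcodes
            expr = data.values
        else:
            expr = np.asarray(data, dtype=float)
            self.barcodes = None
        self.expr = expr
        self.plan = plan if plan is not None else PerturbationPlan()
        self.plan.validate_for(expr.shape[1])
        self.base_clusterer = base_clusterer

    def _census_at(self, k: int):
        runs = run_perturbations(self.expr, self.plan, k, self.base_clusterer)
        stab = build_stability_matrix(runs, self.expr.shape[1])
        labels = consensus_partition(stab, k)
        per_cell, intra, inter = stability_scores(stab, labels)
        return stab, labels, per_cell, intra, inter

    def fit(
        self, k: int | None = None, threshold: float = UNASSIGNED_THRESHOLD
    ) -> CensusResults:
        """Run the census over the plan's k range (or a fixed ``k``)."""
        ks = [k] if k is not None else list(self.plan.k_range)
        labels_by_k, intra_curve, inter_curve = {}, {}, {}
        cache = {}
        for kk in ks:
            stab, labels, per_cell, intra, inter = self._census_at(kk)
            labels_by_k[kk] = labels
            intra_curve[kk] = intra["average"]
            inter_curve[kk] = inter
            cache[kk] = (stab, per_cell, intra, inter)
        note = None
        if k is None:
            selected, note = select_k(intra_curve)
        else:
            selected = k
        stab, per_cell, intra, inter = cache[selected]
        return CensusResults(
            selected_k=selected,
            labels=labels_by_k[selected],
            per_cell_stability=per_cell,
            unassigned=label_unassigned(per_cell, threshold),
            intra_stability=intra,
            inter_stability=inter,
            intra_curve=intra_curve,
            inter_curve=inter_curve,
            labels_by_k=labels_by_k,
            stability_matrix=stab,
            plan=self.plan,
            threshold=threshold,
            selection_note=note,
        )
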