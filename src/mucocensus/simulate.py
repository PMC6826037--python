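"""Synthetic branching-differentiation UMI count generator.

Emulates the statistical structure of an airway mucociliary differentiation
time course: a branching lineage (cycling basal -> basal -> suprabasal ->
club -> {goblet | deuterosomal -> multiciliated}), cell-type-specific marker
modules ramping along pseudotime, negative-binomial counts (dropout arising
from the NB mass at zero), lognormal library sizes, a mitochondrial gene
fraction, and a planted fraction of hybrid cells co-expressing the goblet
and multiciliated (MCC) marker modules.

Every planted attribute is returned as ground truth so downstream operations
(QC, clustering census, marker detection, annotation, hybrid quantification,
smoothing) can be validated against it.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io import CountMatrix, write_10x_triplet  # noqa: F401  (re-exported)

#: logistic rise width of marker activation, in pseudotime units on [0, 1].
ACTIVATION_RAMP = 0.01

#: logistic decay width at the end of a stage. Decay is centered exactly on
#: the boundary but steeper than the rise: a differentiating cell switches
#: modules without a dead zone, yet the outgoing module drops below the
#: detection tail within ~0.01 pseudotime units, so no pure cell carries two
#: modules >= 50% active — that co-activation pattern is reserved for
#: planted hybrids.
ACTIVATION_DECAY = 0.004


@dataclasses.dataclass
class LineageSpec:
    """Tree-shaped differentiation lineage.

    ``nodes`` lists cell-type names (first entry is the root); ``edges`` are
    (parent, child) pairs forming a tree; ``occupancy`` gives the expected
    fraction of cells per type (sums to 1); ``intervals`` maps each type to
    its pseudotime interval on [0, 1]; ``branches`` assigns each type a
    branch label used for ordering and smoothing.
    """

    nodes: list
    edges: list
    occupancy: dict
    intervals: dict
    branches: dict

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        parents = {}
        for parent, child in self.edges:
            if parent not in node_set or child not in node_set:
                raise ValueError(f"edge ({parent}, {child}) uses unknown node")
            if child in parents:
                raise ValueError(f"node {child} has two parents")
            parents[child] = parent
        root = self.nodes[0]
        if root in parents:
            raise ValueError("root node has a parent")
        if len(parents) != len(self.nodes) - 1:
            raise ValueError("edges do not form a spanning tree")
        # every non-root node must reach the root
        for node in self.nodes[1:]:
            seen, cur = set(), node
            while cur != root:
                if cur in seen or cur not in parents:
                    raise ValueError("edges contain a cycle or orphan")
                seen.add(cur)
                cur = parents[cur]
        total = sum(self.occupancy[n] for n in self.nodes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy fractions sum to {total}, not 1")
        for node in self.nodes:
            lo, hi = self.intervals[node]
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"bad pseudotime interval for {node}")
        self._parent = parents

    @property
    def root(self) -> str:
        return self.nodes[0]

    @property
    def branch_points(self) -> list:
        children = {}
        for parent, child in self.edges:
            children.setdefault(parent, []).append(child)
        return [n for n, ch in children.items() if len(ch) > 1]

    def children(self, node: str) -> list:
        return [c for p, c in self.edges if p == node]

    def path_to_root(self, node: str) -> list:
        """Ancestors from root down to ``node`` inclusive."""
        path = [node]
        while path[-1] != self.root:
            path.append(self._parent[path[-1]])
        return path[::-1]


def airway_lineage(cycling_root: bool = True) -> LineageSpec:
    """Default lineage: the mucociliary differentiation tree.

    With ``cycling_root=False`` the cycling-basal stage is folded into the
    basal root, giving the six-type tree (basal -> suprabasal -> club ->
    {goblet | deuterosomal -> multiciliated}) used for validation datasets.
    """
    nodes = [
        "cycling_basal", "basal", "suprabasal", "club",
        "goblet", "deuterosomal", "multiciliated",
    ]
    edges = [
        ("cycling_basal", "basal"),
        ("basal", "suprabasal"),
        ("suprabasal", "club"),
        ("club", "goblet"),
        ("club", "deuterosomal"),
        ("deuterosomal", "multiciliated"),
    ]
    occupancy = {
        "cycling_basal": 0.10, "basal": 0.20, "suprabasal": 0.20,
        "club": 0.20, "goblet": 0.10, "deuterosomal": 0.08,
        "multiciliated": 0.12,
    }
    intervals = {
        "cycling_basal": (0.0, 0.15), "basal": (0.15, 0.35),
        "suprabasal": (0.35, 0.55), "club": (0.55, 0.70),
        "goblet": (0.70, 1.0), "deuterosomal": (0.70, 0.85),
        "multiciliated": (0.85, 1.0),
    }
    branches = {
        "cycling_basal": "trunk", "basal": "trunk", "suprabasal": "trunk",
        "club": "trunk", "goblet": "goblet", "deuterosomal": "mcc",
        "multiciliated": "mcc",
    }
    if not cycling_root:
        nodes = nodes[1:]
        edges = edges[1:]
        occupancy = dict(occupancy)
        occupancy.pop("cycling_basal")
        occupancy["basal"] = 0.30
        intervals = dict(intervals)
        intervals.pop("cycling_basal")
        intervals["basal"] = (0.0, 0.35)
        branches = {n: branches[n] for n in nodes}
    return LineageSpec(nodes, edges, occupancy, intervals, branches)


def gc_mcc_lineage() -> LineageSpec:
    """Goblet/MCC-restricted lineage.

    Models only the secretory-to-multiciliated end of the tree, i.e. the
    goblet + MCC population over which double-positive hybrid fractions are
    quantified.
    """
    nodes = ["goblet", "multiciliated"]
    edges = [("goblet", "multiciliated")]
    occupancy = {"goblet": 0.5, "multiciliated": 0.5}
    intervals = {"goblet": (0.0, 0.5), "multiciliated": (0.5, 1.0)}
    branches = {"goblet": "gc_mcc", "multiciliated": "gc_mcc"}
    return LineageSpec(nodes, edges, occupancy, intervals, branches)


@dataclasses.dataclass
class ExpressionProgram:
    """Gene-level generative parameters.

    ``marker_sets`` maps each cell type to planted marker gene indices
    (pairwise disjoint). The first marker of every set is a *sentinel* — a
    canonical, near-binary marker (very low baseline, very high fold) in the
    mold of MUC5AC or FOXJ1; the rest are ordinary markers elevated by
    ``marker_fold`` in their type. ``nb_dispersion`` is the NB dispersion
    alpha (variance = mu + alpha * mu^2); dropout is the NB mass at zero.
    """

    n_genes: int
    marker_sets: dict
    baseline_mean: np.ndarray
    marker_fold: float = 8.0
    sentinel_fold: float = 1600.0
    nb_dispersion: np.ndarray | float = 0.5
    mito_gene_fraction: float = 0.02
    mito_gene_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        if len(self.baseline_mean) != self.n_genes:
            raise ValueError("baseline_mean length != n_genes")
        if np.any(self.baseline_mean <= 0):
            raise ValueError("all baseline means must be > 0")
        disp = np.broadcast_to(
            np.asarray(self.nb_dispersion, dtype=float), (self.n_genes,)
        )
        if np.any(disp <= 0):
            raise ValueError("dispersion must be > 0")
        seen: set = set()
        for ctype, idx in self.marker_sets.items():
            idx = list(idx)
            if max(idx, default=-1) >= self.n_genes:
                raise ValueError(f"marker indices of {ctype} exceed n_genes")
            overlap = seen.intersection(idx)
            if overlap:
                raise ValueError(
                    f"marker sets overlap at gene indices {sorted(overlap)}"
                )
            seen.update(idx)
        if self.mito_gene_idx is None:
            n_mito = int(round(self.mito_gene_fraction * self.n_genes))
            free = [i for i in range(self.n_genes) if i not in seen]
            self.mito_gene_idx = np.asarray(free[:n_mito], dtype=int)

    @property
    def dispersion(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.nb_dispersion, dtype=float), (self.n_genes,)
        ).copy()

    def gene_ids(self) -> np.ndarray:
        ids = np.array(
            [f"G{i + 1:06d}" for i in range(self.n_genes)], dtype=object
        )
        for i in self.mito_gene_idx:
            ids[i] = f"MT-G{i + 1:06d}"
        return ids

    @classmethod
    def build(
        cls,
        lineage: LineageSpec,
        n_genes: int = 1000,
        markers_per_type: int = 15,
        marker_fold: float = 8.0,
        sentinel_fold: float = 1600.0,
        nb_dispersion: float = 0.5,
        mito_gene_fraction: float = 0.02,
        baseline_log_mean: float = math.log(0.2),
        baseline_log_sd: float = 1.0,
        sentinel_baseline: float = 0.005,
        seed: int = 0,
    ) -> "ExpressionProgram":
        """Draw a default program: lognormal baselines, disjoint marker sets."""
        rng = np.random.default_rng(seed)
        need = markers_per_type * len(lineage.nodes)
        if need > n_genes:
            raise ValueError("marker sets do not fit within n_genes")
        baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, n_genes)
        n_mito = int(round(mito_gene_fraction * n_genes))
        # markers occupy the first genes, mito genes the last ones
        marker_sets = {}
        for t, ctype in enumerate(lineage.nodes):
            idx = list(
                range(t * markers_per_type, (t + 1) * markers_per_type)
            )
            marker_sets[ctype] = idx
            baseline[idx[0]] = sentinel_baseline  # near-binary sentinel
        mito_idx = np.arange(n_genes - n_mito, n_genes)
        return cls(
            n_genes=n_genes,
            marker_sets=marker_sets,
            baseline_mean=baseline,
            marker_fold=marker_fold,
            sentinel_fold=sentinel_fold,
            nb_dispersion=nb_dispersion,
            mito_gene_fraction=mito_gene_fraction,
            mito_gene_idx=mito_idx,
        )


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth, one record per cell."""

    cell_type: np.ndarray
    pseudotime: np.ndarray
    branch: np.ndarray
    is_hybrid: np.ndarray
    library_size: np.ndarray
    marker_sets: dict           # cell type -> list of gene ids
    flag_genes: dict            # cell type -> sentinel gene id
    high_mito: np.ndarray | None = None

    def to_frame(self, barcodes):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_type": self.cell_type,
                "pseudotime": self.pseudotime,
                "branch": self.branch,
                "is_hybrid": self.is_hybrid,
                "library_size": self.library_size,
            },
            index=np.asarray(barcodes, dtype=object),
        )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _activation(
    lineage: LineageSpec, module_type: str, cell_type: str, pt: np.ndarray
) -> np.ndarray:
    """Activation in [0, 1] of ``module_type``'s marker module for cells of
    ``cell_type`` at pseudotime ``pt``.

    Modules are active only along the root path of the cell's type. They
    ramp up logistically at the start of their stage (unless root) and decay
    at the end of it (unless terminal), so each marker module traces a
    unimodal profile along its branch.
    """
    path = lineage.path_to_root(cell_type)
    if module_type not in path:
        return np.zeros_like(pt, dtype=float)
    lo, hi = lineage.intervals[module_type]
    act = np.ones_like(pt, dtype=float)
    if module_type != lineage.root:
        act *= _logistic((pt - lo) / ACTIVATION_RAMP)
    if lineage.children(module_type):
        act *= _logistic((hi - pt) / ACTIVATION_DECAY)
    return act


def generate_counts(
    lineage: LineageSpec,
    program: ExpressionProgram,
    n_cells: int,
    hybrid_fraction: float,
    seed: int,
    exact_hybrid_count: bool = False,
    hybrid_transition: tuple = ("goblet", "multiciliated"),
    library_log_sd: float = 0.35,
    type_scale: dict | None = None,
    high_mito_fraction: float = 0.0,
    high_mito_boost: float = 10.0,
):
    """Draw a synthetic (CountMatrix, SyntheticTruth) pair.

    Counts are negative binomial per gene/cell with mean = cell scale x
    type/pseudotime-dependent gene mean. Hybrid cells sit on the
    ``hybrid_transition`` (goblet -> MCC by default) with BOTH marker
    modules at >= 50% activation. ``exact_hybrid_count`` plants exactly
    ``floor(hybrid_fraction * n_cells)`` hybrids; otherwise hybrid status is
    Binomial per cell. Identical seed and configuration give byte-identical
    output.
    """
    if n_cells < 50:
        raise ValueError("n_cells must be >= 50")
    if not (0 <= hybrid_fraction <= 0.5):
        raise ValueError("hybrid_fraction must be in [0, 0.5]")
    if hybrid_fraction > 0:
        missing = [t for t in hybrid_transition if t not in lineage.nodes]
        if missing:
            raise ValueError(
                f"hybrid transition types {missing} absent from lineage"
            )
    rng = np.random.default_rng(seed)

    types = np.asarray(lineage.nodes, dtype=object)
    probs = np.array([lineage.occupancy[t] for t in types], dtype=float)
    cell_type = rng.choice(types, size=n_cells, p=probs)

    # hybrids live on the transition between the two configured types
    if hybrid_fraction > 0:
        if exact_hybrid_count:
            n_hyb = int(math.floor(hybrid_fraction * n_cells))
            hybrid_idx = rng.choice(n_cells, size=n_hyb, replace=False)
            is_hybrid = np.zeros(n_cells, dtype=bool)
            is_hybrid[hybrid_idx] = True
        else:
            is_hybrid = rng.random(n_cells) < hybrid_fraction
        cell_type[is_hybrid] = rng.choice(
            np.asarray(hybrid_transition, dtype=object),
            size=int(is_hybrid.sum()),
        )
    else:
        is_hybrid = np.zeros(n_cells, dtype=bool)

    intervals = {t: lineage.intervals[t] for t in types}
    u = rng.random(n_cells)
    lo = np.array([intervals[t][0] for t in cell_type])
    hi = np.array([intervals[t][1] for t in cell_type])
    pseudotime = lo + u * (hi - lo)
    branch = np.array([lineage.branches[t] for t in cell_type], dtype=object)

    # per-module activation, genes x cells mean matrix
    disp = program.dispersion
    baseline = program.baseline_mean
    mean = np.tile(baseline[:, None], (1, n_cells))
    act_by_module = {}
    for module in types:
        act = np.zeros(n_cells)
        for ctype in types:
            mask = cell_type == ctype
            if mask.any():
                act[mask] = _activation(
                    lineage, module, ctype, pseudotime[mask]
                )
        act_by_module[module] = act
    # hybrid override: both transition modules at >= 50% activation
    if is_hybrid.any():
        n_hyb = int(is_hybrid.sum())
        for module in hybrid_transition:
            boost = rng.uniform(0.5, 1.0, size=n_hyb)
            act = act_by_module[module]
            act[is_hybrid] = np.maximum(act[is_hybrid], boost)
    for module in types:
        idx = np.asarray(program.marker_sets[module], dtype=int)
        if idx.size == 0:
            continue
        act = act_by_module[module]
        folds = np.full(idx.size, program.marker_fold)
        folds[0] = program.sentinel_fold
        mean[idx, :] *= 1.0 + (folds[:, None] - 1.0) * act[None, :]

    # lognormal library-size scale, normalized to mean 1
    scale = rng.lognormal(0.0, library_log_sd, n_cells)
    scale /= np.exp(library_log_sd**2 / 2.0)
    if type_scale:
        for ctype, factor in type_scale.items():
            scale[cell_type == ctype] *= factor
    mean *= scale[None, :]

    high_mito = np.zeros(n_cells, dtype=bool)
    if high_mito_fraction > 0:
        n_hm = int(round(high_mito_fraction * n_cells))
        hm_idx = rng.choice(n_cells, size=n_hm, replace=False)
        high_mito[hm_idx] = True
        mean[np.ix_(program.mito_gene_idx, hm_idx)] *= high_mito_boost

    # NB draw: n = 1/alpha, p = n / (n + mu)
    n_param = 1.0 / disp[:, None]
    p_param = n_param / (n_param + mean)
    counts = rng.negative_binomial(n_param, p_param).astype(np.int64)

    gene_ids = program.gene_ids()
    barcodes = np.array(
        [f"cell_{i + 1:06d}" for i in range(n_cells)], dtype=object
    )
    matrix = CountMatrix(counts, gene_ids, barcodes, layer_tag="raw")
    marker_ids = {
        t: [str(gene_ids[i]) for i in program.marker_sets[t]] for t in types
    }
    truth = SyntheticTruth(
        cell_type=cell_type,
        pseudotime=pseudotime,
        branch=branch,
        is_hybrid=is_hybrid,
        library_size=mean.sum(axis=0),  # expected total UMI per cell
        marker_sets=marker_ids,
        flag_genes={t: marker_ids[t][0] for t in types},
        high_mito=high_mito,
    )
    return matrix, truth
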