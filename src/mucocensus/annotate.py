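"""Marker-set scoring and z-score cell-type assignment.

For each candidate cell type, the raw score of a cell is the mean
normalized expression of that type's marker genes; scores are z-scored per
type across cells (following the cell-cycle phase-scoring convention) and
each cell is assigned the type with the highest z. Clusters inherit the
modal assignment of their member cells.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import CountMatrix

MIN_USABLE_MARKERS = 5


@dataclasses.dataclass
class CellTypeScores:
    raw_scores: pd.DataFrame     # types x cells
    z_scores: pd.DataFrame       # types x cells
    cell_assignment: pd.Series   # per-cell argmax type
    degenerate_types: list       # zero-variance score rows (z set to 0)


def score_cell_types(
    matrix: CountMatrix,
    marker_sets: dict,
    z_across: str = "cells",
) -> CellTypeScores:
    """Score every cell against every marker set and assign types.

    Marker genes missing from the matrix are dropped with a warning; at
    least 5 usable genes must remain per type. Ties in z are broken by the
    higher raw score, then by type-name order. ``z_across="types"`` z-scores
    each cell across types instead of the default per-type across cells.
    """
    if z_across not in ("cells", "types"):
        raise ValueError("z_across must be 'cells' or 'types'")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    raw = {}
    for ctype in sorted(marker_sets, key=str):
        genes = list(marker_sets[ctype])
        usable = [g for g in genes if g in gene_pos]
        missing = sorted(set(genes) - set(usable))
        if missing:
            warnings.warn(
                f"{ctype}: dropping {len(missing)} missing marker genes",
                stacklevel=2,
            )
        if len(usable) < MIN_USABLE_MARKERS:
            raise ValueError(
                f"marker set for {ctype!r} has only {len(usable)} usable "
                f"genes (need >= {MIN_USABLE_MARKERS})"
            )
        idx = [gene_pos[g] for g in usable]
        raw[ctype] = matrix.values[idx, :].mean(axis=0)
    raw_frame = pd.DataFrame(raw, index=matrix.barcodes).T

    degenerate = []
    if z_across == "cells":
        mean = raw_frame.mean(axis=1)
        sd = raw_frame.std(axis=1, ddof=0)
        degenerate = list(raw_frame.index[sd == 0])
        sd = sd.replace(0, np.inf)  # zero-variance rows -> z = 0
        z_frame = raw_frame.sub(mean, axis=0).div(sd, axis=0)
    else:
        mean = raw_frame.mean(axis=0)
        sd = raw_frame.std(axis=0, ddof=0).replace(0, np.inf)
        z_frame = raw_frame.sub(mean, axis=1).div(sd, axis=1)

    # argmax z with deterministic tie-breaking: raw score, then type name
    types = np.asarray(z_frame.index, dtype=object)
    z = z_frame.to_numpy()
    r = raw_frame.to_numpy()
    order = np.lexsort(
        (np.arange(len(types))[:, None] * np.ones_like(z), -r, -z), axis=0
    )[0]
    assignment = pd.Series(
        types[order], index=raw_frame.columns, name="cell_type"
    )
    return CellTypeScores(
        raw_scores=raw_frame,
        z_scores=z_frame,
        cell_assignment=assignment,
        degenerate_types=degenerate,
    )


def assign_clusters(
    scores: CellTypeScores, labels, ambiguous_below: float = 0.5
) -> pd.DataFrame:
    """Modal per-cell assignment within each cluster.

    Clusters whose agreement fraction falls below ``ambiguous_below`` are
    labeled ``ambiguous``.
    """
    labels = np.asarray(labels)
    if len(labels) != scores.cell_assignment.size:
        raise ValueError("labels must cover every scored cell")
    records = []
    for cluster in np.unique(labels):
        members = scores.cell_assignment.values[labels == cluster]
        types, counts = np.unique(members.astype(str), return_counts=True)
        top = int(np.argmax(counts))
        agreement = counts[top] / counts.sum()
        records.append(
            {
                "cluster": cluster,
                "cell_type": (
                    types[top] if agreement >= ambiguous_below
                    else "ambiguous"
                ),
                "modal_type": types[top],
                "agreement": agreement,
                "n_cells": int(counts.sum()),
            }
        )
    return pd.DataFrame(records).set_index("cluster")
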