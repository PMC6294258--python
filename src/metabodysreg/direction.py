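"""Directionality profiling and heatmap-support computations.

Covers the per-pathway tallies of significantly up-/down-regulated member
genes (radar-plot data), signed fold-change matrices with significance
masking, detection of pathways dysregulated in exactly one cohort, and
deterministic Euclidean complete-linkage clustering orders for heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import PathwayDB
from .scoring import PathwayScoreTable

logger = logging.getLogger(__name__)

DEFAULT_GENE_ALPHA = 0.05


def direction_counts(deg: pd.DataFrame, db: PathwayDB,
                     gene_alpha: float = DEFAULT_GENE_ALPHA) -> pd.DataFrame:
    """Per pathway: counts of significantly up/down member genes.

    A member gene counts as up when adj_p < gene_alpha and log_fc > 0,
    down when adj_p < gene_alpha and log_fc < 0; genes with log_fc == 0
    count in neither direction.  ``n_tested`` is the number of member
    genes present in the DEG table.
    """
    rows = []
    for pid, members in db.items():
        present = deg.index.intersection(members)
        sub = deg.loc[present]
        sig = sub["adj_p_value"] < gene_alpha
        rows.append({
            "pathway_id": pid,
            "n_up": int((sig & (sub["log_fc"] > 0)).sum()),
            "n_down": int((sig & (sub["log_fc"] < 0)).sum()),
            "n_tested": len(present),
        })
    return pd.DataFrame(rows).set_index("pathway_id")


def signed_fc_matrix(deg_by_cohort: Mapping[str, pd.DataFrame], gene_set,
                     gene_alpha: float = DEFAULT_GENE_ALPHA) -> pd.DataFrame:
    """Genes x cohorts matrix of significant log2 fold changes.

    Cells hold log_fc where the gene is significant in that cohort, NaN
    where tested but not significant; genes untested everywhere are
    dropped.  Suitable for min-max scaling and clustering.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    cols = {}
    for cohort, deg in deg_by_cohort.items():
        present = deg.index.intersection(gene_set)
        sub = deg.loc[present]
        vals = sub["log_fc"].where(sub["adj_p_value"] < gene_alpha)
        cols[cohort] = vals
    mat = pd.DataFrame(cols)
    tested_anywhere = [g for g in gene_set
                       if any(g in deg.index for deg in deg_by_cohort.values())]
    mat = mat.reindex(tested_anywhere)
    mat.index.name = "gene_id"
    return mat


def unique_pathways(table: PathwayScoreTable) -> dict[str, list[str]]:
    """Pathways bootstrap-significant in exactly one cohort, keyed by it."""
    mask = table.require_mask()
    if len(table.cohorts) < 2:
        raise ValueError("uniqueness needs >= 2 cohorts")
    sig = mask.fillna(0.0) > 0
    out: dict[str, list[str]] = {c: [] for c in table.cohorts}
    exclusive = sig.sum(axis=0) == 1
    for pid in mask.columns[exclusive]:
        cohort = sig.index[sig[pid]][0]
        out[cohort].append(pid)
    return out


@dataclass(frozen=True)
class ClusterOrder:
    """Deterministic dendrogram summary: leaf order plus merge heights."""

    leaf_order: list[str]
    merge_heights: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.leaf_order)) != len(self.leaf_order):
            raise ValueError("leaf_order must be a permutation")


def hierarchical_order(matrix: pd.DataFrame, axis: str = "rows") -> ClusterOrder:
    """Euclidean complete-linkage clustering order along one axis.

    NaN cells are imputed as 0 for distance purposes (mirroring the
    zero-replacement of non-significant scores before heatmapping).
    Items are pre-sorted by label so ties break lexicographically and the
    result is invariant to input row order.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "rows" else matrix.T
    if data.shape[0] < 2:
        raise ValueError(f"need >= 2 items on the clustered axis (got {data.shape[0]})")
    data = data.sort_index()
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        logger.info("imputing %d NA cell(s) as 0 for clustering distances",
                    int(np.isnan(values).sum()))
        values = np.nan_to_num(values, nan=0.0)
    z = linkage(pdist(values, metric="euclidean"), method="complete")
    order = [data.index[i] for i in leaves_list(z)]
    return ClusterOrder(order, z[:, 2].copy())
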