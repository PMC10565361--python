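"""Range-weighted phylogenetic turnover (RWT) and phyloregionalization.

Between two cells, every branch carries weight w_b = L_b / R_b (length over
range, the same weighting as phylogenetic endemism); with A the shared
weight, B and C the weights unique to either cell, the dissimilarity is the
one-complement of the range-weighted phylogenetic Sørensen index,

    D = 1 − 2A / (2A + B + C),

which is 0 for identical branch composition and 1 when no branch is shared.
Cells are then clustered by average-linkage (UPGMA) agglomeration on D and
phyloregions are obtained by cutting the dendrogram at a requested region
count; cuts are nested, so a (k+1)-region map refines the k-region map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .grid import BranchIncidence

__all__ = [
    "rwt_dissimilarity",
    "turnover_matrix",
    "TurnoverMatrix",
    "upgma_cluster",
    "cut_regions",
    "dendrogram_newick",
]


@dataclass
class TurnoverMatrix:
    """Symmetric pairwise RWT dissimilarities over retained cells."""

    cells: list
    values: np.ndarray  # (n, n), zero diagonal
    resolution: float
    weighting: str = "length/range (phylogenetic-endemism weights)"

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"{ix},{iy}" for ix, iy in self.cells]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def write_phylip(self, path):
        labels = [f"{ix}_{iy}" for ix, iy in self.cells]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(labels)}\n")
            for lbl, row in zip(labels, self.values):
                fh.write(lbl + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def _weights(bi: BranchIncidence) -> np.ndarray:
    R = bi.branch_range.astype(float)
    return np.where(R > 0, bi.branch_length / np.maximum(R, 1.0), 0.0)


def rwt_dissimilarity(bi: BranchIncidence, cell_i, cell_j) -> float:
    """RWT dissimilarity between two cells (0 identical, 1 disjoint)."""
    i, j = bi.cell_index(cell_i), bi.cell_index(cell_j)
    w = _weights(bi)
    a = float(w[bi.incidence[i] & bi.incidence[j]].sum())
    tot_i = float(w[bi.incidence[i]].sum())
    tot_j = float(w[bi.incidence[j]].sum())
    denom = tot_i + tot_j  # = 2A + B + C
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * a / denom


def turnover_matrix(bi: BranchIncidence) -> TurnoverMatrix:
    """All-pairs RWT dissimilarity matrix (vectorized)."""
    if len(bi.cells) < 2:
        raise ValueError("turnover needs at least two cells")
    w = _weights(bi)
    inc = bi.incidence.astype(float)
    shared = (inc * w) @ inc.T  # A_ij
    tot = inc @ w
    denom = tot[:, None] + tot[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / denom
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return TurnoverMatrix(cells=list(bi.cells), values=d, resolution=np.nan)


def upgma_cluster(tm: TurnoverMatrix) -> np.ndarray:
    """Average-linkage (UPGMA) dendrogram as a SciPy linkage matrix.

    Merge heights are non-decreasing; cells enter in their (lexicographic)
    matrix order, which fixes tie-breaking deterministically.
    """
    cond = tm.condensed()
    if np.any(~np.isfinite(cond)):
        raise ValueError("turnover matrix contains non-finite distances")
    return hierarchy.average(cond)


def cut_regions(linkage: np.ndarray, k: int) -> np.ndarray:
    """Cut a dendrogram into exactly k regions.

    Region ids are contiguous 1..k, numbered by first appearance in cell
    order; cutting at k+1 refines the k-cut (nestedness).
    """
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.cut_tree(linkage, n_clusters=k).ravel()
    # relabel 1..k by order of first appearance
    mapping, labels = {}, np.zeros(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


def dendrogram_newick(linkage: np.ndarray, labels: list) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        inner = ",".join(walk(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{parent_height - node.dist:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    inner = ",".join(walk(c, tree.dist) for c in (tree.left, tree.right))
    return f"({inner});"
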