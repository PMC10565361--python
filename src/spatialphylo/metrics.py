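"""Per-cell diversity metrics.

Species-based: species richness SR, weighted endemism WE = Σ 1/range, and
corrected weighted endemism CWE = WE/SR.  Phylogenetic: Faith's PD (summed
length of the branches present), phylogenetic endemism PE (each branch
weighted by the inverse of its range), and their relative forms RPD/RPE —
the ratio of the observed value to the same quantity on a comparison tree
whose branches all share the average length.  RPD > 1 therefore flags a
concentration of longer-than-average branches, RPD < 1 shorter-than-average.

Conservation laws used as test oracles: Σ_cells PE equals the total tree
length and Σ_cells WE equals the species count, because every branch's (or
species') weight 1/range is counted exactly range times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import BranchIncidence, PresenceMatrix, build_branch_incidence, sampling_redundancy
from .phylo import Phylogeny, make_comparison_tree

__all__ = [
    "faith_pd",
    "phylo_endemism",
    "weighted_endemism",
    "relative_metric",
    "pd_vector",
    "pe_vector",
    "compute_cell_metrics",
]


def pd_vector(bi: BranchIncidence, lengths=None) -> np.ndarray:
    """PD for every cell: Σ_b L_b over branches present."""
    L = bi.branch_length if lengths is None else np.asarray(lengths, dtype=float)
    return bi.incidence @ L


def pe_vector(bi: BranchIncidence, lengths=None, ranges=None) -> np.ndarray:
    """PE for every cell: Σ_b L_b / R_b over branches present."""
    L = bi.branch_length if lengths is None else np.asarray(lengths, dtype=float)
    R = bi.branch_range if ranges is None else np.asarray(ranges, dtype=float)
    w = np.where(R > 0, L / np.maximum(R, 1), 0.0)
    return bi.incidence @ w


def faith_pd(bi: BranchIncidence, cell) -> float:
    """Faith's PD of one cell."""
    return float(pd_vector(bi)[bi.cell_index(cell)])


def phylo_endemism(bi: BranchIncidence, cell) -> float:
    """Phylogenetic endemism of one cell."""
    return float(pe_vector(bi)[bi.cell_index(cell)])


def weighted_endemism(pm: PresenceMatrix, cell) -> tuple:
    """(WE, CWE) of one cell: Σ_species 1/range and its richness-corrected form."""
    i = pm.cell_index(cell)
    inv_range = 1.0 / pm.range_size
    we = float(pm.incidence[i] @ inv_range)
    return we, we / float(pm.richness[i])


def relative_metric(obs, comp):
    """Observed/comparison ratio (RPD or RPE); NaN where comparison is 0."""
    obs = np.asarray(obs, dtype=float)
    comp = np.asarray(comp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(comp > 0, obs / comp, np.nan)
    return out if out.ndim else float(out)


def compute_cell_metrics(
    pm: PresenceMatrix,
    tree: Phylogeny,
    bi: BranchIncidence = None,
) -> pd.DataFrame:
    """All per-cell metrics in one table.

    Columns: cell_ix, cell_iy, lon_ll, lat_ll, SR, WE, CWE, PD, PE,
    PD_comp, PE_comp, RPD, RPE, redundancy.  The comparison values reuse the
    observed incidences and ranges; only branch lengths change.
    """
    if bi is None:
        bi = build_branch_incidence(pm, tree)
    if bi.cells != pm.cells:
        # branch incidence may have dropped off-tree species and with them cells
        pm = pm.subset_species(bi.species)
    comp = make_comparison_tree(tree)
    comp_lengths = comp.lengths[comp.branch_indices()]

    sr = pm.richness
    inv_range = 1.0 / pm.range_size
    we = pm.incidence @ inv_range
    pd_obs = pd_vector(bi)
    pe_obs = pe_vector(bi)
    pd_comp = pd_vector(bi, lengths=comp_lengths)
    pe_comp = pe_vector(bi, lengths=comp_lengths)

    res = pm.grid.resolution
    ix = np.array([c[0] for c in pm.cells])
    iy = np.array([c[1] for c in pm.cells])
    return pd.DataFrame(
        {
            "cell_ix": ix,
            "cell_iy": iy,
            "lon_ll": ix * res,
            "lat_ll": iy * res,
            "SR": sr,
            "WE": we,
            "CWE": we / sr,
            "PD": pd_obs,
            "PE": pe_obs,
            "PD_comp": pd_comp,
            "PE_comp": pe_comp,
            "RPD": relative_metric(pd_obs, pd_comp),
            "RPE": relative_metric(pe_obs, pe_comp),
            "redundancy": sampling_redundancy(pm),
        }
    )
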