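"""Rooted phylogenies: parsing, validation, pruning, and the equal-branch-length
comparison tree used by relative phylogenetic diversity / endemism.

A tree is stored as parallel node arrays; a *branch* is the edge above a
non-root node, so ``branch_count == n_nodes - 1`` and the root's subtending
edge (if any appears in the Newick) never enters ``total_length``.  This is
the convention under which Faith's PD of a cell is the summed length of every
edge on the tip-to-root paths of the species present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NewickError",
    "PruneError",
    "normalize_name",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "make_comparison_tree",
    "match_species",
    "MatchReport",
]


class NewickError(ValueError):
    """Malformed or invalid Newick input."""


class PruneError(ValueError):
    """Pruning request that leaves no tips."""


def normalize_name(name: str) -> str:
    """Canonical species-name form: strip whitespace, underscores to spaces."""
    return name.strip().replace("_", " ")


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths.

    Attributes
    ----------
    parent : (n,) int array, ``-1`` at the root.
    lengths : (n,) float array; length of the edge above each node
        (the root entry is ignored and kept at 0).
    labels : per-node label; every tip is labelled, internal labels optional.
    root : index of the root node.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list
    root: int = 0
    _children: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self._validate()

    def _validate(self):
        n = len(self.parent)
        if n == 0:
            raise NewickError("empty tree")
        if (self.parent == -1).sum() != 1:
            raise NewickError("tree must have exactly one root")
        if np.any(self.lengths < 0):
            bad = int(np.argmax(self.lengths < 0))
            raise NewickError(
                f"negative branch length {self.lengths[bad]} on node "
                f"{self.labels[bad] or bad!r}"
            )
        tips = self.tip_indices()
        tip_labels = [self.labels[i] for i in tips]
        if any(lbl is None or lbl == "" for lbl in tip_labels):
            raise NewickError("every tip must carry a non-empty label")
        if len(set(tip_labels)) != len(tip_labels):
            seen, dup = set(), None
            for lbl in tip_labels:
                if lbl in seen:
                    dup = lbl
                    break
                seen.add(lbl)
            raise NewickError(f"duplicate tip label {dup!r}")

    # -- structure ---------------------------------------------------------

    def children(self, node: int) -> list:
        if self._children is None:
            ch = [[] for _ in range(len(self.parent))]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children[node]

    def tip_indices(self) -> np.ndarray:
        has_child = np.zeros(len(self.parent), dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def branch_indices(self) -> np.ndarray:
        """All non-root nodes, i.e. one index per branch."""
        return np.flatnonzero(self.parent >= 0)

    @property
    def branch_count(self) -> int:
        return len(self.parent) - 1

    @property
    def total_length(self) -> float:
        return float(self.lengths[self.branch_indices()].sum())

    def branch_ids(self) -> list:
        """Stable per-branch identifiers (label where present, else b<idx>)."""
        return [self.labels[i] or f"b{i}" for i in self.branch_indices()]

    def descendant_tip_matrix(self, tip_order: list) -> np.ndarray:
        """Boolean (n_tips_requested, branch_count) ancestry matrix.

        Entry (s, b) is True when branch b lies on the path from tip s to the
        root, so a cell containing tip s contains branch b.
        """
        tips = self.tip_indices()
        label_to_node = {self.labels[i]: int(i) for i in tips}
        branches = self.branch_indices()
        col_of = {int(b): j for j, b in enumerate(branches)}
        mat = np.zeros((len(tip_order), len(branches)), dtype=bool)
        for s, lbl in enumerate(tip_order):
            node = label_to_node[lbl]
            while node != self.root:
                mat[s, col_of[node]] = True
                node = int(self.parent[node])
        return mat

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.labels), self.root)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree.

    Branch lengths are taken as written (missing lengths default to 0);
    polytomies are preserved; internal nodes keep their labels where given.
    Raises :class:`NewickError` for malformed input, duplicate tip labels,
    or negative lengths, naming the offending token where possible.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickError("empty Newick input")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError("Newick tree must end with ';'")
    if stripped.count("(") != stripped.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse failed: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes), dtype=np.float64)
    labels: list = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return Phylogeny(parent, lengths, labels, root=0)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; lengths with 12 significant digits."""

    def fmt(node: int) -> str:
        kids = tree.children(node)
        label = tree.labels[node] or ""
        if kids:
            inner = ",".join(fmt(k) for k in kids)
            s = f"({inner}){label}"
        else:
            s = label
        if node != tree.root:
            s += f":{tree.lengths[node]:.12g}"
        return s

    return fmt(tree.root) + ";"


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Prune to the tips whose (normalized) labels are in ``keep``.

    Unary internal nodes arising from the prune are collapsed with their
    lengths summed; a unary root is replaced by its surviving child so the
    root never carries a stem.  Labels in ``keep`` absent from the tree are
    reported as a warning with a count.
    """
    keep_norm = {normalize_name(k) for k in keep}
    tips = tree.tip_indices()
    tip_norm = {i: normalize_name(tree.labels[i]) for i in tips}
    kept_tips = {i for i in tips if tip_norm[i] in keep_norm}
    matched = {tip_norm[i] for i in kept_tips}
    unmatched = sorted(keep_norm - matched)
    if not kept_tips:
        raise PruneError(
            f"no tips matched; {len(unmatched)} unmatched labels: "
            + ", ".join(unmatched[:10])
        )
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} label(s) in keep set not found in tree "
            f"(e.g. {unmatched[:5]})",
            stacklevel=2,
        )

    # (label, length, children) nested build, collapsing unary nodes
    def build(node: int):
        if node in kept_tips:
            return (tree.labels[node], float(tree.lengths[node]), [])
        sub = [build(c) for c in tree.children(node)]
        sub = [s for s in sub if s is not None]
        if not sub:
            return None
        if len(sub) == 1:  # unary: absorb this edge into the child
            lbl, ln, ch = sub[0]
            return (lbl, ln + float(tree.lengths[node]), ch)
        return (tree.labels[node], float(tree.lengths[node]), sub)

    rooted = build(tree.root)
    # a unary chain at the root has already been absorbed by build(); drop
    # whatever stem length it accumulated, as root edges carry no length
    labels, parents, lengths = [], [], []

    def emit(entry, parent_idx: int) -> int:
        lbl, ln, ch = entry
        idx = len(labels)
        labels.append(lbl)
        parents.append(parent_idx)
        lengths.append(ln if parent_idx >= 0 else 0.0)
        for c in ch:
            emit(c, idx)
        return idx

    emit(rooted, -1)
    return Phylogeny(np.array(parents), np.array(lengths), labels, root=0)


def make_comparison_tree(tree: Phylogeny) -> Phylogeny:
    """Same topology, every branch length = total_length / branch_count.

    Total length is conserved by construction; used as the denominator tree
    for RPD and RPE, where observed branch lengths are replaced by their
    average so the ratio isolates the *distribution* of branch lengths.
    """
    total = tree.total_length
    if total <= 0:
        raise ValueError("comparison tree undefined for zero total length")
    out = tree.copy()
    equal = total / tree.branch_count
    out.lengths[:] = equal
    out.lengths[out.root] = 0.0
    return out


@dataclass
class MatchReport:
    """Outcome of matching occurrence species names to tree tips.

    ``matched`` holds normalized names; ``matched_occurrence`` and
    ``matched_tree`` hold the corresponding labels as they appear on each
    side (needed when e.g. the occurrence file uses underscores).
    """

    matched: list
    matched_occurrence: list
    matched_tree: list
    tree_only: list
    occurrences_only: list

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def summary(self) -> str:
        return (
            f"matched {len(self.matched)} species; "
            f"{len(self.tree_only)} tree tips without occurrences; "
            f"{len(self.occurrences_only)} occurrence species not in tree"
        )


def match_species(tree: Phylogeny, species) -> MatchReport:
    """Exact name matching after normalization (trim, underscores→spaces)."""
    tree_names = {normalize_name(t): t for t in tree.tip_labels}
    occ_names = {normalize_name(s): s for s in species}
    shared = sorted(set(tree_names) & set(occ_names))
    return MatchReport(
        matched=shared,
        matched_occurrence=[occ_names[s] for s in shared],
        matched_tree=[tree_names[s] for s in shared],
        tree_only=sorted(set(tree_names) - set(occ_names)),
        occurrences_only=sorted(set(occ_names) - set(tree_names)),
    )
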