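"""Shared fixtures: a 4-tip tree and a 3-cell occurrence set with
hand-computable metrics, used throughout the suite.

Tree ((A:1,B:1)E:1,(C:1,D:3)F:2)R has 6 branches and total length 9.
Cells: c1 = {A,B}, c2 = {A,C}, c3 = {D}.  Branch ranges: A,E,F = 2;
B,C,D = 1 (F spans c2 and c3 through its descendants C and D).
"""

import numpy as np
import pytest

from spatialphylo.grid import GridSpec, build_branch_incidence, build_presence_matrix
from spatialphylo.phylo import parse_newick

FIXTURE_NEWICK = "((A:1,B:1)E:1,(C:1,D:3)F:2)R;"

# one record per (species, cell); cells are (0,0), (1,0), (2,0) at 0.1°
FIXTURE_RECORDS = [
    ("A", 0.01, 0.01),
    ("B", 0.05, 0.05),
    ("A", 0.11, 0.01),
    ("C", 0.15, 0.08),
    ("D", 0.22, 0.03),
]

C1, C2, C3 = (0, 0), (1, 0), (2, 0)


@pytest.fixture
def fixture_tree():
    return parse_newick(FIXTURE_NEWICK)


@pytest.fixture
def fixture_grid():
    return GridSpec(resolution=0.1)


@pytest.fixture
def fixture_pm(fixture_grid):
    return build_presence_matrix(FIXTURE_RECORDS, fixture_grid)


@pytest.fixture
def fixture_bi(fixture_pm, fixture_tree):
    return build_branch_incidence(fixture_pm, fixture_tree)


def random_instance(rng, n_tips=None, n_cells=None, max_tips=12, max_cells=8):
    """Random small tree + presence matrix for oracle comparisons."""
    from spatialphylo.grid import PresenceMatrix

    n_tips = n_tips or int(rng.integers(2, max_tips + 1))
    n_cells = n_cells or int(rng.integers(2, max_cells + 1))
    newick = _random_newick(rng, n_tips)
    tree = parse_newick(newick)
    species = sorted(tree.tip_labels)
    inc = np.zeros((n_cells, n_tips), dtype=bool)
    while not (inc.any(axis=1).all() and inc.any(axis=0).all()):
        inc = rng.random((n_cells, n_tips)) < 0.45
    cells = [(i, 0) for i in range(n_cells)]
    counts = inc.sum(axis=1) + rng.integers(0, 4, size=n_cells)
    pm = PresenceMatrix(cells, species, inc, counts, GridSpec(0.1))
    return tree, pm


def _random_newick(rng, n_tips):
    items = [f"t{i}" for i in range(n_tips)]
    lengths = {}
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        la, lb = rng.uniform(0.1, 2.0, size=2)
        items.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return items[0] + ";"
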