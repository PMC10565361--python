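"""Randomization tests and cradle/museum classification.

The null model shuffles species identities across cells while holding both
margins of the presence–absence matrix fixed — every cell keeps its
richness, every species its range size — using curveball trades (random
exchanges of the species unique to a pair of cells).  Margin-preserving
nulls are the community standard for PE/RPE significance because the
metrics are strongly driven by richness and range size, which the null must
therefore condition on.

Per cell the observed metric is ranked against its null distribution with
the half-tie convention, p = (#{null < obs} + 0.5·#{null = obs}) / n_rand,
and flagged high (p > 0.99), low (p < 0.01) or ns.  Classification modes:

* ``paper``   — palaeo iff RPE flag high, neo iff RPE flag low, else ns.
* ``canape``  — the two-step categorical scheme: a cell is eligible iff its
  PE on the original or on the comparison tree ranks above 0.95
  (one-tailed); among eligible cells, neo iff RPE rank < 0.025, palaeo iff
  > 0.975, super iff both PE ranks > 0.99, else mixed.

High RPE marks an excess of long range-restricted branches (palaeoendemism,
a museum); low RPE marks short range-restricted branches (neoendemism, a
cradle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BranchIncidence, PresenceMatrix
from .metrics import relative_metric
from .phylo import Phylogeny, make_comparison_tree

__all__ = [
    "RandomizationConfig",
    "randomize_matrix",
    "curveball",
    "significance_rank",
    "classify_endemism",
    "run_null_suite",
    "NullSuiteResult",
]

PAPER_MODE = "paper"
CANAPE_MODE = "canape"

# relative tolerance under which a recomputed metric counts as tied with
# the observed value in the rank statistic
_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


@dataclass
class RandomizationConfig:
    n_rand: int = 999
    seed: int = 0
    algorithm: str = "curveball"
    high: float = 0.99
    low: float = 0.01
    mode: str = PAPER_MODE
    include_cwe: bool = False
    # trades per randomization; None → 5 × number of presences
    n_trades: int = None

    def __post_init__(self):
        if self.n_rand < 1:
            raise ValueError("n_rand must be ≥ 1")
        if not (0 < self.low < self.high < 1):
            raise ValueError("need 0 < low < high < 1")
        if self.mode not in (PAPER_MODE, CANAPE_MODE):
            raise ValueError(f"unknown mode {self.mode!r}")


def curveball(incidence: np.ndarray, rng: np.random.Generator, n_trades: int) -> np.ndarray:
    """Curveball trades on a boolean cells × species matrix.

    Each trade picks two cells and re-deals the species unique to either
    between them, preserving both cells' richness and every species' range.
    Returns a new matrix; the input is untouched.  The trade loop runs on a
    stdlib RNG seeded from ``rng``, so results stay deterministic.
    """
    import random as _random

    rows = [set(np.flatnonzero(r)) for r in incidence]
    n = len(rows)
    pyrng = _random.Random(int(rng.integers(0, 2**63)))
    randrange = pyrng.randrange
    for _ in range(n_trades):
        i = randrange(n)
        j = randrange(n)
        if i == j:
            continue
        a, b = rows[i], rows[j]
        only_a = a - b
        only_b = b - a
        if not only_a or not only_b:
            continue
        pool = list(only_a) + list(only_b)
        new_a = set(pyrng.sample(pool, len(only_a)))
        common = a & b
        rows[i] = common | new_a
        rows[j] = common | (set(pool) - new_a)
    out = np.zeros_like(incidence)
    for i, members in enumerate(rows):
        out[i, list(members)] = True
    return out


def randomize_matrix(pm: PresenceMatrix, seed, n_trades: int = None) -> PresenceMatrix:
    """Margin-preserving randomization of a presence matrix.

    Row sums (cell richness) and column sums (species ranges) are preserved
    exactly.  Deterministic given ``seed``.  A matrix with a single row or
    column is returned unchanged with a warning.
    """
    if pm.n_cells < 2 or pm.n_species < 2:
        warnings.warn("matrix has a single row or column; no swap possible", stacklevel=2)
        return pm
    rng = np.random.default_rng(seed)
    if n_trades is None:
        n_trades = 5 * int(pm.incidence.sum())
    inc = curveball(pm.incidence, rng, n_trades)
    return PresenceMatrix(
        cells=list(pm.cells),
        species=list(pm.species),
        incidence=inc,
        record_count=pm.record_count.copy(),
        grid=pm.grid,
    )


def significance_rank(observed: float, null_values, config: RandomizationConfig = None):
    """Half-tie rank of an observed value in its null distribution.

    Returns ``(p, flag)`` with p = (#{null < obs} + 0.5·#{null = obs}) / n
    and flag ∈ {"high", "low", "ns"} per the configured thresholds.
    """
    if config is None:
        config = RandomizationConfig()
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    ties = np.isclose(nulls, observed, rtol=_TIE_RTOL, atol=_TIE_ATOL)
    below = (nulls < observed) & ~ties
    p = (below.sum() + 0.5 * ties.sum()) / nulls.size
    if p > config.high:
        flag = "high"
    elif p < config.low:
        flag = "low"
    else:
        flag = "ns"
    return float(p), flag


def _flags(p: np.ndarray, config: RandomizationConfig):
    out = np.full(p.shape, "ns", dtype=object)
    out[p > config.high] = "high"
    out[p < config.low] = "low"
    return out


def classify_endemism(sig: pd.DataFrame, config: RandomizationConfig) -> pd.Series:
    """Assign each cell a cradle/museum class from its significance ranks.

    ``sig`` must carry ``p_RPE`` (both modes) plus ``p_PE`` and
    ``p_PE_comp`` (canape mode).  See the module docstring for the rules.
    """
    if "p_RPE" not in sig.columns:
        raise ValueError("significance table lacks p_RPE ranks")
    p_rpe = sig["p_RPE"].to_numpy()
    if config.mode == PAPER_MODE:
        out = np.full(len(sig), "ns", dtype=object)
        out[p_rpe > config.high] = "palaeo"
        out[p_rpe < config.low] = "neo"
        return pd.Series(out, index=sig.index, name="endemism_class")
    missing = [c for c in ("p_PE", "p_PE_comp") if c not in sig.columns]
    if missing:
        raise ValueError(f"canape mode needs columns: {', '.join(missing)}")
    p_pe = sig["p_PE"].to_numpy()
    p_pec = sig["p_PE_comp"].to_numpy()
    eligible = (p_pe > 0.95) | (p_pec > 0.95)
    out = np.full(len(sig), "ns", dtype=object)
    out[eligible] = "mixed"
    out[eligible & (p_rpe < 0.025)] = "neo"
    out[eligible & (p_rpe > 0.975)] = "palaeo"
    out[eligible & (p_pe > 0.99) & (p_pec > 0.99)] = "super"
    return pd.Series(out, index=sig.index, name="endemism_class")


@dataclass
class NullSuiteResult:
    significance: pd.DataFrame
    classification: pd.Series
    config: RandomizationConfig
    n_rand: int = field(init=False)

    def __post_init__(self):
        self.n_rand = self.config.n_rand


def _metric_block(inc_bool, anc, L_orig, L_comp, inv_range_cols=None):
    """RPD/RPE (+ PE on both trees) from a cells × species boolean matrix."""
    branch_inc = inc_bool @ anc  # boolean OR over descendant tips
    R = branch_inc.sum(axis=0).astype(float)
    safe_R = np.maximum(R, 1.0)
    pd_o = branch_inc @ L_orig
    pd_c = branch_inc @ L_comp
    pe_o = branch_inc @ (L_orig / safe_R)
    pe_c = branch_inc @ (L_comp / safe_R)
    out = {
        "PD": pd_o,
        "PE": pe_o,
        "PE_comp": pe_c,
        "RPD": relative_metric(pd_o, pd_c),
        "RPE": relative_metric(pe_o, pe_c),
    }
    if inv_range_cols is not None:
        sr = inc_bool.sum(axis=1)
        col_range = np.maximum(inc_bool.sum(axis=0), 1).astype(float)
        out["CWE"] = (inc_bool @ (1.0 / col_range)) / sr
    return out


def run_null_suite(
    pm: PresenceMatrix,
    tree: Phylogeny,
    config: RandomizationConfig,
    bi: BranchIncidence = None,
    progress=None,
) -> NullSuiteResult:
    """Run the full randomization suite and classify cells.

    For each of ``n_rand`` randomized matrices the branch incidence is
    rebuilt and RPD, RPE (and CWE if requested) recomputed; observed values
    are ranked cell-wise against the null draws.  Reproducible given
    ``config.seed``; ``progress`` (if given) is called every 100 draws.
    """
    from .grid import build_branch_incidence

    if bi is None:
        bi = build_branch_incidence(pm, tree)
    if bi.cells != pm.cells or bi.species != pm.species:
        pm = pm.subset_species(bi.species)
    comp = make_comparison_tree(tree)
    anc = bi.ancestry
    L_orig = bi.branch_length
    L_comp = comp.lengths[comp.branch_indices()]

    metrics = ["RPD", "RPE", "PE", "PE_comp"] + (["CWE"] if config.include_cwe else [])
    obs = _metric_block(
        pm.incidence, anc, L_orig, L_comp,
        inv_range_cols=True if config.include_cwe else None,
    )

    n_cells = pm.n_cells
    below = {m: np.zeros(n_cells) for m in metrics}
    ties = {m: np.zeros(n_cells) for m in metrics}
    n_trades = config.n_trades if config.n_trades is not None else 5 * int(pm.incidence.sum())
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.n_rand)
    for k in range(config.n_rand):
        rng = np.random.default_rng(int(seeds[k]))
        rand_inc = curveball(pm.incidence, rng, n_trades)
        null = _metric_block(
            rand_inc, anc, L_orig, L_comp,
            inv_range_cols=True if config.include_cwe else None,
        )
        for m in metrics:
            tie = np.isclose(null[m], obs[m], rtol=_TIE_RTOL, atol=_TIE_ATOL)
            below[m] += (null[m] < obs[m]) & ~tie
            ties[m] += tie
        if progress is not None and (k + 1) % 100 == 0:
            progress(k + 1)

    sig = pd.DataFrame({"cell_ix": [c[0] for c in pm.cells], "cell_iy": [c[1] for c in pm.cells]})
    for m in metrics:
        p = (below[m] + 0.5 * ties[m]) / config.n_rand
        sig[f"obs_{m}"] = obs[m]
        sig[f"p_{m}"] = p
        sig[f"flag_{m}"] = _flags(p, config)
    classification = classify_endemism(sig, config)
    return NullSuiteResult(significance=sig, classification=classification, config=config)
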