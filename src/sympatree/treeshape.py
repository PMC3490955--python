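"""Whole-tree asymmetry statistics and the per-branch rate-shift test.

Under the equal-rates Markov (ERM) null -- every extant lineage equally
likely to split next -- the probability that a clade of n species divides
into unordered daughter diversities {l, n-l} is 2/(n-1) (1/(n-1) for the
even split), independent of branch lengths.  Two classic imbalance summaries
are implemented: the Colless index (sum over internal nodes of the absolute
daughter-size difference; coarse, root-weighted) and Shao & Sokal's B1 (sum
of reciprocal maximum node depths below each non-root internal node; finer,
tip-weighted).  Their significance comes from ERM topology simulation.

The per-branch shift statistic Delta1 asks, for a focal internal branch,
how much better a single diversification-rate shift along that branch
explains the diversity partition at the branch's parent than homogeneous
ERM does.  The shift model multiplies the focal clade's speciation rate by
rho; the induced probability of the parent's partition is that of a
"Yule race" between the focal lineage (rate rho) and its sister (rate 1),
maximised over rho.  The focal clade's own basal split is ERM-distributed
under both models, so it cancels from the ratio, leaving a purely
topological statistic.  Significance is by Monte Carlo: the fraction of ERM
trees of the same size whose *maximal* Delta1 over the internal-branch class
reaches the observed value, which accounts for selecting the best branch.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .chronogram import Chronogram

__all__ = [
    "ShapeStatistics",
    "ShiftTestResult",
    "erm_split_probability",
    "colless_index",
    "b1_index",
    "shape_statistics",
    "erm_pvalue",
    "simulate_erm_topology",
    "delta1",
    "delta1_all_branches",
    "delta1_shift_test",
]


@dataclass(frozen=True)
class ShapeStatistics:
    colless: int
    b1: float
    n_tips: int


@dataclass(frozen=True)
class ShiftTestResult:
    branch: tuple
    delta1: float
    p: float
    n_sim: int
    seed: int


# ----------------------------------------------------------------------
# ERM primitive
# ----------------------------------------------------------------------
def erm_split_probability(n: int, l: int) -> float:
    """ERM probability of the unordered daughter-diversity split {l, n-l}."""
    if n < 2:
        raise ValueError("clade size must be >= 2")
    if not 1 <= l <= n - 1:
        raise ValueError(f"left diversity {l} invalid for clade of {n}")
    if 2 * l == n:
        return 1.0 / (n - 1)
    return 2.0 / (n - 1)


# ----------------------------------------------------------------------
# imbalance indices
# ----------------------------------------------------------------------
def _postorder_counts(chron: Chronogram):
    """Per node: (tip count, max node-path length to a descendant tip)."""
    chron.require_binary()
    info = {}
    for nd in chron.tree.postorder_node_iter():
        if nd.is_leaf():
            info[nd] = (1, 0)
        else:
            kids = nd.child_nodes()
            (nl, hl), (nr, hr) = info[kids[0]], info[kids[1]]
            info[nd] = (nl + nr, 1 + max(hl, hr))
    return info


def colless_index(chron: Chronogram) -> int:
    """Sum over internal nodes of |left tips - right tips|."""
    if chron.n_tips < 3:
        raise ValueError("Colless index needs at least 3 tips")
    info = _postorder_counts(chron)
    total = 0
    for nd in chron.internal_nodes():
        kids = nd.child_nodes()
        total += abs(info[kids[0]][0] - info[kids[1]][0])
    return total


def b1_index(chron: Chronogram) -> float:
    """Sum of 1/M_i over non-root internal nodes; M_i = max depth below i."""
    if chron.n_tips < 3:
        raise ValueError("B1 index needs at least 3 tips")
    info = _postorder_counts(chron)
    return float(
        sum(1.0 / info[nd][1] for nd in chron.internal_nodes(exclude_root=True))
    )


def shape_statistics(chron: Chronogram) -> ShapeStatistics:
    return ShapeStatistics(
        colless=colless_index(chron), b1=b1_index(chron), n_tips=chron.n_tips
    )


# ----------------------------------------------------------------------
# ERM topology simulation (tuple trees; branch lengths are irrelevant)
# ----------------------------------------------------------------------
def simulate_erm_topology(n_tips: int, rng: np.random.Generator):
    """Random ERM (Yule-process) topology as nested tuples; leaves are 0.

    Generated by uniform random pairwise joining, which induces the same
    distribution over labelled topologies as the forward ERM split process.
    """
    items: list = [0] * n_tips
    while len(items) > 1:
        i, j = rng.choice(len(items), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = (items[i], items[j])
        items[j] = items[-1]
        items.pop()
        items[i] = merged
    return items[0]


def _tuple_stats(node) -> tuple[int, int, int, float]:
    """(tips, max depth, colless, b1-contribution incl. this node)."""
    if node == 0:
        return 1, 0, 0, 0.0
    nl, hl, cl, bl = _tuple_stats(node[0])
    nr, hr, cr, br = _tuple_stats(node[1])
    h = 1 + max(hl, hr)
    return nl + nr, h, cl + cr + abs(nl - nr), bl + br + 1.0 / h


def _tuple_colless_b1(tree) -> tuple[int, float]:
    n, h, c, b = _tuple_stats(tree)
    return c, b - 1.0 / h  # root's own term is excluded from B1


def erm_pvalue(
    stat_name: str, observed: float, n_tips: int, n_sim: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo ERM p-value for an imbalance statistic.

    Direction of asymmetry: large Colless, small B1.  p is the +1-corrected
    fraction of ERM topologies at least as asymmetric as observed.
    """
    if stat_name not in ("colless", "b1"):
        raise ValueError("stat_name must be 'colless' or 'b1'")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        c, b = _tuple_colless_b1(simulate_erm_topology(n_tips, rng))
        sim = c if stat_name == "colless" else b
        if stat_name == "colless":
            extreme = sim >= observed - 1e-12
        else:
            extreme = sim <= observed + 1e-12
        count += extreme
    return (count + 1) / (n_sim + 1)


# ----------------------------------------------------------------------
# Delta1 shift statistic
# ----------------------------------------------------------------------
_RHO_GRID = np.exp(np.linspace(np.log(1.0 / 64.0), np.log(64.0), 97))


def _race_logprob(n: int, rho: float) -> np.ndarray:
    """log P(focal daughter ends with k of n tips), k = 1..n-1.

    Jump chain of two competing pure-birth clades started at one lineage
    each: with f focal and s sister lineages, the next split is focal with
    probability rho*f / (rho*f + s).  At rho = 1 the distribution is uniform
    (homogeneous ERM).
    """
    p = np.array([1.0])  # f = 1 at total 2
    for m in range(2, n):
        f = np.arange(1, m)
        pf = rho * f / (rho * f + (m - f))
        nxt = np.zeros(m)
        nxt[: m - 1] += p * (1.0 - pf)  # sister splits, f unchanged
        nxt[1:] += p * pf  # focal splits
        p = nxt
    with np.errstate(divide="ignore"):
        return np.log(p)


@lru_cache(maxsize=512)
def _max_shift_logprob(n: int) -> np.ndarray:
    """max over rho of log P_rho(k of n), element-wise over k = 1..n-1."""
    best = np.full(n - 1, -np.inf)
    for rho in _RHO_GRID:
        best = np.maximum(best, _race_logprob(n, rho))
    return best


def _node_shift_gain(n: int, k: int) -> float:
    """Log-likelihood gain of a one-daughter rate shift at a single node.

    A clade of ``n`` tips splits with one daughter holding ``k``; the gain
    is max over the shift magnitude rho of ln P_rho(k; n) minus the
    homogeneous ERM log-probability ln(1/(n-1)).  Zero when the partition
    is typical, large when it is extreme.
    """
    if n < 3:
        return 0.0
    if not 1 <= k <= n - 1:
        raise ValueError("daughter diversity outside clade")
    return float(_max_shift_logprob(n)[k - 1] + np.log(n - 1))


def delta1(n_parent: int, n_focal: int, n_focal_left: int | None = None) -> float:
    """Shift statistic for the branch from a parent clade into a focal clade.

    The data are the diversity partition at the branch's parent
    (``n_parent`` splitting off ``n_focal``) and the focal clade's own
    basal split (``n_focal`` splitting off ``n_focal_left``).  A rate shift
    along the branch makes the parent partition lopsided while leaving the
    focal clade internally homogeneous, so the statistic is the shift
    log-likelihood gain at the parent minus the gain at the focal node:
    large only when the extremeness starts exactly at this branch, not
    above or below it.
    """
    parent_term = _node_shift_gain(n_parent, n_focal)
    if not n_focal_left:  # terminal or unstructured focal clade
        return parent_term
    return parent_term - _node_shift_gain(n_focal, n_focal_left)


def _tuple_max_delta1(tree) -> float:
    """Max Delta1 over internal non-root branches of a tuple topology."""
    best = [0.0]

    def walk(node) -> int:
        if node == 0:
            return 1
        nl = walk(node[0])
        nr = walk(node[1])
        n = nl + nr
        # focal = each internal child of this node
        for child, nc in ((node[0], nl), (node[1], nr)):
            if child != 0 and nc >= 2:
                nc_left = 1 if child[0] == 0 else _tuple_stats(child[0])[0]
                best[0] = max(best[0], delta1(n, nc, nc_left))
        return n

    walk(tree)
    return best[0]


def _resolve_branch(chron: Chronogram, branch):
    """A focal branch, given as a node or a collection of tip labels."""
    if isinstance(branch, (set, frozenset, list, tuple)):
        node = chron.mrca(branch)
        below = set(Chronogram.leaf_labels_under(node))
        if below != set(branch):
            raise ValueError(
                "tip set is not a clade in this tree "
                f"(MRCA spans {sorted(below)})"
            )
    else:
        node = branch
    if node.is_leaf():
        raise ValueError("focal branch must be internal (not terminal)")
    if node.parent_node is None:
        raise ValueError("the root has no branch above it")
    return node


def delta1_all_branches(chron: Chronogram) -> list[tuple[tuple, float]]:
    """(clade tips, Delta1) for every internal non-root branch."""
    chron.require_binary()
    info = _postorder_counts(chron)
    out = []
    for nd in chron.internal_nodes(exclude_root=True):
        n_parent = info[nd.parent_node][0]
        n_focal = info[nd][0]
        n_left = info[nd.child_nodes()[0]][0]
        tips = tuple(sorted(Chronogram.leaf_labels_under(nd)))
        out.append((tips, delta1(n_parent, n_focal, n_left)))
    return out


def delta1_shift_test(
    chron: Chronogram, branch, n_sim: int = 1000, seed: int = 0
) -> ShiftTestResult:
    """Monte-Carlo probability of a diversification-rate shift along a branch.

    The null distribution is the per-tree maximum Delta1 over internal
    non-root branches of ERM topologies with the same number of tips, so
    the test is valid even when the focal branch was chosen because it
    looked extreme.
    """
    if chron.n_tips < 4:
        raise ValueError("shift test needs at least 4 tips")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    node = _resolve_branch(chron, branch)
    info = _postorder_counts(chron)
    observed = delta1(
        info[node.parent_node][0],
        info[node][0],
        info[node.child_nodes()[0]][0],
    )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        sim = _tuple_max_delta1(simulate_erm_topology(chron.n_tips, rng))
        if sim >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_sim + 1)
    tips = tuple(sorted(Chronogram.leaf_labels_under(node)))
    return ShiftTestResult(
        branch=tips, delta1=observed, p=p, n_sim=n_sim, seed=seed
    )
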