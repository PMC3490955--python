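"""Tempo of diversification from branching times of a dated tree.

Three reconstructed-process models are fit to the branching times of an
ultrametric tree, all conditioned on the crown age:

* ``pure_birth`` -- constant speciation rate lambda, no extinction.  With
  branching times t_2 > ... > t_N (t_2 = crown age) and G the total
  lineage-time (sum of k * interval-length over inter-event intervals,
  including the final interval to the present), logL = (N-2) ln(lambda)
  - lambda * G and the MLE is lambda = (N-2)/G in closed form.
* ``birth_death`` -- constant net rate r = lambda - mu > 0 and relative
  extinction a = mu/lambda in [0, 1), with the Nee-May-Harvey reconstructed
  likelihood.  At a = 0 it reduces exactly to the pure-birth likelihood.
* ``yule_2_rate`` -- pure birth with one shift: rate lambda1 before time s,
  lambda2 after.  The likelihood is piecewise constant in s between events,
  so s is profiled over midpoints between adjacent branching times and the
  per-segment rates have closed-form MLEs.

Model selection uses AICc with n = number of branching times.  The
difference between the best rate-constant and the rate-variable AICc is
compared against a null distribution obtained by simulating pure-birth trees
at the fitted rate with the same number of extant and sampled taxa
(simulate, randomly prune, refit).  Net diversification with unsampled
species uses the Magallon-Sanderson crown method-of-moments estimator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import optimize

from .chronogram import Chronogram

__all__ = [
    "BranchingTimes",
    "FitResult",
    "RateEstimate",
    "NullTestResult",
    "branching_times",
    "ltt_curve",
    "fit_pure_birth",
    "fit_birth_death",
    "fit_yule_2_rate",
    "best_constant_fit",
    "delta_aicc",
    "delta_aicc_stat",
    "delta_aicc_null_test",
    "simulate_yule_tree",
    "ms_rate",
    "expected_crown_size",
    "posterior_rate_distribution",
]


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------
class BranchingTimes:
    """Ordered node ages t_2 > t_3 > ... > t_N (Myr before present)."""

    def __init__(self, ages: Sequence[float]):
        ages = np.asarray(ages, dtype=float)
        if ages.ndim != 1 or ages.size < 1:
            raise ValueError("need at least one branching time")
        if np.any(ages <= 0):
            raise ValueError("branching times must be strictly positive")
        if np.any(np.diff(ages) >= 0):
            raise ValueError("branching times must be strictly decreasing")
        self.ages = ages
        self.ages.flags.writeable = False

    @property
    def n_tips(self) -> int:
        return self.ages.size + 1

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def total_lineage_time(self) -> float:
        """G = sum over inter-event intervals of (lineage count) * length."""
        # telescopes to 2*t_2 + t_3 + ... + t_N
        return float(2 * self.ages[0] + self.ages[1:].sum())

    def data_key(self) -> tuple:
        return tuple(np.round(self.ages, 12))

    def __len__(self) -> int:
        return self.ages.size


@dataclass(frozen=True)
class FitResult:
    """One fitted diversification model: parameters, logL and AICc."""

    model: str
    params: dict
    logL: float
    aicc: float
    n_params: int
    n_obs: int
    converged: bool = True
    data_key: tuple = field(default=(), repr=False)


@dataclass(frozen=True)
class RateEstimate:
    """Net diversification per Myr for a clade of n species, crown age t."""

    r: float
    epsilon: float
    n: int
    crown_age: float
    clamped: bool = False


@dataclass(frozen=True)
class NullTestResult:
    """Simulated pure-birth null for the rate-variability statistic."""

    p: float
    observed: float
    lambda_hat: float
    n_extant: int
    n_sampled: int
    n_sim: int
    seed: int
    null_stats: np.ndarray = field(repr=False, default=None)


# ----------------------------------------------------------------------
# branching times and LTT
# ----------------------------------------------------------------------
def branching_times(tree: Chronogram) -> BranchingTimes:
    """Internal node ages of a binary ultrametric tree, sorted descending."""
    tree.require_binary()
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    ages = sorted((nd.age for nd in tree.internal_nodes()), reverse=True)
    return BranchingTimes(ages)


def ltt_curve(bt: BranchingTimes) -> list[tuple[float, int]]:
    """Lineage-through-time step series: (age before present, count)."""
    return [(float(t), k + 2) for k, t in enumerate(bt.ages)]


def _aicc(logL: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ----------------------------------------------------------------------
# pure birth
# ----------------------------------------------------------------------
def _pb_loglik(lam: float, n_tips: int, G: float) -> float:
    return (n_tips - 2) * math.log(lam) - lam * G


def fit_pure_birth(bt: BranchingTimes, method: str = "closed_form") -> FitResult:
    """Constant-rate pure-birth fit conditioned on the crown age.

    ``method='closed_form'`` uses lambda = (N-2)/G; ``method='optimize'``
    maximises the likelihood numerically (Brent bracket plus one Newton
    polish on the score) -- the two agree to high precision and the numeric
    route exists as an internal consistency check.
    """
    N = bt.n_tips
    if N < 3:
        raise ValueError("pure-birth fit needs at least 3 tips (one free event)")
    G = bt.total_lineage_time()
    lam_cf = (N - 2) / G
    if method == "closed_form":
        lam = lam_cf
    elif method == "optimize":
        res = optimize.minimize_scalar(
            lambda L: -_pb_loglik(L, N, G),
            bounds=(lam_cf / 50.0, lam_cf * 50.0),
            method="bounded",
            options={"xatol": 1e-13},
        )
        lam = float(res.x)
        # one Newton step on the score sharpens the bounded-search optimum
        score = (N - 2) / lam - G
        hess = -(N - 2) / lam**2
        lam -= score / hess
    else:
        raise ValueError("method must be 'closed_form' or 'optimize'")
    logL = _pb_loglik(lam, N, G)
    return FitResult(
        model="pure_birth",
        params={"lambda": lam},
        logL=logL,
        aicc=_aicc(logL, 1, len(bt)),
        n_params=1,
        n_obs=len(bt),
        data_key=bt.data_key(),
    )


# ----------------------------------------------------------------------
# birth-death (Nee-May-Harvey reconstructed process)
# ----------------------------------------------------------------------
def _bd_loglik_batch(X: np.ndarray, r: np.ndarray, a: np.ndarray) -> np.ndarray:
    """logL for batched datasets X (B, M) at per-dataset r, a arrays (B, P).

    X rows are branching times sorted descending (x_2 ... x_N).  Constants
    are chosen so that at a = 0 this equals the pure-birth logL exactly.
    """
    B, M = X.shape
    N = M + 1
    S3 = X[:, 1:].sum(axis=1)  # sum x_3..x_N
    Sall = X.sum(axis=1)
    E = np.exp(-r[:, :, None] * X[:, None, :])  # (B, P, M)
    out = (
        (N - 2) * np.log(r)
        + r * (S3 - 2 * Sall)[:, None]
        + N * np.log1p(-a)
        - 2.0 * np.log1p(-a[:, :, None] * E).sum(axis=2)
    )
    return out


def _fit_bd_batch(
    X: np.ndarray,
    n_zoom: int = 7,
    grid: int = 17,
    a_max: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximise the birth-death likelihood for every row of X.

    Deterministic iterative grid refinement over (ln r, a): a coarse grid is
    evaluated, then re-centred and shrunk around the best point.  The exact
    pure-birth point (r = Yule MLE, a = 0) is always a candidate, so
    logL(bd) >= logL(pb) holds by construction.
    """
    B, M = X.shape
    N = M + 1
    G = 2 * X[:, 0] + X[:, 1:].sum(axis=1)
    lam_hat = (N - 2) / G
    ll_pb = (N - 2) * np.log(lam_hat) - lam_hat * G

    lnr_lo = np.log(lam_hat) - 4.0
    lnr_hi = np.log(lam_hat) + 2.5
    lnr_lo_g, lnr_hi_g = lnr_lo.copy(), lnr_hi.copy()
    a_lo = np.zeros(B)
    a_hi = np.full(B, a_max)

    frac = np.linspace(0.0, 1.0, grid)
    best_ll = np.full(B, -np.inf)
    best_lnr = np.log(lam_hat).copy()
    best_a = np.zeros(B)

    for _ in range(n_zoom):
        lnr = lnr_lo[:, None] + frac[None, :] * (lnr_hi - lnr_lo)[:, None]
        avals = a_lo[:, None] + frac[None, :] * (a_hi - a_lo)[:, None]
        r = np.exp(lnr)
        E = np.exp(-r[:, :, None] * X[:, None, :])  # (B, P, M)
        S3 = X[:, 1:].sum(axis=1)
        Sall = X.sum(axis=1)
        base = (N - 2) * lnr + r * (S3 - 2 * Sall)[:, None]
        it_best_ll = np.full(B, -np.inf)
        it_best_p = np.zeros(B, dtype=int)
        it_best_q = np.zeros(B, dtype=int)
        for q in range(grid):
            aq = avals[:, q]
            ll = (
                base
                + N * np.log1p(-aq)[:, None]
                - 2.0 * np.log1p(-aq[:, None, None] * E).sum(axis=2)
            )
            lmax = ll.max(axis=1)
            upd = lmax > it_best_ll
            it_best_ll[upd] = lmax[upd]
            it_best_p[upd] = ll.argmax(axis=1)[upd]
            it_best_q[upd] = q
        rows = np.arange(B)
        c_lnr = lnr[rows, it_best_p]
        c_a = avals[rows, it_best_q]
        upd = it_best_ll > best_ll
        best_ll[upd] = it_best_ll[upd]
        best_lnr[upd] = c_lnr[upd]
        best_a[upd] = c_a[upd]
        # shrink windows to +/- one grid spacing around this iteration's best
        dlnr = (lnr_hi - lnr_lo) / (grid - 1)
        da = (a_hi - a_lo) / (grid - 1)
        lnr_lo = np.clip(c_lnr - dlnr, lnr_lo_g, lnr_hi_g)
        lnr_hi = np.clip(c_lnr + dlnr, lnr_lo_g, lnr_hi_g)
        a_lo = np.clip(c_a - da, 0.0, a_max)
        a_hi = np.clip(c_a + da, 0.0, a_max)

    # pure-birth guard: nested model can never do better than the full one
    worse = best_ll < ll_pb
    best_ll[worse] = ll_pb[worse]
    best_lnr[worse] = np.log(lam_hat)[worse]
    best_a[worse] = 0.0
    return np.exp(best_lnr), best_a, best_ll


def fit_birth_death(bt: BranchingTimes) -> FitResult:
    """Birth-death fit: net rate r > 0, relative extinction a in [0, 1)."""
    if bt.n_tips < 4:
        raise ValueError("birth-death fit needs at least 4 tips")
    X = bt.ages[None, :]
    r, a, ll = _fit_bd_batch(X)
    logL = float(ll[0])
    converged = bool(np.isfinite(logL))
    return FitResult(
        model="birth_death",
        params={"r": float(r[0]), "a": float(a[0])},
        logL=logL,
        aicc=_aicc(logL, 2, len(bt)),
        n_params=2,
        n_obs=len(bt),
        converged=converged,
        data_key=bt.data_key(),
    )


# ----------------------------------------------------------------------
# yule-2-rate
# ----------------------------------------------------------------------
def _y2r_profile(x: np.ndarray) -> tuple[float, float, float, float]:
    """Best (logL, lambda1, lambda2, s) over candidate shift times.

    Candidates are midpoints between adjacent branching times; within a
    segment the rate MLE is (events)/(lineage-time), requiring at least one
    free event on each side of the shift.
    """
    M = x.size
    N = M + 1
    # interval lengths d_k (k lineages present), k = 2..N
    d = np.empty(M)
    d[:-1] = x[:-1] - x[1:]
    d[-1] = x[-1]
    k = np.arange(2, N + 1)
    kd = k * d
    G_total = kd.sum()
    # candidate j = lineage count in the interval holding the shift midpoint
    js = np.arange(3, N)  # j = 3 .. N-1
    if js.size == 0:
        raise ValueError("no admissible shift point with >=1 event per side")
    # cumulative lineage-time of intervals fully older than x_j
    cum = np.concatenate([[0.0], np.cumsum(kd)])  # cum[m] = sum over k=2..m+1
    s = 0.5 * (x[js - 2] + x[js - 1])  # midpoint between x_j and x_{j+1}
    G1 = cum[js - 2] + js * (x[js - 2] - s)
    G2 = G_total - G1
    n1 = js - 2
    n2 = N - js
    ll = n1 * (np.log(n1 / G1) - 1.0) + n2 * (np.log(n2 / G2) - 1.0)
    b = int(np.argmax(ll))
    return float(ll[b]), float(n1[b] / G1[b]), float(n2[b] / G2[b]), float(s[b])


def fit_yule_2_rate(bt: BranchingTimes) -> FitResult:
    """Single-shift pure-birth fit: lambda1 before time s, lambda2 after."""
    if bt.n_tips < 5:
        raise ValueError("yule-2-rate fit needs at least 5 tips")
    logL, lam1, lam2, s = _y2r_profile(bt.ages)
    return FitResult(
        model="yule_2_rate",
        params={"lambda1": lam1, "lambda2": lam2, "shift_time": s},
        logL=logL,
        aicc=_aicc(logL, 3, len(bt)),
        n_params=3,
        n_obs=len(bt),
        data_key=bt.data_key(),
    )


# ----------------------------------------------------------------------
# model selection
# ----------------------------------------------------------------------
def best_constant_fit(bt: BranchingTimes) -> FitResult:
    """The rate-constant model (pure birth or birth-death) with lower AICc."""
    pb = fit_pure_birth(bt)
    bd = fit_birth_death(bt)
    return pb if pb.aicc <= bd.aicc else bd


def delta_aicc(best_constant: FitResult, best_variable: FitResult) -> float:
    """AICc(constant) - AICc(variable); positive favours rate variability."""
    if best_constant.data_key != best_variable.data_key:
        raise ValueError("fits were made on different branching-time data")
    return best_constant.aicc - best_variable.aicc


def delta_aicc_stat(bt: BranchingTimes) -> float:
    """The rate-variability test statistic for one set of branching times."""
    return delta_aicc(best_constant_fit(bt), fit_yule_2_rate(bt))


def _delta_stats_batch(X: np.ndarray) -> np.ndarray:
    """Vectorised delta-AICc statistic for a batch of same-size datasets."""
    B, M = X.shape
    N = M + 1
    G = 2 * X[:, 0] + X[:, 1:].sum(axis=1)
    lam = (N - 2) / G
    ll_pb = (N - 2) * np.log(lam) - lam * G
    aicc_pb = -2 * ll_pb + 2 + 4.0 / (M - 2)
    _, _, ll_bd = _fit_bd_batch(X)
    aicc_bd = -2 * ll_bd + 4 + 12.0 / (M - 3)
    aicc_const = np.minimum(aicc_pb, aicc_bd)
    ll_var = np.array([_y2r_profile(X[b])[0] for b in range(B)])
    aicc_var = -2 * ll_var + 6 + 24.0 / (M - 4)
    return aicc_const - aicc_var


# ----------------------------------------------------------------------
# Yule simulation (public, dendropy) and a light internal variant
# ----------------------------------------------------------------------
def simulate_yule_tree(n_tips: int, lam: float, seed: int) -> Chronogram:
    """Pure-birth (Yule) tree with exactly ``n_tips`` extant tips.

    The crown process starts with two lineages; waiting times are
    exponential with total rate (lineage count) * lam, the splitting lineage
    is chosen uniformly, and after the last split one further exponential
    interval separates the final event from the present.  Deterministic per
    seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not lam > 0:
        raise ValueError("lambda must be > 0")
    rng = np.random.default_rng(seed)
    root = _LNode(0.0)
    root.split(0.0)
    active = [root.left, root.right]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (lam * len(active)))
        i = rng.integers(len(active))
        nd = active[i]
        nd.split(t)
        active[i] = nd.left
        active.append(nd.right)
    t += rng.exponential(1.0 / (lam * n_tips))
    return _light_to_chronogram(root, t)


class _LNode:
    """Minimal tree node for fast simulation: birth/split absolute times."""

    __slots__ = ("birth", "split_time", "left", "right", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.split_time = None
        self.left = None
        self.right = None
        self.label = None

    def split(self, t: float) -> None:
        self.split_time = t
        self.left = _LNode(t)
        self.right = _LNode(t)


def _grow_yule_light(n_tips: int, lam: float, rng) -> tuple["_LNode", float]:
    root = _LNode(0.0)
    root.split(0.0)
    active = [root.left, root.right]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (lam * len(active)))
        i = rng.integers(len(active))
        nd = active[i]
        nd.split(t)
        active[i] = nd.left
        active.append(nd.right)
    t += rng.exponential(1.0 / (lam * n_tips))
    for k, nd in enumerate(active):
        nd.label = k
    return root, t


def _light_branching_times(
    root: "_LNode", present: float, keep: set | None = None
) -> np.ndarray:
    """Branching times (ages) of the tree induced by the kept tip labels."""
    ages: list[float] = []

    def walk(nd: "_LNode") -> int:
        if nd.split_time is None:
            if keep is None or nd.label in keep:
                return 1
            return 0
        nl = walk(nd.left)
        nr = walk(nd.right)
        if nl >= 1 and nr >= 1:
            ages.append(present - nd.split_time)
        return nl + nr

    walk(root)
    ages.sort(reverse=True)
    return np.asarray(ages)


def _light_to_chronogram(root: "_LNode", present: float) -> Chronogram:
    tree = dendropy.Tree()
    tidx = [0]

    def build(nd: "_LNode", parent):
        child = parent.new_child()
        if nd.split_time is None:
            child.edge.length = present - nd.birth
            tidx[0] += 1
            child.taxon = tree.taxon_namespace.new_taxon(f"t{tidx[0]}")
        else:
            child.edge.length = nd.split_time - nd.birth
            build(nd.left, child)
            build(nd.right, child)

    seed = tree.seed_node
    build(root.left, seed)
    build(root.right, seed)
    return Chronogram(tree)


# ----------------------------------------------------------------------
# simulated null for the delta-AICc statistic
# ----------------------------------------------------------------------
def delta_aicc_null_test(
    tree: Chronogram,
    n_extant: int,
    n_sampled: int,
    n_sim: int = 1000,
    seed: int = 0,
) -> NullTestResult:
    """Rate-constancy test: observed delta-AICc against a pure-birth null.

    ``n_sim`` pure-birth trees are simulated at the rate fitted to the data,
    conditioned on ``n_extant`` tips, randomly pruned to ``n_sampled`` tips
    (the incomplete-sampling correction: same number of extant and collected
    taxa as the data), and the statistic recomputed on each.  The p-value is
    the +1-corrected fraction of simulated statistics >= observed.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if not (2 <= n_sampled <= n_extant):
        raise ValueError("need 2 <= n_sampled <= n_extant")
    if tree.n_tips != n_sampled:
        raise ValueError(
            f"tree has {tree.n_tips} tips but n_sampled = {n_sampled}"
        )
    if n_sampled < 6:
        raise ValueError("statistic needs at least 6 sampled tips (AICc)")
    bt = branching_times(tree)
    lam_hat = fit_pure_birth(bt).params["lambda"]
    observed = delta_aicc_stat(bt)

    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, n_sampled - 1))
    for s in range(n_sim):
        root, present = _grow_yule_light(n_extant, lam_hat, rng)
        if n_sampled < n_extant:
            keep = set(
                rng.choice(n_extant, size=n_sampled, replace=False).tolist()
            )
        else:
            keep = None
        sims[s] = _light_branching_times(root, present, keep)
    null_stats = _delta_stats_batch(sims)
    p = (int(np.sum(null_stats >= observed - 1e-12)) + 1) / (n_sim + 1)
    return NullTestResult(
        p=p,
        observed=observed,
        lambda_hat=lam_hat,
        n_extant=n_extant,
        n_sampled=n_sampled,
        n_sim=n_sim,
        seed=seed,
        null_stats=null_stats,
    )


# ----------------------------------------------------------------------
# net diversification with unsampled species (Magallon-Sanderson crown)
# ----------------------------------------------------------------------
def ms_rate(n: int, t: float, epsilon: float = 0.0) -> RateEstimate:
    """Crown method-of-moments net diversification conditioned on survival.

    At epsilon = 0 this is exactly (ln n - ln 2) / t.  For small clades and
    large epsilon the estimator can be negative (observed diversity below
    the survival-conditioned expectation); it is then clamped at 0 and
    flagged.
    """
    if n < 2:
        raise ValueError("clade size n must be >= 2")
    if not t > 0:
        raise ValueError("crown age must be > 0")
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must lie in [0, 1)")
    e = epsilon
    if e == 0.0:
        r = (math.log(n) - math.log(2.0)) / t
    else:
        inner = n * (n * e * e - 8 * e + 2 * n * e + n)
        r = (
            math.log(
                (n * (1 - e * e) + 2 * e + (1 - e) * math.sqrt(inner)) / 2.0
            )
            - math.log(2.0)
        ) / t
    clamped = r < 0
    return RateEstimate(
        r=max(r, 0.0), epsilon=e, n=int(n), crown_age=float(t), clamped=clamped
    )


def expected_crown_size(r: float, epsilon: float, t: float) -> float:
    """Survival-conditioned expected crown diversity the estimator inverts."""
    e = epsilon
    x = math.exp(r * t)
    if e == 0.0:
        return 2.0 * x
    u = 2.0 * x - e
    return u * u / ((1 - e) * (u * (1 + e) - 2 * e * (1 - e)))


def posterior_rate_distribution(
    trees: Iterable[Chronogram],
    clade: Sequence[str],
    missing: int = 0,
    epsilon: float = 0.0,
) -> tuple[list[RateEstimate], int]:
    """Per-tree clade rate estimates over a posterior sample of chronograms.

    Trees in which the clade is not monophyletic are skipped and counted.
    Returns (estimates, number of skipped trees).
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree list")
    clade = set(clade)
    estimates: list[RateEstimate] = []
    skipped = 0
    for tr in trees:
        if not clade <= set(tr.tip_labels):
            skipped += 1
            continue
        node = tr.mrca(clade)
        if set(Chronogram.leaf_labels_under(node)) != clade:
            skipped += 1
            continue
        estimates.append(
            ms_rate(len(clade) + missing, node.age, epsilon=epsilon)
        )
    return estimates, skipped
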