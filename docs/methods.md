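# Methods

`sympatree` analyses the geography and tempo of speciation in small,
spatially bounded radiations — the situation typified by an insect genus
endemic to a single island, with on the order of 10–40 extant species, a
dated species-level phylogeny, and point collection records per species.
This note documents the models, the estimators, the synthetic-data
generator that supplies ground truth, and the numerical and design choices
behind them.

## 1. Ranges on a quadrat grid

Point localities are converted into species ranges on a fixed
latitude × longitude lattice of 0.025° cells (≈ 2.8 × 2.6 km at 21.5° S).
Each collection spot contributes the set of quadrats whose centers lie
within a great-circle radius of 4 km (an 8 km diameter circle); a species'
range is the union over its localities. The quadrat containing the point is
always included, so the construction is well defined for any radius.
Distances use the haversine formula on a sphere of radius 6371 km —
differences against ellipsoidal distance are sub-metre at this cell size.
The lattice is anchored at (0, 0) so a quadrat index is simply
`floor(coord / 0.025)`, reproducible without any declared map origin, and
cells are half-open so boundary points belong to exactly one quadrat.

Range area is the occupied-quadrat count times the cell area
`(0.025·111.32 km) × (0.025·111.32·cos φ̄ km)` evaluated at the mean
latitude φ̄ of the occupied quadrat centers. Over an island spanning ~2° of
latitude the error of this per-species flat-cell approximation is below 1%;
no map projection is used beyond the cosine correction.

The **degree of sympatry** of two species is
`|Q_a ∩ Q_b| / min(|Q_a|, |Q_b|)`: 0 for fully allopatric pairs, 1 when
the smaller range is nested in the larger. Normalising by the smaller range
makes the index insensitive to the (often very asymmetric) range sizes of
recently diverged microendemics.

## 2. Age-range correlation (ARC)

For every internal node of the chronogram the mean degree of sympatry is
taken over *cross pairs only* — one species from each daughter clade —
never over pairs within a daughter. Cross pairs are the independent
contrasts at that node; mixing in within-daughter pairs would re-count
younger splits and inflate apparent sympatry at old nodes. The mean is
unweighted over cross pairs (a nested clade-weighted variant was
considered and rejected as the less direct reading of a per-node average;
the per-node table is exposed, so any reweighting is a one-liner for the
user). Two further node responses are computed — the proportion of cross
pairs with exactly zero overlap and with exactly complete overlap — which
are less sensitive to range-size change than the mean.

Each response is regressed on node age by ordinary least squares over all
internal nodes including the root (with only ~15 nodes, discarding the
deepest point loses real information; the root is an ordinary contrast
here). Interpretation follows the classical ARC logic:

* slope > 0 and intercept < 0.5 → **allopatric-dominant**: young splits
  show no overlap, sympatry accrues with time (secondary sympatry through
  post-speciational range expansion);
* slope < 0 and intercept > 0.5 → **sympatric-dominant**: young splits
  are fully overlapping, overlap erodes with time;
* anything else → **inconclusive**.

Significance is by Monte-Carlo permutation: a random permutation of species
labels is applied jointly to the rows and columns of the overlap matrix
(the tree stays fixed), node responses and the OLS fit are recomputed, and
the one-tailed p-value is `(#{permuted ≥ observed} + 1) / (n_perm + 1)`,
reported separately for slope and intercept. The +1 correction keeps
p > 0 at finite permutation counts; an exhaustive mode enumerates all n!
permutations for small trees and then reports the plain exceedance
fraction.

**Area–age regression.** A species' age is its terminal branch length (the
age of the node joining it to its sister lineage). Crown ages of higher
clades would conflate species age with clade richness; terminal branch
length is the finest-grained, uniformly defined alternative. Range area is
regressed on species age; a positive slope (old species large, young
species microendemic) is the signature of post-speciational range
expansion. Between-clade range-size comparisons use a two-sided
Mann–Whitney rank-sum test — exact by full enumeration of rank assignments
(midranks for ties) when the smaller group has ≤ 8 members, where
enumeration is cheap, and the tie-corrected normal approximation otherwise.

## 3. Diversification from branching times

Branching times `t_2 > t_3 > … > t_N` are the internal node ages of the
binary ultrametric tree. Three reconstructed-process models are fitted,
all conditioned on the crown age `t_2`:

* **Pure birth.** With `G = Σ_k k·d_k` the total lineage-time (interval
  lengths `d_k` weighted by the lineage count, including the final interval
  to the present), `logL = (N−2)·ln λ − λG` and `λ̂ = (N−2)/G` in closed
  form. A numeric maximiser (bounded Brent plus one Newton step on the
  score) exists solely as an internal consistency check.
* **Birth–death.** The Nee–May–Harvey reconstructed likelihood in terms of
  the net rate `r = λ−μ > 0` and relative extinction `a = μ/λ ∈ [0, 1)`,
  with `ln(e^{rx} − a)` evaluated as `rx + log1p(−a e^{−rx})` for
  stability. The likelihood constant is chosen so that at `a = 0` it equals
  the pure-birth expression exactly. Maximisation is a deterministic
  iterative grid refinement over `(ln r, a)` — a coarse grid is evaluated,
  re-centred on its best point and shrunk, seven times — with the exact
  pure-birth point `(λ̂, 0)` always retained as a candidate. This makes the
  optimiser seed-free and globally searched, and guarantees the nesting
  inequality `logL(bd) ≥ logL(pb)` by construction rather than by hope;
  `a` is capped at 0.99 to exclude the degenerate `a → 1` ridge. The
  routine is vectorised over batches of equally sized datasets, which is
  what makes the simulated null below affordable.
* **Yule-2-rate.** Pure birth with one shift: rate `λ1` before time `s`,
  `λ2` after. The likelihood is piecewise constant in `s` between branching
  events, so `s` is profiled over midpoints between adjacent branching
  times (at least one free event required on each side) and the segment
  rates have closed-form MLEs `n_i/G_i`. One shift point is the model
  fitted; more shift points would be unidentifiable at these tree sizes.

Model selection uses AICc with `n` = the number of branching times
(`N − 1`). The test statistic for rate variability is
`ΔAICc = AICc(best rate-constant model) − AICc(yule-2-rate)`; positive
values favour rate variability. Because the statistic's distribution
depends on tree size and sampling, significance comes from simulation:
pure-birth trees are generated at the fitted `λ̂`, conditioned on the
number of *extant* species, randomly pruned to the number of *sampled*
species (simulate-then-prune rather than an analytic sampling fraction —
it reproduces the exact sampling protocol of the data), and the statistic
is recomputed on each; `p = (#{sim ≥ observed} + 1)/(n_sim + 1)`.
Calibration at the defaults (16/16 taxa, 200 inner simulations) gives an
empirical type-I error of ~4–5% at the nominal 5% level.

**Net diversification with unsampled species** uses the Magallón–Sanderson
crown method-of-moments estimator conditioned on clade survival, at a
user-supplied relative extinction ε (0 and 0.5 by convention). At ε = 0 it
reduces to `r̂ = (ln n − ln 2)/t`. The estimator decreases with ε (survival
conditioning inflates the expected diversity), and for small clades with
large ε it can go formally negative — it is then clamped at zero and
flagged. The inverse relation (survival-conditioned expected crown size at
`(r, ε, t)`) is exposed as `expected_crown_size` and round-trips with the
estimator to 1e−6. Per-tree estimates over a posterior sample of
chronograms are provided for clade-rate comparisons; trees in which the
clade is not monophyletic are skipped and counted.

## 4. Tree shape and the shift test

Under the equal-rates Markov (ERM) null every extant lineage is equally
likely to split next; the probability that a clade of `n` splits into
unordered daughter diversities `{l, n−l}` is `2/(n−1)` (`1/(n−1)` for the
even split). Two imbalance summaries spanning the coarse/fine
depth-sensitivity axis are implemented: the Colless index (sum of
`|L − R|` over internal nodes; root-weighted) and Shao & Sokal's B1 (sum
of reciprocal maximum depths below non-root internal nodes; tip-weighted).
Both are branch-length-free; polytomies are rejected rather than resolved.
Significance is Monte-Carlo: ERM topologies are simulated by uniform random
pairwise joining (which induces the same topology distribution as the
forward ERM process), and `p` is the +1-corrected fraction at least as
asymmetric as observed (large Colless, small B1). Under the null the test
rejects at ~3–7% at the nominal 5% level.

The **per-branch shift statistic Δ1** asks whether a diversification-rate
shift along a focal internal branch explains the local diversity pattern
better than homogeneous ERM. The one-shift model multiplies the focal
clade's rate by ρ; the induced probability of the parent node's partition
is that of a "Yule race" between the focal lineage (rate ρ) and its sister
(rate 1), computed by dynamic programming over the embedded jump chain and
maximised over ρ on a log grid in [1/64, 64]. The branch statistic is the
*difference* of this shift gain at the branch's parent and the same gain at
the focal node's own basal split: a true shift makes the parent partition
extreme while leaving the focal clade internally typical, so the
subtraction localises the signal to the branch instead of letting every
ancestor of a shifted clade inherit it. Significance is Monte-Carlo
against the per-tree *maximum* Δ1 over the internal-branch class of ERM
topologies of the same size — deliberately conservative, because in
practice the tested branch is the one that looked extreme. Users should
expect modest power: ERM split sizes are uniform, so extreme partitions
are common by chance (an 11:1 basal split of a 12-clade has probability
2/11), and on 16-tip trees the branch with the true 10× shift carries the
tree-wide maximum Δ1 in roughly half the replicates — consistent with the
generally marginal behaviour of topology-only shift tests at these sizes.

## 5. The synthetic radiation generator

The generator produces ground-truth datasets — a dated tree plus
co-evolving quadrat ranges plus emitted localities — under controlled
speciation modes, so that every analysis stage can be validated without
any external data. Its defaults emulate the study system the package is
aimed at: 16 species, speciation rate 0.3/Myr (expected crown age
≈ 7.9 Myr), an island-shaped grid of 24 × 120 cells of 0.025°, an
ancestral range of 10 × 20 contiguous quadrats (≈ 1450 km²), and 1–6
emitted localities per species (uniform; mean 3.5, matching a collection
record of ~52 localities over 16 species).

Mechanics, per speciation event and per 0.1-Myr step between events:

* The tree grows as a Yule process (exponential waits, splitting lineage
  chosen proportionally to per-lineage rate). An optional rate shift
  `(f, m)` multiplies one lineage's rate by `m` when the lineage count
  reaches `max(2, round(1/f))`, so the shifted clade's neutral expected
  tip share is ≈ f; the shifted clade is recorded in the ground truth.
* **Vicariant** events bisect the parent range by a random straight line
  through its centroid; cut angles are retried until each daughter holds
  ≥ 30% of the parent's quadrats (a barrier fragments a range into
  comparable blocks; without the balance constraint, corner-shaving
  produces one-quadrat daughters that their sister instantly re-nests).
  A one-quadrat parent cannot be bisected; the new species is founded
  peripatrically two quadrats away. **Sympatric** events copy the parent
  range to both daughters. A mixed mode draws vicariant with probability
  `p_vicariant` per event.
* A vicariant split leaves a **persistent barrier** — the cut, frozen as
  the two daughter cell sets at split time — that blocks range expansion
  across it for `barrier_duration` (default 3 Myr). This is the load-
  bearing piece of vicariance realism: barriers are physical and outlive
  the speciation event, which is why secondary sympatry accrues with time
  since divergence instead of appearing instantly between abutting
  daughters. The 3 Myr default reflects the emulated system's pattern
  (microendemic species younger than ~2 Myr show no mutual sympatry;
  older pairs do). `barrier_width` (default 0) optionally vacates a
  corridor along the cut.
* Between events each range adds every adjacent free quadrat with
  probability `expansion_rate·dt` (4-neighbour adjacency; "free" means
  not already its own — ranges of different species may overlap) and
  loses each boundary quadrat with probability `drift_rate·dt`, never
  dropping below one quadrat. The 0.1-Myr step is fine relative to
  ~10 Myr crown ages and keeps runs deterministic per seed.
* Localities are drawn uniformly with replacement from each terminal
  range and jittered uniformly within their quadrat.

With the reference parameters (vicariant mode, expansion 0.05/Myr), the
full chain — simulate, overlap matrix from the true ranges, ARC,
classification — recovers *allopatric-dominant* in ≥ 95% of seeded
replicates, and the sympatric + drift configuration recovers
*sympatric-dominant* in ≈ 100%; node mean overlap is non-decreasing in
node age in expectation, and the area–age slope is positive in ≥ 90% of
replicates.

**What the generator does not emulate.** Real collection data differ from
the emitted localities in one important way: with an 8 km range circle on
a 2.8 km grid, rasterisation inflates every range by a ~1.4-cell halo, so
*abutting* vicariant daughters acquire substantial apparent overlap
regardless of their age, while the true secondary-sympatry signal
(sub-cell interpenetration at 0.05 cells/Myr) is far below the halo scale.
Real allopatric sister species are typically separated farther than the
circle scale (different mountains), which is precisely why the circle
construction works on real data. Consequently, ARC run on ranges
rasterised from sparse simulated localities is frequently inconclusive;
passing the recovery tests on the true range maps demonstrates the
inference machinery, not the robustness of 8 km circles to abutting
ranges. The emitted dataset therefore includes the true range map
(`ranges.json`), which the pipeline accepts directly as its geography
input. The generator also ignores continuous-space movement,
environmental covariates, and extinction (pure-birth trees only, matching
the null machinery it feeds).

## 6. Numerical and interface conventions

* Ultrametricity is validated on construction with a relative tolerance of
  1e−6 on root-to-tip depths; the worst-deviating tip is named in the
  error. Node ages are depths below the maximum tip depth, tips clamped
  to age 0.
* Exact zero/complete overlap in the ARC indicator responses means within
  1e−12.
* AICc is reported as infinite when its small-sample denominator
  `n − k − 1` is non-positive (fewer than 6 tips for the 3-parameter
  model), rather than silently falling back to AIC.
* All pipeline randomness derives from a single run seed through named
  per-stage substreams (`SeedSequence((seed, crc32(stage)))`), so full
  runs are bit-reproducible and every output records its seed.
* Outgroup tips are pruned before every analysis; the induced subtree sums
  branch lengths across removed degree-2 nodes, preserving ultrametricity.
* Exit codes of the command-line tool: 0 success, 1 validation error,
  2 runtime failure.

## 7. Problem sizes used in the validation suite

The shipped tests and the acceptance script size their experiments to a
single CPU: 100–200 replicate radiations or Yule trees per recovery or
calibration claim, 200 inner simulations per null test within calibration
loops (1000 when a single test is run), 99–999 permutations for ARC
significance, and exhaustive enumeration where the space is small (120
label permutations of a 5-tip tree, all rank assignments for group sizes
≤ 8, merge-history enumeration of ERM splits to n = 8). These sizes give
Monte-Carlo standard errors comfortably inside the asserted margins.

## 8. Known limitations

* ARC assumes limited post-speciational range change and a single
  dominant mode; like its field use, the method frequently returns
  statistically non-significant permutation p-values on small trees —
  the classification reports the direction of evidence, the p-values its
  strength.
* The Δ1 shift test is topology-only and weakly powered at n ≤ 20 (see
  §4); branch-length-aware rate-shift detection is delegated to the
  yule-2-rate model.
* The birth-death grid refinement evaluates a bounded domain
  (`r ∈ λ̂·[e⁻⁴, e^{2.5}]`, `a ∈ [0, 0.99]`); estimates on that boundary
  indicate a likelihood ridge rather than an interior optimum.
* The Magallón–Sanderson estimator conditions on survival only; it is a
  method-of-moments point estimate, not a likelihood, and carries no
  uncertainty of its own (posterior-sample spread is provided instead).
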