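# Methods

This note documents the models, conventions and numerical choices behind
symbionet, in the order the pipeline applies them, followed by the
synthetic-data generator and known limitations.

## From records to matrices

The unit of evidence is one sporocarp collection with a putative host plant.
Host identifications in record databases are frequently genus-only, so all
analysis is at the **plant genus** level. Curation before aggregation:

* **EcM plant whitelist** — only plant genera known to form ectomycorrhizas
  are retained; records databases contain many incidental "host" labels.
* **Fungal EcM status** — records of fungal genera classified
  non-ectomycorrhizal are dropped. A curated exclusion list (*Chalciporus*,
  *Chloridium*, *Gyromitra*, *Lachnum*, *Leptodontidium*, *Leucopaxillus*,
  *Paurocotylis*, *Phialocephala*) is always applied on top of the
  user-supplied status table. Genera absent from the table are dropped with
  a warning by default; strict mode raises instead, because a curated list
  can never cover arbitrary (e.g. synthetic) names.
* **Nothofagaceae split** — the broad genus *Nothofagus* was split into four
  genera; records are re-assigned by species epithet (*menziesii* →
  *Lophozonia*; *solandri*, *fusca*, *truncata* → *Fuscospora*; *antarctica*,
  *nitida* stay *Nothofagus*), and records with no (or an unrecognized)
  species epithet are dropped, since the genus cannot be determined.
* **Fungal taxon keys** — species-level identifications are used where
  available; genus-only identifications are retained as their own taxon
  (`"Genus (genus-level)"`). A sensitivity flag excludes them.
* **Minimum sampling** — plant genera with fewer than `min_collections`
  (default 8) records in a region are excluded, after all fungal filtering
  (the order is a package choice; the alternative is not distinguishable
  from published descriptions of this kind of analysis). Fungal taxa left
  without observations are dropped with them.

Label orderings are lexicographic everywhere, so runs are byte-reproducible.
Fungal genus for lookups is the first whitespace-delimited token of the name.

## Exploration types and functional diversity

Exploration types are assigned at the fungal genus level (six closed
categories, canonical column order: contact, short, medium_smooth,
medium_fringe, medium_matt, long_distance), with optional species-keyed
overrides for known within-genus variation. Observations are summed by type
within each plant genus to give the functional matrix.

**Shannon diversity** uses the natural log. The **group-level H′** is the
arithmetic mean of per-genus H′ values. Rationale: a single group value and a
*t*-test across genera are only mutually consistent for per-genus values; the
pooled-count alternative (H′ of summed group columns) is exposed as
`pooled_group_shannon`. Group comparison uses **Welch's t** with
Welch–Satterthwaite degrees of freedom; zero-variance inputs never crash
(equal means → t=0, p=1; unequal means → flagged degenerate, p=0, with a
warning).

**Ordination** is PCA of row-proportion composition: rows are divided by
their totals, column-centred, and decomposed via the covariance (not
correlation) matrix — proportions share a scale, so correlation scaling would
only inflate rare types. Scores are therefore invariant to multiplying any
genus's counts by a constant.

**Dispersion test.** Each genus's proportion vector is measured against its
status-group centroid with the Mahalanobis metric of the pooled within-group
covariance. With 6 trait columns and typically ≤ 20 genera on a simplex, that
covariance is singular as a rule, so the Moore–Penrose pseudo-inverse is used
(never fatal). Group difference in mean distance is tested by one-way ANOVA
(F with its parametric p) and by label permutation. The permutation p
**recomputes the whole procedure** (centroids, pooled covariance, distances,
F) per shuffled labelling rather than permuting fixed distances; this is
slightly more expensive but exactly calibrated in finite samples, which the
calibration suite verifies. Permutation p-values use the add-one convention
(1 + #{perm ≥ obs})/(1 + n_perm) throughout the package. Groups of size 2
are accepted but degenerate for the F statistic (each member is equidistant
from a 2-point centroid, so within-group variance is 0); the result is then
F = 0 or ∞ rather than an error.

## Fixed-marginal null model

Count matrices are randomized preserving all row and column totals by
repeated 2×2 quantitative swaps: pick random rows i≠j, columns k≠l, pick one
of the two diagonal directions **uniformly at random**, and move one unit
around the submatrix if the decremented cells are positive, else leave the
state unchanged (still a step). The random direction keeps the proposal
symmetric, so the chain is reversible with a uniform stationary distribution
over the fixed-marginal state space; the test suite verifies exact marginal
conservation and irreducibility against a brute-force-enumerated state space.

Sampling defaults follow the common sequential convention: 99 burn-in steps
discarded, then every `thin`-th state recorded (thin=1 by default, 9999
samples for headline runs). Steps are counted as *attempted* swaps by
default; a *successful*-move counter and an independent-restart mode are
available. Sequential thin=1 samples are serially correlated with the
observed matrix (the chain starts there), which biases naive Monte Carlo
p-values on small matrices; for calibration-sensitive work use `thin` of
order the matrix size (the calibration suite uses thin=20 on ~10×6
matrices). For one-sided exceedances deep in the tail (the headline use) the
effect is negligible.

**Diversity-gap test.** The statistic is (mean native per-genus H′) − (mean
alien per-genus H′) on the genus × exploration-type matrix — the matrix whose
H′ is under test, so the randomization holds both each genus's sampling
effort and each type's overall abundance fixed. Reported alongside: the mean
null group H′ per status, which quantifies how much of a raw H′ gap is
small-sample bias (less-sampled genera have downward-biased H′ under the
null as well). Exceedance counts null gaps strictly below the observed gap;
ties count as non-exceeding (conservative).

## Network structure

**Weighted nestedness** (WNODF family), rescaled to [0, 1]: for every ordered
row pair with strictly decreasing row totals, the pair contributes the
percentage of columns in which the poorer row has a positive count strictly
smaller than the richer row's; likewise over column pairs; pairs with tied
totals contribute 0; the statistic averages all row and column pairs.
Published weighted-NODF implementations differ in detail — some additionally
require strictly decreasing fill (returning 0 on fully filled matrices) or
normalize by the poorer line's occupied cells; `nestedness_test` therefore
accepts any statistic callable. Significance: two-sided empirical p,
2·min(frac null ≤ obs, frac null ≥ obs) with add-one correction capped at 1,
against the fixed-marginal ensemble; *antinested* means observed below the
null interval with p < 1 − level.

**Unipartite projection.** For each fungus f and unordered genus pair (g, h)
hosting f, min(count(g,f), count(h,f)) is added to edge (g,h) — the smaller
count bounds the evidence that both populations share the symbiont — and each
host gains count(g,f) on its self-loop, so host-specific fungi contribute
structure instead of vanishing. Per-fungus link records are retained on the
graph for rendering; aggregate edges sum the per-fungus minima.

**Modularity** Q = Σ_c [w_in(c)/W − (s(c)/2W)²] with self-loops counting once
in the total weight W and in w_in, twice in node strength s — the convention
of mainstream graph libraries, so printed Q values are comparable (verified
against networkx on random graphs). Whether self-loops should enter module
detection is a genuine modelling choice: including them (default) honours the
projection's intent of retaining host-specific fungi and penalizes merging
heavy specialist nodes; `include_self_loops=False` reproduces the loop-free
convention.

**Louvain** module detection delegates the two-phase greedy heuristic to
networkx, restarted `n_restarts` times (default 100) with sub-seeds spawned
from the given seed; every candidate is re-scored with the package's own
modularity and the maximum-Q partition wins, ties (within 1e-12) breaking to
the lexicographically smallest canonical labelling. Module ids are
canonicalized by first appearance in node order. On graphs of ≤ 8 nodes the
restarted heuristic attains the brute-force maximum-Q partition in ≥ 95% of
random instances (acceptance suite).

**Host breadth**: per fungal taxon, the number of host genera; each
taxon–genus occurrence attributes the taxon's breadth to that genus's status
group (unweighted by counts), so shared fungi inform both groups.

## Synthetic data

The generator emulates what matters to the pipeline about citizen-science
sporocarp databases; it is not a simulation of fungal ecology.

Construction: native genera are grouped into planted modules (consecutive
pairs). Each module owns `fungi_per_native_module` private fungi, of which
`specialist_fraction` are single-host specialists and the rest occur on every
module member (these shared fungi are what makes modules recoverable from the
projected graph). A generalist pool of `n_generalist_fungi` occurs on each
alien with probability `generalist_on_alien_p` and on each native with
`generalist_on_native_p`; `cointroduction_fraction` of module fungi also
reach one random alien. Private fungi draw exploration types from
`type_distribution_native`, generalists from `type_distribution_alien`. Every
realized association receives a negative-binomial record count (mean
`mean_records_per_association`, dispersion `count_dispersion`; dispersion 1 =
geometric), zeros removing the association — the long-tailed
recording-effort model. Each synthetic fungal species gets its own fungal
genus so the genus-level exploration lookup is exact.

Preset parameter choices (frozen as the package's study conditions):

* **nz_like** — 8 natives in 4 planted pairs, 15 aliens, 100 module fungi
  (15% specialists), 30 generalists (alien occupancy 0.6, native 0.1),
  co-introduction 0.1, mean count 3, dispersion 1. Native type distribution
  (0.21, 0.21, 0.21, 0.21, 0.06, 0.10) has expected H′ ≈ 1.71 with
  medium-matt rarest; the alien distribution (0.44, 0.25, 0.15, 0.10, 0,
  0.06) has expected H′ ≈ 1.39 with medium-matt absent. Design note: with
  min-count edge weighting and geometric counts, a within-pair edge is at
  most ≈ 0.43× a genus's self-loop weight in expectation, while a k-module
  graph needs the ratio to exceed ≈ 1/(2k)·(2L+e)/e for pair recovery —
  4 planted pairs and 85% within-module sharing put the design safely on the
  recoverable side, which is why the preset uses 8 natives rather than a
  minimal 4.
* **uk_like** — 10 natives, 9 aliens, identical native/alien type
  distributions (expected H′ ≈ 1.35), overlapping host pools
  (co-introduction 0.6, generalist occupancy 0.5 on both statuses): group
  differences in functional composition vanish while modular native
  structure remains.
* **null** — 5 + 5 genera, no module fungi, one generalist pool at equal
  occupancy 0.5, identical uniform type distributions, geometric counts:
  no group structure of any kind, used for calibration. Geometric
  per-association counts make the uniform fixed-marginal law a close match
  to the generative law conditional on marginals, so randomization p-values
  are uniform by design rather than approximation.

Ground truth (planted modules, per-fungus types and realized host sets) is
emitted alongside the records (`ground_truth.json`), so tests never re-derive
it from pipeline output.

What the generator does **not** emulate: spatial or temporal structure,
observer bias toward conspicuous taxa, genus-only fungal identifications,
shared fungal genera across species, or record misidentification. Passing
recovery tests therefore shows the pipeline's statistics behave correctly on
data with known structure — not that real databases are free of biases the
generator omits.

## Problem sizes and defaults

Headline defaults (8-collection minimum; burn-in 99; 9999 null samples;
thin 1; 999 dispersion permutations; 100 Louvain restarts; 95% intervals) are
the package's standard settings for real analyses. The test suite uses
reduced sizes chosen to keep statistical power while remaining quick:
499-sample ensembles (thin 20) and 199 permutations across 200 seeds for
calibration; 200 random ≤ 8-node graphs against exhaustive (Bell-number)
partition enumeration for the Louvain check; 20 seeds for planted-structure
recovery; 10⁵ total chained swap steps for conservation plus a 10⁵-step
irreducibility run on the 3×3 all-marginals-2 state space.

## Limitations

* Region matching is exact string equality; no synonym or fuzzy name
  resolution beyond the Nothofagaceae rule.
* Weighted-nestedness values are convention-dependent (see above); compare
  absolute values across software with care. Antinestedness *direction*
  against a matched null is the robust output.
* The dispersion test defaults to group centroids without small-sample bias
  adjustment; spatial-median variants are not implemented.
* Groups with fewer than 2 genera cannot be tested (t-test returned as
  unavailable; dispersion test raises).
* Sequential null ensembles at thin=1 are serially correlated; see the null
  model section for when that matters.
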