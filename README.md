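# symbionet

Analysis of plant–fungal symbiont sharing from sporocarp (fruiting-body)
association records. Given observation records pairing ectomycorrhizal (EcM)
fungi with putative host plants — the kind of data national fungal-record
databases accumulate — the package quantifies two things per region:

1. **Functional diversity** of fungal hyphal exploration types (contact,
   short, medium-smooth, medium-fringe, medium-matt, long-distance) associated
   with native versus alien tree genera: per-genus Shannon diversity H′,
   Welch *t*-tests between groups, PCA ordination of functional composition,
   a Mahalanobis-distance homogeneity-of-dispersion test, and a fixed-marginal
   randomization test asking whether the observed native–alien H′ gap exceeds
   what sampling-effort marginals alone produce.
2. **Interaction-network structure**: weighted nestedness (WNODF family) of
   the bipartite plant × fungus count matrix against a fixed-marginal null
   ensemble; a unipartite plant–plant projection in which a shared fungus
   contributes the smaller of its two observation counts to an edge and every
   fungus contributes its full count to its hosts' self-loops (so
   host-specific fungi are retained); Louvain module detection with weighted
   modularity Q; and fungal host-breadth summaries per host-status group.

A synthetic-data generator with planted ground truth (modules, exploration
types, host pools) stands in for the record databases, so the whole pipeline
is testable offline.

Intended users: ecologists working with interaction networks or fungal trait
data, and anyone needing a tested reference implementation of quantitative
(count-preserving) null models, weighted nestedness, or modularity with
self-loops.

## The statistics in brief

* Shannon diversity (natural log): H′ = −Σᵢ pᵢ ln pᵢ over exploration types
  (functional H′) or fungal taxa (fungal H′) within a plant genus; group
  values are means of per-genus H′, compared by Welch's unequal-variance *t*.
* Fixed-marginal null model: repeated 2×2 quantitative swaps
  (a,b;c,d) → (a−1,b+1;c+1,d−1) preserve every row and column total; the
  symmetric proposal makes the chain's stationary law uniform on the set of
  count matrices with those marginals.
* Weighted nestedness ∈ [0,1]: for each ordered row pair with strictly
  decreasing totals, the fraction of columns where the poorer row holds a
  positive count strictly below the richer row's; likewise over columns;
  averaged over all pairs. *Antinested* = observed below the null interval.
* Modularity with self-loops: Q = Σ_c [w_in(c)/W − (s(c)/2W)²], a loop
  counting once in W and w_in but twice in its node's strength s, the
  convention mainstream graph libraries use.

## Worked example

Generate a synthetic region with planted structure and analyse it:

```bash
symbionet synth --preset nz_like --seed 7 --out demo/data
symbionet -v run --config demo/cfg.yaml
```

with `demo/cfg.yaml`:

```yaml
records_path: demo/data/records.csv
plant_status_path: demo/data/plant_status.csv
ecm_plants_path: demo/data/ecm_plants.csv
fungal_status_path: demo/data/fungal_status.csv
exploration_types_path: demo/data/exploration_types.csv
region: SYN
output_dir: demo/out
seed: 7
n_samples: 999
n_perm: 999
```

This run prints

```
records: 3236 observations of 391 fungal taxa on 23 plant genera
network: 5 modules, Q = 0.636; nestedness 0.008 (antinested)
```

and writes a report bundle (`manifest.json` with checksums, plus the tables
and JSON reports). Highlights of this seed's output:

* `diversity_summary.csv` — mean functional H′ 1.67 (native) vs 1.00 (alien);
  mean fungal H′ 3.91 vs 2.51. Natives carry richer, more even exploration-
  type mixes, as planted.
* `null_report.json` — observed H′ gap 0.667; marginal-preserving
  randomizations give mean group H′ 1.65 (native) and 1.09 (alien), so part
  of the raw gap is small-sample bias, but the observed gap exceeded all 999
  null gaps (exceedance 1.0, p = 0.001).
* `nestedness_report.json` — observed 0.00767 below the null interval
  [0.00771, 0.00781], p = 0.002: the planted specialist structure makes the
  network significantly antinested.
* `partition.csv` — 5 modules: the 4 planted native pairs plus one module
  holding every alien genus.

The same operations are available as library calls
(`symbionet.project_unipartite`, `symbionet.weighted_nestedness`,
`symbionet.louvain_partition`, `symbionet.diversity_gap_test`, ...) on
`InteractionMatrix` / `FunctionalMatrix` objects, and
`symbionet nestedness|modularity|diversity` work directly on a saved
interaction-matrix CSV.

## Input formats

Records CSV/TSV with header `region, plant_genus, fungal_name, fungal_rank
[, plant_species, source_id]`; lookup CSVs `plant_status.csv (region,
plant_genus, status)`, `ecm_plants.csv (plant_genus)`, `fungal_status.csv
(fungal_genus, status)`, `exploration_types.csv (fungal_genus [,
fungal_species], exploration_type)`. See `docs/methods.md` for the filtering
rules (EcM whitelist, non-EcM fungal exclusions, the Nothofagaceae split,
the 8-collection minimum) and every tunable parameter.
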