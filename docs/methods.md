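# Methods

This document specifies the model implemented by `pathscreen`, its
parameters and file formats, what the synthetic generator does and does not
emulate, the numerical conventions, and known limitations.

## 1. Inputs and formats

| Input | Format | Normalization |
|---|---|---|
| Interactome | TSV: `geneA geneB score` | symbols uppercased; duplicate unordered pairs collapse to the max score; self-loops rejected; scores must lie in (0, 1] |
| Drug targets | TSV: `drug_id drug_name target_gene` | drug ids must match `DB\d{5}`; targets deduplicated and sorted; drugs left with zero targets are dropped with a warning |
| Phenotypes | TSV: `label gene` | one row per annotation |
| Gene sets | GMT: `term_id description gene...` | duplicate term ids rejected; empty terms dropped |
| Screens | CSV: `drug,outcome` | repeated measurements of one drug collapse to the maximum outcome; binary screens must be {0, 1}; non-finite outcomes rejected |

Drug names normalize to ids by case-insensitive exact match; names absent
from the vocabulary (e.g. salt forms) return no match rather than an error.

## 2. Network prediction

For drug targets *T* ⊆ interactome genes, define for every gene *v* within
`max_depth` edges of a target

  score(v) = max over simple paths of ≤ `max_depth` edges from any t ∈ T to v
  of the product of edge evidence scores along the path,

with score(t) = 1 for targets. Implemented as a bounded depth-first search
over simple paths; exhaustive for the small depths used (1–3), and verified
in tests against brute-force enumeration of all simple paths.

**Threshold search.** Candidate cutoffs are the unique downstream scores.
For cutoff θ, let N(θ) be the downstream genes with score ≥ θ and μ(θ) their
mean score; the objective is |{v ∈ N(θ) : score(v) > μ(θ)}|. The selected θ*
maximizes the objective, with ties resolved toward the largest θ (sparsest
network). With no downstream candidates the network is targets-only with
θ* = 1. Note the objective is usually maximized at the smallest candidate —
by shifting the mean, removing low-scoring genes rarely increases the count
above the mean — so predicted networks tend to equal the full ≤ depth
reachable set. The search is retained because it is part of the method being
implemented and because it does bind on heterogeneous score distributions.

## 3. Phenotype association

Each drug network is tested against every phenotype gene set with a
one-sided Fisher exact test (enrichment direction) over the universe of all
interactome genes; the p-value is the hypergeometric upper tail
P(X ≥ a) with a = |network ∩ phenotype|. Associations are then filtered
twice:

1. **Randomized-network null.** For each target-set size, 100 (configurable)
   random target sets are drawn uniformly from the target-like gene pool
   (genes that are a target of at least one drug, when a drug–target map is
   available; otherwise all genes). Each random set is rebuilt into a network
   — including the threshold search — and re-associated. An observed
   association is retained only if its p-value beats (is strictly below) the
   per-phenotype median null p-value; phenotypes the null never produced
   count as p = 1. Null ensembles are cached per target-set size.
2. **Benjamini–Hochberg.** Retained rows are BH-adjusted and kept at
   adjusted p ≤ α (default 0.05). The BH implementation is a single shared
   function also used by gene-set enrichment.

## 4. Screen regression

The design matrix is drugs × genes binary network membership (columns:
sorted union of network genes). Outcomes are fit with ridge regression
(`alpha` = 1.0 by default) or L2-penalized logistic regression for binary
outcomes. With `split_fraction` < 1 a seeded shuffle holds out a test set
and reports holdout MSE/R², but the coefficients used downstream always come
from a refit on all rows (an exploratory, not predictive, fit). A
permutation null refits the full matrix after shuffling the outcome column
(shuffle *i* seeded with `seed + i`) and reports per-gene min/max/mean/median
null coefficients.

## 5. Selection, enrichment, consensus

Per screen, genes are selected by signed coefficient thresholds oriented by
the screen's favorable sign (negative coefficients are favorable only in the
in-silico-style screen), or by top-k / quantile rules. Selected lists are
enriched against the GMT library with the same Fisher + BH machinery, using
all interactome genes as background.

Consensus across screens:

- **Shared genes:** intersection of per-screen favorable (and unfavorable)
  selections; Venn region counts are reported.
- **Aggregate effect size:** mean of absolute per-screen coefficients,
  rounded half-to-even to 4 decimals. Only genes present in every screen's
  design matrix are aggregated; absence is treated as lack of evidence, not
  a zero.
- **Shared terms:** tiered as `all_significant` (adjusted p ≤ α in every
  screen), `two_plus_significant`, and `shared_regardless` (present in ≥ 2
  screens' tables). A term absent from a screen's table counts as
  non-significant there.

The reference consensus rows in `pathscreen.reference` reproduce under this
aggregate rule exactly for 27 of 28 rows; one row (CYP1A1) differs by one
unit in the fourth decimal (reported 0.0235, recomputed 0.0234 from an
unrounded mean of 0.0234333…), so comparisons allow 1e-4 on that row.

## 6. Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at a
scale where the full pipeline runs in seconds:

- **Interactome:** a Barabási–Albert preferential-attachment graph
  (default 500 genes, m = 2) giving the heavy-tailed degree distribution of
  protein networks, with edge evidence Beta(2, 2) rescaled into
  (`score_floor`, 1].
- **Planted effects:** the last `n_planted` gene indices are reserved as
  sentinel genes, each attached to the single highest-degree hub by one
  floor-score edge. The hub sits in nearly every network regardless, so its
  membership column is near-constant; a sentinel gene therefore enters a
  network essentially only when it is itself a target. Each sentinel is
  wired as a target of an independent Bernoulli(`planted_target_prevalence`,
  default 0.3) subset of drugs, making its membership column an independent
  Bernoulli draw — the regime in which a linear effect on membership is
  identifiable. (Organically wired planted genes produce membership columns
  that are near-duplicates of their hub neighbors' columns; ridge splits the
  effect across the duplicates and recovery fails structurally.)
- **Drugs:** default 200, each with Poisson(λ = 2, min 1) base targets drawn
  degree-proportionally (hub bias of real drug-target data), plus the
  sentinel wiring above.
- **Annotations:** one phenotype and one gene-set term per planted direction
  concentrate on the planted genes (default 40% / 80%); the rest are uniform
  draws.
- **Screens:** the default layout is three screens sharing one planted
  truth — `in_silico` (continuous, favorable sign −1), `zebrafish`
  (continuous, +1), `clinical` (odds-ratio, +1). The linear predictor is
  η(d) = Σ_g β_g·1[g ∈ network(d)] with |β_g| = `effect_size` (default 0.5)
  and sign set by direction and the screen's convention. Continuous screens
  return η + Normal(0, `noise_sd`); odds-ratio screens return
  exp(`or_scale`·(η + noise)) with `or_scale` = 0.1, giving ratios in the
  realistic 0.7–1.5 range; binary screens draw Bernoulli(logistic(η)).
- **Network radius:** the scenario default is `max_depth` = 1. On a
  500-gene graph a two-hop neighborhood of hub-biased targets spans roughly
  a quarter of all genes — unlike two hops on a 20,000-node interactome —
  so radius 1 restores the realistic regime of sparse networks (mean ≈ 32 of
  500 genes). Pipelines on file-based inputs default to `max_depth` = 2.
- **Selection bounds:** the scenario's nominal bound is `effect_size`/4 for
  linear screens (bracketing the ridge-shrunk planted coefficients) and
  `or_scale`·`effect_size`/2 for odds-ratio screens, where exponential
  convexity shrinks spurious coefficients as or_scale² but the planted slope
  only as or_scale.

All stages draw from independent seeded substreams, so a scenario is a pure
function of its seed: regenerated datasets and re-run pipelines are
byte-identical.

**What the generator does not emulate:** real gene symbols or pathway
structure; correlated measurement error between screens; dose dependence;
partial drug-name matching; missing or contradictory annotations; the size
of real interactomes (~20,000 genes) and libraries (hundreds of drugs with
curated targets); and non-additive (epistatic) effects of network
membership.

## 7. Numerical choices

- Fisher one-sided p-values via the hypergeometric survival function
  (`scipy.stats.hypergeom.sf(a−1, …)`), exact for the one-sided enrichment
  alternative; verified against direct combinatorial enumeration.
- BH adjustment via `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`), wrapped once in `pathscreen.stats.bh_adjust` so both analysis
  stages share one implementation; verified against a hand step-up rule.
- Ridge and logistic fits via scikit-learn; ridge verified against the
  closed form (XᵀX + αI)⁻¹Xᵀy to 1e-8.
- Consensus rounding uses `numpy.round` (half-to-even).
- Seeds feed `numpy.random.default_rng`; the generator uses
  `SeedSequence([seed, stage_id, substream])` so stages are independent and
  reproducible in isolation.

## 8. Limitations

- The empirical threshold search usually selects the smallest candidate
  cutoff (Section 2), so network sparsity is governed in practice by
  `max_depth` rather than by the cutoff.
- Ridge coefficients on binary membership columns are shrunk and split
  across correlated columns; coefficient magnitudes are comparable within a
  screen but are not effect sizes in outcome units.
- The permutation null shuffles outcomes only; it calibrates coefficient
  noise under the no-association hypothesis but not confounding through
  network size.
- Odds-ratio screens are fit on the ratio scale (not log), matching the
  convention of regressing reported odds ratios directly; the exponential
  introduces convexity artifacts that grow with `or_scale`.
- The randomized-network null conditions on target-set size only, not on
  target degree composition.
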