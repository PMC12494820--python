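# Methods

This note documents the models, parameter choices and numerical
conventions behind `tfsignals`, and what the synthetic benchmark does and
does not demonstrate.

## TF activity model

Activity is defined functionally: the influence a TF exerts on its
direct targets' expression, not the TF's own transcript level. The
estimator is rank-based and signed:

* Per-gene signature: expression z-scored across conditions (sample sd;
  zero-variance genes get an all-zero signature). Z-scoring removes
  per-gene baseline and scale so that only condition-relative deviation
  enters the enrichment.
* Normal scores: within each condition, gene signature values are ranked
  (average ranks on ties) and mapped to standard-normal quantiles
  `Φ⁻¹(r/(n+1))`. Consequently the statistic depends on the signature
  only through within-condition ranks and is invariant to any strictly
  monotone per-condition transform of the signature.
* Enrichment: `a(TF, c) = Σ_g s_g · ns(g, c) / √n`, summed over the
  TF's targets with nonzero regulation sign (`n` of them). Dual-mode
  edges (sign 0) are excluded — their direction is undefined; this is
  configurable at the network-reading level, where conflicting duplicate
  edges also collapse to sign 0. TFs need at least 3 signed targets
  present in the matrix to be scored. The statistic is a deliberately
  transparent member of the family of rank-based, signed, size-normalized
  regulon-enrichment scores (the family VIPER's aREA belongs to): exact
  to test, antisymmetric under global sign flips.

### Subnetwork subsampling

Raw scores are univariate per TF, so subsampling is made consequential
by *standardizing scores across subnetwork members within each
condition*: each of the 10 subnetworks holds the target TF plus 40
distinct randomly drawn other TFs (all others when fewer exist; draws
are independent per target TF and per subnetwork, without replacement
within a draw). The TF's activity in a condition is the median of its
standardized scores over the 10 subnetworks. This buffers instability
from uneven regulon sizes: a TF's score is always expressed relative to
a random background of other regulons. Standardization uses the sample
sd; a zero sd (degenerate) falls back to 1. With a single eligible TF
the standardization is skipped with a warning and raw scores are used.

### Knockout benchmark and TF filtering

Conditions whose metadata names a knocked-out gene that is a scored TF,
paired with a control condition, yield a direction check
(`activity(KO) < activity(control)` on the medians), a per-subnetwork
accuracy (fraction of subnetworks agreeing), and a rank percentile (rank
of the KO condition among all conditions, ascending, divided by the
condition count). `dynamic_chi2_threshold` scans midpoints between
consecutive metric values, forms the 2×2 (above/below × correct/
incorrect) table and minimizes the χ² p-value (no continuity
correction) over cutoffs where the above-cutoff group is enriched for
correct assignments, breaking ties toward the smaller cutoff so that
more TFs are retained; if no cutoff qualifies it returns −∞ (no
filtering). The reference cutoffs −0.752 (basal maximum activity) and
0.166 (activity range) from the original *E. coli* dataset ship as
documented constants only; they are dataset-derived and recomputed from
the data at hand. The default pipeline applies no TF-level activity
filter, because on the synthetic benchmark the knockout benchmark is
error-free and the χ² scan would have a single correctness class.

## Metabolomics preprocessing

Fixed order: technical-replicate averaging → total-ion-count (TIC)
normalization of each injection column to unit sum → coefficient-of-
variation filter → exact-mass annotation.

* CV filter: an ion is dropped *entirely* if sd/mean across biological
  replicates is ≥ 0.15 in any condition. The whole-profile granularity
  is a design choice: the downstream correlation needs complete
  40-condition profiles, and per-cell removal would create missing
  values the rank correlation would silently impute around. A zero mean
  with nonzero sd counts as failing. Retained values are means over
  biological replicates.
* Annotation: negative-ionization [M−H]⁻ is assumed, expected m/z =
  monoisotopic mass − 1.007276 Da (configurable adduct shift); ions
  match every reference compound within 0.001 Da. Compounds sharing a
  rounded (6-decimal) mass are indistinguishable and collapse into one
  matrix row carrying the full annotation set; a downstream distance for
  such a row is the minimum over its members, with the position taken
  from the arg-min compound — the most favorable consistent reading.
  Unmatched ions are dropped; when two ions map to the same annotation
  set the smaller mass error wins.

`max_fold_change` (max over min of per-condition means) summarizes the
dynamic range of each metabolite; a zero minimum is reported as an
infinite, flagged ratio.

## Bootstrap correlation, ROC threshold, stability

* Subsampling, not resampling: each of the 1000 samples draws 30 of the
  40 shared conditions *without replacement* — the scheme mutes
  single-condition outliers rather than reweighting them.
* Spearman's ρ is the Pearson correlation of average-ranked profiles;
  a constant profile within a subsample yields a missing value for that
  sample, excluded pairwise from the mean (no imputation of ranks).
* ROC: positives are known interactions of the requested effect
  (scores negated for the inactivating orientation); *all* other
  measured pairs are negatives, including known pairs of the opposite
  effect. FPR uses the strict `>` convention; the per-sample threshold
  is the smallest observed score value with FPR ≤ 0.1, and the reported
  threshold is the median over samples. The median ROC curve (median TPR
  on a 101-point FPR grid) is kept for reporting; deriving the threshold
  from per-sample thresholds rather than inverting the median curve
  keeps it a well-defined score cutoff.
* Stability: fraction of samples whose ρ *strictly exceeds* the
  threshold. The stability cutoff is chosen to maximize
  known-retained / all-retained over observed stability values, with
  retention defined as stability ≥ cutoff (so the pairs defining the
  maximizing value are kept), ties broken toward the larger cutoff.
* Per-sample correlations are retained as float32
  (samples × TFs × metabolites; ~190 MB at the 173 × 279 × 1000 design),
  so thresholding and stability are exact rather than re-simulated.

The default pipeline reports the activating orientation; the
inactivating branch is implemented throughout (score negation) but not
part of the default cascade, reflecting the weaker recoverability of
inhibitory interactions by negative correlation at low FPR.

## Metabolic distance

Undirected bipartite metabolite–reaction graph; compartment-stripped
base ids after dropping non-intracellular species (labels `c`,
`cytosol`, `cytoplasm` by default). Metabolites in more than 50
reactions and a configurable currency-cofactor list (ATP, ADP, AMP,
NAD(H), NADP(H), CoA, Pi, PPi, H₂O, H⁺, CO₂ by default — the canonical
currency set; fully overridable) are removed globally before any path
search. A reaction is regulated by a TF when its flattened gene set
intersects the TF's targets. Distances use Dijkstra with unit edge
weights (equivalently BFS — "consecutive reactions" implies unweighted
hops): a metabolite at bipartite edge-distance `d` from the nearest
regulated reaction lies on a path of `(d+1)/2` reactions and is reported
at distance `(d−1)/2`, making "direct substrate/product = 0" and "+1 per
linking reaction" consistent. Absent metabolites (removed, extracellular
or unannotated), TFs without enzymatic targets, and disconnected pairs
are at infinite distance. Direction is ignored for distance but honored
for classifying distance-0 metabolites: substrate of regulated reactions
only → upstream, product only → downstream, both → within; a reversible
regulated reaction contributes both roles. Positions are only defined at
distance 0; elsewhere the record says `unclassified`.

## Candidate cascade

Correlation strictly above the ROC threshold, stability ≥ cutoff
(boundary inclusive — the cutoff is itself an observed score value),
distance ≤ 0. Infinite distance excludes a pair outright, which
restricts the search to TFs with at least one regulated enzyme. The
summary reports known-signal recovery under both the any-candidate and
the top-candidate reading, since either convention is defensible.

## Synthetic benchmark

`GeneratorConfig` defaults define the study conditions: 30 TFs, 300
genes, 40 conditions (8 of them TF knockouts), 60 metabolites, regulons
of 8 signed targets (≥ 1 of each sign), 10 planted activating couplings
at strength 1, expression and metabolite noise sd 0.1, replicate
structure 2 biological × 2 technical with 2% log-normal scatter and
random per-injection scale factors (removed by TIC normalization), seed
7. One `numpy.random.SeedSequence` spawns independent child generators
for activities/knockouts, network, planted couplings, expression noise,
metabolome noise and replicate noise, so a bundle is byte-reproducible.

Generative choices worth noting:

* Activities are i.i.d. standard normal — the simplest null spanning a
  wide activity range; knockouts force the deleted TF's activity to its
  row minimum − 2, guaranteeing the expected benchmark direction at any
  scale.
* Regulons are drawn disjoint whenever `n_tfs × targets_per_tf ≤
  n_genes` (targets are shared only in the over-subscribed regime). With
  shared targets a gene's expression sums several activities, which is
  realistic but confounds per-TF recovery checks; the benchmark
  separates concerns by keeping regulons disjoint at the default sizes.
* Metabolite coupling uses an exponential link with noise in the
  exponent, `exp(strength · activity + ε)`: abundances stay strictly
  positive and Spearman is invariant to the link, so the choice cannot
  bias recovery; the zero-noise correlation is exactly ±1.
* The toy metabolic model realizes each planted pair's intended
  (distance, position) class with a private linear pathway (cycle of
  upstream/within/downstream at distance 0, plus distance-1 and -2
  chains), rides ATP/ADP on regulated reactions and adds a 51-reaction
  hub metabolite and one extracellular transport — so hub, cofactor and
  compartment filtering are all load-bearing for the planted distances
  to be recovered.

What the benchmark does *not* emulate: real gene/metabolite identifiers
or pathway structure, condition covariance (real conditions cluster),
regulon overlap at default sizes, isotope patterns or adduct diversity,
batch effects. Passing tests therefore demonstrate correctness of the
algorithms and the stated invariants, not field performance on real
data, where network incompleteness and correlated conditions will lower
recovery substantially.

## Problem sizes in tests and acceptance

The test suite and `scripts/acceptance.py` run the correlation stage
once at the full 173 TF × 279 metabolite × 40 condition design with
1000 bootstrap subsamples (~48k pairs, a few seconds vectorized), and
the full pipeline on the default 30 × 60 design. The brute-force
distance oracle covers 100 random models of up to 30 metabolites and 30
reactions; ROC correctness is checked against a tie-corrected
Mann–Whitney U on 100 random score/label sets.

## Known limitations

* The enrichment statistic is a transparent stand-in within the aREA
  family, not a reimplementation of VIPER's pleiotropy correction or
  interaction-confidence weighting.
* No multiple-testing control is applied (the cascade is threshold-
  based by design); promiscuous TFs with many enzymatic targets inflate
  their candidate counts, which the per-TF count column surfaces but
  does not correct.
* Isobaric annotation sets make a candidate's metabolite identity
  ambiguous; the distance uses the most favorable member.
* Hill-kinetics fitting, partial correlations and flux-weighted
  distances are out of scope.
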