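# Methods

This note documents the models and procedures implemented in `ppipred`,
the parameters that matter, and the design choices made where several
reasonable options existed.

## Problem setting

Given per-protein features (sequence and expression properties, coarse
GO process labels, localization), per-pair features (co-expression,
co-localization, chromosomal context, genetic interactions) and a small
curated set of known physical interactions, score every unordered
protein pair with a probability of physical interaction. Two design
constraints dominate everything else:

* **Label quality.** Interaction databases mix assay types of very
  different reliability. A pair enters the positive set only when
  supported by both a yeast two-hybrid (Y2H) record and a capture-type
  record (co-immunoprecipitation, affinity capture with or without mass
  spectrometry, complex reconstitution). Colocalization evidence is
  ignored. The two lines of evidence must come from the same species;
  donor-species pairs are then transferred through one-to-one orthologs
  only (bijective mapping — a gene with two counterparts in either
  direction disqualifies its pairs).
* **Degree bias.** Proteins with many known partners are not a random
  sample. If negatives are uniform random pairs, a classifier can score
  "hubness" instead of interaction. Negatives are therefore generated by
  shuffling the positive network while preserving every protein's degree
  exactly, and excluding every pair observed to interact at least once
  in any species.

## Degree-preserving sampler

`degree_preserving_shuffle` runs a double-edge-swap Markov chain:

1. *Mixing*: `swaps_per_edge × m` attempted swaps (default 10 per edge)
   starting from the input edge list; swaps that would create self-loops
   or multi-edges are rejected.
2. *Repair*: while any current edge lies in the exclusion set, swaps are
   drawn with one endpoint in the overlap and accepted only if the
   overlap does not grow. `100 × m` consecutive rejections (or a hard
   budget of `2000 × m` attempts) trigger a seeded restart.
3. *Valid mixing*: another `swaps_per_edge × m` attempted swaps
   restricted to exclusion-free states, so the chain does not stop at
   the first valid configuration it happens to reach.

Degrees are preserved *exactly* — the spec-level property tests verify
the full degree map on every output, and on graphs of ≤ 8 nodes the
sampler's support across 1000 seeds equals the exhaustively enumerated
feasible set. Uniformity over feasible graphs is approximate (finite
Markov chain), which is documented rather than claimed away. A
pre-check identifies provably rigid nodes (degree larger than the
number of non-excluded partners) and raises an infeasibility error
naming them; exhausting all restarts raises the same error without
names. Silent truncation is never an option because a degree violation
would reintroduce exactly the bias this sampler exists to remove.

## Pair encoding

An interaction is unordered, so the encoding must satisfy
`vector(A,B) == vector(B,A)` bit for bit. Each numeric or binary
per-protein feature `f` contributes the ordered pair
`(min(f_A,f_B), max(f_A,f_B))`; categorical features contribute a
same-level indicator plus a multiset one-hot (level counts in {0,1,2}).
An alternative that orders the two whole protein blocks by a
lexicographic comparison of their profiles is available as
`symmetric_mode="per_protein"`; the per-feature min/max form is the
default because it is symmetric by construction, feature by feature,
with no tie-break subtleties. Pair-level features are appended:
Pearson co-expression over shared non-missing conditions (≥ 3 required,
zero-variance profiles give MISSING), Jaccard co-localization,
same-strand and same-chromosome indicators, midpoint distance, and a
binary known-genetic-interaction flag.

Missing values propagate: any MISSING component marks the vector
incomplete, and only complete vectors are trained on or scored
(`filter_complete`). One deliberate exception: the primitive
`chromosomal_pair_features` returns MISSING distance for
cross-chromosome pairs (distance along a chromosome is undefined
across chromosomes), but the featurizer by default encodes that case
as the total genome span (`cross_chromosome_distance="max"`).
Different-chromosome is known topology, not an unknown measurement;
treating it as missingness would silently discard roughly two thirds
of all pairs under the strict completeness filter. The strict
behaviour remains available (`"missing"`).

## Learners and consensus

* **SVM**: RBF kernel on standardized features; `C ∈ {0.1, 1, 10, 100}`
  and `γ ∈ {0.1, 1, 10}/d` (d = vector length) tuned by 5-fold
  stratified grid search on accuracy; probabilities by the standard
  sigmoid (Platt) fit. These are conventional ranges for this family of
  problem; the tuning winner is recorded in the model metadata.
* **Random forest**: 500 trees, √d features per split, seeded.
* **Consensus**: a pair is called at threshold t only if *both*
  learners score ≥ t (the rule `score ≥ t`, not `>`, everywhere). The
  default genome-wide threshold is 0.87, the exploratory threshold 0.5;
  `calibrate_threshold` returns the smallest observed score grid value
  whose consensus set does not exceed a target interactome size.
* **Feature importance**: permutation importance — mean decrease in
  held-out accuracy over 20 permutations per feature on a 30% stratified
  holdout, ties broken by feature name. This is a plain-permutation
  approximation to conditional (party-style) importance; the two are
  known to broadly agree, and plain permutation keeps the implementation
  transparent.
* Training classes are balanced 1:1 by construction (the shuffle
  preserves edge count), so no reweighting is applied.

## Evaluation battery

Threshold metrics follow the defining formulas exactly: specificity
TN/(TN+FP), sensitivity TP/(TP+FN), accuracy (TP+TN)/total, FPR
FP/(FP+TN); undefined ratios are reported as MISSING rather than 0.
ROC curves sweep the distinct scores with tied blocks collapsed, so the
trapezoidal AUC equals the concordant-pair statistic
(#concordant + ½·#tied)/(P·N) — asserted to 1e−12 against a brute-force
oracle. **AUC50** is the area under the ROC drawn against the absolute
false-positive count, integrated from 0 to 50 false positives and
normalized by 50·P (with fewer than 50 negatives the cutoff shrinks to
N, flagged). Tie blocks are diagonal segments and the cutoff falls
inside a block by linear interpolation; a ranking exhausted before the
cutoff extends flat. Spearman rank correlation uses midranks with an
exact permutation p-value for n ≤ 8 and the t-approximation above
(9!–10! enumerations are not worth their cost; the approximation is
already accurate there). Wilcoxon rank-sum tests delegate to the
standard routine (exact for small groups, normal approximation with
continuity correction otherwise).

## Held-out-complex protocol

To measure reconstruction of an unseen complex: sample as many control
proteins as members, uniformly (seeded) from the universe minus the
members; purge every training pair touching any member or control;
re-draw degree-balanced negatives; train both learners; score all pairs
among members ∪ controls; report the full metric battery against the
all-within-complex truth and list predicted member–control pairs
separately. A leak check asserts that no training pair touches a test
protein. Profile similarity between subunits is Pearson correlation of
their score vectors over the network universe with the two members'
own columns removed.

## Synthetic data generator

The generator's defaults define the study conditions used by the tests
and the acceptance script: 300 proteins, 600 true interactions, 60
expression conditions, 1% missingness — large enough for stable AUC
estimates, small enough for minute-scale runs.

* **Network**: proteins are partitioned into functional modules (sizes
  4–15; the first `n_complexes` modules are exact-size cliques doubling
  as complex annotations). 70% of edges (`intra_module_edge_fraction`)
  fall within modules; the remainder follows the configured degree
  model — preferential attachment (default), uniform, or a heavy-tailed
  configuration model — always with exactly `n_edges` edges.
* **Expression**: condition programs are i.i.d. normal vectors; every
  protein loads on its module's program with `coexpr_effect` (default
  2.0) plus a weak idiosyncratic program (0.7) and unit noise. Two
  proteins in one module then correlate at about
  e²/(e² + b² + 1) ≈ 0.75, so interacting pairs (mostly intra-module)
  show a mean Pearson correlation ≈ 0.5 above non-edges at the
  defaults. An earlier per-edge variant (each edge adds its own program
  loading to both endpoints) was rejected because a hub's correlation
  with each partner decays like 1/degree — module structure is also the
  more faithful picture of co-expressed complexes.
* **Localization / GO**: each module has a home compartment and a home
  GO process term; members adopt them with `coloc_agreement` (0.7) and
  `shared_go_prob` (0.6) respectively, on top of random base terms and
  per-term base membership rates. Planting signal per module rather
  than per edge avoids saturating hub proteins — a saturated hub's
  annotations are shared with its degree-matched negative partners too,
  which would cancel the signal by construction.
* **Evidence**: each true edge is observed by Y2H and by a random
  capture assay with sensitivities 0.8 each; false single-assay records
  are drawn from non-edges at rate 0.05 per true edge per assay, plus
  colocalization noise records the filter must ignore. A donor species
  covers 70% of proteins (10% of mappings made deliberately non-unique)
  and re-reports covered edges with the same sensitivities, exercising
  interolog transfer end to end.
* **Nuisance features**: protein length, mass, isoelectric point, GC
  content, codon adaptation, intron count, mRNA half-life and level,
  Pol-II occupancy, ribosome density, hydropathy, aromaticity — drawn
  from log-normal/normal baselines carrying no pair signal.

What passing tests on this generator do **not** show: recovery of any
real organism's feature marginals or degree-distribution parameters,
robustness to systematic (non-uniform) missingness, or performance
under evidence biased toward well-studied proteins. The generator's
noise is independent across pairs; real assay errors are correlated by
bait and by study.

## Numerical and degenerate-input conventions

Scores are serialized with 10 significant digits (round-trip safe);
MISSING is an empty cell or `NA` on disk and NaN in memory. Pair keys
are lexicographic on case-sensitive identifiers; self-pairs are
rejected at construction and self-interaction records dropped with a
warning. Single-class inputs are errors for ROC/AUC and training;
constant vectors are errors for rank correlation and degree tests.
Empty edge sets shuffle to empty sets. All stochastic stages take
explicit integer seeds, and every CLI command writes a JSON manifest
(config snapshot, seeds, input digests, outputs, version, timestamp)
before its outputs are considered final.

## Problem sizes used in the checks

The repeated cross-validation checks use the default 300-protein study
(two folds, ten repeats, both learners; label-shuffle null with five
repeats); degree preservation is verified on 100 random graphs of
10–200 nodes plus exhaustive-support checks on ≤ 8-node instances;
score symmetry is asserted end-to-end on 1000 random pairs; metric
oracles run on 100 random instances. These sizes were chosen to give
stable estimates in minutes on a single CPU.

## Known limitations

* The sampler approximates uniformity over feasible degree-preserving
  graphs; sequential importance sampling would be needed for exact
  uniformity and is out of scope.
* Conditional feature importance is approximated by plain permutation
  importance; strongly collinear features share credit.
* The AUC50 normalization (area / (50·P)) is one of several published
  partial-AUC conventions; comparisons across tools should check the
  convention first.
* Real-data headline numbers (cross-validation accuracies around
  0.7–0.8 on curated interactomes) depend on the original feature
  compendium and database snapshot and are not reproduced here; the
  synthetic study verifies the machinery, not the biology.
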