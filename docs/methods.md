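# Methods

## The model

`pairdrs` scores the relationship between two drugs by how likely they are
to bind a common protein target, rather than by raw structural similarity.
The premise is the common-binding view of QSAR: drugs acting on the same
target tend to share activity even when their scaffolds differ, and plain
fingerprint similarity misses exactly those structurally unrelated
common-target pairs. The score is learned, not defined: target-sharing
drug pairs are classified against non-sharing pairs in a chemical feature
space, and the classifier's averaged vote becomes the score.

The pipeline:

1. **Descriptor representation.** Each drug is a row of numeric molecular
   descriptors (anything numeric the user supplies — constitutional and
   topological descriptors, fingerprint bits, etc., pooled into one
   matrix). Columns that contain any erroneous/missing cell, or whose
   modal value covers strictly more than 90% of drugs, are dropped.
   Surviving columns are z-scored (sample sd, ddof 1) and projected onto
   the smallest number *k* of principal components whose cumulative
   explained variance reaches 90%. Both the near-constant fraction and the
   variance target are parameters.
2. **Pair vectors.** An unordered pair (a, b) with component scores
   x_a, x_b ∈ R^k becomes the concatenation [M | E] with
   M_i = (x_ai + x_bi)/2 (basal chemistry) and E_i = (x_ai − x_bi)^2
   (per-component dissimilarity). The encoding is symmetric in the pair by
   construction, so every downstream score is too.
3. **Labels.** A pair is *positive* when the two drugs' known target sets
   intersect, *negative* when both sets are non-empty and disjoint, and
   *unknown* when either drug lacks annotation (unknown pairs are
   scoreable but never trained on).
4. **Inverse-density under-sampling.** Negatives outnumber positives by
   orders of magnitude. Balanced negative sets (each the size of the
   positive set) are drawn with per-pair weight proportional to
   1/f(s), where s is the pair's Tanimoto similarity (PubChem-style
   fingerprints in the original setting; any binary fingerprint here) and
   f the estimated density of s over all negative pairs. This
   over-samples structurally unusual pairs, keeping the negative sample
   diverse. Ten sets are drawn independently (overlap permitted).
5. **Ensemble.** One Random Forest per negative set, all sharing the same
   positives. The score of a pair is DRS = 2·p̄ − 1 ∈ [−1, 1], where p̄ is
   the positive-class vote fraction averaged over the forests; (DRS+1)/2
   recovers a [0, 1] similarity-like scale. Threshold 0 is vote parity.
6. **Validation.** Internal: out-of-bag votes of a *single* forest (each
   sample judged only by trees that never saw it). External: a drug-level
   holdout — 50 drugs are removed before training, and every pair touching
   one of them forms the test set.
7. **Target transfer.** A candidate target's score for a query drug is the
   maximum DRS between the query and any database drug binding that
   target; ties break by how many of the target's binders exceed a fixed
   threshold (default 0.5), then lexicographically. Evidence is split into
   shared-target rows (annotation transfer through a target already shared
   with the query) and new-prediction rows (evidence drugs sharing no
   target with the query).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `near_constant_frac` | 0.9 | drop columns whose mode covers > this fraction of drugs |
| `variance_target` | 0.9 | cumulative explained variance the PCA must reach |
| `standardize` | on | z-score descriptors before PCA (raw descriptor scales span orders of magnitude; disable only for pre-scaled input) |
| density method | histogram, 50 bins | density of negative-pair similarity on [0,1]; Gaussian KDE selectable |
| density floor | 1/(10·n) | added to every cell before normalization so empty similarity regions keep finite sampling weight |
| `n_sets` | 10 | negative sets / forests in the ensemble |
| `n_trees` | 500 | trees per forest (Breiman-style defaults; `max_features` = floor(sqrt(2k)), `min_leaf` = 1, bootstrap size = training size) |
| `n_holdout` | 50 | drugs held out for external validation |
| `tie_threshold` | 0.5 | vote threshold for the target-score tie-break frequency |
| ATC levels | 2 → 3 chars, 3 → 4 chars | prefix lengths of the WHO ATC hierarchy used for pharmacology matching |

Weighted sampling without replacement uses exponential sort keys
(Efraimidis–Spirakis), which is distributionally identical to sequential
draws with weight renormalization and O(n) per set; every draw is fully
determined by the seed.

PCA is computed by thin SVD of the standardized matrix with a
deterministic sign convention (the largest-magnitude element of every
loading column is positive), so fitted spaces are bit-reproducible across
runs and platforms. Components beyond the numerical rank are never
selected.

## The synthetic benchmark

`synthetic_data.generate` emulates the joint structure the method
assumes, with ground truth emitted alongside:

- Each of 20 targets has a centroid in 60-dimensional descriptor space.
  Targets are grouped in pairs that share a PFAM-like domain id; grouped
  centroids are correlated (drawn around a common group centroid with sd
  0.4, vs 1.0 between groups), so high-scoring *negative* pairs are
  enriched for domain-sharing targets — the signature the domain-matching
  analysis looks for.
- Each of 200 drugs binds 1 + Poisson(0.5) targets (mean 1.5, matching a
  sparsely annotated interaction database where most drugs have a single
  known target) and its descriptors scatter around the mean of its
  targets' centroids with sd 0.3.
- 10% of drugs are promiscuous: they additionally bind one unrelated
  target that leaves their chemistry untouched, planting the structurally
  dissimilar common-target pairs that motivate a learned score.
- Fingerprint bits are thresholded noisy random projections of the
  descriptors (projection noise sd 0.6, per-bit on-rates 15–45%), so
  Tanimoto similarity correlates with descriptor proximity without
  duplicating it.
- Each target carries one 7-character ATC code whose level-2 class (first
  three characters) is unique to its domain group; a drug inherits the
  codes of all its targets.
- Descriptor columns get heterogeneous lognormal scales, and the last two
  columns are near-constant probes that the cleaning stage must remove.

What the generator does *not* emulate: real chemistry (no SMILES, no
substructure semantics in the bits), the heavy-tailed degree distribution
of curated interaction databases, correlated descriptor blocks, or
annotation noise. Passing the synthetic study shows the machinery
recovers planted structure of the assumed form at realistic
signal-to-noise; it does not certify performance on curated drug data.

## Study sizes and numerical choices

The standard study preset trains ten forests of 200 trees on the 200-drug
benchmark with a 50-drug holdout — about 1,300 positive pairs per forest —
and scores all 19,900 pairs for the transfer analyses; the whole study
runs in well under a minute on one CPU. Forest size is a variance, not
bias, knob here: 200 trees already stabilize the averaged vote (two
disjoint half-ensembles correlate above 0.9 pair-wise).

Degenerate inputs are handled explicitly rather than silently: all-zero
fingerprints have Tanimoto 0 by convention (the 0/0 case), pairs never
out-of-bag are omitted from OOB validation with a logged count,
single-class score sets refuse to produce sensitivity/specificity, a
constant score vector yields an undefined (NaN) correlation, and
thresholds above every score report a missing ratio instead of 0.

Leave-one-drug-out target recovery masks the query's own interaction rows
(the query is removed from the evidence database), so a drug can only
recover its targets through *other* drugs binding them; recovery is
reported on the shared-target evidence table. Note that a query's true
targets can only ever accrue shared-target evidence — any database drug
binding a true target necessarily shares it with the query — which is why
the new-prediction table is evaluated for enrichment (domains, ATC)
rather than for recovery.

## Known limitations

- The descriptor pool is whatever the user supplies; no descriptor
  computation or curation beyond the cleaning rule.
- The score is relative to the training interaction map: unannotated true
  interactions depress it, which is precisely why high-scoring "negatives"
  are treated as predictions rather than errors.
- No probability calibration beyond the linear vote rescale; DRS values
  are comparable within one trained ensemble, not across ensembles.
- The optional SMILES path computes MACCS/Morgan/topological fingerprints
  via RDKit; fingerprint families from other toolkits are consumed only as
  precomputed tables.
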