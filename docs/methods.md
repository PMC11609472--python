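# Methods

## Models

All four classifiers grow binary CART trees. Classification nodes minimise
size-weighted Gini impurity; regression nodes (inside the boosters) minimise
the sum of squared deviations. Candidate split features are drawn without
replacement at every node — √p rounded up by default, configurable to all or
an integer — and the best candidate is taken by gain, with ties broken to the
lowest feature index and then the lowest threshold. Thresholds are midpoints
of adjacent sorted distinct values; a split must have strictly positive gain,
otherwise the node becomes a leaf. Trees stop at purity or below
`min_samples_split` (default 2); there is no depth cap, so bagged trees are
grown out fully in the usual random-forest style.

**Bagging (`rf`, `lavaset`).** Each of `n_trees` (default 150) trees is grown
on an independent subsample of ⌈0.8 n⌉ samples drawn *without* replacement
(`replace=True` switches to a classic bootstrap). Prediction is majority
vote; ties go to the first class in sorted label order. The proximity matrix
records the fraction of trees in which two samples share a leaf.

**Boosting (`gbdt`, `lavaboost`).** One-vs-all multinomial boosting: scores
F start at zero for all K classes; each round converts F to probabilities
through a max-shifted softmax, computes pseudo-residuals (one-hot − p), and
fits one regression tree per class to its residual column on all samples (no
row subsampling). Leaf values are replaced by the Newton-style update
γ = ((K−1)/K)·Σr / Σ|r|(1−|r|) (γ = 0 with a warning when the denominator
vanishes) and applied with shrinkage η (default 0.1, 130 rounds). Argmax
ties at prediction go to the first class, so a zero-round model predicts the
first class everywhere.

**Latent (LAVA) splits.** With a neighbourhood index, a candidate feature j
is replaced by the first principal-component score of the columns in its
neighbourhood, computed from the samples present at the node: columns are
centered (not variance-scaled — the decomposition is of the covariance, and
the features of one assay share a scale), the loading is the first right
singular vector with its sign fixed so the largest-magnitude element is
positive, and routing re-applies the stored center and loadings. Node-local
centering was chosen because the latent step runs before each split decision;
recomputing on the node sample keeps the score faithful to the samples being
split. A zero-variance neighbourhood degrades to a unit loading on the
anchor feature (and yields no valid split). Size-1 neighbourhoods take the
plain axis-aligned path — centering a single column shifts score and
threshold by the same constant, so the stored raw-column form is chosen to
make θ=0 latent models *bit-identical* to their plain counterparts, an
equivalence the tests assert at the serialized-tree level.

## The CLIFI metric

For class i at a split with left/right/parent counts L, R, P and root count
A (the class's count in that tree's training subsample), the two partial
G-test terms against an even split are M₁ = 2L ln(2L/P) and M₂ = 2R ln(2R/P);
zero-count children contribute 0, mirroring the usual positive-observed
restriction of the G statistic. The signed value is

    CLIFI = (M₁ + M₂) / (2 A ln 2) × sign(M₂ − M₁)

Design choices worth stating:

* **A is the root count of the tree**, not the parent count — the only
  normalisation under which a perfect root split scores exactly ±1 and
  deeper splits are discounted by the class share P/A they act on.
* **Counts, not proportions** enter the formula; by its scale invariance
  (multiplying L, R, P, A by any c > 0 leaves the value unchanged, asserted
  on a 10 000-tuple sweep) this is only a convention.
* **sign(0) = 0**: an exactly balanced split contributes exactly zero.
* Classes absent from a split (P = 0) score 0 and generate no record.
* **Latent attribution**: a latent split's value is distributed over its
  neighbourhood features with weights |loading|/Σ|loadings|, each
  contribution taking the sign of its loading (so a feature that enters the
  component negatively is reported with the opposite direction, keeping
  signs congruent with raw feature values). The absolute contributions sum
  to the split value. An unsigned mode (`signed_loadings=False` /
  `--unsigned-loadings`) keeps the split's sign for all neighbours; signed
  is the default.
* **Boosted models**: a regression tree's split counts are tallied per
  *error label* — residuals rounded to 10 decimals, each distinct value one
  label (the rounding guards float jitter; unrounded residuals are the
  natural grouping). Label-level CLIFI values are mixed into true-class
  values by the weights S_hi = (class-h samples with label i)/(class-h
  samples), computed per tree on its training sample, Σᵢ S_hi = 1.

Records are kept at split level (tree id, node id, feature, class, value) —
the finest unit consistent with the per-class distributions the metric is
meant to expose. Per-(feature, class) sums give aCLIFI; dividing by the
largest absolute entry gives naCLIFI (an all-zero table normalises to zeros
with a warning). Top-k selection keeps features strictly above the mean of
the same-signed aggregated values, ranked by magnitude, truncated to k.
Class-difference testing runs a Kruskal–Wallis omnibus per feature across
classes (BH-adjusted over features), then pairwise two-sided Mann–Whitney
tests for significant features (BH-adjusted jointly across pairs).

## Feature networks

Interaction tables are STRING-style rows (two identifiers, combined score;
scores above 1 are treated as the 0–1000 scale and divided by 1000), kept at
confidence ≥ 0.7 by default, deduplicated keeping the best copy. Features
are adjacent when they map to a shared gene or their genes interact;
distances are shortest-path hop counts over that adjacency graph (the
consistent completion of integer distance parameters), +∞ when unreachable.
Identifier matching is exact after whitespace trimming; unmapped features
degrade to self-only neighbourhoods. The neighbourhood of feature j at
threshold θ is every feature within θ hops, always including j; θ is a
required, explicit parameter for the latent models (θ = 0 reduces them to
their plain counterparts; small integers 1–2 are the sensible range for
protein-interaction graphs, and the choice materially changes which features
co-vary in splits, so no default is silently applied).

## Synthetic data

`iris_with_noise` appends three noise columns to the four Fisher Iris
measurements, sharing their pooled location/scale: Gaussian(pooled mean,
pooled sd); uniform over the pooled min–max; and an equal two-component
Gaussian mixture at ±1.5 pooled sd with component sd 0.5× pooled sd (the
separation makes the bimodality unambiguous while keeping the pooled
variance comparable). `permute_within_columns` shuffles each column
independently, preserving marginals while destroying feature–label and
feature–feature association. `synthetic_planted` draws iid Gaussian
features, builds correlated blocks through shared latent factors
(x = √ρ·g + √(1−ρ)·z, unit variance preserved), then adds per-class mean
shifts for the informative (feature, class) pairs; it returns the planted
sign table and a distance matrix linking block members at hop 1. The
package's standard planted conditions are 4 classes × 40 samples over 20
features, eight informative pairs at ±1.5 sd with alternating signs, and two
ρ = 0.7 triples each tying an informative feature to two null neighbours — a
desk-scale analogue of a multi-class panel with correlated feature blocks.
What these generators do *not* emulate: heavy-tailed or skewed expression
marginals, missingness and imputation artifacts, class imbalance at the
28-class scale, and batch structure; passing tests therefore demonstrate
correctness of the machinery and calibration of the metric, not performance
on real assay data.

## Evaluation protocol

`stratified_three_way_split` allocates each class across test (30 %),
validation (20 % of the remainder) and training by largest-remainder
rounding (leftover units go to the larger fractional part, ties favouring
the training set), so class frequencies stay balanced. Metrics are
accuracy and support-weighted precision/recall/F1 in percent, with macro F1
emitted alongside (weighted is primary; both appear in outputs so either
convention can be read off). The weighted metrics are computed from the
confusion matrix directly and are cross-checked against scikit-learn on
random confusion tables in the tests. `run_pipeline` repeats
fit-and-score over a seed list and writes per-seed metrics, mean ± sd
summaries, CLIFI tables and (for bagged models) the proximity matrix; the
proximity matrix is exported for external embedding (e.g. UMAP) rather than
embedded here.

## Determinism and numerics

Every stochastic step flows from explicit integer seeds through spawned
`numpy` seed sequences: per-tree generators are derived from the ensemble
seed by counter, so results are independent of execution order; boosted
trees use one spawned sequence per (round, class). Serialization is JSON
with full double round-trip. The G-test and CLIFI guard their domains
explicitly (zero expected counts, inconsistent child sums, zero ancestor
counts raise; degenerate leaves in the booster fall back to γ = 0).

## Calibration checks and their design

The no-signal checks fit 100 forests of 50 trees (a fresh noise draw or
permutation per seed) and (a) bound the pooled record mean per feature by
±0.02, (b) run the class-difference tests on per-seed mean CLIFI values per
(feature, class). The replicate unit matters: records within one model share
a single data draw, and any finite draw carries chance feature–label
correlations (|r| ≈ 0.08 at n = 150) that rank tests over thousands of
dependent split records will detect; per-seed means are independent
replicates, giving a calibrated null. Direction recovery fits 100-tree
forests on the standard planted conditions over 10 seeds and requires the
naCLIFI sign to match the planted sign for ≥ 95 % of informative pairs
(observed: 100 %).

## Known limitations

* Fully-grown boosted trees make the booster nearly as strong as the forest
  on small, well-separated benchmarks (both ~94 % on iris-with-noise): seven
  rounds of unpruned regression trees effectively memorise the training
  sample, so the benchmark does not separate the two families. Weak-learner
  depth caps are deliberately not exposed.
* CLIFI explains the *model's training-time decisions*, not held-out
  predictions; it is a model explainer, and per-model distributions inherit
  the chance structure of the training draw (see the calibration note).
* The boosted-model error-label reconciliation assumes labels are grouped
  within each tree's own training sample; cross-round or cross-class
  grouping is not supported.
* Latent attribution by |loading| with sign flip is one of two defensible
  conventions; the unsigned alternative is provided but the two disagree
  for neighbours entering the component negatively.
* No missing-value handling: matrices must be imputed upstream (a kNN
  imputer is the conventional choice for RPPA-style panels).
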