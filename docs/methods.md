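# Methods

## Feature space

A modeling sample is the concatenation of two blocks whose layout is
frozen in a `FeatureSchema`:

* **Expression block** — the cell line's normalized log-scale expression
  over an ordered gene panel (at production scale, a few hundred
  cancer-pathway genes; at desk scale, the synthetic panel). Duplicate
  probe rows for one gene symbol are collapsed by arithmetic mean before
  panel restriction.
* **Target block** — a binary fingerprint over an ordered target universe,
  1 wherever a drug of the sample hits a target. A *combination's*
  fingerprint is the element-wise OR of its members' fingerprints; the
  expression block is unchanged. This union encoding is what lets a model
  trained purely on monotherapy responses score arbitrary multi-drug
  combinations: encoding is idempotent and commutative over drug sets, so
  a sham combination (a drug with itself) is featurewise identical to the
  single drug.

Labels come from a monotherapy IC50 table. The regression label defaults
to the natural log of the IC50 in micromolar (`ln_uM`, the convention of
large drug-sensitivity releases); `log10_nM` and `raw` are available
because published IC50 scales are often ambiguous. The classification
label is 1 iff the raw IC50 falls at or below a configurable threshold
(default 10 nM — a strict potency cutoff; the unit is configurable since
desk-scale datasets are better served by micromolar thresholds).
Duplicate (drug, cell line) response rows are resolved by geometric mean,
IC50 being a log-scale quantity; non-positive or missing IC50 rows are
rejected and counted.

Standardization (zero mean, unit population SD per column) is fitted on
the training split only and applied to all columns, including the binary
target block — centering binary columns is a deliberate simplification
that keeps the transform uniform; constant columns are flagged and mapped
to exactly 0. Train/test splitting uses round-half-up on the training
count (201,405 samples at 80% give 161,124 / 40,281).

## Predictors

The network is a fully connected conic MLP: ReLU hidden layers (default
200 and 100 units), inverted dropout after each hidden layer (default
rate 0.5, active only during training), and a single output — linear for
regression under mean squared error, sigmoid for classification under
mean binary cross-entropy over the mini-batch. Default optimization:
Adam at 1e-5, batch 128, 200 epochs (regression); RMSprop at 1e-3, batch
32, 500 epochs (classification); plain SGD is available. Weights use
seeded Glorot-uniform initialization; all randomness (init, dropout
masks, batch order) flows through one `numpy` generator, so a fixed seed
reproduces the loss history bit for bit. There is no early stopping or
learning-rate schedule. Non-finite loss aborts with a diagnostic rather
than training through NaNs. The parameter count obeys
`Σ (w_i·w_{i+1} + w_{i+1})` over consecutive layer widths.

Baselines (KNN, random forest, SVM-RBF, gradient boosting) are
scikit-learn estimators behind the same predict contract, with defaults
set to the tuned reference settings (e.g. KNN regression: 6 neighbors,
uniform weights; RF regression: 200 trees, min leaf 50; SVM regression:
C 10, gamma 0.01; GBM regression: 500 trees, min split 1000, lr 0.01,
min leaf 60 — and the corresponding classification optima). Margin
classifiers without calibrated probabilities report logistic-squashed
decision values so every family yields scores in [0, 1].

`grid_search_cv` enumerates the full Cartesian product of the supplied
grids under k-fold CV with seeded-shuffle, contiguous-block folds;
regression minimizes mean validation MSE, classification maximizes mean
validation accuracy, and ties resolve to the first configuration in
product order. The shipped default grids hold five levels each for
epochs, batch size and the two hidden widths and three each for learning
rate and dropout — 5,625 configurations.

## Metrics

MSE, RMSE and R² are evaluated directly from their definitions (R²
against the mean-prediction baseline, so predicting the label mean scores
exactly 0). Sensitivity, specificity, accuracy and the Matthews
correlation coefficient come from the confusion table; any metric with a
zero denominator is reported as NaN plus an `undefined` flag, never as 0,
so aggregates cannot silently absorb it. ROC/AUC uses trapezoidal
integration over all score thresholds, which equals the rank statistic
(probability a random positive outscores a random negative, ties counted
half) — the equivalence is enforced in the tests against a brute-force
pairwise oracle. When predictions are a least-squares linear transform of
the truth, √R² equals |Pearson r|; this identity is also under test.

## Ranking

`enumerate_combinations` produces every drug subset with sizes in a
given range exactly once (a pool of 7 with sizes 2–7 gives 120; with
singletons appended, a 127-entry ranking universe). `rank_combinations`
scores all candidates for one cell line and sorts ascending by
pseudo-IC50 — rank 1 is the predicted most potent set. Ties (identical
scores, e.g. combinations with identical target unions) break by
canonical combination id, making the table a deterministic permutation of
its inputs regardless of input order. Scores are never converted back to
concentrations.

## Synergy lab

Median-effect fitting regresses `log10(fa/fu)` on `log10(D)` by least
squares; `m` is the slope and `Dm = 10^(−intercept/m)` the IC50. Fractions
affected are clipped to [0.005, 0.995] before the logit so plates with 0%
or 100% viability wells remain fittable; fits require at least three dose
points and a positive slope. Replicate wells are averaged per dose
*before* fitting; control wells (dose 0) set the viability normalization;
mixed dose units in one analysis are refused rather than converted
silently.

A fixed-ratio combination is fitted as one pseudo-agent on total dose and
decomposed by molar-ratio shares at the chosen effect level (default
fa = 0.5, configurable — reported combination indices depend on it). The
CI is the mutually-exclusive Chou–Talalay form without interaction term.
Category boundaries: strong synergy < 0.3 ≤ synergy < 0.9 ≤ additive
≤ 1.1 < antagonism. The ratio schemes for k = 2…5 drugs are the k+1
settings "all ones, then double each drug in turn" (2 drugs: 1:1, 2:1,
1:2; …; 5 drugs: six settings ending 1:1:1:1:2), labeled with Roman
numerals. `best_ic50` selects the minimum IC50 across a combination's
ratio settings (first label on ties); `relative_potency` reports the
reference-to-comparator percentage rounded to one decimal, and the fold
change.

## Synthetic world

The generator emulates the structure the pipeline consumes, with a known
ground truth:

* Genes and targets are assigned round-robin to `n_pathways` pathways
  (default 6). Each cell line activates each pathway independently
  (probability 0.5); genes of an active pathway gain +2.0 expression over
  a baseline of 5.0 with gene-level Gaussian noise (SD 0.5) — a strong,
  clean activity signal.
* Each pathway exposes one canonical druggable **hub target**. A drug
  modulates 1–3 pathways and hits exactly their hubs (optionally, with
  `secondary_target_prob`, extra idiosyncratic targets that carry no
  signal). This hub design makes pathway coverage a function of the
  observable fingerprint — the property that makes monotherapy-trained
  models informative about unseen combinations. Without it (targets drawn
  independently per drug), coverage is unidentifiable from monotherapy
  data and no model could rank combinations well.
* The true log-IC50 of a drug set in a cell line is
  `alpha − beta·A − gamma·max(0, C−1) + ε`, with C the distinct pathways
  covered by the union of targets, A the covered pathways active in that
  cell line, defaults alpha = 3.0 (ln µM), beta = 1.0, gamma = 0.5,
  ε ~ N(0, 0.1²). Synergy is therefore complementary pathway coverage;
  a sham combination has exactly the single drug's truth, and a drug
  adding a new active pathway strictly lowers it.
* Observed responses expose only monotherapy rows (IC50 = exp(truth +
  noise), µM); combination truths are retained separately for evaluation.
* Plates draw viability from the median-effect equation with
  `Dm = exp(true log-IC50)` and slope 1.5 over an 8-point two-fold
  dilution series bracketing Dm, with optional multiplicative noise and
  triplicate wells; member drugs are plated singly alongside so
  combination indices are computable.

The reference desk-scale configuration is 20 cell lines, 100 genes, 60
targets, 10 drugs, noise SD 0.1, seed 1 (200 monotherapy samples). For
worlds of this size the reference training setup is a small conic net —
hidden (32, 16), no dropout, Adam 1e-3, batch 32, 600 epochs — which
trains in about a second on one CPU; the full-scale defaults (200/100,
dropout 0.5) are kept as estimator defaults. Under these conditions a
network trained only on monotherapy recovers the true potency ordering of
all 2–4 drug combinations with pooled Spearman ≈ 0.85–0.95 (threshold
0.8 in the acceptance test).

What the world does **not** emulate: realistic transcriptomic covariance
(genes are conditionally independent given pathway activity), partial
target knowledge, pharmacokinetics, dose-schedule effects, and
off-pathway drug action. Passing tests therefore demonstrate that the
pipeline is correct and that ranking recovery works when the response is
governed by observable pathway coverage — not that real tumor responses
are this clean.

## Enrichment

Over-representation of a query gene set (typically a combination's
targets intersected with the panel) against a GMT collection uses the
one-sided hypergeometric tail over a fixed background universe, raw
p-value cutoff 0.01 by default; Benjamini–Hochberg adjustment is opt-in
because the headline analysis reports raw p-values. Query genes outside
the universe are dropped with a warning.

## Numerical choices and degenerate inputs

* Population (ddof 0) standard deviation in the standardizer; constant
  columns flagged, transformed to 0, restored to their mean on inverse.
* Round-half-up on the train-split size; remainder to test.
* Ranking and enrichment tables break score/p ties lexicographically for
  determinism.
* KNN refuses k larger than the training set; empty drug target sets
  contribute zero fingerprints with a warning; unknown drugs raise before
  any prediction.
* BCE probabilities are clipped at 1e-12 from both ends; training aborts
  on non-finite loss.
* All file formats are plain TSV/CSV/GMT/JSON; writers round-trip with
  their paired readers.

## Known limitations

* The union encoding cannot distinguish combinations whose target unions
  coincide — they receive identical scores by construction.
* Combination indices are reported at a single effect level per analysis;
  CompuSyn-style CI-vs-fa curves are not produced.
* Bliss/Loewe/HSA/ZIP reference models, isobolograms, and GPU training
  are out of scope.
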