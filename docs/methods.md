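# Methods

This note documents the models and procedures implemented in `cyclestate`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data experiments do and do not demonstrate.

## Classifier

**Architecture.** A fully connected network: dense input (one unit per
classifier gene) → 600 ReLU units → dropout → 200 ReLU units → dropout →
softmax over the state vocabulary (7 states by default).  The two dropout
layers (rate 0.5) sit between hidden layer 1 and 2 and between hidden layer 2
and the output, and are active only during training.  The funnel constraint
`hidden1 > hidden2 > n_classes` is enforced.  Weights are initialized
He-style: uniform on ±sqrt(6/fan_in), drawn from the seeded generator, so a
seed fully determines the model.

**Training.** Categorical cross-entropy minimized by minibatch SGD with
momentum.  The schedule is 5 consecutive rounds of 10 epochs; at the start of
each round the cells are randomly re-partitioned into 80% training / 20%
held-out, weights carry over across rounds, cells are reshuffled every epoch,
and held-out accuracy is recorded per epoch into `training_history`.  Because
the split is redrawn each round, later rounds' "held-out" cells were part of
earlier rounds' training data; the recorded accuracy is therefore an
optimization diagnostic, not an unbiased generalization estimate — the test
suite measures generalization on freshly generated cells.  No class weights
or rebalancing are used: per-state F1 already accounts for imbalance, and
rebalancing the training labels worsens performance.

Optimizer defaults: learning rate 0.01, momentum 0.9, batch size 32 —
conventional values for a small dense network, exposed in `ModelConfig`.
On Pearson-residual inputs (roughly unit variance) these converge in the
first round.  On log-CPM inputs the larger dynamic range makes lr 0.01 with
50% dropout unstable (training collapses to the uniform softmax); lr 0.005
is the recommended setting for that scale.

**Decision rule.** For each cell the state with the maximum softmax
likelihood is emitted if that likelihood is ≥ the threshold (default 0.5,
adjustable in [0, 1]); otherwise the cell is labeled "Unknown".  Ties are
broken by the first state in canonical vocabulary order (argmax's
first-occurrence rule) and logged.  Because the classified set at a higher
threshold is the subset of cells clearing the bar, rejection is exactly
monotone in the threshold.  `collapse_g0g1` merges Neural G0 / G1 / Late G1
into "G0/G1" and leaves all other labels (including "Unknown") untouched;
it is idempotent.

**Serialization.** A model archive is a single npz file whose `header` entry
is a JSON document (format tag, version, config, state vocabulary, feature
ids, marker sets, id maps, training history) alongside the six weight
arrays.  Loading verifies the format tag and version and round-trips
bit-for-bit.

## Normalization and feature alignment

Two normalizations are provided, both deterministic:

* **log-CPM**: `log(1 + 10,000 · x / cell_total)`, natural log.
* **Pearson residuals** (recommended): residuals of an offset
  negative-binomial model `mu_gc = gene_total_g · cell_total_c /
  grand_total`, `r = (x − mu) / sqrt(mu + mu²/θ)`, clipped to ±sqrt(n_cells).
  A single strongly regularized dispersion θ = 100 is used for all genes —
  the standard analytic formulation — rather than per-gene estimates, whose
  noise the regularization would mostly remove anyway.  All-zero genes map to
  all-zero rows.  A cell with zero total counts is an error naming the
  barcode.

Alignment projects a normalized genes × cells matrix onto the classifier's
ordered gene list: mouse genes are translated through a one-to-one ortholog
table and symbol↔Ensembl through a lookup (both supplied as `IdMaps`; genes
without an unambiguous translation are dropped with a logged count — symbols
are never upper-cased as a fallback because silent mis-mapping is worse than
a missing gene).  Classifier genes absent from the input are zero-filled and
their share reported as `missing_fraction`; a warning fires above 20%
missing, where error rates grow quickly.  Duplicate gene ids (in input files
or created by translation) are summed, preserving total counts.  Alignment
is idempotent and its output column count always equals the feature-space
size exactly.

## Synthetic data generator

The generator emulates the aspects of a UMI count matrix that the method
suite exercises.  Cells draw a state from `state_proportions` (uniform over
the 7-state vocabulary by default).  Each gene's count is negative-binomial
with common inverse-overdispersion θ (`var = mu + mu²/θ`); the mean is
`baseline_mean` except on the cell's own state's markers, where it is
`baseline_mean · 2^marker_log2fc`.  Marker sets are disjoint blocks of
`markers_per_state` genes per state.  Each observed count is then
independently zeroed with probability `dropout_rate`.  One seed drives state
assignment, counts, and dropout in that fixed order, so identical parameters
reproduce identical matrices.

Defaults — 600 genes, 15 markers per state at log2FC 2, baseline mean 1,
θ = 2, 20% dropout — give a realistic sparse overdispersed matrix whose
states are learnable from a few thousand cells without being trivially
separable in any single gene.  `generate_bulk_signature` emulates bulk
RNA-seq of a sorted state: gene-wise means of bootstrap-resampled cells of
that state times small lognormal noise (so values are on a per-cell-mean
scale, not a library-total scale).  `inject_ambiguity` redraws a fraction of
cells from a 50/50 mixture of their own and another state's mean profile
while keeping the original label — producing genuinely intermediate cells
that receive low winning likelihoods, the regime where threshold rejection
pays off.

What the generator deliberately does **not** model: gene–gene correlation
beyond state membership, batch effects, doublets, cell-size/depth variation,
or graded marker strength.  Passing tests therefore demonstrate correctness
and recoverability of planted structure under an NB + dropout noise model,
not performance on real tissue.

## Marker discovery, overlaps, and bulk-signature mapping

`find_state_markers` runs a one-vs-rest two-sided Wilcoxon rank-sum test per
gene per state (tie-corrected asymptotic p-values), Benjamini–Hochberg
adjusted across genes within each state, and keeps up-regulated genes with
`log2FC ≥ 0.25` and adjusted p ≤ 0.05 (both adjustable).  Fold change is
computed on de-logged means for log-CPM input (pseudo-count 1e-9); on other
scales (residuals may be negative) means are used directly with negatives
clipped at zero.  Genes constant across all cells are excluded outright.

`hypergeometric_overlap` is the upper-tail hypergeometric test
`P(X ≥ n_overlap)` on an explicit caller-supplied universe — the universe is
a required argument because overlap p-values are meaningless without one.

`correlate_signature` computes the Spearman correlation of each cell against
each bulk replicate on a shared filtered gene set (by default: top-2000
variance/mean-ranked single-cell genes present above a bulk abundance floor,
plus any caller-supplied genes such as the classifier list).
`call_signature_positive` calls a cell signature-positive only when it clears
the cutoff (default 0.1) in **every** replicate.

## Permutation feature importance

Baseline likelihoods are computed once; each feature column is permuted
across cells (one seeded permutation per repeat, `repeats` default 1),
likelihoods recomputed, and the mean change recorded per state.  Negative
deltas mark supporting features; `top_features` ranks ascending with
alphabetical tie-breaks.  When per-cell labels are supplied (default mode
when available), the mean for each state is taken over cells carrying that
label.  A constant column is exactly zero by construction.  Deltas for one
feature sum to ~0 across states because both likelihood matrices are
row-stochastic.

A practical note from the synthetic experiments: on this generator's planted
design, a residual-trained network distributes its reliance such that
permuting *another* state's markers perturbs a state's likelihood about as
much as that state's weakest own markers (permutation injects other-state
marker levels into focal cells, pulling them toward the other state).  A
log-CPM-trained network concentrates reliance on the focal state's own
markers, recovering 13–15 of 15 planted markers per state in the top-15.
Marker-importance analyses in the test and acceptance suites therefore use
the log-CPM pipeline; classification-accuracy analyses use the recommended
residual pipeline.

## Cell-cycle signal regression

`module_score` follows the standard binned-control scheme: genes are ranked
by average expression into 24 equal-occupancy bins; for each set gene, 100
control genes are drawn (seeded, set genes excluded) from its bin; the score
is mean(set) − mean(controls) per cell.  24 bins / 100 controls are the
published defaults of the method this mirrors and are exposed as parameters.

`regress_out` fits per-gene OLS on the chosen module scores (with intercept)
and returns residuals; it is an exact projection (idempotent to 1e-8) and
residuals are orthogonal to the covariates.  Identically-zero covariate
columns are dropped (logged) so an all-zero covariate set reduces to mean
centering; genuinely collinear covariates raise with a suggestion to drop
one.

Success is judged by `pc1_variance_explained` — the PC1 share of variance of
the cells × marker-genes submatrix — compared against `n_random` (default
1000) uniformly drawn same-size gene sets: `p = (1 + #{random ≥ observed}) /
(1 + n_random)` (the +1 prevents p = 0).  Removal is declared successful when
p becomes non-significant (> 0.05).  With the five cycling-state covariates
(Late G1, S, S/G2, G2/M, M/Early G1) on default synthetic data at 1,500
cells, the empirical p moves from the grid minimum (≈ 0.001) before
regression to non-significance after; across generator seeds the
post-regression p typically lands between ~0.02 and ~0.2, i.e. removal is
reliably large but its significance call is near the 0.05 boundary for some
draws — a property of regressing noisy score proxies rather than the state
labels themselves.

## Evaluation harness

* **F1** is one-vs-rest per state; "Unknown" predictions count as negative
  predictions; states absent from both labelings are reported as missing,
  not 0.
* **Error rate** is misclassified / classified with "Unknown" excluded from
  both numerator and denominator (an inclusive mode counting "Unknown" as
  error is available); undefined (NaN, with a warning) when nothing is
  classified.
* **AMI** uses the permutation-model expected-MI correction with
  arithmetic-mean normalization; cells whose *prediction* is "Unknown" are
  dropped first by default.
* **Cross-validation** is k independent repetitions of a stratified 80/20
  split (train on 80%, per-state F1 on 20%), seeded.
* **Calibration simulation**: to compare classifiers with different state
  counts, reference labels are drawn uniformly over `k_ref` states; at
  similarity s, exactly round(s·n) cells copy the reference label (through
  the fixed surjection `i → i mod k_pred` when vocabularies differ) and the
  rest draw uniformly from the predicted vocabulary; AMI is averaged over
  (default) 100 replicates.  The curve passes through (1.0, 1.0) exactly for
  matched vocabularies and ≈ 0 at similarity 0.  Only the curve's shape is
  consumed, so the particular mixing scheme matters little.
* **Threshold sweep**: thresholds 0.0–0.9 by 0.1; per threshold the percent
  of cells predicted and the AMI of the survivors vs the reference; AMI is
  not computed when ≤ 20 cells survive.  The baseline removes the same
  *number* of cells uniformly at random while keeping unthresholded labels —
  isolating whether the gain comes specifically from discarding
  low-likelihood cells.  An optional 90% subsample reproduces the
  variance-probe design.
* **Missing-gene sensitivity**: a seeded random subset of feature columns is
  zeroed for all cells (at the classifier-input scale, i.e. after
  normalization and alignment), 10 replicates per fraction; error rate and
  percent predicted are recorded per threshold.
* **Hidden-layer grid search**: trains one model per (hidden1, hidden2) pair
  — the default grid is all 18 funnel-valid pairs with hidden1 ∈ 200..700
  and hidden2 ∈ 100..400 at steps of 100 — and ranks by held-out macro F1,
  then mean AMI over optional external evaluation sets.

## Numerical and design choices

* Problem sizes in the test and acceptance suites (3,000 training cells,
  1,000–2,000 evaluation cells, 600 genes, hidden sizes 200/50 for the
  synthetic models) were chosen as the smallest sizes at which the planted
  structure is comfortably learnable and the statistical contrasts are well
  powered.
* The package ships no pre-trained weights: the canonical model is trained
  from data (real or synthetic) via the API or CLI, and everything needed to
  reproduce a model (config, seed, feature space) is stored in its archive.
* Empirical p-values use the +1 convention; BH adjustment never lowers a
  p-value; argmax ties and dropped genes are logged rather than silent.
* `simulate_ami_calibration`, `module_score`, `empirical_variance_test`,
  `threshold_sweep`, `missing_gene_sensitivity`, and `permutation_importance`
  are all deterministic given their seed arguments.

## Known limitations

* The classifier consumes normalized expression directly; no per-gene
  scaling or batch correction is applied.  Apply the classifier per dataset
  before any integration.
* The Unknown rejection is a raw softmax threshold; softmax confidence is
  not calibrated probability, so thresholds should be tuned per dataset
  (`threshold_sweep` supports this).
* Synthetic validation bounds what the tests show (see the generator section
  above); accuracy on real tissue depends on marker conservation across cell
  types, which the generator does not model.
* The mouse→human and symbol↔Ensembl translations require caller-supplied
  tables; no genome-wide mapping is bundled.
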