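# Methods

## The problem

5C measures relative contact frequencies between restriction fragments of a
genomic region. Each sample yields a symmetric n×n interaction-frequency
(IF) matrix (n ≈ 40 BglII fragments for the *HOXA* cluster design this
package models). The working hypothesis is that disease state — here,
whether a leukemia cell expresses an MLL-fusion protein, and which fusion
partner — leaves a reproducible signature in that matrix. `chromsig`
formalizes this as supervised classification: flatten each matrix into a
vector of IF values over the contact pairs measured in every sample, train
a kernel SVM, and evaluate with leave-one-out cross-validation (LOOCV).

## Data model

A `ContactMatrix` stores values plus an explicit measured mask; unmeasured
cells (failed primers/probes) are NaN, never zero, and are excluded from
all sums and means. Matrices are symmetrized on read: a cell unmeasured on
either side of the diagonal is unmeasured on both, and measured mirror
cells disagreeing by more than a relative 1e-6 are averaged with a logged
warning (array data are noisy and each contact is a single physical
quantity). Self-ligation cells (i = j) are excluded from the feature space
by default — 5C junctions join distinct fragments — which makes the
default feature count n(n−1)/2 = 780 at n = 40. The feature index is
row-major over the upper triangle, so it is deterministic given a panel.
Coordinates are 1-based inclusive internally; BED export is 0-based
half-open. Difference maps (class mean minus class mean) are the one place
a matrix may carry negatives and are marked `signed`.

Two missing-data policies exist: `intersect` (keep pairs measured in every
sample; the default) and `impute_row_mean` (keep pairs measured in ≥ 50% of
samples; missing cells receive the feature's mean over the samples where it
was measured, computed on training data only).

## Normalization

Raw array signal confounds true contact frequency with (a) a per-array
scale — how much DNA hybridized — and (b) per-primer efficiencies, which
attenuate a contact (i, j) by a product of two fragment-level factors.
The correction is multiplicative and two-stage:

1. **Primer efficiencies** by iterative proportional fitting: each round,
   fragment i's factor update is (mean of its measured cells)/(global
   measured mean), and every cell is divided by u_i·u_j. Iteration stops
   when all updates are within `tol` (default 1e-8) of 1, or at `max_iter`
   (default 200; non-convergence is flagged, not raised). Accumulated
   factors are renormalized to geometric mean 1. Arithmetic row means are
   used rather than geometric ones so zero cells do not require a
   pseudocount (one is available for sparse data but defaults to 0).
2. **Array scale**: the corrected matrix is scaled so its measured
   upper-triangle sum equals `target_total` (default 1e6 — IF units are
   relative, so any fixed constant serves).

Both stages are ratio-based, so the pipeline is exactly invariant to
rescaling its input; this is asserted to 1e-9 in the tests. On matrices of
the form e_i·e_j·T with T a fixed point of the balancing, the factors
recover e up to a global constant (verified to 1e-6 noise-free; log-log
Pearson r ≥ 0.95 under lognormal noise of σ = 0.2). Note the balancing
estimates efficiency relative to the matrix's own row structure: what is
guaranteed is that the corrected matrix has uniform row means, which is the
stated goal of the correction family. Re-normalizing an already-normalized
matrix changes factors by less than `tol`, i.e. cells by less than a small
multiple of `tol` in relative terms (values carry the arbitrary
target-total scale, so idempotence is meaningful only relatively).

No background subtraction and no distance-expected (observed/expected)
normalization are applied; the classifier consumes normalized IFs directly.

## Synthetic panels

The generator produces labelled panels with full ground truth. Its defaults
are the study conditions used throughout the tests:

* 40 fragments; expected IF decays with fragment distance as
  base_if·|i−j|^−α with α = 1 and base_if = 100 (strong near-diagonal
  signal, as in real contact maps); the diagonal is unmeasured.
* 30 samples: 10 MLL-AF9 + 10 MLL-ENL (fusion) and 10 wild-type; wild-type
  samples cycle through AML/ALL/embryonal-carcinoma annotations.
* Planted class signatures, fold-change 2.5: the fusion class gains
  contacts on seven pairs involving fragments 26–27; wild-type gains seven
  long-range pairs joining the 3' block (31–35) to the 5' end plus the
  neighbour pairs (14,15) and (32,33); the two subtypes additionally differ
  by disjoint six-pair sets spread across the whole region. This geography
  mirrors the biology the classifier is meant to detect (local gains near
  *HOXA11* in fusions; an open, long-range-contacting 3' end in wild-type;
  subtype differences distributed cluster-wide).
* Technical structure: per-fragment efficiencies e_i ~ lognormal(0, 0.2²),
  a per-array scale s ~ U(0.5, 2), and symmetric multiplicative lognormal
  measurement noise with σ = 0.3 (a fixture choice — realistic array noise
  is not derivable from first principles — exposed in the design).
  raw[i,j] = true[i,j]·e_i·e_j·s·exp(N(0, σ²)).

Multiplicative lognormal noise (rather than Poisson counts) matches
continuous array intensities and keeps the normalization's scale-invariance
property exercised. One root seed is split into independent per-sample
streams, so panels are bit-reproducible from (design, seed).

What the generator does **not** emulate: real inter-sample biological
heterogeneity (cell-line-specific conformations beyond the class signal),
unmeasurable primer pairs, spatial correlation of noise along the matrix,
and translocation breakpoints. Passing tests therefore demonstrate that the
pipeline recovers the signal it is designed for under controlled technical
noise — not that real panels are classifiable at any particular accuracy.

## Classifier

The SVM solves the standard soft-margin dual with the homogeneous
polynomial kernel K(x, y) = ⟨x, y⟩^p (an optional +1 offset gives the
inhomogeneous variant; the homogeneous form is the documented default).
Defaults p = 1 and C = 1 are deliberately plain and both config-exposed.
Features are standardized to zero mean/unit variance before the kernel,
with statistics learned from training data only (IF scales span orders of
magnitude across distance); this is toggleable.

Training is sequential minimal optimization: repeatedly pick a pair of dual
variables and solve the two-variable subproblem in closed form, clipping to
the box [0, C] along the equality constraint Σαy = 0. The working pair is
chosen by the maximal-violating-pair rule — the most extreme candidate
biases among coordinates free to move up and down — which yields a sound
stopping criterion: optimization ends when the largest KKT violation falls
below `kkt_tol` (default 1e-3). (Classical examine-all/second-choice
heuristics were tried first and converged too slowly near degenerate
optima; the violating-pair rule is the standard remedy and keeps every
update identical in form.) An update cap of `max_passes`·n guards runtime;
hitting it flags the model rather than raising. Every trained model is
checked for dual feasibility in the tests, and decision-value signs agree
with an independent quadratic-programming solution on random separable
problems. Multiclass tasks use one-vs-one voting; vote ties break by the
largest summed |decision value|, then label order, logged.

The decision tree splits greedily on maximal information gain with
thresholds at midpoints between sorted distinct values, stopping on pure
nodes or nodes smaller than 2·min_leaf. A node where no single split gains
information but classes remain mixed (the XOR configuration) triggers a
one-step lookahead: the zero-gain split whose children gain most is taken
if any does, otherwise the node becomes a majority leaf. Ties in majority
labels go to the alphabetically first label.

## Evaluation

LOOCV trains n models on n−1 samples each. The feature index, imputation
means and standardization are recomputed per fold from the training
samples, so no statistic of the held-out sample leaks into its predictor.
Folds whose training set degenerates to one class are recorded and skipped
with a warning. Accuracy is trace/total of the confusion matrix. MCC is
reported for binary tasks only, with the convention MCC = 0 when any
denominator factor is zero (an uninformative classifier scores like a
random one). Folds run in declaration order and the result is
order-independent.

## Discriminatory contacts

Per-contact scores combine three computations on the vectorized panel:

* class means, standard errors of the mean, and their difference;
* **information gain**: class-label entropy minus the weighted entropy over
  the bins of a Fayyad–Irani MDL discretization of the feature. Candidate
  cuts are midpoints between adjacent distinct sorted values; a cut is
  accepted only when its gain exceeds the MDL cost
  (log₂(N−1) + log₂(3^k−2) − [k·H(S) − k₁·H(S₁) − k₂·H(S₂)])/N, applied
  recursively. Zero accepted cuts ⇒ 0 bits, so the score is conservative
  for small n. Gain is invariant under strictly monotone transforms of the
  feature;
* a per-feature two-sided two-sample **t-test**. Welch (unequal variances)
  is the default because that is what a plain `t.test` call computes; a
  pooled-variance toggle covers the textbook Student variant. No
  multiple-testing correction is applied in the default analysis —
  per-contact P values are used as a filter, not as inference — and a
  Benjamini–Hochberg option exists, off by default, clearly a deviation.
  Features with zero variance in both classes get P = 1 at equal means and
  P = 0 (with a warning) otherwise.

An "informative" contact passes the t-test filter **and** has positive
gain; both criteria are also reported separately so either reading of the
intersection can be audited. Rows sort by descending gain, ties by (i, j).

## Experiments and study-scale choices

* **Type experiment**: LOOCV of fusion vs wild-type on the default panel.
* **Subtype experiment**: LOOCV of AF9 vs ENL on the 20 fusion samples;
  with more than two subtypes the one-vs-one machinery engages.
* **De novo**: one model trained on the full training panel classifies an
  independently simulated 12-sample panel (2 AF9, 2 ENL, 1 each AF4, AF6,
  AFX, 5 wild-type — fusion partners unseen during training map onto the
  fusion class through the shared planted signature); test features are
  projected onto the training feature index, with training-mean imputation
  for cells the test sample lacks.
* The t-test calibration uses 200 replicate null panels (no planted
  effects, otherwise default design) and checks the P < 0.01 pass fraction
  against 0.01 within three empirical Monte-Carlo standard errors; panel
  replicates are the unit of error because contacts within a panel share
  technical factors and are not independent tests.
* The shuffled-label control permutes MLL-status labels and re-runs the
  full LOOCV; mean accuracy over the shuffles is compared with the binomial
  95% interval around the majority-class rate (2/3).

These problem sizes (30-sample panels, 780 features, tens to hundreds of
replicates) keep the full suite and the acceptance script to seconds or a
few minutes while leaving all Monte-Carlo checks adequately powered.

## Known limitations

* The primer-efficiency model is purely multiplicative and fragment-level;
  orientation-specific (FOR/REV) primer effects are carried in the data
  model but not used by the correction.
* The MDL discretization often accepts zero cuts below ~8 samples per
  class, making information gain a blunt instrument on very small panels
  (an optional median-split fallback exists, off by default).
* MCC is binary-only; multiclass runs report accuracy and the confusion
  matrix.
* Heatmap output is a reporting convenience (symmetric colour scale for
  difference maps), not a faithful reproduction of any published figure
  style.
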