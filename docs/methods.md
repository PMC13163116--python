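# Methods

This note documents the models and procedures the package implements, the
defaults and why they are set where they are, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## 1. Feature extraction

### Model

An RGB image is resized to 224×224 (bilinear) and each channel standardized
with the ImageNet statistics (mean 0.485/0.456/0.406, std 0.229/0.224/0.225;
grayscale inputs are promoted to three channels first). A convolutional
backbone f_θ maps the image to feature maps h ∈ R^{576×H′×W′}; global
average pooling collapses h to z ∈ R^576; a two-block head expands and
re-compresses the representation:

    z1 = ReLU(BN(W1 z + b1)),   W1 ∈ R^{1536×576},  dropout p = 0.3
    z2 = ReLU(BN(W2 z1 + b2)),  W2 ∈ R^{1024×1536}, dropout p = 0.3
    ŷ  = Softmax(W3 z2 + b3),   W3 ∈ R^{C×1024}

Layer order inside a block is Linear → BatchNorm → ReLU → Dropout: the
composition σ(BN(W·+b)) with dropout applied after the activation. The
1024-dimensional z2, taken in evaluation mode (running batch-norm
statistics, dropout off), is the exported feature vector, so repeated
extraction of the same images is bit-identical.

### Training

Only the head trains: exactly `epochs` passes (default 10) of minibatch
Adam (lr = 0.001, batch 32) on the softmax cross-entropy. The backbone is
frozen by construction — no gradient path exists to it — and a SHA-256
checksum of its parameters is compared before and after training as a hard
assertion. `epochs = 0` returns a randomly initialized head untouched.

The backbone itself is a three-stage strided conv+ReLU stack
(3→64→192→576 channels, ~32× spatial downsampling) with He-initialized
weights drawn from the configured seed. Random-weight features are
sufficient for the smoke-test property the suite checks (procedural
textures are separable above chance through a random projection);
task-adapted accuracy comes from the trained head. ImageNet-pretrained
weights are not bundled — `pretrained=True` raises — and a trained extractor
can be saved/loaded as a versioned checkpoint instead.

Head optimizer/loss/batch size are not separately configurable concepts:
the same Adam(0.001)/cross-entropy/batch-32 schedule used for the
neural-network classifier family is adopted for the head, for consistency.

Forward, backward (including the batch-norm gradient) and Adam are
implemented in NumPy inside the package; batch-norm uses ε = 1e-5 and
momentum 0.1 for the running statistics.

### Bookkeeping

A per-image manifest (row index ↔ file path ↔ label) is written with every
extraction so label alignment survives any later shuffling. Class-to-index
mapping is alphabetical over subdirectory names; files sort within class.

## 2. Binary differential-evolution feature selection

### Objective

Candidate solutions are masks x ∈ {0,1}^d; k = |x| counts selected columns.
The default fitness is

    fitness(x) = error(X[:, x], y) + α · k/d

with α = 0.005. `error` is the misclassification proportion of an inner
classifier on a stratified 80/20 holdout at a fixed internal seed (a
stratified k-fold is available instead). An alternative convex blend
α·error + (1−α)·k/d exists behind `fitness_form="convex"`; it is not the
default because at α = 0.005 it weights the error term at 0.005 and the
sparsity term at 0.995, which drives the optimum to near-empty masks — the
additive-penalty form treats α as a per-fraction penalty on subset size,
which is the intended role of a small α.

The inner classifier defaults to multinomial logistic regression: a fast
linear classifier that handles multiclass problems natively. One-vs-rest
ridge regression and nearest-centroid are available alternatives
(`FitnessEvaluatorSpec.inner_classifier`), plus a deterministic error-table
evaluator for oracle and property tests. Ridge is not the default because
one-vs-rest regression systematically loses the middle classes of an
ordinal multiclass layout, reporting ~40% error on fixtures that are in
fact almost perfectly separable. Errors are cached by mask bits: DE
revisits masks constantly and the evaluator dominates runtime.

### Operators

Classic rand/1/bin with defaults Pop = 10, G_max = 200, F = 0.5, Cr = 0.7:

- **Mutation**: donors r1, r2, r3 drawn uniformly, mutually distinct and
  distinct from the target; v = x_r1 + F(x_r2 − x_r3), clipped into [0,1].
- **Crossover**: binomial; coordinate j takes the mutant value when
  rand ≤ Cr or j = jrand (one uniformly drawn forced index per trial);
  mutant-inherited coordinates binarize by the strict threshold
  value > 0.5 → 1 (exactly 0.5 maps to 0).
- **Selection**: greedy one-to-one, replace iff strictly better; ties keep
  the incumbent.
- **Repair**: an all-zero vector (initialization or trial) gets one
  uniformly random bit set — the wrapper error is undefined on zero
  columns and repair keeps the population size fixed.

The run executes exactly G_max generations; the per-generation history
records best fitness, best k, a population digest and per-feature selection
counts. Best-so-far fitness is non-increasing by construction and asserted
in tests on every run.

### Oracle, analytics, leakage policy

- `exhaustive_oracle` evaluates every non-empty mask with the identical
  fitness (shared cache) and returns the minimizer, breaking ties toward
  the lexicographically smallest bit vector; it refuses d > 15.
- `selection_frequency` pools the fraction of (population member ×
  generation) slots holding a 1, over one or more runs, including the
  initial population. Pooling over generations (rather than over repeated
  runs) is a definition choice; frequencies from multiple runs can be
  pooled by passing several states.
- `reduction_percentage(d, k) = 100(d−k)/d` rounded to 2 decimals.
- The pipeline's default runs selection on the training+validation portion
  only (leakage-safe); `--paper-faithful` reproduces the
  split-after-selection ordering in which the selector sees all rows. Both
  paths share all code except the row subset.

## 3. Classification and evaluation

### Split

The three-way stratified split is computed by controlled rounding: per
class, part sizes are the largest-remainder rounding of n·(0.65, 0.15,
0.20), with leftover units steered by the running global deficit so
per-part totals track the requested proportions across classes. This
guarantees an exact partition and per-class counts within ±1 sample of the
quotas — a property a chained two-stage split does not provide. Default
seed 42; the 80/10/10 protocol is just a different `SplitSpec`. Every class
must have ≥ 3 samples.

### Classifier families

Defaults are fixed, standard configurations (random_state 42 throughout):
medium NN 64/32 and wide NN 256/128 (ReLU, softmax, Adam lr = 0.001, batch
32, 10 epochs); SVMs with linear / degree-2 / degree-3 polynomial kernels,
C = 1.0, γ = scale, coef0 = 0, probability outputs enabled (the standard
score-calibration the ecosystem provides; calibration internals are out of
contract); bagged trees with 50 bootstrap estimators; gradient boosting
with 100 depth-3 learners, lr 0.1, Friedman MSE; AdaBoost on depth-1 stumps,
100 iterations, lr 0.5 (the implementation uses the SAMME boosting variant —
the current scikit-learn removed the SAMME.R option; the report's config
echo records this). Overrides are applied via `set_params` and echoed into
the report. Early stopping is not used anywhere.

### Metrics

All confusion-derived metrics come from one K×K count matrix (entry (i,j):
true class i predicted as j):

- accuracy = trace/n; misclassification = 1 − accuracy (identity asserted);
- per-class one-vs-rest precision, sensitivity, specificity, F1 (harmonic
  mean, 0 when precision = sensitivity = 0, with a warning);
- aggregate precision/recall/F1 are **macro** (unweighted) means of the
  per-class values — macro-mean F1, not the harmonic of macro precision and
  macro recall, matching the class-wise tables;
- balanced accuracy = macro sensitivity;
- Cohen's kappa = (p_o − p_e)/(1 − p_e), p_e from the confusion marginals;
- AUC: macro one-vs-rest over predicted class probabilities (or decision
  scores); reported absent when the model exposes neither — never
  fabricated;
- CI half-width: Wald 95% on test accuracy, 1.96·√(acc(1−acc)/n). This
  choice is documented rather than reverse-engineered: published interval
  half-widths in this problem's literature do not match any single standard
  formula;
- prediction time: wall-clock over the full test partition, recorded for
  speed-up tables but hardware-dependent and excluded from any assertion.

`compare_reports` pairs two report sets by family and emits accuracy
difference (after − before) and speed-up before/after as "N.NN×".

## 4. Synthetic data

`generate_features` draws an N×d matrix where columns outside the planted
set are standard Gaussians independent of class, and planted columns for
class k are Gaussian with mean δ·k (δ = `effect_size`, sd = `noise_sd`).
Class means on a line is the simplest layout consistent with
"discriminative features"; one seed drives all randomness.

Defaults (n_per_class = 100, effect δ = 3, noise sd = 1) give a clearly
separable but non-trivial problem. The two standard test fixtures are
d = 8 with 2 planted columns (2 classes) for exhaustive-oracle work, and
d = 32 with 4 planted columns at indices {0, 5, 9, 20} (5 classes,
mirroring the five-class histopathology setting) for recovery studies. The
five-class choice matters: with only 2 classes at δ = 3, two planted
columns already reach zero holdout error, so a sparsity-penalized selector
*correctly* stops at k = 2 and "recover ≥ 3 of 4" is not a meaningful
expectation. Note also that planted columns are redundant by construction
(identical mean structure), so the optimizer may legitimately keep only 3
of 4 at some seeds — the recovery study reports the count rather than
asserting all four.

`generate_images` writes class-per-subdirectory PNG trees of procedural
textures (stripe frequency, orientation and mean brightness step with the
class index, plus mild pixel noise). These are class-separable inputs for
extraction smoke tests — *not* histology simulants. No stain variation,
contrast-enhancement artifacts, or tissue morphology is modeled; passing
tests demonstrate the plumbing and the optimizer's behavior on planted
signal, not clinical performance.

## 5. Numerical and design choices

- Binarization threshold is strictly > 0.5 (0.5 → 0); selection ties keep
  the incumbent; donor indices exclude the target. All three are the
  literal readings of the algorithm's comparison operators.
- Oracle ties break to the lexicographically smallest bit vector so the
  oracle is a pure function of the error table.
- Fitness caching keys on the exact bit tuple.
- Text feature matrices carry 17 significant digits (round-trip well beyond
  10 significant digits); the Parquet twin round-trips bit-exactly.
- The CLI fans a single global seed out to stages by fixed offsets
  (simulate +0, extract +1, select +2); the split seed stays 42 unless
  overridden. Every run directory is timestamped and immutable, and its
  `run_log.json` embeds seeds, package version and a config digest
  sufficient to regenerate the artifact.
- Problem sizes in the test and acceptance studies (d = 8 oracle
  enumeration over 255 masks, d = 32 recovery with N = 500, reduced head
  geometries in extraction tests) are chosen so the full suite runs in
  seconds while still exercising every code path at the default optimizer
  configuration.

## 6. Known limitations

- The bundled backbone is random-weight; absolute feature quality on real
  histopathology requires loading trained backbone weights from a
  checkpoint. The package verifies mechanism, determinism and contracts,
  not clinical accuracy.
- DE is stochastic: equivalence with the exhaustive oracle is a
  high-probability regression property (≥ 8 of 10 fixed seeds on the d = 8
  fixture), not a guarantee; the bound DE ≥ oracle is exact.
- The wrapper fitness inherits the inner classifier's biases; a subset
  optimal for logistic regression need not be optimal for, say, boosted
  trees. The evaluator is pluggable for exactly this reason.
- Wall-clock speed-up numbers depend on hardware and library builds and
  are reported for orientation only.
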