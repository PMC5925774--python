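# Methods

## Dose–response model and synergy score

Single-agent activity is modelled by the 4-parameter Hill curve
`E(c) = E_inf + (E_0 − E_inf) · EC50^h / (EC50^h + c^h)` with `EC50 > 0`
(µM) and slope `h > 0`; responses are percent of untreated control and are
never clipped — values above 100 (growth stimulation) or below 0
(cytotoxicity) are legitimate data. Fitting averages replicates per dose,
then runs bounded least squares (`scipy.optimize.least_squares`, trust
region reflective) on `(E_0, E_inf, log EC50, h)` with `h ∈ [0.1, 10]` and
`EC50` within `[min dose / 100, max dose × 100]`. Initial values: asymptotes
from the extreme-dose responses, `EC50` at the geometric mean of the
nonzero doses, `h = 1`; two jittered restarts follow a failed start. A
readout with no dose response raises a degenerate-fit error that carries a
flat fallback curve (`E_0 = E_inf =` mean response), so screens containing
inactive agents can proceed deliberately rather than silently.

The Loewe reference at doses `(a, b)` is the response `E` solving
`a/A(E) + b/B(E) = 1`, with `A`, `B` the inverse Hill functions. The
equation is solved by bisection over the overlap of the two curves'
attainable response ranges, to an absolute tolerance of 1e-6 %-points
(far below assay noise) with a 200-iteration cap. When the combination
index never crosses 1 inside the overlap — one agent cannot reach the
other's effect level — the reference is clipped to the nearest attainable
boundary instead of erroring, because screens routinely contain one-sidedly
potent pairs. Flat (inactive) curves fall back to the highest-single-agent
response with a warning. Two zero doses return the mean baseline.

A measured 4×4 checkerboard is completed to a 5×5 surface: the zero-dose
row and column come from the fitted single-agent curves at the board's
doses, and the zero–zero corner is the mean of the two fitted baselines
(both should be ≈ 100; no other convention is obviously better). The
synergy score is the **sum** over the 16 nonzero-dose wells of
`(reference − observed)`, so positive = synergistic. Sum rather than mean
is the default because screen-scale Loewe scores spanning roughly −330 to
+180 %-points are only reachable by accumulation across wells; a per-well
mean is available via the `aggregation` flag. Replicates are averaged per
well before scoring. Only interior wells contribute: the zero-dose edges
are reproductions of the single-agent fits and carry no combination
information.

## Features

Drugs are featurized from SMILES after keeping the largest covalent
fragment (salt stripping); protonation-state standardization is not
performed — inputs are used as given, since protonation models are
tool-specific and orthogonal to the method. Three blocks are produced,
each column tagged `count`, `continuous` or `binary`:

- **ECFP counts** — hashed circular-environment counts at radius 3
  (diameter 6), folded to 2048 columns by default (the folded width is a
  free parameter; variance filtering shrinks it further downstream).
- **Physico-chemical panel** — a fixed, documented list of 14 RDKit
  descriptors (molecular weight, Crippen logP and MR, TPSA, H-bond
  donors/acceptors, rotatable bonds, ring and aromatic-ring counts, heavy
  atoms, fraction Csp3, formal charge, heteroatoms, stereocenters). A
  descriptor failing on a molecule yields NaN, never a silent zero.
- **Toxicophore flags** — one binary flag per SMARTS pattern. The shipped
  default is a small set of 15 widely cited structural alerts
  (nitroaromatic, aromatic amine, azo, epoxide, Michael acceptor, …);
  any `name<TAB>pattern` file can replace it, and patterns are validated
  at load time, not per molecule.

Cell lines are described by a summarized gene-expression matrix consumed
as-is (genes × cell lines CSV/TSV); an optional mask file restricts it to
an informative-gene subset, standing in for upstream informative/
non-informative calls. No re-normalization happens at load time.

Columns with exactly zero variance over a reference (training) row set are
dropped; the retained-column mask is reusable on new entities so train and
test vectors always align. Kind tags survive filtering and concatenation
because the MinMax kernel needs them.

## Input normalization

Three column-wise strategies, all with statistics from training rows only:
`norm` (standardize), `norm_tanh` (standardize then tanh, bounding values
in (−1, 1)), and `norm_tanh_norm` (a second standardization using
statistics of the tanh-transformed training data). All feature blocks —
both drugs' chemistry and expression — are transformed jointly under one
strategy; nothing distinguishes blocks or column kinds here. Zero-variance
columns store a standard deviation of 1 so the transform stays defined
when a CV fold reintroduces a constant column.

## The synergy network

A feed-forward network maps `[drug A ‖ drug B ‖ cell line]` to one score:
two or three ReLU hidden layers (conic when widths halve, rectangular when
constant), a linear output, MSE loss, plain minibatch SGD (no momentum or
schedule), optional inverted dropout (input rate 0.2, hidden rate 0.5 when
enabled). Symmetry in the drug pair is handled by data: each training
sample appears in both drug orders, and prediction averages the two
orientations, which is exactly order-invariant by construction rather than
approximately learned. Early stopping tracks the moving average of
validation MSE over a 25-epoch window and restores the weights of the
epoch minimizing that average — selecting the epoch, not merely halting.
Weights use variance-scaled uniform initialization (`U[±sqrt(6/fan_in)]`)
drawn from the config seed; a fixed seed gives bit-identical training runs
single-threaded. A non-finite loss aborts with a diagnostic suggesting a
lower learning rate (very small rates, e.g. 1e-5, are typical for this
architecture at scale). The network is implemented directly in NumPy: the
models this package trains are deliberately CPU-sized, and owning the
training loop keeps the stopping rule, dropout and determinism exact.

Reference hyperparameter grid explored at full screen scale: hidden layouts
{8192², 4096², 2048², [8192, 4096], [4096, 2048], 4096³, 2048³,
[4096, 2048, 1024], [8192, 4096, 2048]}, learning rates 1e-2…1e-5, dropout
on/off, and the three normalizations; the best-performing configuration
there is conic [8192, 4096] with `norm_tanh_norm`-style tanh input
normalization, learning rate 1e-5 and dropout 0.2/0.5. Package defaults
are scaled-down analogues ([64, 32], 1e-3) appropriate to the synthetic
worlds it ships with.

## Baselines

**Median polish** — training medians per drug (either pair position) and
per cell line; a prediction is the mean of the two drug medians and the
cell-line median, with a global-median fallback for unseen entities. It
uses no features at all, which makes it the floor any feature-based model
must beat.

**Modified MinMax kernel** — for nonnegative vectors,
`K(x, z) = Σ_p min(x_p, z_p)/max(x_p, z_p)` over the features active in
either vector, divided by the number of such features; values lie in
[0, 1], `K(x, x) = 1` for nonzero `x`. Continuous columns are first split
into positive and negative parts (`f → max(f, 0), max(−f, 0)`) so counts,
binaries and signed continuous features can share one kernel. For two
all-zero vectors the default convention scores 1 (identical objects); the
alternative reading of the defining formula (denominator fallback 1,
giving 0) is selectable via `empty_support="zero"`. The kernel feeds a
ν-SVR with a precomputed Gram matrix; elastic net, random forests and
gradient boosting plug into the same learner interface through
scikit-learn — their internals are not re-implemented here.

## Cross-validation

Folds are built by quartet; symmetric doubling happens after splitting, so
the two orientations of one sample never straddle folds. Four schemes:
random; leave-combination (all samples of an unordered pair share a test
fold); leave-drug and leave-cell-line (entities partitioned into folds, a
fold's test set being every quartet touching a held-out entity and its
training set excluding all of them). Groups are shuffled with the seed and
assigned greedily to the least-loaded fold, balancing fold sizes by sample
count. In leave-drug a quartet can touch held-out drugs of two different
folds: it is tested in the fold of the lexicographically smaller drug
(deterministic, size-balancing), excluded from both folds' training sets,
and flagged `cross_fold` for audit.

Each outer fold carves a single inner validation split (~3:1, by the same
scheme) from its training pool — one validation set rather than a full
inner k-fold, which matches how a single validation set is typically used
for early stopping; the harness interface allows swapping this. Every grid
point trains on inner-train and is ranked by validation MSE; the best is
refitted on the full outer-training pool (the validation rows remain
available to learners that need early stopping) and applied exactly once
to the test fold.

Metrics: MSE, RMSE, Pearson r (undefined, reported as NaN, under zero
variance — never coerced to 0). Classification binarizes measured scores
at 30 synergy units (the top decile of a typical screen-scale Loewe score
distribution); ROC AUC and PR AUC (average precision) rank the continuous
predictions, and the thresholded panel (ACC, BACC, PREC, TPR, TNR,
Cohen's κ) uses a prediction cut chosen to maximize balanced accuracy on
validation data, searching midpoints of sorted unique predictions plus one
all-positive cut, ties toward the lower threshold. Paired method
comparison uses the Wilcoxon signed-rank test on per-sample squared
errors, dropping zero differences; all-tied inputs report an undefined
statistic. Per-fold reports carry mean ± sd summaries; per-drug and
per-cell-line Pearson correlations flag (rather than drop) groups with
fewer than 3 samples or zero variance.

## Synthetic worlds

The generator exists so every stage has a test surface with known ground
truth; it emulates structure, not any particular compound or cell line.

- **Design**: an exhaustive drug set combined all-vs-all plus a
  supplemental set combined only against the exhaustive drugs, crossed
  with a cell-line panel. At the reference full scale (22 + 16 drugs, 39
  cell lines) this yields 583 pairs — 83 % of all possible pairs — and
  22 737 quartets; tests default to a reduced 8-drug, 6-cell world.
- **World**: drugs carry latent mechanism classes driving sparse Poisson
  count features, Gaussian continuous features and Bernoulli binary
  features; cell lines carry pathway-activity vectors tracked linearly by
  an informative subset of genes (30 of 100 by default) over a noise
  floor. Ground-truth synergy is a symmetric, heavy-tailed (Laplace)
  class-pair interaction modulated by a tanh of the cell's pathway
  activity, affinely calibrated so the noiseless scores have median 4.37
  and, combined with Gaussian label noise (sd 5), a total sd of ≈ 23
  synergy units — a distribution concentrated near additivity with heavy
  tails, as large screens show. Same class pair + same cell line ⇒ same
  expected synergy, by construction.
- **Dose–response corpora**: one Hill curve per (drug, cell line) with
  `E_0 ≈ 100`, `E_inf ∈ [0, 40]`, `EC50` log-uniform over ~2.5 decades,
  `h ∈ [0.8, 2.5]`; single-agent tables use 8 log-spaced doses around each
  EC50 with 6 replicates, checkerboards the 4 central doses in
  quadruplicate — so board doses always lie inside the fitted range. Each
  board equals its Loewe reference minus a planted deviation whose
  16-well sum is specified per quartet; the default per-well pattern is a
  smooth mid-dose bump (exercising interpolation), with a uniform pattern
  available for exact linearity checks. Replicate-level Gaussian noise is
  added last. All generators are pure functions of their seed.

What passing tests on these worlds does **not** show: real chemistry–
mechanism relationships (features are class-driven, not physics), real
expression covariance structure, assay artefacts (edge effects, plate
drift), or performance at the full 10⁸-parameter scale. The synthetic
results demonstrate correctness of the machinery and the expected ordering
of methods (feature-based network ≫ median polish when pair-level
interactions exist), not screen-level benchmark numbers.

## Problem sizes and numerical choices

The shipped test and acceptance workloads use reduced sizes chosen so the
whole suite exercises every stage end-to-end on one CPU in well under a
minute each: 100-draw oracle comparisons for the Loewe solver, 200-quartet
recovery regressions at 2 % replicate noise, and a 12-drug × 8-cell world
(480 quartets, [64, 32] network, 150 epochs) for the cross-validated
network-vs-baseline comparison. Full-scale design arithmetic (583/22 737)
is exact enumeration and runs in milliseconds. Bisection tolerance 1e-6,
fit bounds and multi-start counts are stated above; ties in threshold
selection break toward the lower cut; fold-assignment ties break toward
the lower fold index.

## Known limitations

- The Loewe solver assumes both curves are monotone in the same direction;
  mixed stimulation/inhibition pairs are rejected rather than guessed at.
- The sum-aggregated score depends on the dose-grid placement; scores from
  screens with different ladders are comparable only qualitatively.
- The toxicophore default set is deliberately small; serious use should
  supply a curated SMARTS file.
- `leave_cell_line` needs no cross-fold handling (a quartet has one cell
  line), but `leave_drug` discards cross-fold quartets from two training
  pools, slightly shrinking effective training data relative to an ideal
  design.
- The NumPy training loop is single-threaded and CPU-bound; it is not
  intended for the full-scale [8192, 4096] architecture.
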