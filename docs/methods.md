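# Methods

## Genotype: chromosomes and folding indices

A chromosome is an ordered list of genes. Gene `i` carries a symbol from a
seven-entry vocabulary — scalar operators `Plus_s`, `Minus_s`, `Multi_s`;
vector operators `Plus_v`, `Minus_v`; operands `x`, `y` — and a folding
index `left.right`. `0.i` at position `i` marks a terminal; any other pair
makes the gene an internal node whose children sit at positions `left` and
`right`, both strictly greater than `i`. Forward references guarantee
acyclicity; a valid chromosome's folds form a binary tree spanning *all*
genes with gene 0 as root, so valid chromosomes always have an odd gene
count (`#leaves = #internal + 1`). The decoder nonetheless runs a full
reference-count and reachability check so invalid input is diagnosed (out
of range, backward reference, doubly referenced or unreachable gene,
scalar operator in a leaf) rather than looped on.

Two readings of the vocabulary's arity are possible: the published symbol
table lists arity 1 for the scalar operators, yet the published best
chromosomes give every internal gene exactly two children through its
`left.right` pair. The two-children reading is what the genotypes exhibit,
so decoding uses it; the arity value is kept as `Symbol.arity` metadata
only.

Terminal-acting vector operators: a `Minus_v` (or `Plus_v`) with a
self-fold is a legal leaf meaning direct application to the input pair
(`x − y`, `x + y`); both published chromosomes use terminal `Minus_v`
leaves. Scalar operators have no sensible direct form and are forbidden as
leaves; the validator rejects them and the variation operators never
produce them.

`encode` emits genes breadth-first from the root, which reproduces the
level-by-level layout of the published genotypes; `decode ∘ encode` and
`encode ∘ decode` are identities on valid input (property-tested, and
verified exhaustively against a brute-force recursive builder on all 291
valid structures of ≤ 7 genes).

## Phenotype: the kernel evaluation algebra

The source material never pins down the arithmetic of its operators, so the
algebra is a documented choice, isolated behind one interface:

* leaves: `x → x`, `y → y`, terminal `Plus_v → x + y`, terminal
  `Minus_v → x − y`;
* internal vector operators act elementwise (scalars broadcast);
* internal scalar operators act on scalar *reductions* of their children,
  where a vector `v` reduces to its component sum `Σᵢ vᵢ` — the simplest
  total rule consistent with the scalar/vector naming. An alternative
  squared-norm reduction (`v·v`) is available via `reduction="dot"` for
  sensitivity checks;
* a vector-valued root is reduced the same way.

The raw two-argument function need not be symmetric (a `Minus_v` leaf is
antisymmetric), but an SVM kernel must be, so the Gram matrix is
symmetrized: `K[i,j] = (k(xᵢ,zⱼ) + k(zⱼ,xᵢ))/2`; a square self-Gram is then
exactly symmetric in floating point. Non-finite entries (overflow in deep
`Multi_s` chains on unscaled data) are replaced by 0 and flagged; a flagged
Gram zeroes the chromosome's fitness instead of crashing the search. With
min-max-scaled inputs in `[0,1]` and the 50-gene cap, all evolved Grams
stay finite (property-tested).

Positive semidefiniteness is *diagnosed*, not enforced: `mercer_check`
reports the minimum eigenvalue of the symmetrized Gram, and optional
spectral clipping (negative eigenvalues zeroed) is available behind a flag.
Nothing in the search construction guarantees a Mercer kernel; in practice
libsvm converges on the indefinite Grams that arise at these problem sizes,
and the cross-validated accuracy is measured, not assumed.

## The genetic algorithm

Defaults: population 50, 20 generations, head budget 10, gene cap 50,
crossover rate 0.9, per-gene mutation rate 0.1, tournament size 2, 1 elite,
5-fold cross-validation, SVM cost C = 1. The gene cap and fold count follow
the published experiment setup; the remaining operators and rates are
deliberately minimal, standard GA choices, each isolated behind an
interface:

* **Initialization** — each individual draws a head length `h` uniformly
  from 1 to the head budget (for shape diversity in the initial
  population), fills positions `0..h−1` with random operators, then closes
  every dangling child slot breadth-first with random terminals (operands
  or terminal-acting vector operators), giving `2h + 1 ≤ cap` genes. The
  head is therefore operators-only, as required.
* **Fitness** — mean held-out accuracy (fraction) of a precomputed-kernel
  SVM over stratified k folds derived from the run seed; cached per
  (chromosome serialization, table fingerprint). Sanitized or constant
  Grams score 0. Ties break toward fewer genes, then earlier creation,
  favouring parsimonious kernels.
* **Selection** — tournament of size 2.
* **Crossover** — one-point splice of the two symbol strings at a common
  cut, then repair: the spliced string is re-closed breadth-first (an
  operator becomes internal while two unallocated positions remain), a
  scalar operator forced terminal is replaced by a random operand, and
  positions the closure never reaches are dropped. Offspring are valid by
  construction (property-tested on thousands of events).
* **Mutation** — per-gene symbol redraw from the category-compatible pool
  (internal: operators; leaf: operands + vector operators); tree shape is
  untouched, so validity is preserved.
* **Elitism** — the top individual is copied unchanged, making the
  per-generation best fitness non-decreasing.
* **Order** — selection → crossover → mutation → elitism, the conventional
  arrangement; the termination rule is a fixed generation count.

Per generation the history records best/median/mean/std fitness, diversity
(mean pairwise normalized Hamming distance over aligned symbol strings,
shorter chromosome padded, divided by the longer length) and the best
kernel's complexity (gene count). Both operands stay in the default pool
even though the published best kernels use only `x`-type leaves.

## Data pipeline

Feature tables are CSVs with one row per sample, numeric feature columns
and an `M`/`B` diagnosis column (`M` → +1, malignant; `B` → −1). The
prostate schema (Radius, Texture, Perimeter, Area, Smoothness, Compactness,
Symmetry, Fractal_dimension) and the 30-feature WDBC breast schema load
without special-casing. Preprocessing:

* **min-max standardization** to `[0,1]` per feature (constant features →
  0). By default it is fit on the full table before cross-validation,
  mirroring the original pipeline's dataset-level preprocessing;
  `apply_minmax` with stored parameters supports the leakage-safe
  per-training-fold alternative.
* **log transform** `v → ln(v+1)` (shift-by-one, total on non-negative
  data).
* **Z-score outlier removal** — one pass on the pre-filter table; a sample
  is dropped if `|z| > 3` (configurable) in *any* feature; constant
  columns contribute z = 0. On an n=100 × d=8 Gaussian table ≈ 2 values
  are expected past 3σ, so occasional removals on clean data are normal
  behaviour, not a defect.

Folds are stratified and seeded (scikit-learn `StratifiedKFold`).

## The synthetic fixture generator

The original tables (Kaggle prostate, 100 patients × 8 features; UCI WDBC,
569 × 30) are external and not redistributable, so tests and the
acceptance script run on generated stand-ins: two unit-variance Gaussian
classes in `d` dimensions whose means sit `separation` pooled standard
deviations apart along the diagonal, shifted to positive values to match
the morphology-measurement schema. Defaults n=200, d=8 sit in the
sample-size range of the study data; `separation=6` produces an
essentially linearly separable table (preset linear kernel ≥ 95% CV
accuracy), `separation=0` an uninformative null. What the generator does
*not* emulate: correlated features (real nucleus measurements such as
radius/perimeter/area are strongly collinear), heavy tails, class
imbalance beyond the `class_balance` knob, and measurement noise shared
across features. Passing tests therefore demonstrate that the search
recovers a competitive kernel when one exists and stays at chance on null
data — not that any particular accuracy will be reached on a specific
clinical dataset.

## SVM bridge and bagging

The quadratic program is delegated to scikit-learn's `SVC` with a
precomputed kernel; the contribution here is the kernel search, not the QP
solver. The fitted model stores the dual form (αᵢyᵢ over support vectors,
bias, support indices) and prediction recomputes `f(z)` from those stored
quantities — verified to match the solver's own decision function to
1e−8 — with `sign(0) → +1` fixed. The bagging ensemble is an
interpretation of the named bootstrap-aggregation approach: independent
seeded n-sample bootstraps (resampled until both classes present),
majority vote, default 11 members (odd, so no ties).

## Evaluation metrics

Accuracy is `(TP+TN)/total × 100%` with malignant = positive. MSE is taken
on ±1 class codes (not probabilities), so it equals 4 × error rate; a
single flip contributes 4/n. AUC uses the rank (Mann–Whitney) formulation
— ties counted ½ — which is exact under ties and invariant under strictly
monotone score transforms.

## Numerical choices and problem sizes

Acceptance-level checks run at deliberately modest sizes chosen as
realistic desk-scale experiments: n=200, d=8, population 20, 10
generations, 5 seeds for the statistical acceptance of kernel recovery
(majority of seeds must reach the linear-kernel baseline within 2 accuracy
points) and of the permutation null (best evolved fitness within
0.5 ± 0.1 — note the null band must absorb the GA's selection bias, since
maximizing over a few hundred chromosomes inflates the best CV accuracy on
noise a few points above 0.5). Exhaustive decoder verification covers all
291 valid fold structures of ≤ 7 genes, with the full symbol product at
small sizes and a deterministic symbol cycling at 7 genes, where the
complete cross product (≈ 8.7 million genotypes) adds no structural
coverage.

## Known limitations

* The evaluation algebra is one defensible reading of the operator
  vocabulary; a different algebra would evolve different kernels. It is
  swappable without touching the GA.
* Evolved kernels carry no Mercer guarantee; the SVM dual may be solved on
  an indefinite Gram.
* Dataset-level min-max scaling (the default, matching the original
  pipeline) leaks fold statistics; use the per-fold mode for unbiased
  error estimates.
* The search is single-objective and single-population; no adaptive rates,
  islands, or significance testing across models.
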