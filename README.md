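# genefold

Evolutionary search for SVM kernel functions ("Genetic Folding") applied to
binary biomedical classification — separating malignant (`M`) from benign
(`B`) samples in tabular morphology datasets such as prostate and breast
cancer feature tables.

## The idea

A support vector machine classifies with

```
f(z) = Σᵢ αᵢ yᵢ K(xᵢ, z) + b
```

and its power rests on the kernel `K`. Instead of picking a preset kernel
(linear `xᵢ·xⱼ`, polynomial `(xᵢ·xⱼ + 1)ᵖ`, RBF `exp(−γ‖xᵢ−xⱼ‖²)`), Genetic
Folding *evolves* one. The genotype is a linear chromosome of symbols — the
scalar operators `Plus_s`, `Minus_s`, `Multi_s`, the vector operators
`Plus_v`, `Minus_v`, and the operands `x`, `y` — where each gene carries a
*folding index* `left.right` naming the positions of its two children
(`0.i` at position `i` marks a terminal). Decoding the chromosome yields a
kernel expression tree; its Gram matrix feeds a precomputed-kernel SVM; the
mean stratified 5-fold cross-validated accuracy is the chromosome's
fitness; and a genetic algorithm (tournament selection, one-point crossover
with repair, category-preserving point mutation, elitism) searches kernel
space.

For example, the chromosome

```
symbols  ['Minus_s', 'Plus_s', 'y', 'y', 'x']
folds    ['1.2',     '3.4',   '0.2', '0.3', '0.4']
```

decodes to the kernel `Minus_s(Plus_s(y, x), y)`.

## Worked example

```
genefold evolve --synth 120 8 6.0 --population 10 --generations 3 --seed 2 \
    --out runs/demo -v
```

generates a synthetic two-Gaussian table (120 samples, 8 features, class
means 6 pooled standard deviations apart — a separable stand-in for the
external cancer tables), min-max standardizes it, and evolves a kernel.
Output:

```
gen   0  best=1.0000 median=0.5000 mean=0.4642 std=0.3546 diversity=0.845 complexity=17
gen   1  best=1.0000 median=0.5000 mean=0.4500 std=0.3500 diversity=0.826 complexity=17
gen   2  best=1.0000 median=0.5000 mean=0.6492 std=0.2279 diversity=0.721 complexity=17
best CV accuracy: 100.00%
best kernel (17 genes): Plus_s(Multi_s(Minus_v(Multi_s(Plus_v, Plus_v), Plus_v), Minus_s(y, Minus_v)), Plus_s(Multi_s(Plus_v, Plus_v), Minus_v(y, y)))
artifacts written to runs/demo
```

Per generation you see the best/median/mean/std of population fitness
(cross-validated accuracy as a fraction), the population diversity (mean
pairwise normalized Hamming distance over symbol strings, 0 = all
identical) and the gene count ("complexity") of the generation's best
kernel. The run directory holds the resolved configuration, the evolution
history as JSON and CSV, the best chromosome in the bracketed text dialect
above, and a metrics report (accuracy %, MSE on ±1 class codes, AUC,
confusion table).

On data of your own (a CSV with a `Diagnosis` column of `M`/`B`):

```
genefold evolve  --data patients.csv --seed 1 --out runs/patients
genefold evaluate runs/patients/best_chromosome.txt --data patients.csv
genefold compare --data patients.csv --seed 1 --out runs/cmp
```

`compare` writes one row per model — preset linear/polynomial/RBF SVMs and
the evolved kernel — under identical folds and preprocessing.

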