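# Methods

## Data model

A methylation experiment is a dense CpG-by-sample matrix of beta values
`x_ij ∈ [0, 1]` (fraction of methylated copies of CpG *i* in sample *j*),
with `NaN` for failed probes, and a per-sample class label in
{0 = control, 1 = hypertensive, 2 = pre-hypertensive}. Two binary tasks are
derived from the ternary labels: control vs patient (classes 1 and 2
collapsed; positive class = patient) and hypertensive vs pre-hypertensive
(controls dropped; positive class = hypertensive). The positive-class
convention is declared in every result because sensitivity/specificity and
PPV/NPV swap under the opposite choice.

Parsing follows the GEO series-matrix layout (CpG rows, sample columns,
header of sample ids); empty cells, `NA` and `NaN` are missing. Values
outside [0, 1] are rejected with the offending CpG and sample named — they
indicate a measurement artifact, not data to be clipped.

## Quality control and imputation

A sample is excluded when its fraction of missing CpGs strictly exceeds
the threshold (default 1%); a sample at exactly the threshold is retained.
The filter touches only the sample axis and is idempotent. Residual
missing cells are replaced by the CpG's mean over a caller-specified
reference sample set; inside every evaluation loop the reference is the
training samples of the current split, so held-out data never shapes the
fill values. A strict mode (`drop_missing_cpgs`) removes incomplete CpGs
instead, for callers who want no imputation at all. No normalization is
applied anywhere: inputs are raw beta values.

## Feature scoring and selection

The pre-filter scores each CpG by |Pearson r| against the 0/1 task label.
The absolute value is used because hypo- and hypermethylation are equally
informative and the sign of r depends only on the arbitrary class coding.
Zero-variance rows score 0 by convention. The three secondary metrics are
label-free dispersion summaries of each row: sample standard deviation
(m−1 denominator), interquartile range with linear-interpolation ("type
7") quantiles — the convention declared here because quantile definitions
differ across software — and the relative range (max−min)/(max+min),
defined as 0 for an all-zero row and bounded in [0, 1] for beta values.

Selection keeps the top `⌊n·f⌋` scorers. The floor is what makes the 1%
chain land on exact sizes (223,945 → 2,239 → 22); a floor of zero is an
error rather than an empty model. Ties at the cutoff break
lexicographically by CpG id so selection is a pure function of the scores.
Secondary filters operate on the pre-filtered pool, not the full array.

By default the whole chain is re-applied to the training samples of each
evaluation split (`selection_mode="train_only"`), so the reported test
metrics are free of selection leakage; `"all_samples"` applies the chain
once to the full dataset and evaluates the fixed set — the literal
protocol of correlating against the complete classification vector, kept
for comparison. At desk scale (5,000 CpGs, base pool of 50) the secondary
fraction must be raised above 1% (the examples and acceptance script use
20%) so that the floor count stays positive; at full array scale the
canonical 1%/1% chain applies unchanged.

## Classifier and evaluation protocol

The classifier is a single hidden layer of 50 logistic-sigmoid units
(scikit-learn's MLPClassifier). Training uses L-BFGS with a convergence
tolerance: gradient-based, fast on hundred-sample problems, and
deterministic given the seed — the weight initialization is the only
random element. Inputs are raw beta values (already in [0, 1]); no
rescaling. An optional mode picks the iteration budget from a small grid
by stratified k-fold cross-validation inside the training split (10 folds
by default); it is off by default because the tolerance criterion already
stops training and the extra fits are costly. Training matrices are made
C-contiguous before fitting: BLAS kernels differ by memory layout, and
L-BFGS would otherwise amplify stride-dependent rounding into different
final weights, breaking the reproducibility contract.

Evaluation is Monte-Carlo cross-validation: β independent class-stratified
75/25 splits (each class contributes ⌊n_class · 0.75⌋ training samples; 44
per class gives exactly 33/11), one network per split, metrics from the
held-out confusion matrix. β defaults to 100 in the split scheme; the
pipeline's desk-scale default is 25 repeats, and the test-bed runs use
15–50, enough to estimate a mean accuracy to a few percent. All five
ratios (accuracy, sensitivity, specificity, PPV, NPV) are computed exactly
from the α1..α4 counts; a zero denominator yields an explicit `None`,
never a silent zero. Per-repeat metric lists are always retained so that
distributions (boxplots, densities) can be drawn from the output TSV.

## Greedy elimination

The wrapper starts from an input CpG set and repeats: draw one CpG
uniformly at random (with replacement across iterations — a rejected CpG
may be redrawn), estimate the accuracy of the set without it, and accept
the removal under the configured rule. Two rules exist: `non_worse`
(accept when the candidate accuracy is ≥ the current one, the default) and
`strict_improve` (literal strict improvement). Non-worse is the default
because on a plateaued accuracy surface strict improvement accepts almost
nothing, while the method's purpose is to shed redundant features at
constant accuracy; strict mode remains available.

Candidate accuracy is the mean over `eval_repeats` fits. By default it is
measured on validation splits carved from the training portion of an outer
stratified split fixed once per run, so the outer test samples never
influence which CpGs survive; `evaluate_on="test"` scores candidates on
the outer test split instead. The evaluation seeds are held fixed across
candidates (common random numbers), so consecutive accuracy estimates
differ only through the feature sets and accept/reject decisions are not
dominated by split noise. Stopping: `qmax` iterations, a floor on the set
size, or the `a_min` rule — interpreted as a quality floor (stop once
accuracy falls below it) by default, with a "target" reading (stop once
reached) selectable, since either reading is defensible. The set size is
non-increasing by construction and the full trace (removed CpG, accuracy
before/after, decision, size) is recorded per iteration.

## Synthetic data generator

The generator emulates the study design the package targets: three
balanced groups (44/44/44), a CpG-by-sample beta matrix, sparse missing
cells, and a planted differential signal. Every cell is drawn from
Beta(μ·φ, (1−μ)·φ) — mean/precision parameterization, variance
μ(1−μ)/(φ+1) — so values are natively bounded. Null CpGs share one mean
per CpG across classes, drawn from a bimodal mixture (40% Beta(5,45) near
0.1, 40% Beta(45,5) near 0.9, 20% uniform on [0.2, 0.8]) mimicking the
two-humped distribution of array methylomes. Informative CpGs draw their
baseline from [0.15, 0.85] and shift by ±delta in the hypertensive class
and ±pre_fraction·delta in the pre-hypertensive class (random sign per
CpG, flipped if the shift would leave (0,1)), so the pre-hypertensive
group sits between control and hypertensive — the ordering the two tasks
rely on.

Defaults: 5,000 CpGs (desk scale; the full 223,945 is reachable by
setting `n_cpgs` or the CLI `--full-scale` flag), 200 informative,
delta = 0.15, pre_fraction = 0.5, precision = 30, missing rate 0.5%. The
missing rate sits below the 1% QC threshold so that QC typically excludes
nothing at desk scale while the imputation path still runs; delta = 0.15
with precision 30 gives per-CpG effects around 1.2 within-group standard
deviations — strong enough for the correlation filter to recover the
planted set reliably at n = 132, weak enough that global group means stay
visually indistinguishable.

What the generator does **not** model: probe-type chemistry, batch
effects, cell-type composition, age trends, and inter-CpG correlation
(cells are independent given their means). Passing tests therefore show
that the pipeline's logic is sound and leakage-free and that it recovers
planted signal under idealised noise — not that any particular accuracy
would be attained on real arrays, where correlated probes and confounders
make both filtering and classification harder.

## Numerical and design choices

- Floor rounding for top-fraction counts; selection ties broken by CpG id.
- Sample standard deviation uses the (m−1) denominator; quantiles are
  type 7; the relative range's 0/0 case is defined as 0.
- Split, training, candidate-draw and arm seeds all derive from one global
  seed via `SeedSequence`, making every pipeline arm reproducible
  bit-for-bit from its recorded configuration; reports carry no timestamps
  and serialize with sorted keys so reruns are byte-identical.
- Degenerate inputs fail loudly: all samples excluded by QC, a CpG with no
  reference value to impute from, single-class training labels, an
  all-zero confusion matrix, a selection whose floor is zero.
- The pruning test bed concentrates the signal in 3 individually necessary
  CpGs among 37 nulls: with redundant planted features, removing one is
  genuinely free and no wrapper can prefer it — enrichment is only a
  meaningful expectation when each signal CpG carries unique information.

## Problem sizes used by the shipped runs

Unit and property tests run on matrices up to 5,000 × 132 with repeat
counts of 1–50; the acceptance script generates one 223,945 × 132 array
for the selection-count chain and runs all accuracy measurements at
5,000 × 132 with 20–50 repeats. These sizes estimate the reported
quantities to within a few percent while keeping a full run in the
minutes range on a single CPU.

## Known limitations

- The classifier backend is fixed to one architecture family (one hidden
  layer); deeper nets are out of scope by design.
- `a_min` semantics, acceptance rule, and the candidate-evaluation split
  are all configurable because the canonical protocol leaves them
  under-determined; defaults choose the leakage-free readings.
- The generator's independence across CpGs means feature redundancy in
  real data (correlated neighbouring probes) is not represented; wrapper
  enrichment results transfer only qualitatively.
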