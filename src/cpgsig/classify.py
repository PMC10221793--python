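"""Repeated train/test evaluation of a single-hidden-layer neural network.

The evaluation protocol is Monte-Carlo cross-validation: a class-stratified
75/25 train/test split, drawn independently ``n_repeats`` (beta) times, with
one network trained per repeat and scored on its held-out quarter. Because
network training is randomly initialized, the per-repeat metric distribution
— not any single fit — is the result.

Two binary tasks are supported:

* ``control_vs_rest`` — control (0) vs patient (hypertensive or
  pre-hypertensive collapse to 1); positive class = patient.
* ``hyper_vs_pre`` — hypertensive (1) vs pre-hypertensive (2), control
  samples dropped; positive class = hypertensive.

All leakage-sensitive steps (imputation reference, feature scoring when a
selection chain is supplied, training) see only the training columns of each
split, so perturbing held-out samples cannot change the fitted model.

Goodness of fit comes from the 2x2 confusion matrix (a1=TP, a2=FP, a3=FN,
a4=TN):

    accuracy    = (a1 + a4) / (a1 + a2 + a3 + a4)
    sensitivity = a1 / (a1 + a3)
    specificity = a4 / (a2 + a4)
    PPV         = a1 / (a1 + a2)
    NPV         = a4 / (a3 + a4)

A zero denominator yields an explicit ``None`` marker, never a silent 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import CpgSigError, EvaluationError, SelectionError
from .filtering import correlation_scores, dispersion_scores, select_top
from .matrix import MethylationMatrix, SampleLabels, impute_missing

TASKS = ("control_vs_rest", "hyper_vs_pre")


@dataclass(frozen=True)
class ClassifierConfig:
    """Network architecture and training parameters.

    The replication architecture is one hidden layer of 50 logistic-sigmoid
    units; training uses L-BFGS (deterministic given ``seed``) on raw beta
    inputs, stopping on the convergence tolerance ``tol`` or after
    ``max_epochs`` iterations. ``early_stopping_cv=True`` additionally picks
    the iteration budget by k-fold cross-validation inside the training
    split (see :class:`SplitScheme.cv_folds`).
    """

    hidden_units: int = 50
    hidden_layers: int = 1
    activation: str = "logistic"
    solver: str = "lbfgs"
    max_epochs: int = 200
    learning_rate: float = 1e-3   # used by sgd/adam solvers only
    tol: float = 1e-4
    alpha: float = 1e-4
    early_stopping_cv: bool = False
    epoch_grid: tuple[int, ...] = (25, 50, 100, 200)
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1 or self.hidden_layers < 1:
            raise CpgSigError("need at least one hidden layer with one unit")


@dataclass(frozen=True)
class SplitScheme:
    """Monte-Carlo split design: train fraction, repeat count beta, seed."""

    train_fraction: float = 0.75
    n_repeats: int = 100
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise CpgSigError("train_fraction must lie strictly between 0 and 1")
        if self.n_repeats < 1:
            raise CpgSigError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts: a1=TP, a2=FP, a3=FN, a4=TN (positive class fixed by the caller)."""

    a1: int
    a2: int
    a3: int
    a4: int

    def __post_init__(self):
        if min(self.a1, self.a2, self.a3, self.a4) < 0:
            raise CpgSigError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a1 + self.a2 + self.a3 + self.a4


@dataclass(frozen=True)
class FitMetrics:
    """The five confusion-matrix ratios; ``None`` marks an undefined value."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


def metrics(cm: ConfusionMatrix) -> FitMetrics:
    """Compute the five ratios from a confusion matrix.

    Raises on an all-zero matrix; any individual zero denominator yields
    ``None`` for that metric only.
    """
    if cm.total == 0:
        raise EvaluationError("all-zero confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return FitMetrics(
        accuracy=ratio(cm.a1 + cm.a4, cm.total),
        sensitivity=ratio(cm.a1, cm.a1 + cm.a3),
        specificity=ratio(cm.a4, cm.a2 + cm.a4),
        ppv=ratio(cm.a1, cm.a1 + cm.a2),
        npv=ratio(cm.a4, cm.a3 + cm.a4),
    )


# ---------------------------------------------------------------------------
# Splitting


def stratified_split(labels: SampleLabels, scheme: SplitScheme, repeat_index: int
                     ) -> tuple[list[str], list[str]]:
    """One class-stratified train/test partition, deterministic in (seed, repeat).

    Each class contributes floor(n_class * train_fraction) training samples
    (at least one per side). Train and test are disjoint and exhaustive.
    """
    rng = np.random.default_rng([int(scheme.seed) & 0x7FFFFFFF, int(repeat_index)])
    train: list[str] = []
    test: list[str] = []
    classes = labels.class_array
    ids = np.asarray(labels.sample_ids)
    for cls in sorted(set(labels.classes)):
        members = ids[classes == cls]
        if members.size < 2:
            raise EvaluationError(f"class {cls} has fewer than 2 samples")
        n_train = int(np.floor(members.size * scheme.train_fraction))
        n_train = min(max(n_train, 1), members.size - 1)
        perm = rng.permutation(members)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return sorted(train), sorted(test)


def task_view(labels: SampleLabels, task: str) -> tuple[SampleLabels, int]:
    """Restrict/recode labels for a task; returns (binary labels, positive class)."""
    if task == "control_vs_rest":
        return labels.binary_view(), 1
    if task == "hyper_vs_pre":
        keep = [(s, c) for s, c in zip(labels.sample_ids, labels.classes) if c in (1, 2)]
        if not keep:
            raise EvaluationError("no hypertensive or pre-hypertensive samples")
        ids, cls = zip(*keep)
        return SampleLabels(tuple(ids), tuple(1 if c == 1 else 0 for c in cls)), 1
    raise CpgSigError(f"unknown task {task!r}; one of {TASKS}")


# ---------------------------------------------------------------------------
# Training and scoring


def _derive_int_seed(*parts: int) -> int:
    return int(np.random.SeedSequence([p & 0x7FFFFFFF for p in parts])
               .generate_state(1)[0] % (2 ** 31))


def _build_mlp(config: ClassifierConfig, max_iter: int, seed: int) -> MLPClassifier:
    kwargs = dict(
        hidden_layer_sizes=(config.hidden_units,) * config.hidden_layers,
        activation=config.activation, solver=config.solver, alpha=config.alpha,
        max_iter=max_iter, tol=config.tol, random_state=seed,
    )
    if config.solver in ("sgd", "adam"):
        kwargs["learning_rate_init"] = config.learning_rate
    return MLPClassifier(**kwargs)


def train_nn(X: np.ndarray, y: np.ndarray, config: ClassifierConfig,
             cv_folds: int = 10) -> MLPClassifier:
    """Fit the network on raw beta inputs (rows = samples, columns = CpGs).

    Deterministic given ``config.seed``. With ``early_stopping_cv`` the
    iteration budget is chosen from ``config.epoch_grid`` by stratified
    k-fold accuracy inside the training data before the final fit.
    """
    # contiguous copy: BLAS kernels differ by memory layout, and lbfgs would
    # otherwise amplify stride-dependent rounding into different weights
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, int)
    if np.any(np.isnan(X)):
        raise EvaluationError("training matrix contains missing values; impute first")
    if len(np.unique(y)) < 2:
        raise EvaluationError("training labels contain a single class")
    max_iter = config.max_epochs
    if config.early_stopping_cv:
        max_iter = _epochs_by_cv(X, y, config, cv_folds)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    model = _build_mlp(config, max_iter, config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _epochs_by_cv(X, y, config: ClassifierConfig, cv_folds: int) -> int:
    folds = min(cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        return config.max_epochs
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    best_iter, best_acc = config.max_epochs, -1.0
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    for cand in config.epoch_grid:
        accs = []
        for tr, va in skf.split(X, y):
            model = _build_mlp(config, cand, config.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X[tr], y[tr])
            accs.append(model.score(X[va], y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_iter = acc, cand
    return best_iter


def confusion(model, X_test: np.ndarray, y_test: np.ndarray,
              positive_class: int = 1) -> ConfusionMatrix:
    """Count TP/FP/FN/TN of ``model`` on a held-out set."""
    X_test = np.asarray(X_test, float)
    y_test = np.asarray(y_test, int)
    if X_test.shape[0] == 0:
        raise EvaluationError("empty test set")
    pred = np.asarray(model.predict(X_test), int)
    pos_true = y_test == positive_class
    pos_pred = pred == positive_class
    return ConfusionMatrix(
        a1=int(np.sum(pos_pred & pos_true)),
        a2=int(np.sum(pos_pred & ~pos_true)),
        a3=int(np.sum(~pos_pred & pos_true)),
        a4=int(np.sum(~pos_pred & ~pos_true)),
    )


# ---------------------------------------------------------------------------
# Per-repeat feature selection


@dataclass(frozen=True)
class FilterStage:
    """One selection step: score CpGs by ``metric``, keep a fraction or count."""

    metric: str  # "correlation" | "std" | "iqr" | "range"
    fraction: float | None = None
    count: int | None = None


@dataclass(frozen=True)
class FilterChain:
    """Selection stages applied in sequence to a shrinking CpG pool.

    When the chain is applied inside the evaluation loop it sees training
    samples only, so selection cannot leak held-out information.
    """

    stages: tuple[FilterStage, ...]

    def apply(self, matrix: MethylationMatrix, labels: SampleLabels) -> tuple[str, ...]:
        pool = matrix
        selected = tuple(matrix.cpg_ids)
        for stage in self.stages:
            if stage.metric == "correlation":
                scores = correlation_scores(pool, labels, view="pairwise"
                                            if len(set(labels.classes)) == 2
                                            and set(labels.classes) != {0, 1}
                                            else "binary")
            elif stage.metric in ("std", "iqr", "range"):
                scores = dispersion_scores(pool, stage.metric)
            else:
                raise SelectionError(f"unknown filter metric {stage.metric!r}")
            result = select_top(scores, fraction=stage.fraction, count=stage.count)
            selected = result.selected_cpg_ids
            pool = pool.select_cpgs(list(selected))
        return selected


# ---------------------------------------------------------------------------
# Repeated evaluation


@dataclass
class EvaluationResult:
    """Distribution of fit metrics over the beta Monte-Carlo repeats."""

    per_repeat: list[FitMetrics]
    cpg_set: tuple[str, ...] | None
    selected_per_repeat: list[tuple[str, ...]] | None
    task: str
    positive_class: int
    scheme: SplitScheme
    config: ClassifierConfig

    @property
    def accuracies(self) -> list[float]:
        return [m.accuracy for m in self.per_repeat]

    def summary(self) -> dict[str, dict[str, float | int]]:
        out: dict[str, dict[str, float | int]] = {}
        for name in METRIC_NAMES:
            vals = [getattr(m, name) for m in self.per_repeat]
            defined = np.array([v for v in vals if v is not None], float)
            entry: dict[str, float | int] = {"n_defined": int(defined.size)}
            if defined.size:
                entry.update(
                    mean=float(defined.mean()),
                    median=float(np.median(defined)),
                    q25=float(np.percentile(defined, 25)),
                    q75=float(np.percentile(defined, 75)),
                )
            out[name] = entry
        return out

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "positive_class": self.positive_class,
            "n_repeats": self.scheme.n_repeats,
            "train_fraction": self.scheme.train_fraction,
            "scheme_seed": self.scheme.seed,
            "classifier": {
                "hidden_units": self.config.hidden_units,
                "hidden_layers": self.config.hidden_layers,
                "activation": self.config.activation,
                "solver": self.config.solver,
                "max_epochs": self.config.max_epochs,
                "seed": self.config.seed,
            },
            "cpg_set": list(self.cpg_set) if self.cpg_set is not None else None,
            "selected_per_repeat": ([list(s) for s in self.selected_per_repeat]
                                    if self.selected_per_repeat is not None else None),
            "per_repeat": [m.as_dict() for m in self.per_repeat],
            "summary": self.summary(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def single_split_evaluation(matrix: MethylationMatrix, labels: SampleLabels,
                            cpg_set, scheme: SplitScheme, config: ClassifierConfig,
                            task: str, repeat_index: int,
                            selector: FilterChain | None = None,
                            ) -> tuple[FitMetrics, tuple[str, ...], MLPClassifier]:
    """One split -> impute -> (select) -> train -> confusion -> metrics cycle.

    Returns the metrics, the CpG set actually used, and the fitted model.
    Imputation and selection see training columns only.
    """
    tlabels, positive = task_view(labels, task)
    present = set(matrix.sample_ids)
    missing = [s for s in tlabels.sample_ids if s not in present]
    if missing and len(missing) == len(tlabels):
        raise EvaluationError("labels and matrix share no samples")
    tlabels = tlabels.subset([s for s in tlabels.sample_ids if s in present])
    mat = matrix.select_samples(list(tlabels.sample_ids))
    train_ids, test_ids = stratified_split(tlabels, scheme, repeat_index)
    mat = impute_missing(mat, reference_columns=train_ids)

    if selector is not None:
        base = mat if cpg_set is None else mat.select_cpgs(list(cpg_set))
        train_mat = base.select_samples(train_ids)
        used = selector.apply(train_mat, tlabels.subset(train_ids))
    elif cpg_set is not None:
        used = tuple(cpg_set)
    else:
        raise CpgSigError("provide cpg_set, a selector chain, or both")

    sub = mat.select_cpgs(list(used))
    y = dict(zip(tlabels.sample_ids, tlabels.classes))
    X_train = sub.select_samples(train_ids).values.T
    X_test = sub.select_samples(test_ids).values.T
    y_train = np.array([y[s] for s in train_ids])
    y_test = np.array([y[s] for s in test_ids])

    fit_seed = _derive_int_seed(config.seed, scheme.seed, repeat_index)
    model = train_nn(X_train, y_train, replace(config, seed=fit_seed),
                     cv_folds=scheme.cv_folds)
    cm = confusion(model, X_test, y_test, positive_class=positive)
    return metrics(cm), used, model


def repeated_evaluation(matrix: MethylationMatrix, labels: SampleLabels,
                        cpg_set=None, scheme: SplitScheme = SplitScheme(),
                        config: ClassifierConfig = ClassifierConfig(),
                        task: str = "control_vs_rest",
                        selector: FilterChain | None = None) -> EvaluationResult:
    """Run beta independent split/train/score cycles and collect the metrics.

    ``cpg_set`` fixes the feature set; a ``selector`` chain instead reselects
    features on each repeat's training samples (the leakage-free default of
    the pipeline). With both, the chain selects within the given pool.
    """
    per_repeat: list[FitMetrics] = []
    selected: list[tuple[str, ...]] = []
    _, positive = task_view(labels, task)
    for r in range(scheme.n_repeats):
        fit, used, _ = single_split_evaluation(
            matrix, labels, cpg_set, scheme, config, task, r, selector)
        per_repeat.append(fit)
        selected.append(used)
    return EvaluationResult(
        per_repeat=per_repeat,
        cpg_set=tuple(cpg_set) if cpg_set is not None else None,
        selected_per_repeat=selected if selector is not None else None,
        task=task, positive_class=positive, scheme=scheme, config=config)
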