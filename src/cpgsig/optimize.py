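"""Greedy stochastic backward elimination of CpGs.

A wrapper feature-selection loop: starting from an input CpG set, each
iteration removes one uniformly drawn CpG, re-estimates classification
accuracy on the candidate set, and keeps the removal if accuracy does not
suffer (``non_worse``, the default) or only if it strictly improves
(``strict_improve``). The set size therefore never increases; the loop
stops at ``qmax`` iterations, at a floor set size, or on the ``a_min``
accuracy condition.

Accuracy during the search is, by default, estimated on validation splits
carved from the training portion of an outer train/test partition, so the
final held-out set never influences which CpGs survive; ``evaluate_on
= "test"`` reproduces the literal protocol of scoring candidates on the
outer test split. Because single network fits are noisy, each candidate is
scored as the mean over ``eval_repeats`` independent splits/fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import (ClassifierConfig, SplitScheme, confusion, metrics,
                       repeated_evaluation, stratified_split, task_view, train_nn,
                       _derive_int_seed)
from .errors import ConfigError, EvaluationError
from .matrix import MethylationMatrix, SampleLabels, impute_missing

ACCEPT_RULES = ("strict_improve", "non_worse")
A_MIN_MODES = ("floor", "target")


@dataclass(frozen=True)
class OptimizerConfig:
    """Search parameters for the elimination loop.

    ``a_min`` is interpreted per ``a_min_mode``: a quality *floor* (stop
    once estimated accuracy drops below it — the default) or a *target*
    (stop once accuracy reaches it).
    """

    qmax: int = 100
    a_min: float = 0.0
    accept_rule: str = "non_worse"
    a_min_mode: str = "floor"
    eval_repeats: int = 5
    min_set_size: int = 1
    evaluate_on: str = "validation"  # "validation" (leakage-free) | "test" (literal)
    seed: int = 0

    def __post_init__(self):
        if self.qmax < 0:
            raise ConfigError("qmax must be >= 0")
        if not 0.0 <= self.a_min <= 1.0:
            raise ConfigError("a_min must lie in [0, 1]")
        if self.accept_rule not in ACCEPT_RULES:
            raise ConfigError(f"accept_rule must be one of {ACCEPT_RULES}")
        if self.a_min_mode not in A_MIN_MODES:
            raise ConfigError(f"a_min_mode must be one of {A_MIN_MODES}")
        if self.min_set_size < 1:
            raise ConfigError("min_set_size must be >= 1")
        if self.eval_repeats < 1:
            raise ConfigError("eval_repeats must be >= 1")
        if self.evaluate_on not in ("validation", "test"):
            raise ConfigError("evaluate_on must be 'validation' or 'test'")


@dataclass(frozen=True)
class IterationRecord:
    """One elimination attempt."""

    iteration: int
    removed_cpg: str
    accuracy_before: float
    accuracy_after: float
    accepted: bool
    set_size: int  # size after the accept/reject decision


@dataclass
class OptimizerTrace:
    """Full history of a pruning run."""

    initial_set: tuple[str, ...]
    initial_accuracy: float
    records: list[IterationRecord] = field(default_factory=list)
    final_set: tuple[str, ...] = ()
    final_accuracy: float = float("nan")
    stop_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "initial_set": list(self.initial_set),
            "initial_accuracy": self.initial_accuracy,
            "records": [vars(r) for r in self.records],
            "final_set": list(self.final_set),
            "final_accuracy": self.final_accuracy,
            "stop_reason": self.stop_reason,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _default_accuracy_fn(matrix: MethylationMatrix, labels: SampleLabels,
                         task: str, opt: OptimizerConfig, scheme: SplitScheme,
                         clf_config: ClassifierConfig):
    """Build the candidate-set accuracy estimator.

    An outer stratified split is fixed once per run. In ``validation`` mode
    candidates are scored by ``eval_repeats`` Monte-Carlo splits *within*
    the outer training samples; in ``test`` mode each candidate is trained
    ``eval_repeats`` times on the outer training samples and scored on the
    outer test split.
    """
    tlabels, positive = task_view(labels, task)
    present = set(matrix.sample_ids)
    tlabels = tlabels.subset([s for s in tlabels.sample_ids if s in present])
    mat = matrix.select_samples(list(tlabels.sample_ids))
    outer_seed = _derive_int_seed(opt.seed, scheme.seed, 0xA11CE)
    outer_train, outer_test = stratified_split(
        tlabels, replace(scheme, seed=outer_seed), 0)
    mat = impute_missing(mat, reference_columns=outer_train)
    y = dict(zip(tlabels.sample_ids, tlabels.classes))

    if opt.evaluate_on == "validation":
        # original class coding: repeated_evaluation re-derives the task view
        inner_labels = labels.subset(outer_train)
        inner_mat = mat.select_samples(outer_train)

        def accuracy(cpg_set) -> float:
            scheme_i = replace(scheme, n_repeats=opt.eval_repeats,
                               seed=_derive_int_seed(opt.seed, scheme.seed, 1))
            res = repeated_evaluation(inner_mat, inner_labels, cpg_set=list(cpg_set),
                                      scheme=scheme_i, config=clf_config, task=task)
            return float(np.mean(res.accuracies))
    else:
        def accuracy(cpg_set) -> float:
            sub = mat.select_cpgs(list(cpg_set))
            X_tr = sub.select_samples(outer_train).values.T
            X_te = sub.select_samples(outer_test).values.T
            y_tr = np.array([y[s] for s in outer_train])
            y_te = np.array([y[s] for s in outer_test])
            accs = []
            for r in range(opt.eval_repeats):
                seed = _derive_int_seed(opt.seed, clf_config.seed, r)
                model = train_nn(X_tr, y_tr, replace(clf_config, seed=seed),
                                 cv_folds=scheme.cv_folds)
                cm = confusion(model, X_te, y_te, positive_class=positive)
                accs.append(metrics(cm).accuracy)
            return float(np.mean(accs))

    return accuracy


def greedy_prune(matrix: MethylationMatrix | None, labels: SampleLabels | None,
                 initial_set, task: str = "control_vs_rest",
                 opt: OptimizerConfig = OptimizerConfig(),
                 scheme: SplitScheme = SplitScheme(),
                 clf_config: ClassifierConfig = ClassifierConfig(),
                 accuracy_fn=None) -> OptimizerTrace:
    """Run the elimination loop and return its trace.

    ``accuracy_fn(cpg_set) -> float`` may be injected (e.g. a stub in tests
    or a cheaper surrogate); otherwise the default network-based estimator
    is built from ``matrix``/``labels``. Fully reproducible from the seeds
    in ``opt``, ``scheme`` and ``clf_config``.
    """
    initial = tuple(dict.fromkeys(initial_set))  # preserve order, drop dups
    if len(initial) <= opt.min_set_size:
        raise ConfigError("initial set must be larger than min_set_size")
    if accuracy_fn is None:
        if matrix is None or labels is None:
            raise ConfigError("matrix and labels required without an accuracy_fn")
        accuracy_fn = _default_accuracy_fn(matrix, labels, task, opt, scheme, clf_config)

    current = list(initial)
    acc_current = float(accuracy_fn(current))
    if not np.isfinite(acc_current):
        raise EvaluationError("initial accuracy estimate is not finite")
    trace = OptimizerTrace(initial_set=initial, initial_accuracy=acc_current)
    rng = np.random.default_rng([opt.seed & 0x7FFFFFFF, 0x9E37])

    stop_reason = "qmax_reached" if opt.qmax > 0 else "qmax_zero"
    for q in range(1, opt.qmax + 1):
        if len(current) <= opt.min_set_size:
            stop_reason = "min_set_size"
            break
        victim = current[int(rng.integers(len(current)))]
        candidate = [c for c in current if c != victim]
        acc_new = float(accuracy_fn(candidate))
        acc_before = acc_current
        if opt.accept_rule == "strict_improve":
            accepted = acc_new > acc_current
        else:
            accepted = acc_new >= acc_current
        if accepted:
            current, acc_current = candidate, acc_new
        trace.records.append(IterationRecord(
            iteration=q, removed_cpg=victim, accuracy_before=acc_before,
            accuracy_after=acc_new, accepted=accepted, set_size=len(current)))
        if opt.a_min_mode == "floor" and acc_current < opt.a_min:
            stop_reason = "below_a_min"
            break
        if opt.a_min_mode == "target" and acc_current >= opt.a_min:
            stop_reason = "reached_a_min"
            break

    trace.final_set = tuple(current)
    trace.final_accuracy = acc_current
    trace.stop_reason = stop_reason
    return trace


def prune_report(trace: OptimizerTrace) -> dict:
    """Summarise a trace: sizes, acceptance rate, accuracy trajectory.

    ``size_ratio`` is final/initial (1.0 for an empty trace);
    ``reduction`` is the complementary fraction of CpGs removed.
    """
    n_init = len(trace.initial_set)
    n_final = len(trace.final_set) if trace.records else n_init
    n_iter = len(trace.records)
    n_accepted = sum(r.accepted for r in trace.records)
    size_ratio = n_final / n_init if n_init else 1.0
    return {
        "initial_size": n_init,
        "final_size": n_final,
        "size_ratio": size_ratio,
        "reduction": 1.0 - size_ratio,
        "iterations": n_iter,
        "accepted": n_accepted,
        "acceptance_rate": (n_accepted / n_iter) if n_iter else 0.0,
        "initial_accuracy": trace.initial_accuracy,
        "final_accuracy": trace.final_accuracy,
        "accuracy_trajectory": [r.accuracy_after if r.accepted else None
                                for r in trace.records],
        "stop_reason": trace.stop_reason,
    }
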