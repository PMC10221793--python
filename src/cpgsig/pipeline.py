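"""End-to-end experiment orchestration.

Mirrors the study layout: a baseline group-mean summary, a "base"
experiment (correlation top-1% filter into the network, both tasks), three
secondary dispersion-filter experiments stacked on the base pool, and a
greedy-elimination arm. One configuration object is the source of truth;
every stage seed derives deterministically from the global seed, and each
result echoes the configuration so any arm can be recomputed from its own
report (reports carry no timestamps and serialize with sorted keys, so
reruns are byte-identical).

Feature selection runs in one of two modes:

* ``train_only`` (default) — the filter chain is re-applied to each
  repeat's training samples, so held-out samples never influence selection.
* ``all_samples`` — the chain is applied once to the full dataset and the
  resulting fixed set evaluated, the literal protocol of correlating
  against the whole classification vector.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (ClassifierConfig, FilterChain, FilterStage, SplitScheme,
                       repeated_evaluation)
from .errors import ConfigError
from .matrix import (MethylationMatrix, SampleLabels, impute_missing,
                     mean_methylation_by_group, quality_filter_samples,
                     read_beta_matrix, read_labels)
from .optimize import OptimizerConfig, greedy_prune, prune_report
from .simulate import SyntheticConfig, generate

SELECTION_MODES = ("train_only", "all_samples")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run (and re-run) the full study."""

    matrix_path: str | None = None
    labels_path: str | None = None
    synthetic: SyntheticConfig | None = None
    tasks: tuple[str, ...] = ("control_vs_rest", "hyper_vs_pre")
    base_fraction: float = 0.01
    secondary_fraction: float = 0.01
    secondary_metrics: tuple[str, ...] = ("std", "iqr", "range")
    selection_mode: str = "train_only"
    max_missing: float = 0.01
    scheme: SplitScheme = field(default_factory=lambda: SplitScheme(n_repeats=25))
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(qmax=50, eval_repeats=3, min_set_size=5))
    optimizer_task: str = "hyper_vs_pre"
    seed: int = 0

    def __post_init__(self):
        has_files = self.matrix_path is not None and self.labels_path is not None
        if not has_files and self.synthetic is None:
            raise ConfigError("provide matrix_path+labels_path or a synthetic config")
        if self.selection_mode not in SELECTION_MODES:
            raise ConfigError(f"selection_mode must be one of {SELECTION_MODES}")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if "group_sizes" in syn:
                syn["group_sizes"] = tuple(syn["group_sizes"])
            d["synthetic"] = SyntheticConfig(**syn)
        if d.get("scheme") is not None:
            d["scheme"] = SplitScheme(**d["scheme"])
        if d.get("classifier") is not None:
            clf = dict(d["classifier"])
            if "epoch_grid" in clf:
                clf["epoch_grid"] = tuple(clf["epoch_grid"])
            d["classifier"] = ClassifierConfig(**clf)
        if d.get("optimizer") is not None:
            d["optimizer"] = OptimizerConfig(**d["optimizer"])
        for key in ("tasks", "secondary_metrics"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _arm_seed(global_seed: int, arm: str) -> int:
    """Deterministic 31-bit seed for a named pipeline arm."""
    tag = int.from_bytes(arm.encode()[:8].ljust(8, b"\0"), "big") % (2 ** 31)
    return int(np.random.SeedSequence([global_seed & 0x7FFFFFFF, tag])
               .generate_state(1)[0] % (2 ** 31))


def load_inputs(config: PipelineConfig
                ) -> tuple[MethylationMatrix, SampleLabels, object | None]:
    """Read matrix/labels from disk, or generate the configured synthetic data."""
    if config.matrix_path is not None and config.labels_path is not None:
        return (read_beta_matrix(config.matrix_path),
                read_labels(config.labels_path), None)
    matrix, labels, truth = generate(config.synthetic)
    return matrix, labels, truth


def select_reference_set(matrix: MethylationMatrix, labels: SampleLabels,
                         chain: FilterChain, task: str = "control_vs_rest"
                         ) -> tuple[str, ...]:
    """Apply a filter chain once, on all samples (the ``all_samples`` protocol)."""
    from .classify import task_view
    tlabels, _ = task_view(labels, task)
    mat = impute_missing(matrix.select_samples(list(tlabels.sample_ids)))
    return chain.apply(mat, tlabels)


def _evaluate_arm(matrix: MethylationMatrix, labels: SampleLabels,
                  chain: FilterChain, task: str, config: PipelineConfig,
                  arm_name: str) -> dict:
    scheme = replace(config.scheme, seed=_arm_seed(config.seed, arm_name))
    clf = replace(config.classifier, seed=_arm_seed(config.seed, arm_name + "/clf"))
    if config.selection_mode == "train_only":
        result = repeated_evaluation(matrix, labels, cpg_set=None, scheme=scheme,
                                     config=clf, task=task, selector=chain)
        sets = result.selected_per_repeat
        counts = pd.Series([c for s in sets for c in s]).value_counts()
        consensus = sorted(counts.index[counts > len(sets) / 2])
        n_selected = len(sets[0])
        selection = {"mode": "train_only", "n_selected_per_repeat": n_selected,
                     "consensus_set": consensus}
    else:
        fixed = select_reference_set(matrix, labels, chain, task)
        result = repeated_evaluation(matrix, labels, cpg_set=list(fixed),
                                     scheme=scheme, config=clf, task=task)
        n_selected = len(fixed)
        selection = {"mode": "all_samples", "n_selected_per_repeat": n_selected,
                     "selected_set": list(fixed)}
    return {
        "arm": arm_name,
        "task": task,
        "chain": [dataclasses.asdict(s) for s in chain.stages],
        "selection": selection,
        "evaluation": {
            "summary": result.summary(),
            "per_repeat": [m.as_dict() for m in result.per_repeat],
            "positive_class": result.positive_class,
        },
        "seeds": {"scheme": scheme.seed, "classifier": clf.seed},
    }


def run_base_experiment(matrix: MethylationMatrix, labels: SampleLabels,
                        config: PipelineConfig, task: str = "control_vs_rest") -> dict:
    """QC -> impute -> correlation top-fraction -> repeated evaluation."""
    matrix, qc = quality_filter_samples(matrix, config.max_missing)
    labels = labels.subset(matrix.sample_ids)
    chain = FilterChain((FilterStage("correlation", fraction=config.base_fraction),))
    bundle = _evaluate_arm(matrix, labels, chain, task, config, f"base_{task}")
    bundle["qc"] = qc.to_dict()
    bundle["provenance"] = _provenance(config)
    return bundle


def run_secondary_experiment(matrix: MethylationMatrix, labels: SampleLabels,
                             config: PipelineConfig, metric: str,
                             task: str = "control_vs_rest") -> dict:
    """Correlation pre-filter then one dispersion filter, evaluated end to end.

    With the study's array sizes this is the 223,945 -> 2,239 -> 22 chain.
    """
    matrix, qc = quality_filter_samples(matrix, config.max_missing)
    labels = labels.subset(matrix.sample_ids)
    chain = FilterChain((FilterStage("correlation", fraction=config.base_fraction),
                         FilterStage(metric, fraction=config.secondary_fraction)))
    bundle = _evaluate_arm(matrix, labels, chain, task, config,
                           f"secondary_{metric}_{task}")
    bundle["qc"] = qc.to_dict()
    bundle["provenance"] = _provenance(config)
    return bundle


def run_optimizer_arm(matrix: MethylationMatrix, labels: SampleLabels,
                      config: PipelineConfig) -> dict:
    """Greedy elimination starting from the correlation-selected pool."""
    matrix, _ = quality_filter_samples(matrix, config.max_missing)
    labels = labels.subset(matrix.sample_ids)
    task = config.optimizer_task
    chain = FilterChain((FilterStage("correlation", fraction=config.base_fraction),))
    initial = select_reference_set(matrix, labels, chain, task)
    opt = replace(config.optimizer, seed=_arm_seed(config.seed, "optimizer"))
    scheme = replace(config.scheme, seed=_arm_seed(config.seed, "optimizer/scheme"))
    clf = replace(config.classifier, seed=_arm_seed(config.seed, "optimizer/clf"))
    trace = greedy_prune(matrix, labels, initial, task=task, opt=opt,
                         scheme=scheme, clf_config=clf)
    final_eval = repeated_evaluation(
        matrix, labels, cpg_set=list(trace.final_set),
        scheme=replace(scheme, seed=_arm_seed(config.seed, "optimizer/final")),
        config=clf, task=task)
    return {
        "arm": "optimizer",
        "task": task,
        "initial_size": len(initial),
        "report": prune_report(trace),
        "final_evaluation": {"summary": final_eval.summary(),
                             "per_repeat": [m.as_dict() for m in final_eval.per_repeat]},
        "seeds": {"optimizer": opt.seed, "scheme": scheme.seed, "classifier": clf.seed},
        "provenance": _provenance(config),
    }


def run_full_study(config: PipelineConfig, out_dir=None) -> dict:
    """Run every arm and assemble one report (optionally written to ``out_dir``).

    Arms: per-class mean methylation, base experiment for each configured
    task, one secondary experiment per dispersion metric, and the optimizer.
    Each arm fails loudly with its name attached.
    """
    matrix, labels, truth = load_inputs(config)
    report: dict = {"config": _jsonable(config.to_dict()),
                    "provenance": _provenance(config), "arms": {}}
    if truth is not None:
        report["synthetic_truth"] = {
            "n_informative": len(truth.informative_cpg_ids),
            "informative_cpg_ids": sorted(truth.informative_cpg_ids)}

    stages: list[tuple[str, callable]] = []
    qc_matrix, qc = quality_filter_samples(matrix, config.max_missing)
    qc_labels = labels.subset(qc_matrix.sample_ids)
    report["qc"] = qc.to_dict()
    report["group_mean_methylation"] = {
        str(k): v for k, v in mean_methylation_by_group(qc_matrix, qc_labels).items()}

    for task in config.tasks:
        stages.append((f"base_{task}",
                       lambda t=task: run_base_experiment(matrix, labels, config, t)))
    for metric in config.secondary_metrics:
        stages.append((f"secondary_{metric}",
                       lambda m=metric: run_secondary_experiment(
                           matrix, labels, config, m, "control_vs_rest")))
    stages.append(("optimizer", lambda: run_optimizer_arm(matrix, labels, config)))

    for name, runner in stages:
        try:
            report["arms"][name] = runner()
        except Exception as exc:
            raise type(exc)(f"[arm {name}] {exc}") from exc

    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir) -> None:
    """Write report.json plus a long-format TSV of per-repeat accuracies."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = []
    for name, arm in report["arms"].items():
        per_repeat = (arm.get("evaluation") or arm.get("final_evaluation"))["per_repeat"]
        for i, m in enumerate(per_repeat):
            rows.append({"arm": name, "repeat": i, "accuracy": m["accuracy"]})
    pd.DataFrame(rows).to_csv(out / "accuracies.tsv", sep="\t", index=False)


def _provenance(config: PipelineConfig) -> dict:
    return {"package": "cpgsig", "version": __version__, "global_seed": config.seed,
            "selection_mode": config.selection_mode}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# convenience re-exports used by the CLI
__all__ = [
    "PipelineConfig", "load_inputs", "run_base_experiment",
    "run_secondary_experiment", "run_optimizer_arm", "run_full_study",
    "select_reference_set", "write_report",
]
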