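"""CpG scoring and top-fraction selection.

Two families of univariate scores drive dimensionality reduction:

* **Label correlation** — |Pearson r| between each CpG's beta values across
  samples and a 0/1 class vector. The absolute value is used because hypo-
  and hypermethylation are equally informative and the sign depends only on
  the arbitrary class coding.
* **Dispersion metrics** — per-CpG sample standard deviation (m-1
  denominator), interquartile range (linear-interpolation quantiles), and
  relative range (max-min)/(max+min). These are label-free and pick CpGs
  that vary at all, a cheap secondary reduction after the correlation
  pre-filter.

Selection keeps the top floor(parent_count * fraction) scorers; the floor
convention makes a 1% cut of 223,945 CpGs keep exactly 2,239 and a further
1% cut keep exactly 22. Ties at the cutoff break lexicographically by CpG
id so results are deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BetaRangeError, CpgSigError, SelectionError
from .matrix import MethylationMatrix, SampleLabels

DISPERSION_METRICS = ("std", "iqr", "range")


@dataclass(frozen=True)
class CpGScores:
    """One finite score per CpG under a named metric."""

    cpg_ids: tuple[str, ...]
    scores: np.ndarray
    metric_name: str

    def __post_init__(self):
        if len(self.cpg_ids) != len(self.scores):
            raise CpgSigError("cpg_ids and scores differ in length")
        if not np.all(np.isfinite(self.scores)):
            raise CpgSigError(f"non-finite {self.metric_name} scores emitted")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"cpg_id": self.cpg_ids, "score": self.scores}) \
            .to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FilterResult:
    """Outcome of a top-k selection."""

    selected_cpg_ids: tuple[str, ...]
    n_selected: int
    fraction: float | None
    parent_count: int
    metric_name: str

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "fraction": self.fraction,
            "n_selected": self.n_selected,
            "parent_count": self.parent_count,
            "selected_cpg_ids": list(self.selected_cpg_ids),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Scores


def _binary_vector(labels: SampleLabels, view: str) -> np.ndarray:
    if view == "binary":
        return labels.binary_view().class_array.astype(float)
    if view == "pairwise":
        present = sorted(set(labels.classes))
        if len(present) != 2:
            raise CpgSigError(
                f"pairwise view needs exactly two classes, got {present}")
        return (labels.class_array == present[1]).astype(float)
    raise CpgSigError(f"unknown view {view!r}; expected 'binary' or 'pairwise'")


def correlation_scores(matrix: MethylationMatrix, labels: SampleLabels,
                       view: str = "binary") -> CpGScores:
    """|Pearson correlation| between each CpG row and the 0/1 label vector.

    Requires a complete matrix (impute first) and at least 3 samples.
    Zero-variance rows score 0 by convention. ``view='binary'`` collapses
    control vs patient; ``view='pairwise'`` requires exactly two classes in
    the labels (e.g. hypertensive vs pre-hypertensive).
    """
    if matrix.has_missing:
        raise CpgSigError("correlation_scores requires a complete matrix; impute first")
    if matrix.n_samples < 3:
        raise CpgSigError("need at least 3 samples for a correlation score")
    aligned = labels.subset(matrix.sample_ids)
    y = _binary_vector(aligned, view)
    yc = y - y.mean()
    y_norm = float(np.sqrt((yc ** 2).sum()))
    X = matrix.values
    Xc = X - X.mean(axis=1, keepdims=True)
    row_norm = np.sqrt((Xc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (row_norm * y_norm)
    r[row_norm == 0.0] = 0.0
    if y_norm == 0.0:
        r[:] = 0.0
    return CpGScores(tuple(matrix.cpg_ids), np.abs(r), "correlation")


def dispersion_std(row) -> float:
    """Sample standard deviation (m-1 denominator) of a complete row of >= 2 values."""
    row = _checked_row(row, min_len=2)
    return float(np.std(row, ddof=1))


def dispersion_iqr(row) -> float:
    """Interquartile range Q75 - Q25 via linear-interpolation ("type 7") quantiles."""
    row = _checked_row(row, min_len=4)
    q75, q25 = np.percentile(row, [75, 25], method="linear")
    return float(q75 - q25)


def dispersion_range(row) -> float:
    """Relative range (max - min) / (max + min); 0 for an all-zero row.

    Values must lie in [0, 1], which also guarantees the score lies in [0, 1].
    """
    row = _checked_row(row, min_len=2)
    if np.any((row < 0.0) | (row > 1.0)):
        bad = row[(row < 0.0) | (row > 1.0)][0]
        raise BetaRangeError("<row>", "<row>", float(bad))
    hi, lo = float(np.max(row)), float(np.min(row))
    if hi + lo == 0.0:
        return 0.0
    return (hi - lo) / (hi + lo)


def _checked_row(row, min_len: int) -> np.ndarray:
    arr = np.asarray(row, dtype=float)
    if arr.ndim != 1 or arr.size < min_len:
        raise CpgSigError(f"need a 1-D row of at least {min_len} values")
    if np.any(np.isnan(arr)):
        raise CpgSigError("row contains missing values; impute first")
    return arr


def dispersion_scores(matrix: MethylationMatrix, metric: str) -> CpGScores:
    """Apply one dispersion metric to every CpG row of a complete matrix."""
    if matrix.has_missing:
        raise CpgSigError("dispersion scores require a complete matrix; impute first")
    X = matrix.values
    if metric == "std":
        if matrix.n_samples < 2:
            raise CpgSigError("std needs >= 2 samples")
        scores = np.std(X, axis=1, ddof=1)
    elif metric == "iqr":
        if matrix.n_samples < 4:
            raise CpgSigError("iqr needs >= 4 samples")
        q75, q25 = np.percentile(X, [75, 25], axis=1, method="linear")
        scores = q75 - q25
    elif metric == "range":
        if matrix.n_samples < 2:
            raise CpgSigError("range needs >= 2 samples")
        hi, lo = X.max(axis=1), X.min(axis=1)
        denom = hi + lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(denom == 0.0, 0.0, (hi - lo) / denom)
    else:
        raise CpgSigError(f"unknown dispersion metric {metric!r}; one of {DISPERSION_METRICS}")
    return CpGScores(tuple(matrix.cpg_ids), scores, metric)


# ---------------------------------------------------------------------------
# Selection


def top_fraction_count(parent_count: int, fraction: float) -> int:
    """floor(parent_count * fraction), erroring when the floor is zero.

    The floor rule reproduces the canonical 1% chain 223,945 -> 2,239 -> 22.
    """
    if parent_count < 1:
        raise SelectionError("parent_count must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise SelectionError(f"fraction must lie in (0, 1], got {fraction}")
    k = math.floor(parent_count * fraction)
    if k == 0:
        raise SelectionError(
            f"top fraction {fraction} of {parent_count} CpGs selects none")
    return k


def select_top(scores: CpGScores, fraction: float | None = None,
               count: int | None = None) -> FilterResult:
    """Keep the k highest-scoring CpGs (k = count, or floor(n * fraction)).

    Ties at the cutoff break lexicographically by CpG id, so the selection
    is a deterministic function of the scores. Exactly one of ``fraction``
    and ``count`` must be given.
    """
    if (fraction is None) == (count is None):
        raise SelectionError("give exactly one of fraction or count")
    n = len(scores.cpg_ids)
    k = top_fraction_count(n, fraction) if fraction is not None else int(count)
    if k < 1 or k > n:
        raise SelectionError(f"cannot select {k} of {n} scored CpGs")
    order = sorted(range(n), key=lambda i: (-scores.scores[i], scores.cpg_ids[i]))
    chosen = tuple(scores.cpg_ids[i] for i in order[:k])
    return FilterResult(selected_cpg_ids=chosen, n_selected=k, fraction=fraction,
                        parent_count=n, metric_name=scores.metric_name)
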