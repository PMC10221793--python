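"""Beta-value matrices, sample labels, and quality control.

A methylation array experiment is summarised as a CpG-by-sample matrix of
beta values: at CpG *i* in sample *j*, the fraction ``x_ij`` of methylated
copies, bounded in [0, 1]. The matrix is stored dense with ``NaN`` marking
missing cells (failed probes); orientation is fixed as CpG rows x sample
columns, matching the GEO series-matrix convention.

Quality control follows the usual array practice: a sample missing more
than a small fraction of its probes (default 1%, strict inequality) is
excluded outright; residual missing cells in retained samples may then be
mean-imputed per CpG, using a caller-specified reference sample set so that
held-out samples never inform the fill values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BetaRangeError, CpgSigError, FormatError, ImputationError, QCError

#: cell contents parsed as "missing" (common GEO matrix dialects)
MISSING_TOKENS = frozenset({"", "NA", "NaN"})

CONTROL, HYPERTENSIVE, PREHYPERTENSIVE = 0, 1, 2
VALID_CLASSES = frozenset({CONTROL, HYPERTENSIVE, PREHYPERTENSIVE})


class MethylationMatrix:
    """Dense CpG x sample matrix of beta values with optional missing cells.

    Parameters
    ----------
    data
        DataFrame with CpG ids as index, sample ids as columns, float
        values in [0, 1] or NaN.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate CpG ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = np.where(~np.isnan(values) & ((values < 0.0) | (values > 1.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise BetaRangeError(str(data.index[i]), str(data.columns[j]), float(values[i, j]))
        self._data = data.astype(float, copy=False)

    # -- basic accessors ---------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def cpg_ids(self) -> list[str]:
        return [str(c) for c in self._data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self._data.columns]

    @property
    def values(self) -> np.ndarray:
        """CpG x sample array (NaN = missing)."""
        return self._data.to_numpy()

    @property
    def n_cpgs(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self._data.isna().to_numpy().any())

    def __repr__(self) -> str:  # pragma: no cover
        return f"MethylationMatrix({self.n_cpgs} CpGs x {self.n_samples} samples)"

    # -- construction / subsetting -----------------------------------------

    @classmethod
    def from_arrays(cls, cpg_ids, sample_ids, values) -> "MethylationMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(cpg_ids), columns=list(sample_ids)))

    def select_samples(self, sample_ids) -> "MethylationMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return MethylationMatrix(self._data.loc[:, list(sample_ids)])

    def select_cpgs(self, cpg_ids) -> "MethylationMatrix":
        missing = [c for c in cpg_ids if c not in self._data.index]
        if missing:
            raise KeyError(f"unknown CpG ids: {missing[:5]}")
        return MethylationMatrix(self._data.loc[list(cpg_ids), :])

    def missing_fraction_per_sample(self) -> pd.Series:
        return self._data.isna().sum(axis=0) / self.n_cpgs


@dataclass(frozen=True)
class SampleLabels:
    """Per-sample class labels: 0 = control, 1 = hypertensive, 2 = pre-hypertensive."""

    sample_ids: tuple[str, ...]
    classes: tuple[int, ...]

    def __post_init__(self):
        if len(self.sample_ids) != len(self.classes):
            raise FormatError("sample_ids and classes differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in labels")
        bad = sorted(set(self.classes) - VALID_CLASSES)
        if bad:
            raise FormatError(f"invalid class values {bad}; allowed: {sorted(VALID_CLASSES)}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def class_array(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=int)

    def binary_view(self) -> "SampleLabels":
        """Collapse to control (0) vs patient (1): both hypertensive classes map to 1."""
        return SampleLabels(self.sample_ids,
                            tuple(0 if c == CONTROL else 1 for c in self.classes))

    def subset(self, sample_ids) -> "SampleLabels":
        lookup = dict(zip(self.sample_ids, self.classes))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids in labels: {missing[:5]}")
        return SampleLabels(tuple(sample_ids), tuple(lookup[s] for s in sample_ids))

    def class_counts(self) -> dict[int, int]:
        uniq, counts = np.unique(self.class_array, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}


@dataclass
class QCReport:
    """Outcome of per-sample missingness filtering."""

    excluded_sample_ids: list[str]
    missing_fraction: dict[str, float]
    threshold: float
    range_violations: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded_sample_ids": self.excluded_sample_ids,
            "missing_fraction": self.missing_fraction,
            "threshold": self.threshold,
            "range_violations": [list(v) for v in self.range_violations],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# I/O


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


def read_beta_matrix(path, dialect: str = "tsv") -> MethylationMatrix:
    """Read a series-matrix-style beta table.

    Layout: header row of sample ids, first column CpG ids, one column per
    sample. Empty cells, ``NA`` and ``NaN`` parse as missing; any other
    non-numeric cell is a format error, and numeric values outside [0, 1]
    raise :class:`~cpgsig.errors.BetaRangeError` naming the offending cell.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(dialect))[1:]
    if len(set(header)) != len(header):  # read_csv silently renames duplicates
        raise FormatError(f"duplicate sample ids in {path}")
    raw = pd.read_csv(path, sep=_sep(dialect), header=0, index_col=0,
                      dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        raise FormatError(f"duplicate CpG ids in {path}")
    cleaned = raw.apply(lambda col: col.str.strip())
    is_missing = cleaned.isin(MISSING_TOKENS)
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {cleaned.iat[i, j]!r} at CpG {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    numeric = numeric.where(~is_missing, np.nan)
    return MethylationMatrix(numeric)


def write_beta_matrix(matrix: MethylationMatrix, path, dialect: str = "tsv") -> None:
    """Write a matrix back to disk; missing cells become ``NA``. Round-trips exactly."""
    matrix.data.to_csv(path, sep=_sep(dialect), na_rep="NA", index_label="cpg_id")


def read_labels(path, dialect: str = "tsv") -> SampleLabels:
    """Read a two-column table (sample_id, class in {0,1,2}) with a header row."""
    df = pd.read_csv(path, sep=_sep(dialect), header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"label table {path} needs two columns (sample_id, class)")
    try:
        classes = tuple(int(c) for c in df.iloc[:, 1])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer class in {path}: {exc}") from exc
    return SampleLabels(tuple(str(s) for s in df.iloc[:, 0]), classes)


def write_labels(labels: SampleLabels, path, dialect: str = "tsv") -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "class": labels.classes}) \
        .to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# Quality control and imputation


def quality_filter_samples(matrix: MethylationMatrix, max_missing: float = 0.01
                           ) -> tuple[MethylationMatrix, QCReport]:
    """Drop samples whose fraction of missing CpGs strictly exceeds ``max_missing``.

    The CpG axis is untouched. A sample at exactly the threshold is retained.
    """
    frac = matrix.missing_fraction_per_sample()
    excluded = [str(s) for s in frac.index[frac > max_missing]]
    kept = [s for s in matrix.sample_ids if s not in set(excluded)]
    if not kept:
        raise QCError(f"all {matrix.n_samples} samples exceed missing fraction {max_missing}")
    report = QCReport(excluded_sample_ids=excluded,
                      missing_fraction={str(s): float(f) for s, f in frac.items()},
                      threshold=max_missing)
    return matrix.select_samples(kept), report


def impute_missing(matrix: MethylationMatrix, reference_columns=None) -> MethylationMatrix:
    """Fill missing cells with each CpG's mean over ``reference_columns``.

    Restricting the reference to training samples keeps held-out data out of
    the fill values. Defaults to all samples when ``reference_columns`` is
    None. A CpG with no observed value in the reference raises
    :class:`~cpgsig.errors.ImputationError`.
    """
    if not matrix.has_missing:
        return matrix
    ref_ids = matrix.sample_ids if reference_columns is None else list(reference_columns)
    ref = matrix.data.loc[:, ref_ids]
    means = ref.mean(axis=1, skipna=True)
    if means.isna().any():
        raise ImputationError([str(c) for c in means.index[means.isna()]])
    vals = matrix.data.to_numpy(copy=True)
    rows, cols = np.where(np.isnan(vals))
    vals[rows, cols] = means.to_numpy()[rows]
    return MethylationMatrix(pd.DataFrame(vals, index=matrix.data.index,
                                          columns=matrix.data.columns))


def drop_missing_cpgs(matrix: MethylationMatrix) -> MethylationMatrix:
    """Strict-mode alternative to imputation: remove every CpG with any missing cell."""
    keep = ~matrix.data.isna().any(axis=1)
    if not keep.any():
        raise QCError("every CpG has at least one missing cell")
    return MethylationMatrix(matrix.data.loc[keep])


def mean_methylation_by_group(matrix: MethylationMatrix, labels: SampleLabels
                              ) -> dict[int, float]:
    """Average methylation per class over all non-missing cells, on a shared CpG set.

    Produces one scalar in [0, 1] per class: the grand mean of that class's
    samples across every CpG, the usual first-look summary of global
    methylation differences between groups.
    """
    missing = set(matrix.sample_ids) - set(labels.sample_ids)
    if missing:
        raise CpgSigError(f"labels missing for samples: {sorted(missing)[:5]}")
    aligned = labels.subset(matrix.sample_ids)
    out: dict[int, float] = {}
    for cls in sorted(set(aligned.classes)):
        cols = [s for s, c in zip(aligned.sample_ids, aligned.classes) if c == cls]
        block = matrix.data.loc[:, cols].to_numpy()
        if np.all(np.isnan(block)):
            raise QCError(f"class {cls} has no observed values")
        out[int(cls)] = float(np.nanmean(block))
    return out
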