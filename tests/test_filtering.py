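"""Scoring and selection: correlation filter, dispersion metrics, top-k rules."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgsig import (CpGScores, CpgSigError, MethylationMatrix, SampleLabels,
                    SelectionError, correlation_scores, dispersion_iqr,
                    dispersion_range, dispersion_scores, dispersion_std,
                    select_top, top_fraction_count)


def _matrix(rows, sample_ids=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    sample_ids = sample_ids or [f"s{j}" for j in range(rows.shape[1])]
    return MethylationMatrix(pd.DataFrame(
        rows, index=[f"cg{i:03d}" for i in range(rows.shape[0])], columns=sample_ids))


def _pearson_oracle(x, y):
    """Textbook sum-formula Pearson correlation, kept independent of numpy.corrcoef."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


class TestCorrelationScores:
    def test_row_equal_to_labels_scores_one(self):
        m = _matrix([[0, 0, 1, 1]])
        labels = SampleLabels(tuple(m.sample_ids), (0, 0, 1, 1))
        assert correlation_scores(m, labels).scores[0] == pytest.approx(1.0)

    def test_constant_row_scores_zero(self):
        m = _matrix([[0.4, 0.4, 0.4, 0.4]])
        labels = SampleLabels(tuple(m.sample_ids), (0, 0, 1, 1))
        assert correlation_scores(m, labels).scores[0] == 0.0

    def test_matches_hand_pearson_on_four_points(self):
        row = [0.1, 0.2, 0.8, 0.9]
        m = _matrix([row])
        labels = SampleLabels(tuple(m.sample_ids), (0, 0, 1, 1))
        expected = abs(_pearson_oracle(row, [0, 0, 1, 1]))
        assert correlation_scores(m, labels).scores[0] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 50)), int(rng.integers(4, 20))
        vals = rng.random((n, m))
        y = rng.integers(0, 2, m)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, m)
        mat = _matrix(vals)
        labels = SampleLabels(tuple(mat.sample_ids), tuple(int(v) for v in y))
        scores = correlation_scores(mat, labels).scores
        for i in range(n):
            expected = abs(_pearson_oracle(vals[i].tolist(), y.tolist()))
            assert scores[i] == pytest.approx(expected, abs=1e-12)

    def test_binary_view_collapses_prehypertensive(self):
        m = _matrix([[0.1, 0.9, 0.9, 0.1]])
        labels = SampleLabels(tuple(m.sample_ids), (0, 1, 2, 0))  # 2 -> patient
        expected = abs(_pearson_oracle([0.1, 0.9, 0.9, 0.1], [0, 1, 1, 0]))
        assert correlation_scores(m, labels, view="binary").scores[0] == \
            pytest.approx(expected)

    def test_pairwise_view_requires_two_classes(self):
        m = _matrix([[0.1, 0.9, 0.5]])
        labels = SampleLabels(tuple(m.sample_ids), (0, 1, 2))
        with pytest.raises(CpgSigError):
            correlation_scores(m, labels, view="pairwise")

    def test_missing_cells_rejected(self):
        m = MethylationMatrix(pd.DataFrame([[0.1, np.nan, 0.3, 0.5]],
                                           index=["cg0"],
                                           columns=["a", "b", "c", "d"]))
        labels = SampleLabels(("a", "b", "c", "d"), (0, 0, 1, 1))
        with pytest.raises(CpgSigError, match="impute"):
            correlation_scores(m, labels)

    def test_fewer_than_three_samples_rejected(self):
        m = _matrix([[0.1, 0.9]])
        labels = SampleLabels(tuple(m.sample_ids), (0, 1))
        with pytest.raises(CpgSigError):
            correlation_scores(m, labels)


class TestDispersionMetrics:
    def test_std_hand_values(self):
        assert dispersion_std([0.3, 0.3, 0.3]) == 0.0
        assert dispersion_std([0.0, 1.0]) == pytest.approx(np.sqrt(0.5))
        assert dispersion_std([0.2, 0.4, 0.6]) == pytest.approx(0.2)

    def test_iqr_hand_values(self):
        assert dispersion_iqr([0.3, 0.3, 0.3, 0.3]) == 0.0
        assert dispersion_iqr([0.0, 0.25, 0.5, 0.75, 1.0]) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=4, max_size=40))
    def test_iqr_matches_sort_and_interpolate_oracle(self, row):
        # type-7 quantile: h = (n-1)p, linear interpolation of order statistics
        srt = sorted(row)
        n = len(srt)

        def q(p):
            h = (n - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, n - 1)
            return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

        assert dispersion_iqr(row) == pytest.approx(q(0.75) - q(0.25), abs=1e-12)

    def test_relative_range_hand_values(self):
        assert dispersion_range([0.0, 0.0, 0.0]) == 0.0  # 0/0 convention
        assert dispersion_range([0.2, 0.6]) == pytest.approx(0.5)
        assert dispersion_range([0.7, 0.7, 0.7]) == 0.0

    def test_range_rejects_values_outside_unit_interval(self):
        with pytest.raises(CpgSigError):
            dispersion_range([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_relative_range_bounded_in_unit_interval(self, row):
        assert 0.0 <= dispersion_range(row) <= 1.0

    def test_short_rows_rejected(self):
        with pytest.raises(CpgSigError):
            dispersion_std([0.5])
        with pytest.raises(CpgSigError):
            dispersion_iqr([0.1, 0.2, 0.3])

    def test_matrix_scores_match_row_functions_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        mat = _matrix(rng.random((20, 12)))
        perm = rng.permutation(mat.sample_ids).tolist()
        shuffled = mat.select_samples(perm)
        for metric, fn in [("std", dispersion_std), ("iqr", dispersion_iqr),
                           ("range", dispersion_range)]:
            scores = dispersion_scores(mat, metric).scores
            expected = [fn(row) for row in mat.values]
            np.testing.assert_allclose(scores, expected, atol=1e-12)
            np.testing.assert_allclose(
                dispersion_scores(shuffled, metric).scores, scores, atol=1e-12)


class TestSelection:
    def test_published_signature_fixture_matches_floor_count(self):
        """The shipped 22-CpG standard-deviation signature is exactly the
        floor-rule size of a 1% cut of a 2239-CpG pool."""
        path = Path(__file__).parent / "fixtures" / "table2_cpgs.txt"
        ids = path.read_text().split()
        assert len(ids) == len(set(ids)) == 22
        assert all(i.startswith("cg") for i in ids)
        assert top_fraction_count(2239, 0.01) == len(ids)

    def test_floor_rule_counts(self):
        assert top_fraction_count(223_945, 0.01) == 2239
        assert top_fraction_count(2239, 0.01) == 22
        assert top_fraction_count(100, 0.01) == 1

    def test_empty_selection_rejected(self):
        with pytest.raises(SelectionError):
            top_fraction_count(50, 0.01)

    def test_select_top_by_count(self):
        scores = CpGScores(("a", "b", "c"), np.array([0.9, 0.5, 0.1]), "std")
        assert select_top(scores, count=2).selected_cpg_ids == ("a", "b")

    def test_tie_break_is_lexicographic(self):
        scores = CpGScores(("b", "a", "c"), np.array([0.5, 0.5, 0.1]), "std")
        assert select_top(scores, count=1).selected_cpg_ids == ("a",)

    def test_fraction_uses_floor_count(self):
        rng = np.random.default_rng(0)
        ids = tuple(f"cg{i:06d}" for i in range(2239))
        scores = CpGScores(ids, rng.random(2239), "correlation")
        result = select_top(scores, fraction=0.01)
        assert result.n_selected == 22
        assert set(result.selected_cpg_ids) <= set(ids)

    def test_monotone_in_count(self):
        rng = np.random.default_rng(1)
        ids = tuple(f"cg{i:04d}" for i in range(200))
        scores = CpGScores(ids, rng.random(200), "correlation")
        previous: set = set()
        for k in (5, 20, 80, 200):
            chosen = set(select_top(scores, count=k).selected_cpg_ids)
            assert previous <= chosen
            previous = chosen

    def test_count_exceeding_pool_rejected(self):
        scores = CpGScores(("a", "b"), np.array([0.2, 0.1]), "std")
        with pytest.raises(SelectionError):
            select_top(scores, count=3)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(CpgSigError):
            CpGScores(("a",), np.array([np.nan]), "std")
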