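"""Data layer: parsing, QC, imputation, and group means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgsig import (BetaRangeError, FormatError, ImputationError,
                    MethylationMatrix, QCError, SampleLabels, drop_missing_cpgs,
                    impute_missing, mean_methylation_by_group,
                    quality_filter_samples, read_beta_matrix, read_labels,
                    write_beta_matrix, write_labels)


def _write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_round_trip_preserves_ids_and_values(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_beta_matrix(tiny_matrix, path)
        back = read_beta_matrix(path)
        assert back.cpg_ids == tiny_matrix.cpg_ids
        assert back.sample_ids == tiny_matrix.sample_ids
        np.testing.assert_array_equal(back.values, tiny_matrix.values)

    def test_round_trip_with_missing_cells(self, tmp_path):
        m = MethylationMatrix(pd.DataFrame([[0.1, np.nan], [np.nan, 0.9]],
                                           index=["a", "b"], columns=["s1", "s2"]))
        path = tmp_path / "m.csv"
        write_beta_matrix(m, path, dialect="csv")
        back = read_beta_matrix(path, dialect="csv")
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(m.values))
        assert back.values[0, 0] == 0.1

    @pytest.mark.parametrize("token", ["", "NA", "NaN"])
    def test_missing_tokens_parse_as_missing(self, tmp_path, token):
        path = _write(tmp_path, f"cpg\ts1\ts2\ncg0\t0.5\t{token}\n")
        m = read_beta_matrix(path)
        assert np.isnan(m.values[0, 1]) and m.values[0, 0] == 0.5
        assert np.isnan(m.values).sum() == 1

    def test_out_of_range_cell_names_cpg_and_sample(self, tmp_path):
        path = _write(tmp_path, "cpg\ts1\ts2\ncg0\t0.5\t1.2\n")
        with pytest.raises(BetaRangeError) as exc:
            read_beta_matrix(path)
        assert exc.value.cpg_id == "cg0" and exc.value.sample_id == "s2"
        assert exc.value.value == 1.2

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        path = _write(tmp_path, "cpg\ts1\ncg0\thello\n")
        with pytest.raises(FormatError, match="hello"):
            read_beta_matrix(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_beta_matrix(_write(tmp_path, "cpg\ts1\ncg0\t0.1\ncg0\t0.2\n"))
        with pytest.raises(FormatError):
            read_beta_matrix(_write(tmp_path, "cpg\ts1\ts1\ncg0\t0.1\t0.2\n"))

    def test_labels_round_trip(self, tiny_labels, tmp_path):
        path = tmp_path / "labels.tsv"
        write_labels(tiny_labels, path)
        assert read_labels(path) == tiny_labels

    def test_labels_reject_invalid_class(self):
        with pytest.raises(FormatError):
            SampleLabels(("a", "b"), (0, 7))


class TestQualityFilter:
    def _matrix_with_missing(self, n_cpgs=100, miss_per_sample=(0, 1, 2)):
        vals = np.full((n_cpgs, len(miss_per_sample)), 0.5)
        for j, k in enumerate(miss_per_sample):
            vals[:k, j] = np.nan
        return MethylationMatrix(pd.DataFrame(
            vals, index=[f"cg{i}" for i in range(n_cpgs)],
            columns=[f"s{j}" for j in range(len(miss_per_sample))]))

    def test_strictly_above_threshold_excluded(self):
        m = self._matrix_with_missing()  # 0%, 1%, 2% missing
        kept, report = quality_filter_samples(m, max_missing=0.01)
        assert report.excluded_sample_ids == ["s2"]
        assert kept.sample_ids == ["s0", "s1"]  # exactly 1% retained
        assert kept.n_cpgs == m.n_cpgs

    def test_no_missing_is_identity_with_empty_report(self, tiny_matrix):
        kept, report = quality_filter_samples(tiny_matrix)
        assert kept.sample_ids == tiny_matrix.sample_ids
        assert report.excluded_sample_ids == []

    def test_idempotent(self):
        m = self._matrix_with_missing()
        once, _ = quality_filter_samples(m, 0.01)
        twice, _ = quality_filter_samples(once, 0.01)
        assert twice.sample_ids == once.sample_ids
        np.testing.assert_array_equal(twice.values, once.values)

    def test_all_excluded_raises(self):
        m = self._matrix_with_missing(n_cpgs=10, miss_per_sample=(5, 6))
        with pytest.raises(QCError):
            quality_filter_samples(m, max_missing=0.01)


class TestImputation:
    def test_mean_fill_all_reference(self):
        m = MethylationMatrix(pd.DataFrame([[0.2, np.nan, 0.4]],
                                           index=["cg0"], columns=["a", "b", "c"]))
        out = impute_missing(m)
        np.testing.assert_allclose(out.values, [[0.2, 0.3, 0.4]])

    def test_reference_columns_only(self):
        m = MethylationMatrix(pd.DataFrame([[0.1, 0.5, np.nan]],
                                           index=["cg0"], columns=["a", "b", "c"]))
        out = impute_missing(m, reference_columns=["a", "b"])
        assert out.values[0, 2] == pytest.approx(0.3)

    def test_complete_matrix_is_identity(self, tiny_matrix):
        assert impute_missing(tiny_matrix) is tiny_matrix

    def test_all_missing_in_reference_raises(self):
        m = MethylationMatrix(pd.DataFrame([[np.nan, 0.4]],
                                           index=["cg0"], columns=["a", "b"]))
        with pytest.raises(ImputationError) as exc:
            impute_missing(m, reference_columns=["a"])
        assert "cg0" in exc.value.cpg_ids

    def test_strict_mode_drops_incomplete_cpgs(self):
        m = MethylationMatrix(pd.DataFrame([[0.1, np.nan], [0.2, 0.3]],
                                           index=["cg0", "cg1"], columns=["a", "b"]))
        assert drop_missing_cpgs(m).cpg_ids == ["cg1"]


class TestGroupMeans:
    def test_uniform_matrix_gives_uniform_means(self):
        m = MethylationMatrix(pd.DataFrame(np.full((3, 4), 0.5),
                                           index=list("abc"),
                                           columns=["s1", "s2", "s3", "s4"]))
        labels = SampleLabels(("s1", "s2", "s3", "s4"), (0, 1, 2, 1))
        assert mean_methylation_by_group(m, labels) == {0: 0.5, 1: 0.5, 2: 0.5}

    def test_hand_computed_class_means(self):
        m = MethylationMatrix(pd.DataFrame([[0.2, 0.6], [0.4, 0.8]],
                                           index=["a", "b"], columns=["s1", "s2"]))
        labels = SampleLabels(("s1", "s2"), (0, 1))
        means = mean_methylation_by_group(m, labels)
        assert means[0] == pytest.approx(0.3)
        assert means[1] == pytest.approx(0.7)

    def test_single_sample_class_and_missing_cells(self):
        m = MethylationMatrix(pd.DataFrame([[0.2, np.nan], [0.4, 0.9]],
                                           index=["a", "b"], columns=["s1", "s2"]))
        labels = SampleLabels(("s1", "s2"), (0, 2))
        means = mean_methylation_by_group(m, labels)
        assert means[0] == pytest.approx(0.3)
        assert means[2] == pytest.approx(0.9)  # mean over non-missing only

    @settings(max_examples=25, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_invariant_under_sample_permutation(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2 ** 31))
        vals = rng.random((6, 9))
        ids = [f"s{j}" for j in range(9)]
        m = MethylationMatrix(pd.DataFrame(vals, index=[f"c{i}" for i in range(6)],
                                           columns=ids))
        labels = SampleLabels(tuple(ids), tuple(rng.integers(0, 3, 9).tolist()))
        base = mean_methylation_by_group(m, labels)
        perm = rng.permutation(ids).tolist()
        permuted = mean_methylation_by_group(m.select_samples(perm), labels)
        for cls in base:
            assert permuted[cls] == pytest.approx(base[cls])
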