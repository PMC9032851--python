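import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpgsieve import (
    BetaMatrix,
    LabelVector,
    ValidationError,
    drop_incomplete_cpgs,
    encode_labels,
    make_split_plan,
    read_beta_matrix,
    read_labels,
    write_beta_matrix,
)
from cpgsieve.data import train_size


def _example_matrix():
    values = np.array([[0.651094, 0.960434, 0.899284], [0.650451, 0.954877, 0.91]])
    return BetaMatrix(values, ["cg00000029", "cg00000108", "cg00000109"], ["p1", "p2"])


class TestBetaMatrixIO:
    @pytest.mark.parametrize("orientation", ["cpgs_in_rows", "samples_in_rows"])
    @pytest.mark.parametrize("suffix", [".tsv", ".csv"])
    def test_round_trip_preserves_values_and_order(self, tmp_path, orientation, suffix):
        bm = _example_matrix()
        path = tmp_path / f"beta{suffix}"
        write_beta_matrix(bm, path, orientation=orientation)
        back = read_beta_matrix(path, orientation=orientation)
        np.testing.assert_array_equal(back.values, bm.values)
        assert back.cpg_ids == bm.cpg_ids
        assert back.sample_ids == bm.sample_ids

    def test_reads_cpg_per_row_dialect(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text(
            "cpg\tp1\tp2\n"
            "cg00000029\t0.651094\t0.650451\n"
            "cg00000108\t0.960434\t0.954877\n"
            "cg00000109\t0.899284\t0.91\n"
        )
        bm = read_beta_matrix(path)
        assert bm.sample_ids == ["p1", "p2"]
        assert bm.cpg_ids == ["cg00000029", "cg00000108", "cg00000109"]
        assert bm.values[0, 0] == pytest.approx(0.651094, abs=0)
        assert bm.values[1, 1] == pytest.approx(0.954877, abs=0)

    def test_empty_body_is_an_error(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg\n")
        with pytest.raises((ValidationError, pd.errors.EmptyDataError)):
            read_beta_matrix(path)

    def test_out_of_range_value_is_rejected(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg\tp1\tp2\ncg1\t0.5\t1.5\n")
        with pytest.raises(ValidationError, match="outside"):
            read_beta_matrix(path)

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg\tp1\tp2\ncg1\t0.5\toops\n")
        with pytest.raises(ValidationError, match="cg1.*p2"):
            read_beta_matrix(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            BetaMatrix(np.zeros((2, 2)), ["cg1", "cg1"], ["a", "b"])
        with pytest.raises(ValidationError, match="duplicate"):
            BetaMatrix(np.zeros((2, 2)), ["cg1", "cg2"], ["a", "a"])


class TestLabels:
    def test_encode_class_names(self):
        lv = encode_labels(["Control", "Huntington", "Huntington"])
        assert lv.labels.tolist() == [0, 1, 1]

    def test_empty_passthrough(self):
        assert encode_labels([]).labels.tolist() == []

    def test_case_insensitive(self):
        assert encode_labels(["control", "CONTROL"]).labels.tolist() == [0, 0]

    def test_numeric_codes_pass_through(self):
        assert encode_labels([0, 1, 1, 0]).labels.tolist() == [0, 1, 1, 0]

    def test_unknown_label_is_named_in_error(self):
        with pytest.raises(ValidationError, match="banana"):
            encode_labels(["Control", "banana"])

    def test_round_trip_through_class_names(self):
        lv = encode_labels(["Control", "Huntington", "Control"])
        assert encode_labels(lv.names()).labels.tolist() == lv.labels.tolist()

    def test_read_labels_reorders_to_sample_ids(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("sample_id\tlabel\nb\tHuntington\na\tControl\n")
        lv = read_labels(path, sample_ids=["a", "b"])
        assert lv.labels.tolist() == [0, 1]


class TestSplitPlan:
    def test_two_thirds_split_of_76(self):
        labels = LabelVector(np.array([0] * 24 + [1] * 52))
        plan = make_split_plan(76, labels, n_repeats=3, train_fraction=0.666, seed=0)
        for train, test in plan.partitions:
            assert len(train) == 51
            assert len(test) == 25

    def test_half_split_of_odd_count_gives_train_the_extra(self):
        labels = LabelVector(np.array([0] * 24 + [1] * 19))
        plan = make_split_plan(43, labels, n_repeats=2, train_fraction=0.5, seed=0)
        for train, test in plan.partitions:
            assert len(train) == 22
            assert len(test) == 21

    def test_same_seed_reproduces_identical_partitions(self):
        labels = LabelVector(np.array([0, 0, 0, 1, 1, 1, 1, 1]))
        a = make_split_plan(8, labels, n_repeats=5, seed=42)
        b = make_split_plan(8, labels, n_repeats=5, seed=42)
        for (tr1, te1), (tr2, te2) in zip(a.partitions, b.partitions):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    @settings(max_examples=100, derandomize=True)
    @given(
        m=st.integers(6, 60),
        frac=st.floats(0.2, 0.8),
        seed=st.integers(0, 2**31 - 1),
        stratified=st.booleans(),
    )
    def test_partitions_are_disjoint_and_cover_all_samples(self, m, frac, seed, stratified):
        labels = LabelVector(np.arange(m) % 2)
        k = train_size(m, frac)
        if k == 0 or k == m:
            return
        plan = make_split_plan(m, labels, n_repeats=4, train_fraction=frac,
                               seed=seed, stratified=stratified)
        for train, test in plan.partitions:
            assert len(np.intersect1d(train, test)) == 0
            np.testing.assert_array_equal(np.union1d(train, test), np.arange(m))
            assert len(train) == k
            assert len(test) > 0

    def test_stratified_preserves_class_proportions_within_rounding(self):
        labels = LabelVector(np.array([0] * 24 + [1] * 52))
        plan = make_split_plan(76, labels, n_repeats=10, train_fraction=2 / 3, seed=7)
        for train, _ in plan.partitions:
            n1 = int(labels.labels[train].sum())
            # 52 * 2/3 = 34.67 -> 34 or 35 cases in a 51-sample training set
            assert n1 in (34, 35)

    def test_degenerate_fractions_are_rejected(self):
        labels = LabelVector(np.array([0, 0, 1, 1]))
        with pytest.raises(ValidationError):
            make_split_plan(4, labels, train_fraction=0.01, seed=0)
        with pytest.raises(ValidationError):
            make_split_plan(3, LabelVector(np.array([0, 1, 1])), seed=0)

    def test_single_class_labels_rejected_for_stratified(self):
        with pytest.raises(ValidationError):
            make_split_plan(6, LabelVector(np.ones(6, dtype=int)), seed=0)


class TestCovariates:
    def test_read_and_align_to_sample_order(self, tmp_path):
        from cpgsieve import read_covariates

        path = tmp_path / "covariates.tsv"
        path.write_text("sample_id\tage\tbmi\nb\t61\t24.2\na\t48\t27.9\n")
        table = read_covariates(path, sample_ids=["a", "b"])
        assert table.table.index.tolist() == ["a", "b"]
        assert table.table.loc["a", "age"] == 48

    def test_missing_sample_is_an_error(self, tmp_path):
        from cpgsieve import read_covariates

        path = tmp_path / "covariates.tsv"
        path.write_text("sample_id\tage\na\t48\n")
        with pytest.raises(ValidationError, match="b"):
            read_covariates(path, sample_ids=["a", "b"])


class TestDropIncompleteCpgs:
    def test_nan_column_removed_and_reported(self):
        values = np.array([[0.1, np.nan, 0.3], [0.2, 0.5, 0.4]])
        bm = BetaMatrix(values, ["cg1", "cg2", "cg3"], ["a", "b"])
        cleaned, report = drop_incomplete_cpgs(bm)
        assert cleaned.cpg_ids == ["cg1", "cg3"]
        assert report.removed_cpgs == ["cg2"]
        assert report.n_removed == 1

    def test_complete_matrix_is_identity(self):
        bm = _example_matrix()
        cleaned, report = drop_incomplete_cpgs(bm)
        assert report.n_removed == 0
        np.testing.assert_array_equal(cleaned.values, bm.values)

    def test_all_columns_missing_is_an_error(self):
        values = np.full((2, 3), np.nan)
        bm = BetaMatrix(values, ["cg1", "cg2", "cg3"], ["a", "b"])
        with pytest.raises(ValidationError, match="no usable CpGs"):
            drop_incomplete_cpgs(bm)
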