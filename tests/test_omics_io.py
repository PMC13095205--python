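import numpy as np
import pandas as pd
import pytest

from mojknet.datatypes import Modality, OmicsMatrix
from mojknet import omics_io as oi


def make_matrix(values, missing=None, modality=Modality.CNA, ids=None, feats=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        modality=modality,
        sample_ids=ids or [f"S{i}" for i in range(n)],
        feature_ids=feats or [f"f{j}" for j in range(p)],
        values=values,
        missing_mask=missing,
    )


class TestReadWrite:
    def test_missing_token_sets_mask(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SAMPLE_ID\tf1\tf2\nS1\t1.0\tNA\nS2\t2.0\t3.0\nS3\t4.0\t5.0\n")
        mat = oi.read_omics_table(path, Modality.CNA)
        assert mat.missing_mask.sum() == 1
        assert mat.missing_mask[0, 1]
        assert np.isnan(mat.values[0, 1])

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            oi.read_omics_table(path, Modality.CNA)

    def test_non_numeric_cell_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SAMPLE_ID\tf1\nS1\thello\nS2\t1.0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            oi.read_omics_table(path, Modality.CNA)

    def test_duplicate_feature_ids_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("SAMPLE_ID\tf1\tf1\nS1\t1\t2\nS2\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate feature"):
            oi.read_omics_table(path, Modality.CNA)

    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, 5))
        missing = np.zeros((4, 5), dtype=bool)
        missing[1, 2] = True
        values[missing] = np.nan
        mat = make_matrix(values, missing)
        oi.write_omics_table(mat, tmp_path / "rt.tsv")
        back = oi.read_omics_table(tmp_path / "rt.tsv", Modality.CNA)
        assert back.sample_ids == mat.sample_ids
        assert back.feature_ids == mat.feature_ids
        assert np.array_equal(back.missing_mask, mat.missing_mask)
        assert np.array_equal(back.values[~missing], mat.values[~missing])

    def test_features_in_rows_orientation(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("GENE\tS1\tS2\tS3\ng1\t1\t2\t3\ng2\t4\t5\t6\n")
        mat = oi.read_omics_table(path, Modality.MRNA, samples_in_rows=False)
        assert mat.sample_ids == ["S1", "S2", "S3"]
        assert mat.feature_ids == ["g1", "g2"]
        assert mat.values[2, 1] == 6.0


class TestTruncateAndDedup:
    def test_tcga_style_truncation(self):
        assert oi.truncate_sample_ids(["TCGA-CS-4938-01"]) == ["TCGA-CS-4938"]

    def test_short_id_unchanged(self):
        assert oi.truncate_sample_ids(["ABC"]) == ["ABC"]

    def test_collision_raises(self):
        with pytest.raises(ValueError, match="collide"):
            oi.truncate_sample_ids(["TCGA-CS-4938-01", "TCGA-CS-4938-06"])

    def test_dedup_keeps_last_occurrence(self):
        values = np.arange(8, dtype=float).reshape(4, 2)
        mat = OmicsMatrix(
            modality=Modality.CNA,
            sample_ids=["TCGA-AA-0001-01", "TCGA-AA-0002-01",
                        "TCGA-AA-0001-06", "TCGA-AA-0003-01"],
            feature_ids=["f0", "f1"],
            values=values,
        )
        out = oi.dedup_keep_last(mat)
        assert out.sample_ids == ["TCGA-AA-0002", "TCGA-AA-0001", "TCGA-AA-0003"]
        # the retained TCGA-AA-0001 row is the later (-06) one
        assert np.array_equal(out.values[1], values[2])


class TestFilterAndImpute:
    def test_feature_above_missing_threshold_dropped(self):
        # 100 samples, feature 0 has 11 missing (11% > 10%), feature 1 has 10 (kept)
        values = np.ones((100, 2))
        missing = np.zeros((100, 2), dtype=bool)
        missing[:11, 0] = True
        missing[:10, 1] = True
        values[missing] = np.nan
        out = oi.filter_and_impute(make_matrix(values, missing))
        assert out.feature_ids == ["f1"]
        # the 10 missing entries were imputed with zero
        assert (out.values[:10, 0] == 0).all()

    def test_clean_feature_retained_unchanged(self):
        values = np.arange(1, 11, dtype=float).reshape(10, 1)
        out = oi.filter_and_impute(make_matrix(values))
        assert np.array_equal(out.values, values)

    def test_imputation_feeds_zero_filter(self):
        # 10 samples: 2 missing + 1 literal zero -> 3/10 zeros post-imputation > 10%
        col = np.array([np.nan, np.nan, 0.0, 1, 2, 3, 4, 5, 6, 7])
        good = np.arange(1, 11, dtype=float)
        values = np.column_stack([col, good])
        out = oi.filter_and_impute(make_matrix(values))
        assert out.feature_ids == ["f1"]

    def test_exactly_ten_percent_retained(self):
        # strict inequality: exactly 10% missing and 10% zeros survives
        col = np.array([np.nan, 1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        out = oi.filter_and_impute(make_matrix(col.reshape(10, 1)))
        assert out.n_features == 1
        assert out.values[0, 0] == 0.0

    def test_idempotent(self, small_cohort):
        mat = small_cohort.omics[Modality.MRNA]
        once = oi.filter_and_impute(mat)
        twice = oi.filter_and_impute(once)
        assert once.feature_ids == twice.feature_ids
        assert np.array_equal(once.values, twice.values)

    def test_all_dropped_errors(self):
        values = np.full((10, 1), np.nan)
        with pytest.raises(ValueError, match="removed"):
            oi.filter_and_impute(make_matrix(values))


def _clinical(ids, subtypes, times=None, status=None):
    df = pd.DataFrame({"PATIENT_ID": ids, "SUBTYPE": subtypes})
    if times is not None:
        df["OS_MONTHS"] = times
        df["OS_STATUS"] = status
    return df


class TestAlignSamples:
    def _mats(self, id_sets):
        mats = []
        for k, (mod, ids) in enumerate(zip(Modality.ordered(), id_sets)):
            rng = np.random.default_rng(k)
            mats.append(make_matrix(rng.normal(size=(len(ids), 3)),
                                    modality=mod, ids=list(ids)))
        return mats

    def test_intersection_and_sort(self):
        shared = [f"S{i}" for i in range(5)]
        mats = self._mats([
            shared + ["EXTRA-A"], shared + ["EXTRA-B"], shared, shared,
        ])
        clin = _clinical(shared + ["EXTRA-A", "EXTRA-B"], ["x"] * 7)
        ds = oi.align_samples(mats, clin)
        assert ds.sample_ids == sorted(shared)
        assert ds.n_samples == 5

    def test_sample_missing_one_modality_excluded(self):
        ids = ["A", "B", "C"]
        mats = self._mats([ids, ids, ids, ["A", "B"]])  # C lacks RPPA
        ds = oi.align_samples(mats, _clinical(ids, ["s1", "s2", "s1"]))
        assert "C" not in ds.sample_ids

    def test_missing_subtype_excluded(self):
        ids = ["A", "B", "C"]
        mats = self._mats([ids] * 4)
        for token in ("", "NA", "[Not Available]"):
            ds = oi.align_samples(mats, _clinical(ids, ["s1", token, "s2"]))
            assert ds.sample_ids == ["A", "C"]

    def test_empty_intersection_errors(self):
        mats = self._mats([["A"], ["B"], ["C"], ["D"]])
        with pytest.raises(ValueError, match="no samples"):
            oi.align_samples(mats, _clinical(["A"], ["s1"]))

    def test_survival_attached_and_status_parsed(self):
        ids = ["A", "B", "C"]
        mats = self._mats([ids] * 4)
        clin = _clinical(ids, ["s1", "s2", "s1"], times=[10.0, 20.0, 5.0],
                         status=["1:DECEASED", "0:LIVING", "DECEASED"])
        ds = oi.align_samples(mats, clin)
        assert list(ds.survival["event"]) == [1, 0, 1]
        assert list(ds.survival["time"]) == [10.0, 20.0, 5.0]


class TestSplits:
    def test_stratified_two_classes_of_five(self, small_cohort):
        from mojknet.datatypes import MultiOmicsDataset
        ids = [f"P{i}" for i in range(10)]
        labels = pd.Series([0] * 5 + [1] * 5, index=ids)
        ds = MultiOmicsDataset(
            omics={}, labels=labels, sample_ids=ids)
        plan = oi.make_splits(ds, n_folds=5, seed=0, stratified=True)
        y = labels.to_numpy()
        for fold in range(5):
            mask = plan.test_mask(fold)
            assert (y[mask] == 0).sum() == 1 and (y[mask] == 1).sum() == 1

    def test_determinism_and_partition(self, small_cohort):
        a = oi.make_splits(small_cohort, n_folds=5, seed=3)
        b = oi.make_splits(small_cohort, n_folds=5, seed=3)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert np.bincount(a.fold_of, minlength=5).sum() == small_cohort.n_samples

    def test_per_fold_class_counts(self):
        from mojknet.datatypes import MultiOmicsDataset
        ids = [f"P{i}" for i in range(60)]
        labels = pd.Series([0] * 30 + [1] * 20 + [2] * 10, index=ids)
        ds = MultiOmicsDataset(omics={}, labels=labels, sample_ids=ids)
        plan = oi.make_splits(ds, n_folds=5, seed=1, stratified=True)
        y = labels.to_numpy()
        for fold in range(5):
            mask = plan.test_mask(fold)
            counts = np.bincount(y[mask], minlength=3)
            assert list(counts) == [6, 4, 2]

    def test_holdout_75_25(self, small_cohort):
        plan = oi.make_splits(small_cohort, seed=0, holdout=True)
        assert plan.kind == "holdout"
        frac = plan.test_mask(1).mean()
        assert abs(frac - 0.25) < 0.05

    def test_too_many_folds_errors(self, small_cohort):
        with pytest.raises(ValueError):
            oi.make_splits(small_cohort, n_folds=1000)


class TestStandardize:
    def test_self_standardization_zero_mean_unit_sd(self, toy_matrix):
        out = oi.standardize_features(toy_matrix, toy_matrix)
        assert np.allclose(out.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0), 1, atol=1e-12)

    def test_constant_feature_maps_to_zero(self):
        values = np.column_stack([np.full(5, 3.0), np.arange(5, dtype=float)])
        mat = OmicsMatrix(modality=Modality.CNA,
                          sample_ids=[f"S{i}" for i in range(5)],
                          feature_ids=["c", "v"], values=values)
        out = oi.standardize_features(mat, mat)
        assert (out.values[:, 0] == 0).all()

    def test_closed_form_zscore(self):
        values = np.array([[1.0], [2.0], [3.0]])
        mat = OmicsMatrix(modality=Modality.CNA, sample_ids=["a", "b", "c"],
                          feature_ids=["f"], values=values)
        out = oi.standardize_features(mat, mat)
        sd = np.sqrt(2.0 / 3.0)  # population sd of (1,2,3)
        assert np.allclose(out.values[:, 0], np.array([-1, 0, 1]) / sd)


class TestBundle:
    def test_round_trip(self, small_cohort, tmp_path):
        oi.write_bundle(small_cohort, tmp_path / "bundle")
        back = oi.read_bundle(tmp_path / "bundle")
        assert back.sample_ids == small_cohort.sample_ids
        assert np.array_equal(back.y, small_cohort.y)
        for mod in small_cohort.omics:
            assert np.allclose(back.omics[mod].values,
                               small_cohort.omics[mod].values)
        assert np.allclose(back.survival["time"], small_cohort.survival["time"])
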