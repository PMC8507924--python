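"""Radiomics features against brute-force oracles and worked examples."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import habitatsurv as hs
from habitatsurv.radiomics import (DEFAULT_OFFSETS, N_FEATURES,
                                   RadiomicsError, feature_names,
                                   glcm_matrix)
from _oracles import glcm_bruteforce


class TestHistogramStats:
    def test_symmetric_sample(self):
        st = hs.histogram_stats([1, 2, 3, 4])
        assert st.mean == pytest.approx(2.5)
        assert st.skewness == pytest.approx(0.0, abs=1e-12)
        # sample SD sqrt(5/3); excess kurtosis of the 4-point uniform grid
        assert st.sd == pytest.approx(1.2909944, abs=1e-6)
        assert st.kurtosis == pytest.approx(-1.36, abs=1e-12)

    def test_constant_sample(self):
        st = hs.histogram_stats([5.0, 5.0, 5.0, 5.0])
        assert st.mean == 5.0
        assert st.sd == 0.0
        assert np.isnan(st.skewness) and np.isnan(st.kurtosis)

    def test_empty_and_tiny_samples(self):
        st = hs.histogram_stats([])
        assert all(np.isnan(x) for x in (st.mean, st.sd, st.skewness,
                                         st.kurtosis))
        st2 = hs.histogram_stats([1.0, 2.0])
        assert np.isfinite(st2.sd)
        assert np.isnan(st2.skewness)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_scipy_moments(self, trial):
        rng = np.random.default_rng(trial)
        v = rng.gamma(2.0, 1.5, size=rng.integers(5, 60))
        st = hs.histogram_stats(v)
        assert st.skewness == pytest.approx(stats.skew(v, bias=True),
                                            abs=1e-12)
        assert st.kurtosis == pytest.approx(
            stats.kurtosis(v, fisher=True, bias=True), abs=1e-12)
        assert st.sd == pytest.approx(float(np.sqrt(
            ((v - v.mean()) ** 2).sum() / (len(v) - 1))), abs=1e-12)


class TestQuantize:
    def test_range_endpoints(self):
        v = np.linspace(0.0, 32.0, 100, endpoint=False)
        lv = hs.quantize_roi(v, 32)
        assert lv[0] == 1
        assert lv[-1] == 32
        assert lv.min() >= 1 and lv.max() <= 32

    def test_constant_roi(self):
        assert np.all(hs.quantize_roi([7.0, 7.0, 7.0], 32) == 1)

    def test_matches_histogram_binning(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 100)
        lv = hs.quantize_roi(v, 4)
        counts = np.bincount(lv, minlength=5)[1:]
        expected, _ = np.histogram(v, bins=4, range=(v.min(), v.max()))
        np.testing.assert_array_equal(counts, expected)

    def test_empty_raises(self):
        with pytest.raises(RadiomicsError):
            hs.quantize_roi([], 4)


class TestGlcm:
    def test_worked_example_single_offset(self):
        """Six horizontal pairs of the 3x3 example, counted symmetrically."""
        img = np.array([[1, 1, 2], [1, 1, 2], [1, 3, 3]])
        mask = np.ones((3, 3), bool)
        feats = hs.glcm_features(img, mask, n_levels=3, offsets=[(0, 1)])
        assert feats.contrast == pytest.approx(1.0)
        assert feats.homogeneity == pytest.approx(13 / 18)
        assert feats.energy == pytest.approx(30 / 144)

    def test_constant_roi(self):
        img = np.ones((4, 4), dtype=np.int64)
        feats = hs.glcm_features(img, np.ones((4, 4), bool), n_levels=1)
        assert feats.contrast == 0.0
        assert feats.homogeneity == pytest.approx(1.0)
        assert feats.energy == pytest.approx(1.0)
        assert feats.correlation == 0.0  # sigma = 0 policy

    def test_offset_sign_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.integers(1, 6, size=(7, 7, 3))
        mask = rng.random((7, 7, 3)) > 0.3
        a = hs.glcm_features(img, mask, 5, offsets=[(0, 1), (1, 1)])
        b = hs.glcm_features(img, mask, 5, offsets=[(0, -1), (-1, -1)])
        assert a == b

    def test_no_valid_pairs(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        feats = hs.glcm_features(np.ones((4, 4), np.int64), mask, 2)
        assert all(np.isnan(x) for x in (feats.contrast, feats.correlation,
                                         feats.energy, feats.homogeneity))

    def test_matrix_is_symmetric_and_normalized(self):
        rng = np.random.default_rng(3)
        img = rng.integers(1, 5, size=(6, 6))
        p = glcm_matrix(img, np.ones((6, 6), bool), 4)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T)

    @pytest.mark.parametrize("trial", range(15))
    def test_bruteforce_oracle(self, trial):
        """Pooled-matrix features equal explicit pair enumeration to 1e-12
        on random masked level images (2-D and thin 3-D)."""
        rng = np.random.default_rng(100 + trial)
        shape = ((rng.integers(3, 8), rng.integers(3, 8))
                 if trial % 2 else
                 (rng.integers(3, 8), rng.integers(3, 8), 2))
        n_levels = int(rng.integers(2, 6))
        img = rng.integers(1, n_levels + 1, size=shape)
        mask = rng.random(shape) > 0.25
        mask.flat[0] = True
        mask.flat[1] = True
        got = hs.glcm_features(img, mask, n_levels, DEFAULT_OFFSETS)
        want = glcm_bruteforce(img, mask, n_levels, DEFAULT_OFFSETS)
        for g, w in zip((got.contrast, got.correlation, got.energy,
                         got.homogeneity), want):
            if np.isnan(w):
                assert np.isnan(g)
            else:
                assert g == pytest.approx(w, abs=1e-12)


class TestVolumes:
    def test_unit_conversion(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        vr = hs.roi_volumes(one_catalog, vols.tumor_mask, vols.voxel_size)
        n = int(vols.tumor_mask.sum())
        assert vr.loc["tumor", "absolute_cm3"] == pytest.approx(n / 1000.0)
        assert vr.loc["tumor", "relative"] == 1.0

    def test_relative_bounds(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        vr = hs.roi_volumes(one_catalog, vols.tumor_mask, vols.voxel_size)
        assert ((vr["relative"] >= 0) & (vr["relative"] <= 1)).all()

    def test_compartments_sum_to_tumor(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        vr = hs.roi_volumes(one_catalog, vols.tumor_mask, vols.voxel_size)
        total = vr.loc[["CE", "non_en", "necrotic"], "absolute_cm3"].sum()
        assert total == pytest.approx(vr.loc["tumor", "absolute_cm3"],
                                      abs=1e-3)

    def test_measured_equals_truth_on_noise_free_phantom(self):
        spec = hs.PhantomSpec(seed=1)
        gm = hs.default_group_model("long")
        gm.noise_sd = {k: 0.0 for k in gm.noise_sd}
        vols, truth = hs.generate_subject(spec, gm, 2718)
        cat = hs.segment_subject(vols, seed=3)
        vr = hs.roi_volumes(cat, vols.tumor_mask, vols.voxel_size)
        assert vr.loc["lmd_lrcbv", "absolute_cm3"] == pytest.approx(
            truth.true_volumes["lmd_lrcbv"])
        assert vr.loc["HMD_LrCBV_nec", "absolute_cm3"] == pytest.approx(
            truth.true_volumes["HMD_LrCBV_nec"])

    def test_empty_tumor_raises(self, one_catalog):
        with pytest.raises(RadiomicsError):
            hs.roi_volumes(one_catalog, np.zeros((64, 64, 64), bool),
                           (1, 1, 1))


class TestExtraction:
    def test_feature_vector_shape_and_names(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        vec = hs.extract_subject_features(vols, one_catalog)
        assert len(vec) == N_FEATURES == 480
        assert vec.index.is_unique
        assert list(vec.index) == feature_names()

    def test_empty_roi_yields_48_missing(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        masks = {k: v.copy() for k, v in one_catalog.masks.items()}
        masks["En_HrCBV"][:] = False
        cat = hs.ROICatalog(masks=masks, voxel_size=one_catalog.voxel_size)
        vec = hs.extract_subject_features(vols, cat)
        en_hr = vec[[n for n in vec.index if n.startswith("En_HrCBV__")]]
        assert len(en_hr) == 48
        assert en_hr.isna().all()
        others = vec[[n for n in vec.index
                      if not n.startswith("En_HrCBV__")]]
        assert others.notna().mean() > 0.9

    def test_determinism(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        a = hs.extract_subject_features(vols, one_catalog)
        b = hs.extract_subject_features(vols, one_catalog)
        pd.testing.assert_series_equal(a, b)

    def test_missing_map_raises(self, one_subject, one_catalog):
        _, _, vols, _ = one_subject
        crippled = hs.SubjectVolumes(
            maps={k: v for k, v in vols.maps.items() if k != "fa"},
            tumor_mask=vols.tumor_mask, nawm_mask=vols.nawm_mask,
            voxel_size=vols.voxel_size)
        with pytest.raises(RadiomicsError, match="fa"):
            hs.extract_subject_features(crippled, one_catalog)


class TestAssembleTable:
    def _vectors(self, data):
        names = [f"f{i}" for i in range(len(data[0]))]
        return [pd.Series(row, index=names, dtype=float) for row in data]

    def test_median_imputation(self):
        vecs = self._vectors([[1, 10], [2, 10], [3, 12], [np.nan, 14]])
        table = hs.assemble_feature_table(vecs, ["short", "long"] * 2)
        # imputed value is the column median 2, then standardized
        filled = table.raw.fillna(table.raw.median())
        assert filled.iloc[3, 0] == pytest.approx(2.0)
        expected = (2.0 - filled["f0"].mean()) / filled["f0"].std(ddof=0)
        assert table.features.iloc[3, 0] == pytest.approx(expected)

    def test_columns_standardized(self, table29):
        means = table29.features.mean(axis=0)
        sds = table29.features.std(axis=0, ddof=0)
        assert np.all(np.abs(means.to_numpy()) < 1e-9)
        assert np.all(np.abs(sds.to_numpy() - 1.0) < 1e-9)

    def test_all_missing_column_dropped(self):
        vecs = self._vectors([[1, np.nan], [2, np.nan], [3, np.nan],
                              [4, np.nan]])
        with pytest.warns(UserWarning, match="all-missing"):
            table = hs.assemble_feature_table(vecs, ["short", "long"] * 2)
        assert table.n_features == 1

    def test_missing_label_raises(self):
        vecs = self._vectors([[1.0], [2.0]])
        with pytest.raises(RadiomicsError):
            hs.assemble_feature_table(vecs, ["short", None])

    def test_inconsistent_names_raise(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(RadiomicsError):
            hs.assemble_feature_table([a, b], ["short", "long"])

    def test_csv_roundtrip(self, tmp_path, table29):
        path = tmp_path / "features.csv"
        table29.to_csv(path)
        loaded = hs.FeatureTable.from_csv(path)
        assert loaded.n_features == table29.n_features
        np.testing.assert_allclose(loaded.features.to_numpy(),
                                   table29.features.to_numpy(), atol=1e-8)
        assert list(loaded.labels) == list(table29.labels)
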