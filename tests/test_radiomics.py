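import numpy as np
import pandas as pd
import pytest

from radgen.maps import MapVolume, VoiMask
from radgen.radiomics import (DIRECTIONS, FIRSTORDER_NAMES, GLCM_BASE,
                              extract_all, extract_feature_matrix,
                              feature_manifest, firstorder_features,
                              glcm_features, glcm_matrix, ngldm_features,
                              per_map_feature_names, quantize, rlm_features,
                              rlm_matrix, szm_features, szm_matrix)


def voi(mask, voi_id="v", min_voxels=1):
    return VoiMask(np.asarray(mask, dtype=bool), voi_id, min_voxels=min_voxels)


class TestQuantize:
    def test_constant_voi_single_level(self):
        q = quantize(np.full((3, 3, 1), 7.0), np.ones((3, 3, 1), bool), ng=32)
        assert set(q.in_mask_codes) == {1}

    def test_identity_coding_for_integer_ramp(self):
        vals = np.arange(32, dtype=float).reshape(4, 4, 2)
        q = quantize(vals, np.ones((4, 4, 2), bool), ng=32)
        assert np.array_equal(np.sort(q.in_mask_codes), np.arange(1, 33))

    def test_histogram_matches_direct_binning_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (6, 6, 4))
        mask = rng.random((6, 6, 4)) < 0.8
        ng = 16
        q = quantize(vals, mask, ng=ng)
        inm = vals[mask]
        edges = np.linspace(inm.min(), inm.max(), ng + 1)
        oracle = np.clip(np.digitize(inm, edges[1:-1], right=False) + 1, 1, ng)
        got = np.bincount(q.in_mask_codes, minlength=ng + 1)
        exp = np.bincount(oracle, minlength=ng + 1)
        assert np.array_equal(got, exp)

    def test_too_small_voi_rejected(self):
        m = np.zeros((2, 2, 1), bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError, match=">= 2"):
            quantize(np.ones((2, 2, 1)), m)


class TestFirstOrder:
    def test_constant_voi_known_vector(self):
        f = firstorder_features(np.full(20, 3.0))
        assert f["stddev"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["entropy"] == 0.0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])
        assert f["mean"] == f["median"] == f["mode"] == 3.0

    def test_two_value_voi_closed_form(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        f = firstorder_features(x)
        assert f["mean"] == 0.5
        assert f["uniformity"] == 0.5
        assert f["entropy"] == 1.0  # two equal bins, bits
        assert f["variance"] == 0.25

    def test_random_voi_matches_direct_formulas(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 3, 500)
        f = firstorder_features(x, voxel_volume=2.0)
        sd = x.std()
        assert np.isclose(f["mean"], x.mean(), atol=1e-10)
        assert np.isclose(f["variance"], x.var(), atol=1e-10)
        assert np.isclose(f["skewness"], ((x - x.mean()) ** 3).mean() / sd ** 3,
                          atol=1e-10)
        assert np.isclose(f["kurtosis"], ((x - x.mean()) ** 4).mean() / sd ** 4,
                          atol=1e-10)
        assert np.isclose(f["energy"], (x ** 2).sum(), atol=1e-8)
        assert np.isclose(f["total_energy"], 2.0 * (x ** 2).sum(), atol=1e-8)
        assert np.isclose(f["rms"], np.sqrt((x ** 2).mean()), atol=1e-10)
        assert np.isclose(f["mad"], np.abs(x - x.mean()).mean(), atol=1e-10)
        assert np.isclose(f["iqr"], np.subtract(*np.percentile(x, [75, 25])),
                          atol=1e-10)
        assert np.isclose(f["cov"], sd / x.mean(), atol=1e-12)
        assert len(f) == 21 and set(f) == set(FIRSTORDER_NAMES)


class TestGlcm:
    def test_hand_counted_toy_matrix(self):
        # codes [[1,1],[2,2]] on a single slice
        codes = np.array([[[1], [1]], [[2], [2]]], dtype=np.int32)
        mask = np.ones((2, 2, 1), bool)
        q = quantize(codes.astype(float), mask, ng=2)
        assert np.array_equal(np.unique(q.codes), [1, 2])
        # x-direction (1,0,0): pairs (1,2) twice -> symmetric counts
        m = glcm_matrix(q, (1, 0, 0))
        assert np.array_equal(m, [[0, 2], [2, 0]])
        # y-direction (0,1,0): pairs (1,1) and (2,2)
        m = glcm_matrix(q, (0, 1, 0))
        assert np.array_equal(m, [[2, 0], [0, 2]])
        # diagonal (1,1,0): one pair (1,2)
        m = glcm_matrix(q, (1, 1, 0))
        assert np.array_equal(m, [[0, 1], [1, 0]])

    def test_constant_voi_degenerate_features(self):
        q = quantize(np.full((3, 3, 2), 5.0), np.ones((3, 3, 2), bool), ng=8)
        f = glcm_features(q)
        assert f["energy_mean"] == 1.0
        assert f["entropy_mean"] == 0.0
        assert f["contrast_mean"] == 0.0
        assert np.isnan(f["correlation_mean"])

    def test_cardinality_and_directional_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (5, 5, 4))
        q = quantize(vals, np.ones((5, 5, 4), bool), ng=8)
        f = glcm_features(q)
        assert len(f) == 168
        for name in GLCM_BASE:
            per_dir = [f[f"{name}_d{d:02d}"] for d in range(1, 14)]
            assert np.isclose(f[f"{name}_mean"], np.mean(per_dir), atol=1e-12)


class TestRlm:
    def test_hand_counted_strip(self):
        # 1D strip of codes 1,1,1,2 along x
        vals = np.array([1.0, 1.0, 1.0, 2.0]).reshape(4, 1, 1)
        mask = np.ones((4, 1, 1), bool)
        q = quantize(vals, mask, ng=2)
        m = rlm_matrix(q, (1, 0, 0))
        assert m[0, 3] == 1  # gray 1, run length 3
        assert m[1, 1] == 1  # gray 2, run length 1
        assert m.sum() == 2

    def test_mask_break_terminates_run(self):
        vals = np.ones((5, 1, 1))
        mask = np.ones((5, 1, 1), bool)
        mask[2] = False
        q = quantize(vals, mask, ng=2)
        m = rlm_matrix(q, (1, 0, 0))
        assert m[0, 2] == 2  # two runs of length 2

    def test_cardinality(self):
        rng = np.random.default_rng(4)
        q = quantize(rng.normal(0, 1, (4, 4, 3)), np.ones((4, 4, 3), bool), ng=8)
        f = rlm_features(q)
        assert len(f) == 90


class TestSzm:
    def test_constant_voi_one_zone(self):
        mask = np.ones((3, 3, 2), bool)
        q = quantize(np.full((3, 3, 2), 1.0), mask, ng=8)
        m = szm_matrix(q.codes, q.mask, q.ng)
        assert m.sum() == 1
        assert m[0, 18] == 1  # single zone of size 18 at gray level 1

    def test_two_disjoint_zones_same_level(self):
        vals = np.zeros((5, 1, 1))
        vals[0] = vals[4] = 1.0
        mask = np.ones((5, 1, 1), bool)
        q = quantize(vals, mask, ng=2)
        m = szm_matrix(q.codes, q.mask, q.ng)
        assert m[1, 1] == 2  # two size-1 zones of the high level
        assert m[0, 3] == 1  # one size-3 zone of the low level

    def test_cardinality(self):
        rng = np.random.default_rng(5)
        q = quantize(rng.normal(0, 1, (4, 4, 3)), np.ones((4, 4, 3), bool), ng=32)
        assert len(szm_features(q)) == 42


class TestNgldm:
    def test_cardinality_and_constant_voi(self):
        q = quantize(np.full((4, 4, 3), 2.0), np.ones((4, 4, 3), bool), ng=8)
        f = ngldm_features(q)
        assert len(f) == 15
        # constant VOI: no gray-level differences -> coarseness indeterminate
        assert np.isnan(f["coarseness_d1"])
        assert f["contrast_d1"] == 0.0


@pytest.fixture(scope="module")
def maps_and_mask():
    rng = np.random.default_rng(6)
    shape = (10, 10, 6)
    mask = np.zeros(shape, bool)
    mask[3:8, 3:8, 2:5] = True
    maps = {k: MapVolume(rng.normal(100, 20, shape), (1, 1, 3), k)
            for k in ("T2w", "ADC1500", "B1500", "Ktrans", "Kep", "ve", "vp")}
    return maps, voi(mask)


class TestExtractAll:
    def test_exactly_2352_features(self, maps_and_mask):
        maps, mask = maps_and_mask
        row = extract_all(maps, mask)
        assert len(row) == 2352
        fams = pd.Series([c.split("|")[1] for c in row.index]).value_counts()
        assert fams["firstorder"] == 21 * 7
        assert fams["glcm"] == 168 * 7
        assert fams["rlm"] == 90 * 7
        assert fams["szm"] == 42 * 7
        assert fams["ngldm"] == 15 * 7
        assert list(row.index) == list(feature_manifest()["column"])

    def test_missing_modality_block_is_nan(self, maps_and_mask):
        maps, mask = maps_and_mask
        partial = dict(maps)
        partial["Kep"] = None
        row = extract_all(partial, mask)
        kep_block = row[[c for c in row.index if c.startswith("Kep|")]]
        assert len(kep_block) == 336 and kep_block.isna().all()
        rest = row[[c for c in row.index if not c.startswith("Kep|")]]
        assert rest.notna().all()

    def test_voxel_permutation_invariance_of_first_order_only(self, maps_and_mask):
        maps, mask = maps_and_mask
        rng = np.random.default_rng(7)
        shuffled = {}
        for k, m in maps.items():
            data = m.data.copy()
            inm = data[mask.mask]
            data[mask.mask] = rng.permutation(inm)
            shuffled[k] = MapVolume(data, m.spacing, k)
        a = extract_all(maps, mask)
        b = extract_all(shuffled, mask)
        fo = [c for c in a.index if "|firstorder|" in c]
        tex = [c for c in a.index if "|firstorder|" not in c]
        pd.testing.assert_series_equal(a[fo], b[fo])
        assert (a[tex] != b[tex]).any()

    def test_empty_mask_rejected(self, maps_and_mask):
        maps, _ = maps_and_mask
        with pytest.raises(ValueError):
            empty = VoiMask(np.zeros((10, 10, 6), bool), "e", min_voxels=0)
            extract_all(maps, empty)
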