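"""Feature bank: local maps vs brute force, descriptors, catalogue counts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from zotrad.features import (DESCRIPTORS, TUMOUR_LOCALS, ZOT_LOCALS,
                             FeatureConfig, FeatureName, compute_local_map,
                             compute_local_maps, generate_catalogue,
                             ratio_feature, summarize_map)

N_BINS = 64


def naive_local_stats(image, mask, radius, n_bins=N_BINS):
    """Per-pixel first-order statistics by plain loops (oracle)."""
    H, W = image.shape
    region = image[mask]
    lo, hi = region.min(), region.max()
    out = {code: [] for code in ZOT_LOCALS}
    for y, x in np.argwhere(mask):
        vals = []
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < H and 0 <= xx < W and mask[yy, xx]:
                    vals.append(image[yy, xx])
        if len(vals) < 4:
            continue
        v = np.asarray(vals, dtype=float)
        m = v.mean()
        m2 = ((v - m) ** 2).mean()
        out["M"].append(m)
        out["V"].append(m2)
        if m2 > 1e-24:
            out["S"].append(((v - m) ** 3).mean() / m2 ** 1.5)
            out["K"].append(((v - m) ** 4).mean() / m2 ** 2)
        else:
            out["S"].append(0.0)
            out["K"].append(0.0)
        out["D"].append(float(np.median(v)))
        out["R"].append(v.max() - v.min())
        out["A"].append(np.abs(v - m).mean())
        out["Q"].append(math.sqrt((v ** 2).mean()))
        if hi > lo:
            idx = np.clip(((v - lo) / (hi - lo) * n_bins).astype(int),
                          0, n_bins - 1)
        else:
            idx = np.zeros(len(v), dtype=int)
        p = np.bincount(idx, minlength=n_bins) / len(v)
        nz = p[p > 0]
        out["E"].append(float(-(nz * np.log2(nz)).sum()))
        out["U"].append(float((nz ** 2).sum()))
    return {k: np.asarray(v) for k, v in out.items()}


class TestLocalMaps:
    def test_constant_region_entropy_zero_uniformity_one(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        maps = compute_local_maps(np.full((12, 12), 5.0), mask, ("E", "U"), 2)
        assert np.allclose(maps["E"], 0.0)
        assert np.allclose(maps["U"], 1.0)

    def test_checkerboard_uniformity_half(self):
        img = np.indices((2, 2)).sum(axis=0) % 2
        maps = compute_local_maps(img.astype(float), np.ones((2, 2), bool),
                                  ("U",), window_radius=1)
        assert np.allclose(maps["U"], 0.5)

    def test_matches_brute_force_recomputation(self, rng):
        """All ten local first-order statistics agree with a plain-loop
        recomputation on a <=100-pixel mask to 1e-10."""
        img = rng.normal(50, 10, size=(14, 14))
        mask = rng.random((14, 14)) < 0.5
        mask[0, :] = False
        oracle = naive_local_stats(img, mask, radius=2)
        maps = compute_local_maps(img, mask, ZOT_LOCALS, window_radius=2)
        for code in ZOT_LOCALS:
            assert np.allclose(maps[code], oracle[code], atol=1e-10), code

    def test_small_neighbourhoods_excluded(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True       # isolated pixel: window holds 1 < 4 pixels
        mask[5:8, 5:8] = True
        maps = compute_local_maps(np.random.default_rng(0).normal(size=(10, 10)),
                                  mask, ("M",), window_radius=1)
        assert len(maps["M"]) == 9  # the isolated pixel is dropped

    def test_full_map_shape_and_nan(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 2:7] = True
        full = compute_local_map(np.ones((10, 10)), mask, "M", 2)
        assert full.shape == (10, 10)
        assert np.isnan(full[0, 0]) and np.isfinite(full[4, 4])


class TestSummarizeMap:
    def test_symmetric_skewness_zero(self):
        assert summarize_map([-2, -1, 0, 1, 2], "s") == pytest.approx(0.0)

    def test_two_value_entropy_one_bit(self):
        assert summarize_map([0.0, 0.0, 1.0, 1.0], "e") == pytest.approx(1.0)

    def test_mean_matches_direct_sum(self, rng):
        v = rng.normal(size=200)
        assert summarize_map(v, "m") == pytest.approx(v.sum() / 200, abs=1e-12)

    def test_too_few_values_missing(self):
        assert np.isnan(summarize_map([1.0, 2.0], "m"))

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40))
    def test_entropy_uniformity_bounds(self, values):
        e = summarize_map(values, "e")
        u = summarize_map(values, "u")
        assert e >= 0.0
        assert 0.0 < u <= 1.0
        if len(set(values)) == 1:
            assert u == 1.0 and e == 0.0

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError):
            summarize_map([1, 2, 3, 4], "zz")


class TestRatioFeature:
    def test_basic(self):
        assert ratio_feature(2.0, 1.0) == 2.0
        assert ratio_feature(3.5, 3.5) == 1.0

    def test_zero_denominator_missing(self):
        assert np.isnan(ratio_feature(1.0, 0.0))

    def test_missing_propagates(self):
        assert np.isnan(ratio_feature(float("nan"), 1.0))


class TestCatalogue:
    def test_cardinalities(self, demo_catalogue):
        assert len(demo_catalogue) == 654
        counts = demo_catalogue.family_counts()
        assert counts["tumour_local_A"] == counts["tumour_local_V"] == 84
        assert counts["zot_local_A"] == counts["zot_local_V"] == 120
        assert counts["zot_global_A"] == counts["zot_global_V"] == 12
        assert counts["ratio"] == 216
        assert counts["size"] == 6

    def test_names_unique_and_canonical(self, demo_catalogue):
        names = list(demo_catalogue.values)
        assert len(set(names)) == 654
        for expected in ("S-s [ZOT,A]", "E-e [T,A]", "U-e [ZOT,V]",
                         "S-s [ZOT,A/V]", "GLOBAL-e [ZOT,V]", "SIZE [T,A/V]"):
            assert expected in names

    def test_order_stable_across_runs(self, demo_case, demo_zot,
                                      demo_catalogue):
        _, arterial, venous, _ = demo_case
        images = {"arterial": arterial, "venous": venous}
        tmasks = {p: demo_zot[p][0] for p in images}
        zmasks = {p: demo_zot[p][1].support for p in images}
        again = generate_catalogue(images, tmasks, zmasks, FeatureConfig())
        assert list(again.values) == list(demo_catalogue.values)

    def test_identical_phases_give_unit_ratios(self, demo_case, demo_zot):
        _, arterial, _, _ = demo_case
        images = {"arterial": arterial, "venous": arterial}
        tmask = demo_zot["arterial"][0]
        zmask = demo_zot["arterial"][1].support
        vec = generate_catalogue(images, {"arterial": tmask, "venous": tmask},
                                 {"arterial": zmask, "venous": zmask},
                                 FeatureConfig())
        ratios = [v for n, v in vec.values.items()
                  if n.endswith("A/V]") and np.isfinite(v)]
        assert len(ratios) >= 200
        assert np.allclose(ratios, 1.0)

    def test_volume_features_and_ratio(self, demo_case):
        _, arterial, venous, _ = demo_case
        tmask_a = np.zeros(arterial.voxels.shape, bool)
        tmask_a[30:40, 30:40] = True          # 100 voxels
        tmask_v = np.zeros_like(tmask_a)
        tmask_v[30:40, 30:35] = True          # 50 voxels
        zmask = np.zeros_like(tmask_a)
        zmask[28:44, 28:44] = True
        vec = generate_catalogue(
            {"arterial": arterial, "venous": venous},
            {"arterial": tmask_a, "venous": tmask_v},
            {"arterial": zmask, "venous": zmask}, FeatureConfig())
        assert vec.values["SIZE [T,A]"] == 100
        assert vec.values["SIZE [T,V]"] == 50
        assert vec.values["SIZE [T,A/V]"] == 2.0

    def test_feature_name_rendering(self):
        assert FeatureName("S", "s", "ZOT", "A").render() == "S-s [ZOT,A]"
        assert FeatureName("SIZE", "", "T", "A/V").render() == "SIZE [T,A/V]"
        assert len(TUMOUR_LOCALS) == 7
        assert len(ZOT_LOCALS) == 10
        assert len(DESCRIPTORS) == 12
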