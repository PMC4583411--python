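"""Feature extraction: scalar gaze properties, histograms, density maps,
the 872-dim concatenation and the mean-value representation."""

import math

import numpy as np
import pytest

from gazevalence.features import (
    BLOCK_SIZES, DEFAULT_SCHEMES, TOTAL_DIMS, BinningScheme, MeanValueFeaturizer,
    SaliencyMap, build_histogram, block_slices, compute_saliency_map,
    extract_features, fixation_duration, fixation_histogram, mean_features,
    saccade_length, saccade_orientation, saccade_slope_angle, saccade_velocity,
    saliency_histogram, top10_salient,
)
from gazevalence.gaze_data import (
    Fixation, GazeRecordset, Saccade, Scanpath, derive_saccades,
)


def fix(x, y, t0, t1, img="i", obs="o"):
    return Fixation(image_id=img, observer_id=obs, x=x, y=y, t_start=t0, t_end=t1)


def sac(x0, y0, x1, y1, t0=0.0, t1=50.0):
    return Saccade(x_start=x0, y_start=y0, x_end=x1, y_end=y1, t_start=t0, t_end=t1)


class TestScalarProperties:
    @pytest.mark.parametrize("t0,t1,expected", [(0, 250, 250), (100, 200, 100)])
    def test_fixation_duration(self, t0, t1, expected):
        assert fixation_duration(fix(0, 0, t0, t1)) == expected

    @pytest.mark.parametrize(
        "s, expected",
        [(sac(0, 0, 3, 4), 5.0), (sac(7, 7, 7, 7), 0.0)],
    )
    def test_saccade_length(self, s, expected):
        assert saccade_length(s) == pytest.approx(expected)

    def test_saccade_length_matches_hypot(self, rng):
        for _ in range(50):
            x0, y0, x1, y1 = rng.uniform(0, 1000, 4)
            assert saccade_length(sac(x0, y0, x1, y1)) == pytest.approx(
                math.hypot(x1 - x0, y1 - y0)
            )

    @pytest.mark.parametrize(
        "dx, dy, expected",
        [(1, 0, 0.0), (0, 5, 90.0), (1, 1, 45.0), (-1, 1, 135.0)],
    )
    def test_slope_angle(self, dx, dy, expected):
        assert saccade_slope_angle(sac(10, 10, 10 + dx, 10 + dy)) == pytest.approx(expected)

    def test_slope_undefined_for_zero_displacement(self):
        assert saccade_slope_angle(sac(5, 5, 5, 5)) is None

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (sac(0, 0, 10, 0), sac(10, 0, 20, 0), 0.0),     # colinear
            (sac(0, 0, 10, 0), sac(10, 0, 0, 0), 180.0),    # reversal
            (sac(0, 0, 10, 0), sac(10, 0, 10, 10), 90.0),   # perpendicular
        ],
    )
    def test_orientation(self, a, b, expected):
        assert saccade_orientation(b, a) == pytest.approx(expected)

    def test_orientation_undefined_for_zero_displacement(self):
        assert saccade_orientation(sac(0, 0, 0, 0), sac(0, 0, 5, 5)) is None

    def test_velocity(self):
        assert saccade_velocity(sac(0, 0, 100, 0, 0, 50)) == pytest.approx(2.0)
        assert saccade_velocity(sac(5, 5, 5, 5, 0, 40)) == 0.0
        assert saccade_velocity(sac(0, 0, 9, 9, 30, 30)) is None


class TestBuildHistogram:
    def test_single_value_lands_in_one_bin(self):
        h = build_histogram([37.0], BinningScheme("p", 10, 0, 100))
        assert h.sum() == pytest.approx(1.0)
        assert (h > 0).sum() == 1

    def test_empty_input_gives_zero_vector(self):
        h = build_histogram([], BinningScheme("p", 8, 0, 1))
        assert h.shape == (8,) and h.sum() == 0

    def test_out_of_range_values_clip_to_end_bins(self):
        scheme = BinningScheme("p", 5, 0, 10)
        h = build_histogram([-50.0, 999.0], scheme, counts=True)
        assert h[0] == 1 and h[-1] == 1

    def test_matches_naive_counting_oracle(self, rng):
        scheme = BinningScheme("p", 23, -5.0, 17.0)
        values = rng.uniform(-10, 25, size=1000)
        # brute force: nearest uniform bin center, per value
        centers = scheme.centers
        naive = np.zeros(23)
        for v in values:
            naive[int(np.argmin(np.abs(centers - np.clip(v, -5.0, 17.0))))] += 1
        naive /= naive.sum()
        np.testing.assert_allclose(build_histogram(values, scheme), naive, atol=1e-12)

    def test_scheme_rejects_bad_ranges(self):
        with pytest.raises(ValueError):
            BinningScheme("p", 0, 0, 1)
        with pytest.raises(ValueError):
            BinningScheme("p", 5, 1.0, 1.0)


class TestSaliencyMap:
    def test_single_fixation_peak_at_its_location(self):
        m = compute_saliency_map([fix(512, 384, 0, 150)], sigma=10)
        r, c = np.unravel_index(np.argmax(m.full_map), m.full_map.shape)
        assert (c, r) == (512, 384)
        assert m.full_map.max() == pytest.approx(1.0)
        assert m.coarse_map.shape == (15, 20)
        assert 0 <= m.coarse_map.min() and m.coarse_map.max() <= 1.0

    def test_two_separated_fixations_give_two_unit_peaks(self):
        m = compute_saliency_map(
            [fix(10, 10, 0, 150), fix(50, 40, 0, 150)],
            sigma=3, width=64, height=48,
        )
        assert m.full_map[10, 10] == pytest.approx(1.0)
        assert m.full_map[40, 50] == pytest.approx(1.0)

    def test_matches_gaussian_sum_oracle_on_small_canvas(self, rng):
        w, h, sigma = 64, 48, 4.0
        fixes = [fix(float(rng.integers(0, w)), float(rng.integers(0, h)), 0, 150)
                 for _ in range(20)]
        m = compute_saliency_map(fixes, sigma=sigma, width=w, height=h)
        yy, xx = np.mgrid[0:h, 0:w]
        oracle = np.zeros((h, w))
        for f in fixes:
            oracle += np.exp(-((xx - int(f.x)) ** 2 + (yy - int(f.y)) ** 2)
                             / (2 * sigma**2))
        oracle /= oracle.max()
        np.testing.assert_allclose(m.full_map, oracle, atol=2e-3)

    def test_no_fixations_is_an_error(self):
        with pytest.raises(ValueError):
            compute_saliency_map([], sigma=10)

    def test_coarse_map_of_uniform_field_is_flat_zero(self):
        # constant coarse map has no spread: min-max convention maps it to 0
        m = SaliencyMap(full_map=np.ones((48, 64)), sigma=3)
        from gazevalence.features import _pool_matrix
        coarse = _pool_matrix(48, 15) @ m.full_map @ _pool_matrix(64, 20).T
        assert np.allclose(coarse, 1.0)  # pooling preserves a constant


class TestSaliencyHistogram:
    def test_single_fixation_mass_in_top_bin(self):
        f = [fix(30, 20, 0, 150)]
        m = compute_saliency_map(f, sigma=3, width=64, height=48)
        h = saliency_histogram(m, f)
        assert h[-1] == pytest.approx(1.0)

    def test_empty_fixations_zero_vector(self):
        m = compute_saliency_map([fix(1, 1, 0, 150)], sigma=3, width=64, height=48)
        assert saliency_histogram(m, []).sum() == 0

    def test_matches_naive_lookup(self, rng):
        fixes = [fix(float(rng.integers(0, 64)), float(rng.integers(0, 48)), 0, 150)
                 for _ in range(40)]
        m = compute_saliency_map(fixes, sigma=3, width=64, height=48)
        vals = [m.full_map[int(f.y), int(f.x)] for f in fixes]
        naive = np.zeros(10)
        for v in vals:
            naive[min(int(v * 10), 9)] += 1
        naive /= naive.sum()
        np.testing.assert_allclose(saliency_histogram(m, fixes), naive, atol=1e-12)


class TestFixationHistogram:
    def test_origin_fixation_in_cell_zero(self):
        h = fixation_histogram([fix(0, 0, 0, 150)])
        assert h[0] == pytest.approx(1.0)

    def test_grid_geometry_1024x768(self):
        # 16x16 grid -> 256 cells of 64x48 px
        h = fixation_histogram([fix(63.9, 47.9, 0, 150)], counts=True)
        assert h.size == 256 and h[0] == 1
        assert fixation_histogram([fix(64, 0, 0, 150)], counts=True)[1] == 1
        assert fixation_histogram([fix(0, 48, 0, 150)], counts=True)[16] == 1

    def test_counts_conserved(self, rng):
        fixes = [fix(float(rng.uniform(0, 1023)), float(rng.uniform(0, 767)), 0, 150)
                 for _ in range(57)]
        assert fixation_histogram(fixes, counts=True).sum() == 57

    def test_matches_integer_division_oracle(self, rng):
        fixes = [fix(float(rng.uniform(0, 1023)), float(rng.uniform(0, 767)), 0, 150)
                 for _ in range(200)]
        naive = np.zeros(256)
        for f in fixes:
            naive[int(f.y // 48) * 16 + int(f.x // 64)] += 1
        naive /= naive.sum()
        np.testing.assert_allclose(fixation_histogram(fixes), naive, atol=1e-12)


class TestTopSalient:
    def test_dominant_peak_extracted_first(self):
        f = [fix(100, 60, 0, 150)] * 3 + [fix(300, 200, 0, 150)]
        m = compute_saliency_map(f, sigma=5, width=400, height=300)
        coords = top10_salient(m)
        assert coords[0] == pytest.approx(100 / 400)
        assert coords[1] == pytest.approx(60 / 300)
        assert np.all((coords >= 0) & (coords <= 1))

    def test_ten_distant_equal_peaks_all_recovered(self):
        w, h, sigma = 200, 100, 2.0
        peaks = [(20 * (k + 1) - 10, 25 if k % 2 else 75) for k in range(10)]
        full = np.zeros((h, w))
        yy, xx = np.mgrid[0:h, 0:w]
        for px, py in peaks:
            full += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * sigma**2))
        full /= full.max()
        m = SaliencyMap(full_map=full, sigma=sigma)
        coords = top10_salient(m)
        got = {(round(coords[2 * k] * w), round(coords[2 * k + 1] * h))
               for k in range(10)}
        assert got == set(peaks)

    def test_constant_map_tie_breaks_to_origin(self):
        m = SaliencyMap(full_map=np.ones((48, 64)), sigma=3)
        coords = top10_salient(m)
        assert coords[0] == 0.0 and coords[1] == 0.0


class TestExtractFeatures:
    def test_dimensionality_and_block_sizes(self, small_recordset):
        img = small_recordset.image_ids[0]
        fv = extract_features(small_recordset.scanpaths_for(img))
        assert len(fv.values) == TOTAL_DIMS == 872
        assert tuple(n for _, n in BLOCK_SIZES) == (300, 20, 256, 10, 60, 60, 30, 50, 50, 36)
        for name, n in BLOCK_SIZES:
            assert fv.blocks[name].size == n

    def test_histogram_blocks_are_probability_masses(self, small_recordset):
        img = small_recordset.image_ids[0]
        fv = extract_features(small_recordset.scanpaths_for(img))
        for name in ("fixation_histogram", "saliency_histogram",
                     "fixation_duration_hist", "saccade_duration_hist",
                     "saccade_slope_hist", "saccade_length_hist",
                     "saccade_velocity_hist", "saccade_orientation_hist"):
            s = fv.blocks[name].sum()
            assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0
            assert (fv.blocks[name] >= 0).all()

    def test_single_fixation_image_zeroes_saccade_blocks(self):
        sp = Scanpath("i", "o", [fix(500, 300, 0, 400)])
        fv = extract_features([sp])
        for name in ("saccade_duration_hist", "saccade_slope_hist",
                     "saccade_length_hist", "saccade_velocity_hist",
                     "saccade_orientation_hist"):
            assert fv.blocks[name].sum() == 0
        assert fv.blocks["fixation_histogram"].sum() == pytest.approx(1.0)

    def test_observer_order_invariance(self, small_recordset):
        img = small_recordset.image_ids[0]
        sps = small_recordset.scanpaths_for(img)
        a = extract_features(sps).values
        b = extract_features(sps[::-1]).values
        np.testing.assert_array_equal(a, b)

    def test_no_fixations_is_an_error(self):
        with pytest.raises(ValueError):
            extract_features([Scanpath("i", "o", [])])


class TestRigidMotionInvariance:
    def _scanpath(self, rng, cx=512, cy=384, r=150):
        t, fixes = 0.0, []
        for _ in range(12):
            ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0, r)
            fixes.append(fix(cx + rad * np.cos(ang), cy + rad * np.sin(ang),
                             t, t + 200))
            t += 250
        return Scanpath("i", "o", fixes)

    @staticmethod
    def _transform(sp, theta, tx, ty, cx=512, cy=384):
        c, s = np.cos(theta), np.sin(theta)
        out = []
        for f in sp.fixations:
            x, y = f.x - cx, f.y - cy
            out.append(fix(c * x - s * y + cx + tx, s * x + c * y + cy + ty,
                           f.t_start, f.t_end))
        return Scanpath("i", "o", out)

    def test_length_and_orientation_invariant_slope_shifts(self, rng):
        theta = np.deg2rad(37.0)
        sp = self._scanpath(rng)
        sp2 = self._transform(sp, theta, 40.0, -25.0)
        sac1, sac2 = derive_saccades(sp), derive_saccades(sp2)
        for a, b in zip(sac1, sac2):
            assert saccade_length(a) == pytest.approx(saccade_length(b))
            expected = (saccade_slope_angle(a) + 37.0) % 180.0
            assert saccade_slope_angle(b) == pytest.approx(expected, abs=1e-6)
        for (a1, a2), (b1, b2) in zip(zip(sac1[1:], sac1[:-1]),
                                      zip(sac2[1:], sac2[:-1])):
            assert saccade_orientation(a1, a2) == pytest.approx(
                saccade_orientation(b1, b2), abs=1e-6
            )


class TestMeanFeatures:
    def _recordset_from_scanpaths(self, groups):
        rs = GazeRecordset()
        for img, sps in groups.items():
            rs.mean_valence[img] = 5.0
            rs.valence_class[img] = "neutral"
            rs.scanpaths.extend(sps)
        return rs

    def test_two_point_min_max(self):
        a = Scanpath("a", "o", [fix(0, 0, 0, 500, img="a"), fix(90, 0, 600, 1100, img="a")])
        b = Scanpath("b", "o", [fix(0, 0, 0, 200, img="b"), fix(30, 0, 300, 500, img="b")])
        mf = mean_features(self._recordset_from_scanpaths({"a": [a], "b": [b]}))
        assert mf.loc["a", "fixation_duration"] == 1.0
        assert mf.loc["b", "fixation_duration"] == 0.0
        assert mf.loc["a", "saccade_length"] == 1.0

    def test_degenerate_constant_feature_maps_to_zero(self):
        a = Scanpath("a", "o", [fix(10, 10, 0, 300, img="a")])
        b = Scanpath("b", "o", [fix(700, 500, 0, 300, img="b")])
        mf = mean_features(self._recordset_from_scanpaths({"a": [a], "b": [b]}))
        assert (mf["fixation_duration"] == 0.0).all()

    def test_single_image_is_an_error(self):
        a = Scanpath("a", "o", [fix(10, 10, 0, 300, img="a")])
        with pytest.raises(ValueError):
            mean_features(self._recordset_from_scanpaths({"a": [a]}))

    def test_matches_naive_min_max(self, small_recordset):
        from gazevalence.features import _raw_mean_features
        raw = _raw_mean_features(small_recordset)
        mf = mean_features(small_recordset)
        for col in raw.columns:
            lo, hi = raw[col].min(), raw[col].max()
            if hi > lo:
                np.testing.assert_allclose(mf[col], (raw[col] - lo) / (hi - lo))

    def test_transformer_clips_held_out_images(self, small_recordset):
        ft = MeanValueFeaturizer().fit(small_recordset)
        out = ft.transform(small_recordset)
        assert ((out >= 0) & (out <= 1)).all().all()
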