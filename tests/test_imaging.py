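import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nephroscope import imaging, simulate
from nephroscope.imaging import (
    AnnotatedImage,
    ParameterError,
    compare_spot_densities,
    detect_spots,
    quantify_niche_profiles,
    rolling_ball_subtract,
    subtract_autofluorescence,
)


class TestRollingBall:
    def test_constant_image_removed(self):
        img = np.full((40, 40), 7.0)
        out = rolling_ball_subtract(img, 3)
        np.testing.assert_allclose(out, 0.0)

    def test_impulse_preserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 9.0
        out = rolling_ball_subtract(img, 3)
        assert out[20, 20] == pytest.approx(9.0)

    def test_slow_background_mostly_removed(self):
        rr, cc = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        background = 20 + 10 * np.sin(rr / 60.0) + 8 * (cc / 128.0)
        rng = np.random.default_rng(0)
        spots = np.zeros((128, 128))
        for r, c in rng.integers(10, 118, (20, 2)):
            spots[r, c] = 50.0
        out = rolling_ball_subtract(background + spots, 5)
        residual = out[spots == 0]
        assert np.sqrt((residual ** 2).mean()) < 0.05 * 38.0

    def test_radius_bounds(self):
        with pytest.raises(ParameterError):
            rolling_ball_subtract(np.zeros((10, 10)), 0)
        with pytest.raises(ParameterError):
            rolling_ball_subtract(np.zeros((10, 10)), 6)


class TestAutofluorescence:
    def test_zero_gfp_identity(self):
        rng = np.random.default_rng(1)
        ch = rng.uniform(0, 10, (30, 30))
        with pytest.warns(UserWarning):
            out, alpha = subtract_autofluorescence(ch, np.zeros((30, 30)))
        np.testing.assert_array_equal(out, ch)
        assert alpha == 0.0

    def test_pure_scaled_gfp_vanishes(self):
        rng = np.random.default_rng(2)
        gfp = rng.uniform(0, 50, (64, 64))
        ch = 0.7 * gfp
        out, alpha = subtract_autofluorescence(ch, gfp)
        assert alpha == pytest.approx(0.7, abs=1e-9)
        assert np.sqrt((out ** 2).mean()) < 1e-6 * np.sqrt((ch ** 2).mean())

    def test_signal_decorrelated_from_gfp_after_subtraction(self):
        rng = np.random.default_rng(3)
        gfp = rng.uniform(5, 50, (96, 96))
        signal = np.zeros((96, 96))
        for r, c in rng.integers(5, 91, (15, 2)):
            signal[r, c] = 200.0
        ch = signal + 0.5 * gfp + rng.normal(0, 1.0, (96, 96)).clip(0)
        out, alpha = subtract_autofluorescence(ch, gfp)
        assert alpha == pytest.approx(0.5, abs=0.05)
        bg = signal == 0
        r = np.corrcoef(out[bg], gfp[bg])[0, 1]
        assert abs(r) < 0.05


class TestDetectSpots:
    def test_blank_image_no_spots(self):
        res = detect_spots(np.zeros((32, 32)), threshold=1.0)
        assert res.n_spots == 0

    def test_area_two_rejected_however_bright(self):
        img = np.zeros((32, 32))
        img[10, 10] = img[10, 11] = 1000.0
        res = detect_spots(img, threshold=10.0, min_area=3)
        assert res.n_spots == 0
        img[10, 12] = 1000.0
        res3 = detect_spots(img, threshold=10.0, min_area=3)
        assert res3.n_spots == 1

    def test_translation_invariance(self):
        spec = simulate.ImageSimSpec(image_size=(96, 96), n_spots=10,
                                     spot_amplitude=10.0, noise_sd=1.0,
                                     background_level=0.0, margin=20, seed=6)
        img, _ = simulate.generate_spot_image(spec)
        roi = np.zeros((96, 96), bool)
        roi[10:86, 10:86] = True
        res = detect_spots(img, roi, threshold=5.0)
        shifted = np.roll(img, (4, -3), axis=(0, 1))
        roi_shifted = np.roll(roi, (4, -3), axis=(0, 1))
        res2 = detect_spots(shifted, roi_shifted, threshold=5.0)
        assert res.n_spots == res2.n_spots
        assert res.density_per_px2 == pytest.approx(res2.density_per_px2)

    def test_matches_brute_force_component_oracle(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 10, (24, 24))
        thr = 7.0
        res = detect_spots(img, threshold=thr, min_area=1, q3_filter=False)
        # brute-force 8-connected labeling by flood fill
        binary = img > thr
        seen = np.zeros_like(binary)
        comps = []
        for r in range(24):
            for c in range(24):
                if binary[r, c] and not seen[r, c]:
                    stack, comp = [(r, c)], []
                    seen[r, c] = True
                    while stack:
                        y, x = stack.pop()
                        comp.append((y, x))
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                yy, xx = y + dy, x + dx
                                if (0 <= yy < 24 and 0 <= xx < 24
                                        and binary[yy, xx] and not seen[yy, xx]):
                                    seen[yy, xx] = True
                                    stack.append((yy, xx))
                    comps.append(comp)
        assert res.n_spots == len(comps)
        got_areas = sorted(res.spots["area_px"])
        assert got_areas == sorted(len(c) for c in comps)

    def test_planted_spots_precision_recall(self):
        spec = simulate.ImageSimSpec(n_spots=50, spot_amplitude=10.0,
                                     noise_sd=1.0, seed=3)
        img, gt = simulate.generate_spot_image(spec)
        sub = rolling_ball_subtract(img, 3)
        res = detect_spots(sub, threshold=5.0, min_area=3)
        det = res.spots[["row", "col"]].to_numpy()
        d = cdist(det, gt.spot_centers)
        precision = (d.min(axis=1) <= 2).mean()
        recall = (d.min(axis=0) <= 2).mean()
        assert precision >= 0.95 and recall >= 0.95

    def test_flat_image_otsu_raises(self):
        with pytest.raises(ParameterError, match="absolute"):
            detect_spots(np.ones((16, 16)))


class TestCompareSpotDensities:
    def test_one_row_per_unordered_pair(self):
        rng = np.random.default_rng(8)
        groups = {g: list(rng.uniform(1, 2, 6)) for g in "abc"}
        out = compare_spot_densities(groups)
        assert len(out) == 3
        assert set(map(tuple, out[["group_a", "group_b"]].to_numpy())) == {
            ("a", "b"), ("a", "c"), ("b", "c")}

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(9)
        out = compare_spot_densities({
            "wt": list(rng.normal(1.0, 0.1, 10)),
            "mut": list(rng.normal(5.0, 0.5, 8)),
        })
        assert (out["adjusted_p"] < 0.05).all()
        assert (out["stars"] != "").all()

    def test_small_group_excluded(self):
        rng = np.random.default_rng(10)
        with pytest.warns(UserWarning, match="excluded"):
            out = compare_spot_densities({
                "a": list(rng.uniform(1, 2, 5)),
                "b": list(rng.uniform(1, 2, 5)),
                "tiny": [1.0, 2.0],
            })
        assert len(out) == 1

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            base = rng.normal(1.0, 0.2, 16)
            out = compare_spot_densities({"a": list(base[:8]), "b": list(base[8:])})
            hits += (out["adjusted_p"] < 0.05).any()
        assert hits / n_runs <= 0.06


class TestNicheProfiles:
    def _gradient_image(self, lam=20.0, noise=0.01, seed=0):
        contour = np.array([[20.0, 10.0], [20.0, 246.0]])
        spec = simulate.ImageSimSpec(image_size=(256, 256), decay_length=lam,
                                     gradient_amplitude=100.0, background_level=0.0,
                                     noise_sd=noise, contour=contour, seed=seed)
        img, _ = simulate.generate_gradient_image(spec)
        return img, contour

    def test_identical_channels_ratio_one(self):
        img, contour = self._gradient_image()
        aimg = AnnotatedImage(channels={"a": img, "b": img.copy()},
                              roi=np.ones((256, 256), bool), ub_contour=contour)
        prof = quantify_niche_profiles(aimg, ("a", "b"), max_d=60)
        ok = ~np.isnan(prof.ratio_profile)
        np.testing.assert_allclose(prof.ratio_profile[ok], 1.0, atol=1e-12)

    def test_uniform_channel_flat_normalized_profile(self):
        img = np.full((128, 128), 5.0)
        contour = np.array([[10.0, 10.0], [10.0, 118.0]])
        aimg = AnnotatedImage(channels={"a": img},
                              roi=np.ones((128, 128), bool), ub_contour=contour)
        prof = quantify_niche_profiles(aimg, ["a"], max_d=40)
        ok = ~np.isnan(prof.d_profile["a"])
        np.testing.assert_allclose(prof.d_profile["a"][ok], 1.0, atol=1e-12)

    def test_exponential_gradient_recovered(self):
        lam = 20.0
        img, contour = self._gradient_image(lam=lam)
        aimg = AnnotatedImage(channels={"a": img},
                              roi=np.ones((256, 256), bool), ub_contour=contour)
        prof = quantify_niche_profiles(aimg, ["a"], max_d=int(3 * lam))
        d = prof.d_bins_px
        got = prof.d_profile["a"]
        ok = ~np.isnan(got)
        rmse = np.sqrt(np.mean((got[ok] - np.exp(-d[ok] / lam)) ** 2))
        assert rmse < 0.05

    def test_s_values_in_unit_interval_and_monotone(self):
        img, contour = self._gradient_image()
        mask = np.ones((256, 256), bool)
        sections = imaging._auto_cross_sections(contour, 30.0, 60, mask)
        s_vals = [s for _, _, s in sections]
        assert all(0 <= s <= 1 for s in s_vals)
        assert s_vals == sorted(s_vals)

    def test_missing_contour_raises(self):
        aimg = AnnotatedImage(channels={"a": np.zeros((32, 32))})
        with pytest.raises(ParameterError):
            quantify_niche_profiles(aimg, ["a"])
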