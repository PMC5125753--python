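"""Maxima detection, Lorentzian sizing, quality filters and population stats."""

import numpy as np
import pytest

import mrnatrack as mt
from mrnatrack import ImageSimParams, ParameterError, StedImage
from mrnatrack import profiler as prof
from mrnatrack.simulate import lorentzian_spot


def image_of(pixels, pixel_size=14.6):
    return StedImage(pixels=np.asarray(pixels, float), pixel_size=pixel_size)


def brute_force_prominence_maxima(img, tol):
    """Independent oracle: union-find persistence over descending pixels.

    A maximum is accepted iff its persistence (peak minus the level at
    which its component merges into one with a higher peak) exceeds tol.
    """
    h, w = img.shape
    order = np.argsort(img.ravel())[::-1]
    parent = np.arange(h * w)
    peak = {}
    active = np.zeros(h * w, bool)
    accepted = []

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx in order:
        y, x = divmod(idx, w)
        roots = set()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and active[ny * w + nx]:
                    roots.add(find(ny * w + nx))
        active[idx] = True
        if not roots:
            peak[idx] = img[y, x]
            continue
        roots = sorted(roots, key=lambda r: peak[r], reverse=True)
        winner = roots[0]
        parent[idx] = winner
        for r in roots[1:]:
            if peak[r] - img[y, x] > tol:
                accepted.append(r)
            parent[r] = winner
    for r in {find(i) for i in np.nonzero(active)[0]}:
        accepted.append(r)
    return {(int(i % w), int(i // w)) for i in accepted}


class TestFindMaxima:
    def test_single_isolated_peak(self):
        img = np.zeros((32, 32))
        img[16, 10] = 50.0
        out = prof.find_maxima(image_of(img), tolerance=2.0, exclude_border=0)
        assert out == [(10, 16)]

    def test_flat_image_no_maxima(self):
        out = prof.find_maxima(image_of(np.full((16, 16), 3.0)), 2.0, exclude_border=0)
        assert out == []

    def test_saddle_tolerance_semantics(self):
        # two peaks (10 and 9) joined by a saddle at 7.5: prominence of the
        # lower peak is 1.5, so tolerance 2 merges it and tolerance 1 keeps it
        img = np.zeros((9, 21))
        img[4, 5] = 10.0
        img[4, 15] = 9.0
        img[4, 6:15] = 7.5
        assert len(prof.find_maxima(image_of(img), 2.0, exclude_border=0)) == 1
        assert len(prof.find_maxima(image_of(img), 1.0, exclude_border=0)) == 2

    def test_matches_brute_force_oracle_on_random_images(self, rng):
        for _ in range(5):
            img = rng.normal(0, 1, (40, 40))
            for tol in (1.0, 2.5):
                mine = set(prof.find_maxima(image_of(img), tol, exclude_border=0))
                oracle = brute_force_prominence_maxima(img, tol)
                assert mine == oracle

    def test_noise_false_positive_rate(self, rng):
        # prominent maxima on pure noise are rare once the tolerance sits
        # well above the noise scale (4 sigma here)
        sd = 1.0
        img = rng.normal(0, sd, (400, 400))
        out = prof.find_maxima(image_of(img), tolerance=4 * sd, exclude_border=0)
        assert len(out) <= max(1, img.size // 100_000)

    def test_border_exclusion(self):
        img = np.zeros((32, 32))
        img[3, 3] = 50.0
        assert prof.find_maxima(image_of(img), 2.0, exclude_border=10) == []

    def test_empty_image_error(self):
        with pytest.raises(ParameterError):
            StedImage(pixels=np.zeros((0, 0)), pixel_size=14.6)


class TestExtractProfiles:
    def test_constant_image(self):
        img = image_of(np.full((40, 40), 5.0))
        px, py = prof.extract_profiles(img, (20, 20))
        assert np.allclose(px, 5.0) and np.allclose(py, 5.0)
        assert px.size == py.size == 21

    def test_vertical_ridge(self):
        arr = np.zeros((40, 40))
        arr[:, 20] = 10.0
        px, py = prof.extract_profiles(image_of(arr), (20, 20), width_px=1)
        assert px[10] == 10.0 and px[0] == 0.0  # peaked across the ridge
        assert np.allclose(py, 10.0)  # flat along it

    def test_separable_lorentzian_matches_generator(self):
        spot = lorentzian_spot((64, 64), 32.0, 32.0, 3.0, 5.0, 40.0)
        px, py = prof.extract_profiles(image_of(spot), (32, 32), radius_px=10, width_px=3)
        xs = np.arange(22, 43, dtype=float)
        lx = 40.0 / (1 + ((xs - 32) / 3.0) ** 2)
        # profile = mean over 3 perpendicular rows of the separable product
        perp = np.mean(1.0 / (1 + ((np.arange(31, 34) - 32) / 5.0) ** 2))
        assert np.allclose(px, lx * perp, rtol=1e-12)

    def test_edge_center_rejected(self):
        with pytest.raises(ParameterError):
            prof.extract_profiles(image_of(np.zeros((40, 40))), (3, 20))


class TestFitLorentzian:
    def test_exact_profile_gives_1168nm(self):
        x = np.arange(21, dtype=float)
        profile = 5.0 + 30.0 / (1 + ((x - 10) / 4.0) ** 2)
        fit = prof.fit_lorentzian(profile, pixel_size=14.6)
        assert fit.fwhm == pytest.approx(116.8, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_pure_noise_low_r2(self):
        n_low = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = prof.fit_lorentzian(rng.normal(5, 1, 21), pixel_size=14.6)
            n_low += fit.r2 < 0.8
        assert n_low >= 95

    def test_noisy_fwhm_bias_below_2pct(self):
        x = np.arange(21, dtype=float)
        truth = 30.0 / (1 + ((x - 10) / 3.0) ** 2)
        fwhms = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fit = prof.fit_lorentzian(truth + rng.normal(0, 0.6, 21), 14.6)
            fwhms.append(fit.fwhm)
        assert abs(np.mean(fwhms) - 2 * 3.0 * 14.6) / (2 * 3.0 * 14.6) < 0.02

    def test_short_profile_rejected(self):
        with pytest.raises(ParameterError):
            prof.fit_lorentzian(np.ones(5), 14.6)


class TestProfileSpot:
    def _spot_image(self, gx, gy, amp=40.0, size=64):
        c = size // 2
        return image_of(lorentzian_spot((size, size), c, c, gx, gy, amp) + 2.0), (c, c)

    def test_symmetric_spot_accepted(self):
        img, c = self._spot_image(4.0, 4.0)
        s = prof.profile_spot(img, c)
        assert s.accepted and s.rejection_reason == "none"
        assert s.diameter == pytest.approx(2 * 4.0 * 14.6, rel=0.02)

    def test_elongated_spot_rejected_axis_ratio(self):
        img, c = self._spot_image(2.0, 5.0)  # FWHM ratio 2.5
        s = prof.profile_spot(img, c)
        assert not s.accepted and s.rejection_reason == "axis_ratio"

    def test_dense_pair_rejected(self):
        arr = lorentzian_spot((64, 64), 30.0, 32.0, 4.0, 4.0, 40.0) \
            + lorentzian_spot((64, 64), 40.0, 32.0, 4.0, 4.0, 40.0)
        img = image_of(arr)
        s = prof.profile_spot(img, (30, 32), all_maxima=[(30, 32), (40, 32)])
        assert s.rejection_reason == "dense"

    def test_edge_spot_flagged(self):
        img, _ = self._spot_image(4.0, 4.0)
        s = prof.profile_spot(img, (5, 32))
        assert s.rejection_reason == "edge"

    def test_rejection_partition_property(self):
        # every spot carries either accepted or exactly one rejection reason
        img, truth = mt.simulate_sted_image(ImageSimParams(
            shape=(256, 256), n_spots=20, seed=13))
        for s in prof.profile_image(img, tolerance=10.0):
            assert s.accepted == (s.rejection_reason == "none")


class TestSummedFluorescence:
    def test_uniform_disc_value(self):
        arr = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        inside = ((xx - 32) / 6) ** 2 + ((yy - 32) / 6) ** 2 <= 1
        arr[inside] = 3.0
        img = image_of(arr)
        spot = mt.SpotFit(x0=32, y0=32)
        spot.fit_x = prof.LorentzianFit(10, 6.0, 3.0, 0.0, 2 * 6 * 14.6, 0.9)
        spot.fit_y = prof.LorentzianFit(10, 6.0, 3.0, 0.0, 2 * 6 * 14.6, 0.9)
        total = prof.summed_fluorescence(img, spot)
        assert total == pytest.approx(3.0 * inside.sum(), rel=1e-9)

    def test_amplitude_linearity(self):
        arr = lorentzian_spot((64, 64), 32.0, 32.0, 4.0, 4.0, 20.0)
        spot = mt.SpotFit(x0=32, y0=32)
        fit = prof.LorentzianFit(10, 4.0, 20.0, 0.0, 2 * 4 * 14.6, 0.99)
        spot.fit_x = spot.fit_y = fit
        v1 = prof.summed_fluorescence(image_of(arr), spot)
        v2 = prof.summed_fluorescence(image_of(2 * arr), spot)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_matches_mask_sum_oracle(self):
        img, _ = mt.simulate_sted_image(ImageSimParams(shape=(128, 128), n_spots=3,
                                                       seed=4, noise_scale=0.0))
        spots = [s for s in prof.profile_image(img, tolerance=10.0) if s.accepted]
        assert spots
        for s in spots:
            ax = s.fit_x.fwhm / 2 / img.pixel_size
            ay = s.fit_y.fwhm / 2 / img.pixel_size
            base = (s.fit_x.baseline + s.fit_y.baseline) / 2
            total = 0.0
            for y in range(128):
                for x in range(128):
                    if ((x - s.x0) / ax) ** 2 + ((y - s.y0) / ay) ** 2 <= 1:
                        total += img.pixels[y, x] - base
            assert s.summed_fluorescence == pytest.approx(total, rel=1e-9)


class TestNearestNeighbour:
    def test_two_points(self):
        assert prof.nearest_neighbour_stats([(0, 0), (10, 0)], 14.6) == pytest.approx(146.0)

    def test_collinear_triplet(self):
        d = prof.nearest_neighbour_stats([(0, 0), (7, 0), (14, 0)], 1.0)
        assert d == pytest.approx(7.0)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 100, (100, 2))
        mine = prof.nearest_neighbour_stats(pts, 14.6)
        dists = []
        for i in range(100):
            best = np.inf
            for j in range(100):
                if i != j:
                    best = min(best, np.hypot(*(pts[i] - pts[j])))
            dists.append(best)
        assert mine == pytest.approx(np.mean(dists) * 14.6, rel=1e-12)

    def test_single_point_error(self):
        with pytest.raises(ParameterError):
            prof.nearest_neighbour_stats([(0, 0)], 14.6)


class TestScaleProperties:
    def test_pixel_size_equivariance(self):
        x = np.arange(21, dtype=float)
        profile = 5.0 + 30.0 / (1 + ((x - 10) / 3.5) ** 2)
        f1 = prof.fit_lorentzian(profile, pixel_size=14.6)
        f2 = prof.fit_lorentzian(profile, pixel_size=29.2)
        assert f2.fwhm == pytest.approx(2 * f1.fwhm, rel=1e-9)

    def test_intensity_invariance_of_size(self):
        img, _ = mt.simulate_sted_image(ImageSimParams(shape=(128, 128), n_spots=3,
                                                       seed=8, noise_scale=0.0))
        s1 = [s for s in prof.profile_image(img, 10.0) if s.accepted]
        img2 = StedImage(pixels=img.pixels * 7.0, pixel_size=img.pixel_size)
        s2 = [s for s in prof.profile_image(img2, 70.0) if s.accepted]
        assert len(s1) == len(s2) > 0
        for a, b in zip(s1, s2):
            assert b.diameter == pytest.approx(a.diameter, rel=1e-6)


class TestPopulationAnalysis:
    def _accepted_spot(self, d, fluor, dist, oocyte):
        s = mt.SpotFit(x0=int(dist * 10), y0=0, accepted=True)
        s.diameter = d
        s.summed_fluorescence = fluor
        s.distance_from_anterior = dist
        s.oocyte_id = oocyte
        return s

    def test_identical_sizes_sem_zero(self, rng):
        spots = [self._accepted_spot(110.0, rng.normal(500, 50), rng.uniform(0, 40),
                                     f"o{i % 4}") for i in range(40)]
        stats = prof.population_analysis(spots)
        assert stats.sem_size == 0.0
        assert stats.size_vs_distance_p > 0.5

    def test_distance_independent_size(self, rng):
        spots = [self._accepted_spot(rng.normal(110, 8), rng.normal(500, 50),
                                     rng.uniform(0, 40), f"o{i % 5}")
                 for i in range(100)]
        stats = prof.population_analysis(spots)
        assert stats.size_vs_distance_p > 0.01

    def test_intensity_proportional_to_distance_detected(self, rng):
        spots = []
        for i in range(100):
            dist = rng.uniform(0, 40)
            spots.append(self._accepted_spot(rng.normal(110, 8),
                                             200 + 20 * dist + rng.normal(0, 30),
                                             dist, f"o{i % 5}"))
        stats = prof.population_analysis(spots)
        assert stats.fluorescence_vs_distance_p < 0.01
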