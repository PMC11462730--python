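"""Elliptical integration: profiles, k-NN, overlap partition, statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from pinklaue.geometry import DetectorModel
from pinklaue.integrate import (
    EllipticalProfile,
    IntegrationError,
    IntegrationParams,
    build_strong_profile,
    fit_background_plane,
    integrate_spot,
    integrate_still,
    knn_weak_profiles,
)
from pinklaue.synthetic import SyntheticConfig, render_image


def _quiet_config(**kw):
    base = dict(background_level=0.0, poisson_noise=False, read_noise=0.0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestBackgroundPlane:
    def test_constant_background(self):
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        a, b, c = fit_background_plane(xs.ravel(), ys.ravel(), np.full(100, 10.0))
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(10.0)

    def test_exact_plane_recovered(self):
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        vals = 0.1 * xs.ravel() + 0.2 * ys.ravel() + 5.0
        a, b, c = fit_background_plane(xs.ravel(), ys.ravel(), vals)
        assert a == pytest.approx(0.1, abs=1e-10)
        assert b == pytest.approx(0.2, abs=1e-10)
        assert c == pytest.approx(5.0, abs=1e-10)

    def test_hot_pixel_clipped(self):
        rng = np.random.default_rng(0)
        xs, ys = np.meshgrid(np.arange(12.0), np.arange(12.0))
        xs, ys = xs.ravel(), ys.ravel()
        vals = 0.1 * xs + 0.2 * ys + 5.0 + rng.normal(0, 0.1, xs.size)
        vals[40] += 1000.0
        a, b, c = fit_background_plane(xs, ys, vals)
        mid = a * 5.5 + b * 5.5 + c
        assert mid == pytest.approx(0.1 * 5.5 + 0.2 * 5.5 + 5.0, rel=0.01)

    def test_collinear_layout_falls_back_to_constant(self):
        xs = np.arange(8.0)
        a, b, c = fit_background_plane(xs, xs, np.full(8, 3.0))
        assert (a, b) == (0.0, 0.0) and c == pytest.approx(3.0)


class TestStrongProfile:
    def test_isotropic_gaussian_second_moments(self, small_detector):
        cfg = _quiet_config(spot_sigma_px=2.0)
        refl = pd.DataFrame({"x_px": [32.0], "y_px": [32.0], "intensity": [1e6]})
        img = render_image(refl, small_detector, cfg)
        prof, flag = build_strong_profile(img, (32.0, 32.0), search_radius_px=10)
        assert flag == ""
        assert np.allclose(np.diag(prof.shape), 4.0, rtol=0.02)
        assert abs(prof.shape[0, 1]) < 0.05

    def test_anisotropic_axis_ratio(self, small_detector):
        cfg = _quiet_config()
        refl = pd.DataFrame(
            {"x_px": [32.0], "y_px": [32.0], "intensity": [1e6],
             "sxx": [1.5**2], "sxy": [0.0], "syy": [3.0**2]}
        )
        img = render_image(refl, small_detector, cfg)
        prof, _ = build_strong_profile(img, (32.0, 32.0), search_radius_px=12)
        evals = np.sort(np.linalg.eigvalsh(prof.shape))
        assert evals[1] / evals[0] == pytest.approx(4.0, rel=0.10)

    def test_rotated_spot_eigenvectors_align(self, small_detector):
        theta = math.radians(30.0)
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        cov = R @ np.diag([1.0, 9.0]) @ R.T
        refl = pd.DataFrame(
            {"x_px": [32.0], "y_px": [32.0], "intensity": [1e6],
             "sxx": [cov[0, 0]], "sxy": [cov[0, 1]], "syy": [cov[1, 1]]}
        )
        img = render_image(refl, small_detector, _quiet_config())
        prof, _ = build_strong_profile(img, (32.0, 32.0), search_radius_px=12)
        _, vecs = np.linalg.eigh(prof.shape)
        major = vecs[:, -1]
        want = R @ np.array([0.0, 1.0])
        angle = math.degrees(math.acos(abs(float(major @ want))))
        assert angle < 5.0

    def test_no_signal_flags_weak_fallback(self, small_detector):
        img = np.zeros((64, 64))
        prof, flag = build_strong_profile(img, (32.0, 32.0))
        assert prof is None and flag == "weak_fallback"


class TestKnnWeakProfiles:
    def _profile(self, x, y, s):
        return EllipticalProfile(center=np.array([x, y]), shape=np.eye(2) * s)

    def test_single_strong_profile_copied(self):
        strong = [self._profile(10, 10, 4.0)]
        out = knn_weak_profiles([[30.0, 30.0]], strong, k=5)
        assert np.allclose(out[0].shape, np.eye(2) * 4.0)
        assert np.allclose(out[0].center, [30.0, 30.0])

    def test_equidistant_pair_averaged(self):
        strong = [self._profile(0, 0, 4.0), self._profile(20, 0, 8.0)]
        out = knn_weak_profiles([[10.0, 0.0]], strong, k=2)
        assert np.allclose(out[0].shape, np.eye(2) * 6.0)

    def test_neighbor_selection_matches_brute_force(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(0, 100, size=(20, 2))
        strong = [self._profile(x, y, 2.0 + i) for i, (x, y) in enumerate(centers)]
        weak = rng.uniform(0, 100, size=(5, 2))
        out = knn_weak_profiles(weak, strong, k=3)
        for w, prof in zip(weak, out):
            order = np.argsort(((centers - w) ** 2).sum(axis=1))[:3]
            want = np.mean([strong[i].shape for i in order], axis=0)
            assert np.allclose(prof.shape, want)

    def test_no_strong_profiles_is_an_error(self):
        with pytest.raises(IntegrationError):
            knn_weak_profiles([[0.0, 0.0]], [], k=3)


class TestIntegrateSpot:
    def test_isolated_spot_pure_poisson_sigma(self):
        # 1000 counts fully inside the foreground on a zero background
        img = np.zeros((40, 40))
        img[19:21, 19:21] = 250.0
        prof = EllipticalProfile(center=np.array([20.0, 20.0]), shape=np.eye(2) * 4.0)
        res = integrate_spot(img, prof)
        assert res.intensity == pytest.approx(1000.0)
        assert res.sigma == pytest.approx(math.sqrt(1000.0))

    def test_uniform_image_pulls_are_standard_normal(self):
        rng = np.random.default_rng(2)
        prof = EllipticalProfile(center=np.array([15.0, 15.0]), shape=np.eye(2) * 4.0)
        pulls = []
        for _ in range(500):
            img = rng.poisson(20.0, size=(30, 30)).astype(float)
            res = integrate_spot(img, prof)
            pulls.append(res.intensity / res.sigma)
        pulls = np.array(pulls)
        assert abs(pulls.mean()) < 0.1
        assert 0.9 < pulls.std() < 1.1

    def test_monte_carlo_bias_and_pull(self, small_detector):
        # 50-replicate version of the unbiasedness check; the acceptance
        # suite runs the full 200-replicate condition
        rng = np.random.default_rng(3)
        cfg = SyntheticConfig(background_level=20.0, read_noise=0.0, spot_sigma_px=1.5)
        gx, gy = np.meshgrid(np.arange(64) + 0.5, np.arange(64) + 0.5)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        biases, pulls = [], []
        for _ in range(50):
            x0, y0 = 32 + rng.uniform(-2, 2), 32 + rng.uniform(-2, 2)
            refl = pd.DataFrame({"x_px": [x0], "y_px": [y0], "intensity": [5000.0]})
            img = render_image(refl, small_detector, cfg, rng=rng)
            prof, _ = build_strong_profile(img, (x0, y0), search_radius_px=8)
            res = integrate_spot(img, prof)
            s2 = cfg.spot_sigma_px**2
            gauss = np.exp(
                -((pts[:, 0] - x0) ** 2 + (pts[:, 1] - y0) ** 2) / (2 * s2)
            ) / (2 * math.pi * s2)
            expected = 5000.0 * gauss[prof.mahalanobis(pts) <= prof.fg_scale].sum()
            biases.append(res.intensity / expected - 1)
            pulls.append((res.intensity - expected) / res.sigma)
        assert abs(np.mean(biases)) < 0.03
        assert 0.8 < np.std(pulls) < 1.2

    def test_insufficient_pixels_flagged(self):
        img = np.ones((10, 10))
        prof = EllipticalProfile(center=np.array([-20.0, -20.0]), shape=np.eye(2))
        res = integrate_spot(img, prof)
        assert not res.ok


class TestIntegrateStill:
    def test_separated_spots_match_independent_integration(self, small_detector):
        cfg = _quiet_config(background_level=5.0, spot_sigma_px=1.2)
        refl = pd.DataFrame(
            {"x_px": [16.0, 48.0], "y_px": [16.0, 48.0],
             "intensity": [4000.0, 6000.0], "strong": [True, True]}
        )
        img = render_image(refl, small_detector, cfg)
        table = integrate_still(img, refl, IntegrationParams())
        for i in range(2):
            prof, _ = build_strong_profile(
                img, (refl.x_px[i], refl.y_px[i]), search_radius_px=8
            )
            solo = integrate_spot(img, prof)
            assert table["intensity"][i] == pytest.approx(solo.intensity, rel=1e-9)
            assert table["n_fg"][i] == solo.n_fg

    def test_overlap_partition_is_perpendicular_bisector(self, small_detector):
        cfg = _quiet_config(background_level=5.0, spot_sigma_px=1.0)
        refl = pd.DataFrame(
            {"x_px": [31.0, 33.0], "y_px": [32.0, 32.0],
             "intensity": [5000.0, 5000.0], "strong": [True, True]}
        )
        img = render_image(refl, small_detector, cfg)
        table = integrate_still(img, refl, IntegrationParams())
        # equal shapes, centroids 2 px apart: the pixel split is symmetric
        assert table["integrated"].all()
        assert abs(int(table["n_fg"][0]) - int(table["n_fg"][1])) <= 2

    def test_no_pixel_double_counting(self, small_detector):
        rng = np.random.default_rng(4)
        xy = rng.uniform(12, 52, size=(8, 2))
        cfg = _quiet_config(background_level=5.0, spot_sigma_px=1.3)
        refl = pd.DataFrame(
            {"x_px": xy[:, 0], "y_px": xy[:, 1],
             "intensity": np.full(8, 5000.0), "strong": True}
        )
        img = render_image(refl, small_detector, cfg)
        table = integrate_still(img, refl, IntegrationParams())
        touched = (
            np.pi * (IntegrationParams().bg_outer_scale
                     * np.sqrt(np.linalg.eigvalsh(np.eye(2) * 9).max())) ** 2 * 8
        )
        assert table["n_fg"].sum() <= 64 * 64
        assert table["n_fg"].sum() <= touched
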