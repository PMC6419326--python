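import numpy as np
import pytest

from leeac.errors import ParameterError
from leeac.preprocess import PatchSpec
from leeac.prob_map import (
    GEODESIC_EPS,
    combine_probability,
    fit_gaussian_models,
    fuse_edge_indicator,
    geodesic_distance,
    minimize_prob,
    pixel_likelihood,
    probability_map,
)


class TestGaussianModels:
    def test_density_peak_at_mean(self, rng):
        img = rng.uniform(0, 255, size=(50, 50, 3))
        model = fit_gaussian_models(img, PatchSpec(0, 0, 20, 20), PatchSpec(30, 30, 20, 20, "background"))
        for ch in range(3):
            sigma = model.sigma[0, ch]
            assert model.density(0, ch, model.mu[0, ch]) == pytest.approx(
                1.0 / (np.sqrt(2 * np.pi) * sigma)
            )

    def test_constant_patch_sigma_floored(self):
        img = np.zeros((40, 40))
        img[20:, :] = 90.0
        model = fit_gaussian_models(
            img, PatchSpec(0, 0, 15, 15), PatchSpec(25, 0, 15, 15, "background")
        )
        assert model.mu[0, 0] == 0.0 and model.mu[1, 0] == 90.0
        assert model.sigma[0, 0] == pytest.approx(1e-3)

    def test_parameter_recovery_from_known_normal(self, rng):
        """10^4 samples from N(120, 15) recover mu and sigma within 1 unit."""
        img = rng.normal(120, 15, size=(100, 100))
        bgp = rng.normal(40, 5, size=(100, 100))
        full = np.vstack([img, bgp])
        model = fit_gaussian_models(
            full, PatchSpec(0, 0, 100, 100), PatchSpec(100, 0, 100, 100, "background")
        )
        assert abs(model.mu[0, 0] - 120) < 1
        assert abs(model.sigma[0, 0] - 15) < 1

    def test_out_of_bounds_patch_rejected(self):
        with pytest.raises(ParameterError):
            fit_gaussian_models(np.zeros((30, 30)), PatchSpec(0, 0, 40, 40), PatchSpec(0, 0, 5, 5))


class TestPixelLikelihood:
    def _model(self):
        img = np.zeros((20, 40, 3))
        img[:, 20:] = 200.0
        return img, fit_gaussian_models(
            img + np.tile(np.arange(3) * 1e-3, (20, 40, 1)),  # tiny spread keeps sigma finite
            PatchSpec(0, 20, 20, 20),
            PatchSpec(0, 0, 20, 20, "background"),
        )

    def test_equal_densities_give_half(self, rng):
        img = rng.uniform(0, 255, size=(10, 10, 3))
        model = fit_gaussian_models(img, PatchSpec(0, 0, 5, 5), PatchSpec(5, 5, 5, 5, "background"))
        # force identical fg/bg models
        model.mu[1] = model.mu[0]
        model.sigma[1] = model.sigma[0]
        p = pixel_likelihood(img, model)
        np.testing.assert_allclose(p, 0.5)

    def test_foreground_mean_pixel_approaches_one(self):
        img, model = self._model()
        p = pixel_likelihood(img, model)
        assert p[0, 30] > 0.999  # at the fg mean, bg density ~ 0
        assert p[0, 5] < 0.001

    def test_channel_weights_average_channel_probabilities(self):
        # channels engineered so per-channel P = (1, 0.5, 0) at the probe pixel
        img = np.zeros((4, 4, 3))
        img[..., 0] = 100.0  # fg channel value
        img[..., 1] = 50.0
        img[..., 2] = 0.0
        mu = np.array([[100.0, 50.0, 100.0], [0.0, 50.0, 0.0]])
        sigma = np.full((2, 3), 5.0)
        from leeac.prob_map import GaussianChannelModel

        model = GaussianChannelModel(mu=mu, sigma=sigma)
        p = pixel_likelihood(img, model, weights=[1 / 3, 1 / 3, 1 / 3])
        assert p[0, 0] == pytest.approx((1.0 + 0.5 + 0.0) / 3, abs=1e-6)

    def test_weight_validation(self, rng):
        img = rng.uniform(0, 255, size=(10, 10, 3))
        model = fit_gaussian_models(img, PatchSpec(0, 0, 5, 5), PatchSpec(5, 5, 5, 5, "background"))
        with pytest.raises(ParameterError):
            pixel_likelihood(img, model, weights=[0.5, 0.5])
        with pytest.raises(ParameterError):
            pixel_likelihood(img, model, weights=[0.5, 0.4, 0.3])

    def test_two_label_normalization(self, rng):
        """P_F + P_B = 1 pixelwise by the ratio construction."""
        img = rng.uniform(0, 255, size=(12, 12, 3))
        model = fit_gaussian_models(img, PatchSpec(0, 0, 6, 6), PatchSpec(6, 6, 6, 6, "background"))
        p_f = pixel_likelihood(img, model)
        # swapping labels gives the complement
        from leeac.prob_map import GaussianChannelModel

        swapped = GaussianChannelModel(mu=model.mu[::-1].copy(), sigma=model.sigma[::-1].copy())
        p_b = pixel_likelihood(img, swapped)
        np.testing.assert_allclose(p_f + p_b, 1.0, atol=1e-12)


def _bellman_ford_oracle(p, seed_mask, eps=GEODESIC_EPS):
    """Independent all-paths relaxation on the 8-connected grid graph."""
    h, w = p.shape
    dist = np.where(seed_mask, 0.0, np.inf)
    moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    changed = True
    while changed:
        changed = False
        for i in range(h):
            for j in range(w):
                for dr, dc in moves:
                    ni, nj = i + dr, j + dc
                    if 0 <= ni < h and 0 <= nj < w:
                        step = np.sqrt(2.0) if dr and dc else 1.0
                        cand = dist[ni, nj] + abs(p[i, j] - p[ni, nj]) + eps * step
                        if cand < dist[i, j] - 1e-15:
                            dist[i, j] = cand
                            changed = True
    return dist


class TestGeodesicDistance:
    def test_zero_on_seed_pixels(self, rng):
        p = rng.random((10, 10))
        d = geodesic_distance(p, PatchSpec(2, 3, 3, 4))
        assert d[2:5, 3:7].max() == 0.0

    def test_constant_field_distance_is_epsilon_hop_count(self):
        p = np.full((7, 7), 0.4)
        d = geodesic_distance(p, PatchSpec(0, 0, 1, 1))
        # diagonal-first shortest paths: chebyshev steps with diagonal length
        assert d[0, 3] == pytest.approx(3 * GEODESIC_EPS, rel=1e-9)
        assert d[3, 3] == pytest.approx(3 * np.sqrt(2) * GEODESIC_EPS, rel=1e-9)

    def test_matches_bellman_ford_oracle_on_random_fields(self, rng):
        for _ in range(20):
            p = rng.random((12, 12))
            seed = np.zeros((12, 12), dtype=bool)
            seed[tuple(rng.integers(0, 12, 2))] = True
            ours = geodesic_distance(p, seed)
            oracle = _bellman_ford_oracle(p, seed)
            np.testing.assert_allclose(ours, oracle, rtol=0, atol=1e-12)

    def test_monotone_in_edge_cost(self, rng):
        p = rng.random((10, 10))
        p[5, 5] = p[4:7, 4:7].max()  # local maximum: a bump raises every incident cost
        seed = np.zeros((10, 10), dtype=bool)
        seed[0, 0] = True
        base = geodesic_distance(p, seed)
        bumped = p.copy()
        bumped[5, 5] += 0.5
        after = geodesic_distance(bumped, seed)
        assert np.all(after >= base - 1e-12)

    def test_empty_seed_rejected(self):
        with pytest.raises(ParameterError):
            geodesic_distance(np.zeros((5, 5)), np.zeros((5, 5), dtype=bool))


class TestCombineAndMinimize:
    def test_patch_pixels_get_extreme_probabilities(self):
        p = np.full((6, 6), 0.5)
        d_f = np.ones((6, 6))
        d_b = np.ones((6, 6))
        d_f[1, 1] = 0.0  # foreground patch pixel
        d_b[4, 4] = 0.0
        s = combine_probability(p, d_f, d_b)
        assert s[1, 1] == 1.0
        assert s[4, 4] == 0.0
        assert s[2, 2] == 0.5  # tie

    def test_both_zero_falls_back_to_color_probability(self):
        p = np.full((3, 3), 0.37)
        z = np.zeros((3, 3))
        np.testing.assert_allclose(combine_probability(p, z, z), 0.37)

    def test_minimize_prob_analytic_points(self):
        s = np.array([[0.7, 0.2, 0.0]])
        np.testing.assert_allclose(minimize_prob(s), [[0.0, 0.5, 0.98]], atol=1e-15)

    def test_minimize_prob_center_validation(self):
        with pytest.raises(ParameterError):
            minimize_prob(np.zeros((2, 2)), center=1.0)

    def test_generic_center_half(self):
        assert minimize_prob(np.array([[0.0]]), center=0.5)[0, 0] == pytest.approx(0.5)


class TestFuseEdgeIndicator:
    def test_multiplicative_fusion(self, rng):
        g = rng.random((5, 5))
        prob = rng.random((5, 5))
        np.testing.assert_allclose(fuse_edge_indicator(g, prob), g * prob)

    def test_prob_one_is_identity_and_zero_annihilates(self, rng):
        g = rng.random((4, 4))
        np.testing.assert_array_equal(fuse_edge_indicator(g, np.ones_like(g)), g)
        assert fuse_edge_indicator(g, np.zeros_like(g)).max() == 0.0

    def test_threshold_floors_weak_edges_to_zero(self):
        g = np.array([[1.0, 1.0], [1.0, 1.0]])
        prob = np.array([[0.001, 0.5], [0.9, 0.2]])
        out = fuse_edge_indicator(g, prob, edge_threshold=0.05)
        assert out[0, 0] == 0.0 and out[0, 1] == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            fuse_edge_indicator(np.zeros((3, 3)), np.zeros((4, 4)))


class TestProbabilityMapEndToEnd:
    def test_two_region_image_recovered_by_s_threshold(self, rng):
        """Well-separated Gaussian colors: s > 0.5 recovers the true labels."""
        truth = np.zeros((60, 60), dtype=bool)
        truth[15:45, 15:45] = True
        img = np.where(truth[..., None], 80.0, 180.0) + rng.normal(0, 5, (60, 60, 1))
        img = np.clip(np.repeat(img, 3, axis=2), 0, 255)
        fg = PatchSpec(25, 25, 10, 10)
        bg = PatchSpec(0, 0, 10, 10, "background")
        fields = probability_map(img, fg, bg)
        acc = ((fields["s"] > 0.5) == truth).mean()
        assert acc >= 0.99
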