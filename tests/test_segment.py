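"""Intensity mixture fitting, adaptive thresholding, region growing."""

import numpy as np
import pytest
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from vasomap import segment
from vasomap.segment import (
    IntensityModel,
    adaptive_refine,
    evaluate_segmentation,
    fit_intensity_model,
    generate_seeds,
    initial_segmentation,
    region_grow_3d,
    segment_volume,
)


def _mixture_volume(frac=0.02, mu_b=200, mu_o=100, sd=10, shape=(40, 40, 40), seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.random(shape) < frac
    vol = np.where(labels, rng.normal(mu_b, sd, shape), rng.normal(mu_o, sd, shape))
    return vol, labels


class TestIntensityModel:
    def test_parameter_recovery(self):
        vol, _ = _mixture_volume(frac=0.3)
        m = fit_intensity_model(vol)
        assert m.mu_b == pytest.approx(200, abs=2)
        assert m.mu_o == pytest.approx(100, abs=2)

    def test_weight_recovery_on_sparse_vessels(self):
        vol, labels = _mixture_volume(frac=0.02, seed=1)
        m = fit_intensity_model(vol)
        assert m.weight_b == pytest.approx(labels.mean(), abs=0.01)

    def test_bright_component_always_reported_as_vessels(self):
        vol, _ = _mixture_volume(frac=0.7, seed=2)  # bright class is majority
        m = fit_intensity_model(vol)
        assert m.mu_b > m.mu_o

    def test_loglikelihood_nondecreasing(self):
        vol, _ = _mixture_volume(seed=3)
        m = fit_intensity_model(vol)
        assert len(m.log_likelihood) >= 2
        assert np.all(np.diff(m.log_likelihood) >= -1e-9)

    def test_agrees_with_reference_em(self):
        # independent route: sklearn's EM on the same samples
        vol, _ = _mixture_volume(frac=0.3, seed=4)
        m = fit_intensity_model(vol)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(vol.reshape(-1, 1))
        mus = np.sort(gm.means_.ravel())
        assert m.mu_o == pytest.approx(mus[0], abs=1.0)
        assert m.mu_b == pytest.approx(mus[1], abs=1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fit_intensity_model(np.full((10, 10, 10), 7.0))

    def test_inverted_model_rejected(self):
        with pytest.raises(ValueError):
            IntensityModel(mu_b=100, mu_o=200, sigma_b=1, sigma_o=1, weight_b=0.5)


class TestInitialSegmentation:
    def test_equal_variance_boundary_at_midpoint(self):
        m = IntensityModel(mu_b=200, mu_o=100, sigma_b=10, sigma_o=10, weight_b=0.5)
        vol = np.array([[[149.9, 150.1]]])
        out = initial_segmentation(vol, m)
        assert out.tolist() == [[[False, True]]]

    def test_noiseless_phantom_exact(self, noiseless_phantom):
        m = fit_intensity_model(noiseless_phantom.intensities)
        mask = initial_segmentation(noiseless_phantom.intensities, m)
        assert np.array_equal(mask, noiseless_phantom.truth_mask)

    def test_error_rate_bounded_by_gaussian_overlap(self):
        # separation 100, SD 10: misclassification is governed by the
        # Gaussian tail beyond the midpoint, ~Phi(-5) per class
        vol, labels = _mixture_volume(frac=0.02, sd=10, seed=5)
        m = fit_intensity_model(vol)
        pred = initial_segmentation(vol, m)
        assert (pred != labels).mean() <= 1e-3


class TestAdaptiveRefine:
    def test_local_threshold_is_midpoint(self, noisy_phantom):
        m = fit_intensity_model(noisy_phantom.intensities)
        init = initial_segmentation(noisy_phantom.intensities, m)
        _, recs = adaptive_refine(noisy_phantom.intensities, init)
        done = [r for r in recs if not r["skipped"]]
        assert done
        for r in done:
            assert r["threshold"] == pytest.approx(0.5 * (r["mu_b"] + r["mu_o"]))
            assert r["mu_o"] < r["threshold"] < r["mu_b"]

    def test_refined_superset_of_initial(self, noisy_phantom):
        m = fit_intensity_model(noisy_phantom.intensities)
        init = initial_segmentation(noisy_phantom.intensities, m)
        refined, _ = adaptive_refine(noisy_phantom.intensities, init)
        assert not (init & ~refined).any()

    def test_noiseless_refinement_is_identity(self, noiseless_phantom):
        m = fit_intensity_model(noiseless_phantom.intensities)
        init = initial_segmentation(noiseless_phantom.intensities, m)
        refined, _ = adaptive_refine(noiseless_phantom.intensities, init)
        assert np.array_equal(refined, init)

    def test_recovers_faint_thin_branch(self):
        # a faint thin vessel below the global decision boundary but above
        # the local window threshold must be at least half recovered
        shape = (30, 40, 40)
        rng = np.random.default_rng(6)
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        thick = (yy - 20) ** 2 + (xx - 14) ** 2 <= 16
        thin = (np.abs(yy - 20) < 1) & (np.abs(xx - 26) < 1)
        vol = np.full(shape, 100.0)
        vol[thick] = 200.0
        vol[thin] = 152.0
        vol += rng.normal(0, 2, shape)
        model = IntensityModel(mu_b=200, mu_o=100, sigma_b=10, sigma_o=10, weight_b=0.02)
        init = initial_segmentation(vol, model)
        assert init[thin].mean() < 0.5  # mostly missed initially
        refined, _ = adaptive_refine(vol, init)
        assert refined[thin].mean() >= 0.5


class TestSeeds:
    def test_noiseless_seeds_equal_truth(self, noiseless_phantom):
        res = segment_volume(noiseless_phantom.intensities)
        seeds = set(map(tuple, res.seeds))
        truth = set(map(tuple, np.argwhere(noiseless_phantom.truth_mask)))
        assert seeds == truth

    def test_empty_refined_mask_gives_no_seeds(self):
        vol = np.zeros((8, 8, 8))
        seeds = generate_seeds(vol, np.zeros((8, 8, 8), bool), [])
        assert len(seeds) == 0

    def test_bright_isolated_voxel_becomes_seed(self):
        vol = np.full((5, 20, 20), 100.0)
        mask = np.zeros(vol.shape, bool)
        mask[2, 10, 5] = True  # an in-mask component
        vol[2, 10, 5] = 200.0
        vol[2, 10, 12] = 180.0  # bright outlier inside the search window
        refined, recs = adaptive_refine(vol, mask, window_growth=10.0)
        seeds = generate_seeds(vol, mask, recs)
        assert (2, 10, 12) in set(map(tuple, seeds))


class TestRegionGrowing:
    @staticmethod
    def _naive_bfs(volume, seeds, threshold):
        """Queue-based flood fill oracle over 26-neighborhoods."""
        from collections import deque

        accept = volume > threshold
        visited = np.zeros(volume.shape, bool)
        q = deque()
        for s in map(tuple, seeds):
            if not visited[s]:
                visited[s] = True
                q.append(s)
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if any(c < 0 or c >= s for c, s in zip(n, volume.shape)):
                    continue
                if accept[n] and not visited[n]:
                    visited[n] = True
                    q.append(n)
        return visited

    def test_growth_respects_connectivity(self):
        vol = np.full((10, 20, 20), 100.0)
        vol[:, 5:8, 5:8] = 200.0
        vol[:, 12:15, 12:15] = 200.0
        m = IntensityModel(mu_b=200, mu_o=100, sigma_b=5, sigma_o=5, weight_b=0.1)
        seeds = np.array([[0, 6, 6]])
        final = region_grow_3d(vol, seeds, m)
        assert final[:, 5:8, 5:8].all()
        assert not final[:, 12:15, 12:15].any()

    def test_seeds_in_both_tubes_recover_truth(self, noiseless_phantom):
        m = fit_intensity_model(noiseless_phantom.intensities)
        seeds = np.argwhere(noiseless_phantom.truth_mask)
        final = region_grow_3d(noiseless_phantom.intensities, seeds, m)
        assert np.array_equal(final, noiseless_phantom.truth_mask)

    def test_matches_naive_flood_fill(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            vol = rng.normal(100, 40, (20, 20, 20))
            m = IntensityModel(mu_b=160, mu_o=80, sigma_b=10, sigma_o=10, weight_b=0.3)
            seed_idx = np.argwhere(vol > 150)[:3]
            if len(seed_idx) == 0:
                continue
            fast = region_grow_3d(vol, seed_idx, m, min_component_size=1)
            slow = self._naive_bfs(vol, seed_idx, m.threshold)
            assert np.array_equal(fast, slow)

    def test_min_component_size_filter(self):
        vol = np.full((8, 8, 8), 100.0)
        vol[4, 4, 4] = 200.0  # isolated single bright voxel
        m = IntensityModel(mu_b=200, mu_o=100, sigma_b=5, sigma_o=5, weight_b=0.1)
        final = region_grow_3d(vol, np.array([[4, 4, 4]]), m, min_component_size=5)
        assert not final.any()

    def test_requires_seeds(self):
        m = IntensityModel(mu_b=2, mu_o=1, sigma_b=1, sigma_o=1, weight_b=0.5)
        with pytest.raises(ValueError):
            region_grow_3d(np.zeros((4, 4, 4)), np.empty((0, 3)), m)


class TestEvaluate:
    def test_identity_is_perfect(self):
        t = np.zeros((6, 6, 6), bool)
        t[2:4, 2:4, 2:4] = True
        m = evaluate_segmentation(t, t)
        assert m == {"dice": 100.0, "sensitivity": 100.0, "specificity": 100.0}

    def test_complement_has_zero_dice(self):
        t = np.zeros((6, 6, 6), bool)
        t[2:4, 2:4, 2:4] = True
        assert evaluate_segmentation(~t, t)["dice"] == 0.0

    def test_hand_computed_overlap(self):
        truth = np.zeros(200, bool)
        truth[:100] = True
        pred = np.zeros(200, bool)
        pred[40:120] = True  # |P|=80, |P∩T|=60
        m = evaluate_segmentation(pred.reshape(8, 5, 5), truth.reshape(8, 5, 5))
        assert m["dice"] == pytest.approx(66.67, abs=0.01)  # 2·60 / (80 + 100)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))


class TestFullChain:
    def test_monotone_masks_and_determinism(self, noisy_phantom):
        a = segment_volume(noisy_phantom.intensities)
        b = segment_volume(noisy_phantom.intensities)
        assert not (a.initial_mask & ~a.refined_mask).any()
        assert np.array_equal(a.final_mask, b.final_mask)

    def test_noiseless_chain_exact(self, noiseless_phantom):
        res = segment_volume(noiseless_phantom.intensities)
        assert np.array_equal(res.final_mask, noiseless_phantom.truth_mask)
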