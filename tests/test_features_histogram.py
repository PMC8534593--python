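"""Histogram computation and the four-Gaussian fit, checked against
brute-force tallies, grid-search least squares, and generative recovery."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from busecho import phantom
from busecho.features_histogram import (
    Histogram,
    HistogramModel,
    compute_histogram,
    extract_features,
    fit_four_gaussians,
    fit_gaussian_curve,
    gaussian_mixture_curve,
)


class TestComputeHistogram:
    def test_constant_image_is_delta(self):
        h = compute_histogram(np.full((10, 10), 7, dtype=np.uint8))
        assert h.counts[7] == 1.0 and h.counts.sum() == 1.0

    def test_checkerboard_splits_mass(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255
        h = compute_histogram(img.astype(np.uint8))
        assert h.counts[0] == 0.5 and h.counts[255] == 0.5

    def test_matches_brute_force_tally(self, benign_params):
        img, _ = phantom.generate_phantom(benign_params)
        h = compute_histogram(img)
        tally = np.zeros(256)
        for v in img.ravel():  # independent pixel-by-pixel oracle
            tally[v] += 1
        np.testing.assert_allclose(h.counts, tally / tally.sum(), atol=1e-12)
        assert h.counts.sum() == pytest.approx(1.0, abs=1e-9)

    def test_region_restriction(self, benign_params):
        img, mask = phantom.generate_phantom(benign_params)
        h = compute_histogram(img, mask == 255)
        lesion_pixels = img[mask == 255]
        assert h.counts.argmax() == np.bincount(lesion_pixels).argmax()

    def test_empty_region_rejected(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        with pytest.raises(ValueError):
            compute_histogram(img, np.zeros((8, 8), dtype=bool))


def _grid_search_residual(counts: np.ndarray) -> float:
    """Exhaustive coarse-lattice least squares: choose 4 means from a candidate
    set and a shared width, solve amplitudes by non-negative least squares."""
    bins = np.arange(256.0)
    best = np.inf
    mean_candidates = np.linspace(16, 240, 8)
    for means in itertools.combinations(mean_candidates, 4):
        for sigma in (10.0, 20.0, 40.0, 80.0, 160.0):
            design = np.exp(-((bins[:, None] - np.array(means)) ** 2)
                            / (2 * sigma ** 2))
            amps, _ = nnls(design, counts)
            resid = float(np.sum((design @ amps - counts) ** 2))
            best = min(best, resid)
    return best


class TestFitFourGaussians:
    def test_recovers_well_separated_truth(self):
        truth = np.array([[0.01, 30, 6], [0.02, 95, 8], [0.015, 160, 7],
                          [0.01, 220, 5]])
        counts = gaussian_mixture_curve(truth.ravel(), np.arange(256.0))
        model = fit_four_gaussians(Histogram(counts / counts.sum()), seed=0)
        # fit of the normalized curve keeps means/widths, scales amplitudes
        np.testing.assert_allclose(model.means, truth[:, 1], atol=1.0)
        np.testing.assert_allclose(model.widths, truth[:, 2], rtol=0.15)

    def test_recovery_from_mixture_image(self):
        comps = np.array([[1, 40, 6], [1, 110, 8], [1, 170, 7], [1, 230, 5]])
        img = phantom.generate_mixture_image(comps, n_pixels=65536, seed=4)
        model = fit_four_gaussians(compute_histogram(img), seed=0)
        np.testing.assert_allclose(np.sort(model.means), comps[:, 1], atol=1.0)

    def test_recovery_error_shrinks_with_more_pixels(self):
        comps = np.array([[1, 40, 6], [1, 110, 8], [1, 170, 7], [1, 230, 5]])
        errs = []
        for n_pixels in (2048, 65536):
            per_seed = []
            for seed in (0, 1, 2):
                img = phantom.generate_mixture_image(comps, n_pixels, seed=seed)
                model = fit_four_gaussians(compute_histogram(img), seed=0)
                per_seed.append(np.abs(np.sort(model.means) - comps[:, 1]).mean())
            errs.append(np.mean(per_seed))
        assert errs[1] <= errs[0]

    def test_beats_grid_search_on_uniform_histogram(self):
        counts = np.full(256, 1.0 / 256)
        model = fit_four_gaussians(Histogram(counts), seed=0)
        assert model.residual <= _grid_search_residual(counts) + 1e-12

    def test_beats_grid_search_on_phantom_histogram(self, benign_params):
        img, _ = phantom.generate_phantom(benign_params)
        h = compute_histogram(img)
        model = fit_four_gaussians(h, seed=0)
        assert model.residual <= _grid_search_residual(h.counts) + 1e-12

    def test_components_sorted_by_mean(self):
        scrambled = np.array([[1, 200, 5], [2, 10, 5], [3, 120, 5], [4, 60, 5]])
        model = HistogramModel(components=scrambled, residual=0.0)
        assert np.all(np.diff(model.means) >= 0)

    def test_deterministic_given_seed(self, benign_params):
        img, _ = phantom.generate_phantom(benign_params)
        h = compute_histogram(img)
        a = fit_four_gaussians(h, seed=7)
        b = fit_four_gaussians(h, seed=7)
        np.testing.assert_array_equal(a.components, b.components)

    def test_scale_equivariance(self):
        truth = np.array([[0.01, 50, 8], [0.02, 140, 10], [0.005, 200, 6],
                          [0.008, 90, 7]])
        counts = gaussian_mixture_curve(truth.ravel(), np.arange(256.0))
        base = fit_gaussian_curve(counts, seed=0)
        scaled = fit_gaussian_curve(counts * 10.0, seed=0)
        np.testing.assert_allclose(scaled.means, base.means, atol=0.1)
        np.testing.assert_allclose(scaled.widths, base.widths, rtol=0.02)
        np.testing.assert_allclose(scaled.amplitudes, base.amplitudes * 10.0,
                                   rtol=0.02)


class TestExtractFeatures:
    def test_means_projection(self):
        model = HistogramModel(
            components=np.array([[1, 30, 5], [1, 90, 5], [1, 150, 5], [1, 210, 5]]),
            residual=0.0)
        np.testing.assert_array_equal(extract_features(model), [30, 90, 150, 210])

    def test_identical_histograms_identical_features(self, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        h1, h2 = compute_histogram(img), compute_histogram(img.copy())
        f1 = extract_features(fit_four_gaussians(h1, seed=1))
        f2 = extract_features(fit_four_gaussians(h2, seed=1))
        np.testing.assert_array_equal(f1, f2)

    def test_alternative_schemes_and_errors(self):
        model = HistogramModel(
            components=np.array([[1, 30, 5], [2, 90, 6], [3, 150, 7], [4, 210, 8]]),
            residual=0.0)
        np.testing.assert_array_equal(extract_features(model, "amplitudes"),
                                      [1, 2, 3, 4])
        np.testing.assert_array_equal(extract_features(model, "widths"),
                                      [5, 6, 7, 8])
        np.testing.assert_array_equal(
            extract_features(model, lambda m: m.means / 2), [15, 45, 75, 105])
        with pytest.raises(ValueError):
            extract_features(model, "bogus")
        with pytest.raises(ValueError):
            extract_features(model, lambda m: m.means[:2])

    def test_lesion_classes_shift_feature_distribution(self):
        """Benign lesions add low-intensity mass; the lowest fitted mean drops."""
        def lowest_mean(class_label, seed):
            if class_label == phantom.NORMAL:
                params = phantom.PhantomParams(class_label=class_label, seed=seed)
            else:
                params = phantom.PhantomParams(
                    class_label=class_label, lesion_axes=(40.0, 30.0), seed=seed)
            img, _ = phantom.generate_phantom(params)
            model = fit_four_gaussians(compute_histogram(img), seed=0)
            return model.means[0]

        normal = [lowest_mean(phantom.NORMAL, s) for s in range(3)]
        benign = [lowest_mean(phantom.BENIGN, s) for s in range(3)]
        assert np.mean(benign) < np.mean(normal)
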