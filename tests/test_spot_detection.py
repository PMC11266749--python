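import numpy as np
import pandas as pd
import pytest

from granulefish import ImageStack, PipelineConfig, SimParams, generate_embryo
from granulefish.spot_detection import (
    auto_threshold,
    detect_candidates,
    detect_spots,
    fit_gaussian_mask,
    subtract_background,
)
from granulefish.synthetic_data import render_foci

from conftest import match_one_to_one


def render(shape, foci, sigma=(1.0, 1.0), unit=1000.0):
    df = pd.DataFrame(foci, columns=["z", "y", "x", "n_molecules"])
    return render_foci(shape, df, sigma[0], sigma[1], unit)


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(np.full((4, 64, 64), 37.5), radius_px=20)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_radius_exceeding_plane_raises(self):
        with pytest.raises(ValueError, match="radius"):
            subtract_background(np.zeros((2, 32, 32)), radius_px=40)

    def test_spot_intensity_preserved_on_ramp(self):
        # the same spot, with and without a linear ramp background: its
        # fitted integrated intensity must agree within 5%
        shape = (9, 96, 96)
        spot = render(shape, [(4.0, 48.3, 47.6, 1)], unit=5000.0)
        yy = np.arange(96, dtype=float)
        ramp = np.zeros(shape) + 0.5 * yy[None, :, None] + 20.0
        flat_fit = fit_gaussian_mask(
            subtract_background(spot + 20.0, 30), (4, 48, 48), (1.0, 1.0)
        )
        ramp_fit = fit_gaussian_mask(
            subtract_background(spot + ramp, 30), (4, 48, 48), (1.0, 1.0)
        )
        assert ramp_fit.integrated_intensity == pytest.approx(
            flat_fit.integrated_intensity, rel=0.05
        )


class TestDetectCandidates:
    def test_noise_only_image_above_threshold_is_empty(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 1, size=(6, 40, 40))
        assert len(detect_candidates(img, threshold=50.0)) == 0

    def test_two_spots_six_pixels_apart_give_two_seeds(self):
        shape = (9, 48, 48)
        img = render(shape, [(4.0, 24.0, 18.0, 1), (4.0, 24.0, 24.0, 1)])
        seeds = detect_candidates(img, threshold=5.0, min_separation_px=3)
        assert len(seeds) == 2

    def test_spot_straddling_slice_boundary_gives_one_seed(self):
        # maxima are 3D: a spot centred between two z-slices must not be
        # seeded once per slice
        shape = (9, 32, 32)
        img = render(shape, [(4.5, 16.0, 16.0, 1)])
        seeds = detect_candidates(img, threshold=5.0, min_separation_px=1)
        assert len(seeds) == 1

    def test_count_monotone_nonincreasing_in_threshold(self):
        params = SimParams(
            n_molecules=40, n_granules=0, p_granule=0.0, rng_seed=5,
            shape=(12, 72, 72), cell_radii=(5, 30, 30), nucleus_radii=(2, 9, 9),
        )
        rna, _, _, _ = generate_embryo(params)
        img = subtract_background(rna.astype_float(), 30)
        counts = [
            len(detect_candidates(img, thr)) for thr in (20, 50, 100, 200, 400)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_candidates(np.zeros((2, 8, 8)), threshold=0.0)


class TestFitGaussianMask:
    def test_noiseless_subpixel_recovery(self):
        shape = (12, 40, 40)
        img = render(shape, [(5.0, 20.4, 31.7, 1)])
        fit = fit_gaussian_mask(img, (5, 20, 32), (1.0, 1.0))
        assert fit.converged
        assert fit.z == pytest.approx(5.0, abs=0.05)
        assert fit.y == pytest.approx(20.4, abs=0.05)
        assert fit.x == pytest.approx(31.7, abs=0.05)
        assert fit.integrated_intensity == pytest.approx(1000.0, rel=0.02)

    def test_voxel_centred_spot_fits_at_voxel_centre(self):
        img = render((12, 40, 40), [(5.0, 20.0, 30.0, 1)])
        fit = fit_gaussian_mask(img, (5, 20, 30), (1.0, 1.0))
        assert fit.z == pytest.approx(5.0, abs=1e-6)
        assert fit.y == pytest.approx(20.0, abs=1e-6)
        assert fit.x == pytest.approx(30.0, abs=1e-6)

    def test_intensity_linear_in_amplitude(self):
        img1 = render((12, 40, 40), [(5.0, 20.4, 31.7, 1)], unit=1000.0)
        img2 = render((12, 40, 40), [(5.0, 20.4, 31.7, 1)], unit=2000.0)
        f1 = fit_gaussian_mask(img1, (5, 20, 32), (1.0, 1.0))
        f2 = fit_gaussian_mask(img2, (5, 20, 32), (1.0, 1.0))
        assert f2.integrated_intensity / f1.integrated_intensity == pytest.approx(
            2.0, rel=0.01
        )

    @pytest.mark.parametrize("phase", [0.0, 0.25, 0.5, 0.75, 0.9])
    def test_intensity_independent_of_subpixel_phase(self, phase):
        img = render((12, 40, 40), [(5.0, 20.0 + phase, 30.0, 1)])
        fit = fit_gaussian_mask(img, (5, 20, 30), (1.0, 1.0))
        assert fit.integrated_intensity == pytest.approx(1000.0, rel=0.02)

    def test_seed_outside_bounds_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian_mask(np.zeros((4, 8, 8)), (9, 0, 0), (1.0, 1.0))

    def test_edge_window_is_flagged(self):
        img = render((12, 40, 40), [(1.0, 2.0, 2.0, 1)])
        fit = fit_gaussian_mask(img, (1, 2, 2), (1.0, 1.0))
        assert fit.edge_truncated


class TestDetectSpots:
    def test_high_snr_recall_and_precision(self, somatic_field, config):
        _, rna, roi, truth = somatic_field
        spots = detect_spots(rna, config, roi)
        pairs = match_one_to_one(
            truth.foci[["z", "y", "x"]], spots[["z", "y", "x"]]
        )
        recall = len(pairs) / len(truth.foci)
        precision = len(pairs) / len(spots)
        assert recall >= 0.99
        assert precision >= 0.99
        assert (spots["lineage"] == "somatic").all()

    def test_deterministic_on_same_stack(self, somatic_field, config):
        _, rna, roi, _ = somatic_field
        a = detect_spots(rna, config, roi)
        b = detect_spots(rna, config, roi)
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_stack_gives_empty_table(self, config):
        stack = ImageStack(np.zeros((6, 64, 64)))
        spots = detect_spots(stack, config)
        assert len(spots) == 0

    def test_translation_equivariance(self, config):
        params = SimParams(
            n_molecules=30, n_granules=0, p_granule=0.0, rng_seed=21,
            shape=(16, 96, 96), cell_radii=(5, 28, 28), nucleus_radii=(2, 8, 8),
            min_focus_separation_px=6.0,
        )
        rna, _, _, _ = generate_embryo(params)
        shift = (2, 10, 15)
        shifted = ImageStack(np.roll(rna.voxels, shift, axis=(0, 1, 2)))
        a = detect_spots(rna, config).sort_values(["z", "y", "x"]).reset_index(drop=True)
        b = detect_spots(shifted, config).sort_values(["z", "y", "x"]).reset_index(drop=True)
        assert len(a) == len(b)
        np.testing.assert_allclose(b["z"], a["z"] + shift[0], atol=0.05)
        np.testing.assert_allclose(b["y"], a["y"] + shift[1], atol=0.05)
        np.testing.assert_allclose(b["x"], a["x"] + shift[2], atol=0.05)

    def test_auto_threshold_scales_with_noise(self):
        rng = np.random.default_rng(0)
        low = rng.normal(100, 5, size=(4, 64, 64))
        high = rng.normal(100, 25, size=(4, 64, 64))
        assert auto_threshold(high) > auto_threshold(low)
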