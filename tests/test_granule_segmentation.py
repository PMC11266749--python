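import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from granulefish import (
    ImageStack,
    PipelineConfig,
    SimParams,
    cytoplasm_fraction,
    generate_embryo,
    granule_bounding_cube,
    max_entropy_threshold,
    segment_granules,
)
from granulefish.imaging_io import CellROI


def kapur_oracle(hist):
    """Exhaustive-search reference for the maximum-entropy threshold."""
    p = np.asarray(hist, float)
    p = p / p.sum()
    nonzero = np.flatnonzero(p)
    best_t, best_v = None, -np.inf
    for t in range(len(p) - 1):
        if t < nonzero[0] or t >= nonzero[-1]:
            continue
        pb = p[: t + 1].sum()
        pf = 1.0 - pb
        hb = -sum(q / pb * math.log(q / pb) for q in p[: t + 1] if q > 0)
        hf = -sum(q / pf * math.log(q / pf) for q in p[t + 1 :] if q > 0)
        if best_t is None or hb + hf > best_v + 1e-9 * (1.0 + abs(best_v)):
            best_v, best_t = hb + hf, t
    return best_t


class TestMaxEntropyThreshold:
    def test_two_spike_histogram_splits_between_spikes(self):
        hist = np.zeros(256)
        hist[10] = 500
        hist[200] = 100
        t = max_entropy_threshold(hist)
        assert 10 <= t < 200

    def test_single_populated_bin_raises(self):
        hist = np.zeros(64)
        hist[7] = 100
        with pytest.raises(ValueError, match="single"):
            max_entropy_threshold(hist)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            max_entropy_threshold(np.array([3, -1, 5]))

    @given(
        st.lists(st.integers(min_value=0, max_value=500), min_size=8, max_size=128)
    )
    @settings(max_examples=150, deadline=None)
    def test_equals_exhaustive_oracle(self, counts):
        hist = np.asarray(counts, float)
        if (hist > 0).sum() < 2:
            return
        assert max_entropy_threshold(hist) == kapur_oracle(hist)


class TestSegmentGranules:
    def test_single_ellipsoid_recovered(self, config):
        params = SimParams(
            n_molecules=0, n_granules=1, rng_seed=4, shape=(20, 72, 72),
            cell_radii=(8, 30, 30), nucleus_radii=(3, 9, 9),
            granule_minor_range=(3.0, 3.0), granule_major_range=(5.0, 5.0),
            cyto_marker_sd=0.0,
        )
        _, marker, _, truth = generate_embryo(params)
        labels, table = segment_granules(marker, config)
        assert len(table) == 1
        g = table.iloc[0]
        t = truth.granules.iloc[0]
        assert abs(g.z - t.z) <= 1 and abs(g.y - t.y) <= 1 and abs(g.x - t.x) <= 1
        assert g.minor_radius_px == pytest.approx(3.0, abs=1.0)
        assert g.major_radius_px == pytest.approx(5.0, abs=1.0)

    def test_touching_spheres_split_by_watershed(self, config):
        # two spheres 2.5 radii apart merge after blur; the watershed must
        # recover both
        shape = (20, 64, 64)
        img = np.zeros(shape)
        zz, yy, xx = np.ogrid[:20, :64, :64]
        for cy in (26, 38):  # radius 5, centers 12.5 = 2.5 r apart... use r=4.8
            ball = ((zz - 10) / 4.8) ** 2 + ((yy - cy) / 4.8) ** 2 + (
                (xx - 32) / 4.8
            ) ** 2 <= 1
            img[ball] = 160.0
        img = ndimage.gaussian_filter(img, 0.6) + 100.0
        rng = np.random.default_rng(0)
        img = np.clip(rng.poisson(img) + rng.normal(0, 5, shape), 0, None)
        _, table = segment_granules(ImageStack(img), config)
        assert len(table) == 2

    def test_noise_only_stack_yields_no_granules(self, config):
        rng = np.random.default_rng(1)
        noise = np.clip(
            rng.poisson(100, size=(12, 128, 128)) + rng.normal(0, 5, (12, 128, 128)),
            0,
            None,
        )
        _, table = segment_granules(ImageStack(noise), config)
        assert len(table) == 0

    def test_label_count_invariant_under_intensity_scaling(self, config):
        params = SimParams(
            n_molecules=0, n_granules=5, rng_seed=6, shape=(20, 96, 96),
            cell_radii=(8, 40, 40), nucleus_radii=(3, 12, 12),
        )
        _, marker, _, _ = generate_embryo(params)
        _, t1 = segment_granules(marker, config)
        scaled = ImageStack(marker.voxels * 5.0)
        _, t5 = segment_granules(scaled, config)
        assert len(t1) == len(t5)

    def test_high_snr_one_to_one_matching(self, config):
        matched, total = 0, 0
        for seed in range(3):
            params = SimParams(
                n_molecules=0, n_granules=10, rng_seed=seed, shape=(24, 112, 112),
                cell_radii=(9.5, 48, 48), nucleus_radii=(4, 15, 15),
            )
            _, marker, _, truth = generate_embryo(params)
            labels, _ = segment_granules(marker, config)
            used = set()
            for row in truth.granules.itertuples():
                total += 1
                lbl = labels[
                    int(round(row.z)), int(round(row.y)), int(round(row.x))
                ]
                if lbl > 0 and lbl not in used:
                    used.add(lbl)
                    matched += 1
        assert matched / total >= 0.95


class TestBoundingCube:
    @pytest.mark.parametrize(
        "minor, major, pad, extents",
        [
            (3, 5, 2, (10, 10, 10)),  # (z, y, x) full extents
            (1, 1, 2, (2, 6, 6)),
            (3, 5, 0, (10, 6, 6)),  # removing the pad shrinks x/y by 4
        ],
    )
    def test_extent_arithmetic(self, minor, major, pad, extents):
        cube = granule_bounding_cube(
            {
                "granule_id": 0,
                "z": 10.0,
                "y": 10.0,
                "x": 10.0,
                "minor_radius_px": minor,
                "major_radius_px": major,
            },
            cube_pad_px=pad,
        )
        assert cube.full_extents == extents

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            granule_bounding_cube(
                {
                    "granule_id": 0,
                    "z": 0,
                    "y": 0,
                    "x": 0,
                    "minor_radius_px": 5,
                    "major_radius_px": 3,
                },
            )


class TestCytoplasmFraction:
    def _roi(self, cell_vox=1100, nuc_vox=100):
        cell = np.zeros((12, 20, 20), dtype=bool)
        cell.flat[:cell_vox] = True
        nuc = np.zeros_like(cell)
        nuc.flat[:nuc_vox] = True
        return CellROI(cell, nuc, "P4")

    def test_arithmetic(self):
        granules = pd.DataFrame({"volume_vox": [100]})
        assert cytoplasm_fraction(granules, self._roi()) == pytest.approx(10.0)

    def test_no_granules_gives_zero(self):
        granules = pd.DataFrame({"volume_vox": []})
        assert cytoplasm_fraction(granules, self._roi()) == 0.0

    def test_nucleus_filling_cell_rejected(self):
        granules = pd.DataFrame({"volume_vox": [10]})
        with pytest.raises(ValueError):
            cytoplasm_fraction(granules, self._roi(cell_vox=100, nuc_vox=100))

    def test_recovers_truth_on_synthetic_embryo(self, config):
        params = SimParams(
            n_molecules=0, n_granules=10, rng_seed=2, shape=(24, 112, 112),
            cell_radii=(9.5, 48, 48), nucleus_radii=(4, 15, 15),
        )
        _, marker, roi, truth = generate_embryo(params)
        _, table = segment_granules(marker, config)
        measured = cytoplasm_fraction(table, roi)
        expected = (
            100.0
            * truth.granules["volume_vox"].sum()
            / (roi.cell_volume_vox - roi.nucleus_volume_vox)
        )
        assert measured == pytest.approx(expected, rel=0.10)
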