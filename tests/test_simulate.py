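"""Synthetic scan rendering and tissue-footprint simulation."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from postarray import (
    ArrayGeometry,
    ellipse_region,
    inject_artifacts,
    simulate_scan,
    simulate_tissue_mask,
    uniform_truth,
)
from postarray.geometry import post_rect
from postarray.simulate import CLEAN, DUST, FALLEN, SATURATION, SimulationTruth


class TestScanRendering:
    def test_noiseless_post_block_and_background(self):
        geometry = ArrayGeometry(n_rows=1, n_cols=1, posts_per_well=1)
        truth = uniform_truth(geometry, 500.0, background=100.0)
        image, _ = simulate_scan(geometry, truth)
        x0, y0, x1, y1 = post_rect(geometry, 0, 0, 0, truth.grid_anchor)
        assert (image[y0:y1, x0:x1] == 500).all()
        outside = image.copy()
        outside[y0:y1, x0:x1] = 100
        assert (outside == 100).all()

    def test_same_seed_is_bit_identical(self, small_geometry):
        def render():
            truth = uniform_truth(small_geometry, 500.0, noise_sigma=12.0, seed=42)
            return simulate_scan(small_geometry, truth)[0]

        assert np.array_equal(render(), render())

    def test_different_seeds_differ(self, small_geometry):
        imgs = []
        for seed in (1, 2):
            truth = uniform_truth(small_geometry, 500.0, noise_sigma=12.0, seed=seed)
            imgs.append(simulate_scan(small_geometry, truth)[0])
        assert not np.array_equal(*imgs)

    def test_overbright_truth_clips_to_16bit(self):
        geometry = ArrayGeometry(n_rows=1, n_cols=1, posts_per_well=1)
        truth = uniform_truth(geometry, 70000.0, background=100.0)
        image, _ = simulate_scan(geometry, truth)
        assert image.max() == SATURATION

    def test_dust_saturates_and_fallen_stays_at_background(self, small_geometry):
        truth = uniform_truth(small_geometry, 500.0, background=100.0)
        truth.labels[0, 0, 0] = DUST
        truth.labels[1, 1, 2] = FALLEN
        image, _ = simulate_scan(small_geometry, truth)
        x0, y0, x1, y1 = post_rect(small_geometry, 0, 0, 0, truth.grid_anchor)
        assert image[(y0 + y1) // 2, (x0 + x1) // 2] == SATURATION
        x0, y0, x1, y1 = post_rect(small_geometry, 1, 1, 2, truth.grid_anchor)
        assert (image[y0:y1, x0:x1] == 100).all()

    def test_too_small_image_shape_rejected(self, small_geometry):
        truth = uniform_truth(small_geometry, 500.0)
        with pytest.raises(ValueError, match="too small"):
            simulate_scan(small_geometry, truth, image_shape=(50, 50))

    def test_poisson_mode_is_seeded(self, small_geometry):
        def render():
            truth = uniform_truth(
                small_geometry, 500.0, seed=5, noise_sigma=0.0
            )
            truth.noise_model = "poisson"
            return simulate_scan(small_geometry, truth)[0]

        a, b = render(), render()
        assert np.array_equal(a, b)
        assert a.std() > 0


class TestArtifactBookkeeping:
    def test_injected_counts_match_labels(self, small_geometry):
        truth = uniform_truth(small_geometry, 500.0, seed=11)
        truth = inject_artifacts(truth, n_dust=4, n_fallen=7)
        counts = truth.label_counts()
        assert counts[DUST] == 4
        assert counts[FALLEN] == 7
        assert counts[CLEAN] == small_geometry.n_wells * 5 - 11
        assert len(truth.fallen_set()) == 7

    def test_cannot_overfill(self, small_geometry):
        truth = uniform_truth(small_geometry, 500.0)
        with pytest.raises(ValueError):
            inject_artifacts(truth, n_fallen=small_geometry.n_wells * 5 + 1)


class TestTissueMask:
    def test_full_coverage(self, small_geometry):
        pitch = small_geometry.well_size_um + small_geometry.well_spacing_um
        big = box(-pitch, -pitch, 7 * pitch, 7 * pitch)
        frac = simulate_tissue_mask(small_geometry, big)
        assert frac.shape == (6, 6)
        assert np.allclose(frac, 1.0)

    def test_half_well_by_area(self, small_geometry):
        # left half of well (0, 0)
        half = box(0, 0, 150, 300)
        frac = simulate_tissue_mask(small_geometry, half)
        assert frac[0, 0] == pytest.approx(0.5)
        assert frac[0, 1] == 0.0

    def test_empty_region_gives_zeros(self, small_geometry):
        frac = simulate_tissue_mask(small_geometry, Polygon())
        assert (frac == 0).all()

    def test_ellipse_agrees_with_dense_rasterization(self, small_geometry, rng):
        center = (1000.0, 900.0)
        axes = (700.0, 500.0)
        frac = simulate_tissue_mask(small_geometry, ellipse_region(center, axes))
        # oracle: 1-um pixel rasterization of the exact ellipse equation
        pitch = small_geometry.well_size_um + small_geometry.well_spacing_um
        for r, c in [(0, 0), (1, 2), (2, 2), (3, 1), (2, 4)]:
            x0, y0 = c * pitch, r * pitch
            xs = np.arange(x0 + 0.5, x0 + 300)
            ys = np.arange(y0 + 0.5, y0 + 300)
            xx, yy = np.meshgrid(xs, ys)
            inside = ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1
            assert frac[r, c] == pytest.approx(inside.mean(), abs=0.02)

    def test_conservation_of_area(self, small_geometry):
        region = ellipse_region((900.0, 900.0), (600.0, 450.0))
        frac = simulate_tissue_mask(small_geometry, region)
        well_area = small_geometry.well_size_um**2
        covered = frac.sum() * well_area
        # region area intersected with the union of well footprints
        pitch = small_geometry.well_size_um + small_geometry.well_spacing_um
        wells = [
            box(c * pitch, r * pitch, c * pitch + 300, r * pitch + 300)
            for r in range(6)
            for c in range(6)
        ]
        from shapely.ops import unary_union

        truth_area = region.intersection(unary_union(wells)).area
        assert covered == pytest.approx(truth_area, rel=1e-6)


class TestTruthValidation:
    def test_label_and_shape_checks(self, small_geometry):
        truth = uniform_truth(small_geometry, 500.0)
        bad = truth.labels.copy()
        bad[0, 0, 0] = "melted"
        with pytest.raises(ValueError, match="label"):
            SimulationTruth(truth.intensities, bad, background=100.0)
        with pytest.raises(ValueError, match="tissue"):
            SimulationTruth(
                truth.intensities,
                truth.labels,
                background=100.0,
                tissue_fraction=np.full((6, 6), 1.5),
            )
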