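"""Max-average window extraction, artifact QC, imputation, subtraction."""

import numpy as np
import pandas as pd
import pytest

from postarray import (
    build_heatmap,
    estimate_background,
    flag_artifacts,
    impute_fallen,
    measure_post,
    quantify_image,
    simulate_scan,
    subtract_negative,
    uniform_truth,
)
from postarray.quantify import (
    FLAG_CLEAN,
    FLAG_HIGH,
    FLAG_IMPUTED,
    FLAG_ISOLATED,
    FLAG_LOW,
)
from tests.conftest import PANEL_LEVELS


def brute_force_max_mean(region, k):
    """Independent oracle: enumerate every k x k window."""
    best = -np.inf
    h, w = region.shape
    for y in range(h - k + 1):
        for x in range(w - k + 1):
            best = max(best, region[y : y + k, x : x + k].mean())
    return best


class TestMeasurePost:
    def test_constant_field(self):
        image = np.full((30, 30), 500, dtype=np.uint16)
        assert measure_post(image, (5, 5, 25, 25), 8) == 500.0

    def test_planted_optimum(self):
        image = np.full((40, 40), 100, dtype=np.uint16)
        image[12:20, 15:23] = 1000
        assert measure_post(image, (5, 5, 35, 35), 8) == 1000.0

    def test_matches_brute_force_on_random_windows(self, rng):
        for _ in range(30):
            image = rng.integers(0, 65536, size=(20, 20), dtype=np.uint16)
            value = measure_post(image, (0, 0, 20, 20), 8)
            assert value == brute_force_max_mean(image, 8)

    def test_tie_broken_by_smallest_origin(self):
        image = np.full((20, 30), 100, dtype=np.uint16)
        # two equal optima; smaller y wins, then smaller x
        image[2:10, 20:28] = 900
        image[2:10, 3:11] = 900
        _, origin = measure_post(image, (0, 0, 30, 20), 8, return_origin=True)
        assert origin == (3, 2)

    def test_window_smaller_than_post_rejected(self):
        image = np.zeros((20, 20), dtype=np.uint16)
        with pytest.raises(ValueError, match="smaller"):
            measure_post(image, (0, 0, 5, 20), 8)

    def test_window_outside_image_rejected(self):
        image = np.zeros((20, 20), dtype=np.uint16)
        with pytest.raises(ValueError, match="outside"):
            measure_post(image, (10, 10, 30, 30), 8)


class TestEstimateBackground:
    def test_constant_well_with_bright_posts(self):
        image = np.full((60, 60), 100, dtype=np.uint16)
        image[10:18, 10:18] = 5000
        bg = estimate_background(image, (0, 0, 60, 60), [(10, 10, 18, 18)])
        assert bg == 100.0

    def test_all_constant_image(self):
        image = np.full((60, 60), 321, dtype=np.uint16)
        assert estimate_background(image, (0, 0, 60, 60), []) == 321.0

    def test_fully_tiled_well_falls_back_with_warning(self):
        image = np.full((20, 20), 7, dtype=np.uint16)
        with pytest.warns(UserWarning, match="global"):
            bg = estimate_background(image, (0, 0, 10, 10), [(0, 0, 10, 10)])
        assert bg == 7.0

    def test_recovers_truth_under_noise(self, small_geometry):
        truth = uniform_truth(small_geometry, 500.0, background=100.0, noise_sigma=5.0, seed=3)
        image, _ = simulate_scan(small_geometry, truth)
        from postarray.quantify import estimate_array_background

        bg, _mad = estimate_array_background(image, small_geometry, truth.grid_anchor)
        assert bg == pytest.approx(100.0, abs=2.0)


class TestQuantifyImage:
    def test_noiseless_recovery_is_exact(self, small_geometry, small_scan, panel):
        image, truth = small_scan
        df = quantify_image(image, small_geometry, truth.grid_anchor, panel=panel)
        assert len(df) == small_geometry.n_wells * 5
        for p, level in PANEL_LEVELS.items():
            assert (df.loc[df.post_index == p, "raw_intensity"] == level).all()

    def test_noisy_recovery_within_half_sigma(self, small_geometry, panel):
        # window mean of 64 pixels: SE = sigma/8; demand error <= 4*SE
        sigma = 5.0
        hits = total = 0
        for seed in (1, 2, 3):
            truth = uniform_truth(
                small_geometry, PANEL_LEVELS, background=100.0, noise_sigma=sigma, seed=seed
            )
            image, _ = simulate_scan(small_geometry, truth)
            df = quantify_image(image, small_geometry, truth.grid_anchor, panel=panel)
            for p, level in PANEL_LEVELS.items():
                err = (df.loc[df.post_index == p, "raw_intensity"] - level).abs()
                hits += int((err <= 4 * sigma / 8).sum())
                total += len(err)
        assert hits / total >= 0.99


class TestFlagArtifacts:
    def make_df(self, raws):
        return pd.DataFrame(
            {
                "well_row": range(len(raws)),
                "well_col": 0,
                "post_index": 0,
                "target": "t",
                "role": "endogenous",
                "raw_intensity": raws,
                "qc_flag": FLAG_CLEAN,
                "final_intensity": raws,
            }
        )

    def test_high_low_and_clean(self):
        df = flag_artifacts(self.make_df([65535.0, 500.0, 10.0]), 60000, 50, 100)
        assert list(df.qc_flag) == [FLAG_HIGH, FLAG_CLEAN, FLAG_LOW]
        assert list(df.final_intensity) == [100.0, 500.0, 100.0]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="upper"):
            flag_artifacts(self.make_df([1.0]), 50, 60000, 100)


class TestImputeFallen:
    def grid_df(self, n=3, value=400.0):
        rows = [
            {
                "well_row": r,
                "well_col": c,
                "post_index": 0,
                "target": "t",
                "role": "endogenous",
                "raw_intensity": value,
                "qc_flag": FLAG_CLEAN,
                "final_intensity": value,
            }
            for r in range(n)
            for c in range(n)
        ]
        return pd.DataFrame(rows)

    def test_interior_constant_neighbourhood(self):
        df, retention = impute_fallen(self.grid_df(), fallen_set=[(1, 1, 0)])
        val = df[(df.well_row == 1) & (df.well_col == 1)]
        assert val.final_intensity.iloc[0] == 400.0
        assert val.qc_flag.iloc[0] == FLAG_IMPUTED
        assert retention == pytest.approx(8 / 9)

    def test_corner_three_neighbours_hand_mean(self):
        df = self.grid_df(2)
        df.loc[(df.well_row == 0) & (df.well_col == 1), "final_intensity"] = 100.0
        df.loc[(df.well_row == 1) & (df.well_col == 0), "final_intensity"] = 200.0
        df.loc[(df.well_row == 1) & (df.well_col == 1), "final_intensity"] = 300.0
        out, _ = impute_fallen(df, fallen_set=[(0, 0, 0)])
        assert out[(out.well_row == 0) & (out.well_col == 0)].final_intensity.iloc[0] == 200.0

    def test_fallen_neighbours_excluded(self):
        df = self.grid_df(3)
        df.loc[(df.well_row == 0) & (df.well_col == 1), "final_intensity"] = 999.0
        out, _ = impute_fallen(df, fallen_set=[(1, 1, 0), (0, 1, 0)])
        center = out[(out.well_row == 1) & (out.well_col == 1)]
        assert center.final_intensity.iloc[0] == 400.0  # the 999 neighbour is fallen too

    def test_isolated_post_left_at_background_with_warning(self):
        df = self.grid_df(1)
        with pytest.warns(UserWarning, match="no valid neighbours"):
            out, retention = impute_fallen(df, fallen_set=[(0, 0, 0)], background=50.0)
        assert out.final_intensity.iloc[0] == 50.0
        assert out.qc_flag.iloc[0] == FLAG_ISOLATED
        assert retention == 0.0

    def test_idempotent_and_clean_posts_untouched(self):
        df = self.grid_df(3)
        fallen = [(0, 0, 0)]
        once, r1 = impute_fallen(df, fallen_set=fallen)
        twice, r2 = impute_fallen(once, fallen_set=fallen)
        pd.testing.assert_frame_equal(once, twice)
        assert r1 == r2
        clean = once[once.qc_flag == FLAG_CLEAN]
        assert (clean.final_intensity == 400.0).all()

    def test_retention_plus_fallen_fraction_is_one(self):
        df = self.grid_df(3)
        _, retention = impute_fallen(df, fallen_set=[(0, 0, 0), (2, 2, 0)])
        assert retention + 2 / 9 == 1.0

    def test_default_fallen_set_from_low_flag(self):
        df = self.grid_df(3)
        df.loc[(df.well_row == 1) & (df.well_col == 1), "qc_flag"] = FLAG_LOW
        df.loc[(df.well_row == 1) & (df.well_col == 1), "final_intensity"] = 100.0
        out, retention = impute_fallen(df)
        center = out[(out.well_row == 1) & (out.well_col == 1)]
        assert center.qc_flag.iloc[0] == FLAG_IMPUTED
        assert center.final_intensity.iloc[0] == 400.0
        assert retention == pytest.approx(8 / 9)


class TestSubtractNegative:
    def make_measurements(self, panel, values_by_target, n=2):
        rows = []
        for r in range(n):
            for c in range(n):
                for e in panel.entries:
                    rows.append(
                        {
                            "well_row": r,
                            "well_col": c,
                            "post_index": e.post_index,
                            "target": e.target_name,
                            "role": e.role,
                            "raw_intensity": values_by_target[e.target_name],
                            "qc_flag": FLAG_CLEAN,
                            "final_intensity": values_by_target[e.target_name],
                        }
                    )
        return pd.DataFrame(rows)

    def test_subtraction_clipping_and_self(self, panel):
        vals = {
            "miR-167a": 600.0,
            "miR-159a": 80.0,
            "miR-396b": 300.0,
            "internal-control": 2000.0,
            "cel-miR-54": 100.0,
        }
        df = self.make_measurements(panel, vals)
        wells = subtract_negative(df, panel)
        assert (wells["miR-167a"] == 500.0).all()
        assert (wells["miR-159a"] == 0.0).all()  # 80 - 100 clipped at zero
        assert (wells["cel-miR-54"] == 0.0).all()  # control's own net signal
        assert (wells["internal_control"] == 2000.0).all()

    def test_missing_negative_control_excludes_well(self, panel):
        vals = {
            "miR-167a": 600.0,
            "miR-159a": 400.0,
            "miR-396b": 300.0,
            "internal-control": 2000.0,
            "cel-miR-54": 100.0,
        }
        df = self.make_measurements(panel, vals)
        df = df[
            ~((df.well_row == 0) & (df.well_col == 0) & (df.target == "cel-miR-54"))
        ]
        wells = subtract_negative(df, panel)
        assert len(wells) == 3
        assert wells.attrs["errors"] == [
            {"well_row": 0, "well_col": 0, "error": "missing negative control"}
        ]


class TestBuildHeatmap:
    def base_wells(self):
        return pd.DataFrame(
            {
                "well_row": [0, 0, 1, 1],
                "well_col": [0, 1, 0, 1],
                "t": [500.0, 70000.0, 123.4, 10.0],
                "masked_in": [True, True, True, False],
            }
        )

    def test_values_clipping_and_masking(self):
        from postarray import ArrayGeometry

        geometry = ArrayGeometry(n_rows=2, n_cols=2)
        heat = build_heatmap(self.base_wells(), geometry, "t")
        assert heat.dtype == np.uint16
        assert heat[0, 0] == 500
        assert heat[0, 1] == 65535  # 16-bit clip
        assert heat[1, 0] == 123  # rounded
        assert heat[1, 1] == 0  # masked out

    def test_unknown_target_rejected(self):
        from postarray import ArrayGeometry

        with pytest.raises(KeyError):
            build_heatmap(self.base_wells(), ArrayGeometry(n_rows=2, n_cols=2), "nope")
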