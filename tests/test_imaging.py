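"""Tests for the two-channel ratio-imaging pipeline."""

import numpy as np
import pandas as pd
import pytest

from gshquant.calibration import HELA_CALIBRATION, ratio_from_concentration
from gshquant.imaging import (
    RatioMap,
    TwoChannelImage,
    per_cell_summary,
    pixel_ratio_map,
    quantify_timelapse,
    read_two_channel_tiff,
    segment_cells,
    subtract_background,
    track_cells,
    write_two_channel_tiff,
)
from gshquant.synthetic import GeneratorConfig, gen_image_series


@pytest.fixture(scope="module")
def noisy_frame():
    cfg = GeneratorConfig(
        seed=5, frame_times_s=(240.0,), schedule=((0.0, 4.1), (240.0, 4.1))
    )
    frames, times, truth = gen_image_series(cfg)
    return cfg, frames[0], truth


@pytest.fixture(scope="module")
def clean_frame():
    cfg = GeneratorConfig(
        seed=5, frame_times_s=(0.0,), schedule=((0.0, 5.0),), cell_cv=0.0,
        background_level=0.0, read_noise_sd=0.0,
    )
    frames, times, truth = gen_image_series(cfg, noise=False)
    return cfg, frames[0], truth


class TestSubtractBackground:
    def test_constant_image_zeroed_by_percentile(self):
        img = TwoChannelImage(np.full((32, 32), 7.0), np.full((32, 32), 3.0))
        out = subtract_background(img, method="percentile", percentile=5)
        assert np.all(out.ch405 == 0)
        assert np.all(out.ch488 == 0)

    def test_zero_image_unchanged(self):
        img = TwoChannelImage(np.zeros((16, 16)), np.zeros((16, 16)))
        out = subtract_background(img)
        assert np.all(out.ch405 == 0)

    def test_flat_background_recovered_on_synthetic_cells(self, noisy_frame):
        cfg, frame, _ = noisy_frame
        out = subtract_background(frame)
        # Poisson background: median estimate within a few counts
        assert out.background["bg405"] == pytest.approx(cfg.background_level, abs=2.0)
        assert out.background["bg488"] == pytest.approx(cfg.background_level, abs=2.0)

    def test_dark_region_outside_image_rejected(self):
        img = TwoChannelImage(np.ones((8, 8)), np.ones((8, 8)))
        with pytest.raises(ValueError):
            subtract_background(
                img, method="dark-region", dark_region=(slice(0, 20), slice(0, 4))
            )


class TestSegmentCells:
    def test_blank_image_yields_no_cells(self):
        img = TwoChannelImage(np.zeros((64, 64)), np.zeros((64, 64)))
        assert segment_cells(img).max() == 0

    def test_generator_cell_count_recovered(self, noisy_frame):
        cfg, frame, _ = noisy_frame
        labels = segment_cells(subtract_background(frame))
        assert labels.max() == cfg.n_cells

    def test_touching_cells_merge_into_one_label(self):
        ch = np.zeros((40, 40))
        ch[10:20, 5:20] = 100.0
        ch[10:20, 20:35] = 100.0  # adjacent blocks share an edge
        img = TwoChannelImage(ch, ch)
        labels = segment_cells(img, min_area_px=10)
        assert labels.max() == 1


class TestPixelRatioMap:
    def test_uniform_double_ratio(self):
        ch488 = np.full((16, 16), 50.0)
        img = TwoChannelImage(2 * ch488, ch488)
        labels = np.ones((16, 16), int)
        rmap = pixel_ratio_map(img, labels, denominator_floor=0.0)
        np.testing.assert_allclose(rmap.ratio, 2.0)

    def test_floor_masks_dim_pixels(self):
        ch488 = np.full((4, 4), 10.0)
        ch488[0, 0] = 0.5
        img = TwoChannelImage(np.full((4, 4), 20.0), ch488)
        rmap = pixel_ratio_map(img, np.ones((4, 4), int), denominator_floor=1.0)
        assert np.isnan(rmap.ratio[0, 0])
        assert rmap.ratio[1, 1] == pytest.approx(2.0)

    def test_common_gain_invariance(self, noisy_frame):
        _, frame, _ = noisy_frame
        labels = segment_cells(frame)
        r1 = pixel_ratio_map(frame, labels, denominator_floor=1.0)
        scaled = TwoChannelImage(frame.ch405 * 3.7, frame.ch488 * 3.7)
        r2 = pixel_ratio_map(scaled, labels, denominator_floor=3.7)
        np.testing.assert_allclose(r1.ratio[r1.mask], r2.ratio[r2.mask], rtol=1e-12)


class TestPerCellSummary:
    def test_noiseless_cells_recover_exact_truth(self, clean_frame):
        cfg, frame, truth = clean_frame
        labels = segment_cells(frame)
        rmap = pixel_ratio_map(frame, labels, denominator_floor=0.0)
        summary = per_cell_summary(rmap, labels, cfg.calibration)
        assert (summary.flag == "ok").all()
        np.testing.assert_allclose(
            np.sort(summary.gsh_mM), np.sort(truth.true_gsh_mM), rtol=1e-6
        )

    @pytest.mark.parametrize("true_c", [5.0, 4.1])
    def test_population_mean_within_2pct_at_budget_500(self, true_c):
        cfg = GeneratorConfig(
            seed=11, frame_times_s=(0.0,), schedule=((0.0, true_c),)
        )
        frames, _, truth = gen_image_series(cfg)
        sub = subtract_background(frames[0])
        labels = segment_cells(sub)
        summary = per_cell_summary(pixel_ratio_map(sub, labels), labels, cfg.calibration)
        mean_c = summary[summary.flag == "ok"].gsh_mM.mean()
        assert mean_c == pytest.approx(truth.true_gsh_mM.mean(), rel=0.02)

    def test_saturated_cell_flagged(self, hela_cal):
        ratio = np.full((10, 10), hela_cal.r_max + 0.5)
        rmap = RatioMap(ratio=ratio, mask=np.ones((10, 10), bool), denominator_floor=0)
        summary = per_cell_summary(rmap, np.ones((10, 10), int), hela_cal)
        assert summary.flag.iloc[0] == "saturated"
        assert np.isinf(summary.gsh_mM.iloc[0])

    def test_label_permutation_invariance(self, noisy_frame):
        cfg, frame, _ = noisy_frame
        sub = subtract_background(frame)
        labels = segment_cells(sub)
        rmap = pixel_ratio_map(sub, labels)
        s1 = per_cell_summary(rmap, labels, cfg.calibration)
        # renumber labels in reverse
        perm = np.zeros(labels.max() + 1, int)
        perm[1:] = np.arange(labels.max(), 0, -1)
        s2 = per_cell_summary(rmap, perm[labels], cfg.calibration)
        np.testing.assert_allclose(
            np.sort(s1.median_ratio), np.sort(s2.median_ratio)
        )

    def test_error_shrinks_with_photon_budget(self):
        """Median concentration error decreases as the photon budget grows."""
        errs = []
        for budget in (60.0, 250.0, 1000.0):
            cfg = GeneratorConfig(
                seed=21, frame_times_s=(0.0,), schedule=((0.0, 5.0),),
                photon_budget=budget, cell_cv=0.0,
            )
            frames, _, truth = gen_image_series(cfg)
            sub = subtract_background(frames[0])
            labels = segment_cells(sub)
            summary = per_cell_summary(
                pixel_ratio_map(sub, labels), labels, cfg.calibration
            )
            ok = summary[summary.flag == "ok"]
            errs.append(np.median(np.abs(ok.gsh_mM - 5.0)))
        assert errs[0] > errs[1] > errs[2]


class TestTracking:
    @staticmethod
    def _square_labels(offsets):
        lm = np.zeros((64, 64), int)
        for i, (dy, dx) in enumerate(offsets, start=1):
            lm[10 + dy:18 + dy, 10 * i + dx:10 * i + 6 + dx] = i
        return lm

    def test_static_cells_keep_identity(self):
        lm = self._square_labels([(0, 0), (0, 0)])
        maps = track_cells([lm, lm.copy()])
        assert maps[0] == maps[1]

    def test_known_drift_linked_correctly(self):
        lm0 = self._square_labels([(0, 0), (0, 0)])
        lm1 = self._square_labels([(2, 0), (2, 0)])  # 2-px drift
        maps = track_cells([lm0, lm1], max_displacement=5.0)
        assert maps[1] == maps[0]

    def test_disappearing_cell_track_terminates(self):
        lm0 = self._square_labels([(0, 0), (0, 0)])
        lm1 = np.where(lm0 == 2, 0, lm0)  # cell 2 vanishes
        maps = track_cells([lm0, lm1, lm0], max_displacement=5.0)
        # cell 2 in the last frame gets a fresh track id
        assert maps[2][2] != maps[0][2]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            track_cells([np.zeros((8, 8), int)])


class TestQuantifyTimelapse:
    def test_oxidative_step_recovered_within_90s(self):
        """A 5.0 -> 4.1 mM population step completes within 90 s."""
        cfg = GeneratorConfig(seed=7)
        frames, times, truth = gen_image_series(cfg)
        _, pop = quantify_timelapse(frames, times, cfg.calibration)
        baseline = pop[pop.time_s <= 120].mean_mM.mean()
        stepped = pop[(pop.time_s >= 210) & (pop.time_s <= 270)].mean_mM.mean()
        assert baseline == pytest.approx(5.0, rel=0.02)
        assert stepped == pytest.approx(4.1, rel=0.02)
        assert pop.n_cells.min() >= 40

    def test_constant_truth_gives_flat_curve(self):
        cfg = GeneratorConfig(
            seed=9, frame_times_s=(0.0, 30.0, 60.0), schedule=((0.0, 5.0), (60.0, 5.0))
        )
        frames, times, _ = gen_image_series(cfg)
        _, pop = quantify_timelapse(frames, times, cfg.calibration)
        assert pop.mean_mM.std() < 3 * pop.sem_mM.mean()

    def test_single_frame_produces_table_without_tracking(self):
        cfg = GeneratorConfig(seed=5, frame_times_s=(0.0,), schedule=((0.0, 5.0),))
        frames, times, _ = gen_image_series(cfg)
        traces, pop = quantify_timelapse(frames, times, cfg.calibration)
        assert len(pop) == 1
        assert pop.n_cells.iloc[0] == cfg.n_cells


class TestTiffIo:
    def test_two_channel_roundtrip(self, tmp_path, noisy_frame):
        _, frame, _ = noisy_frame
        path = tmp_path / "frame.tif"
        write_two_channel_tiff(frame, path)
        back = read_two_channel_tiff(path)
        np.testing.assert_allclose(back.ch405, frame.ch405.astype(np.float32))
        np.testing.assert_allclose(back.ch488, frame.ch488.astype(np.float32))

    def test_channel_order_override(self, tmp_path, noisy_frame):
        _, frame, _ = noisy_frame
        path = tmp_path / "frame.tif"
        write_two_channel_tiff(frame, path)
        swapped = read_two_channel_tiff(path, channel_order=(1, 0))
        np.testing.assert_allclose(swapped.ch405, frame.ch488.astype(np.float32))
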