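"""Tests for cytometry gating, calibration and group comparison."""

import numpy as np
import pandas as pd
import pytest

from gshquant.calibration import concentration_from_ratio, ratio_from_concentration
from gshquant.cytometry import (
    EventTable,
    GateReport,
    compare_facs_to_lysate,
    exclude_fluorescence_outliers,
    fit_facs_calibration,
    gate_scatter,
    gate_singlets,
    group_comparison,
    per_event_ratio_summary,
    standard_gating,
)
from gshquant.synthetic import (
    GeneratorConfig,
    bso_dose_series_config,
    erastin_timecourse_config,
    gen_event_tables,
)


def make_events(n=1000, seed=0, r=2.0):
    rng = np.random.default_rng(seed)
    fsc_a = rng.lognormal(np.log(1e5), 0.15, n)
    ssc_a = rng.lognormal(np.log(5e4), 0.2, n)
    f488 = rng.lognormal(np.log(1e3), 0.3, n)
    return EventTable(pd.DataFrame({
        "fsc_a": fsc_a, "fsc_h": fsc_a / np.exp(rng.normal(0, 0.05, n)),
        "ssc_a": ssc_a, "ssc_h": ssc_a / np.exp(rng.normal(0, 0.05, n)),
        "f405": r * f488, "f488": f488,
    }))


@pytest.fixture(scope="module")
def planted_sample():
    cfg = GeneratorConfig(seed=4, sample_true_c_mM=(5.0,), debris_frac=0.10)
    tables, manifest = gen_event_tables(cfg)
    return cfg, tables[0]


class TestGateScatter:
    def test_clean_events_pass_through(self):
        t = make_events()
        gated, report = gate_scatter(t)
        assert len(gated) / len(t) >= 0.99
        assert report.stages[0]["stage"] == "scatter"

    def test_planted_debris_removed(self, planted_sample):
        _, table = planted_sample
        gated, _ = gate_scatter(table)
        n_debris_in = (table.data.truth == "debris").sum()
        n_debris_out = (gated.data.truth == "debris").sum()
        assert 1 - n_debris_out / n_debris_in >= 0.95

    def test_explicit_bounds_respected(self):
        t = make_events()
        with pytest.warns(UserWarning, match="removed every event"):
            gated, report = gate_scatter(
                t, bounds={"fsc_a": (0, 1e4), "ssc_a": (0, np.inf)}
            )
        assert len(gated) == (t.data.fsc_a <= 1e4).sum()

    def test_reference_percentile_box(self):
        ref = make_events(seed=1)
        t = make_events(seed=2)
        gated, report = gate_scatter(t, reference=ref)
        assert 0.90 <= len(gated) / len(t) <= 0.98  # ~2% trimmed per side

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            EventTable(pd.DataFrame(columns=["fsc_a", "fsc_h", "ssc_a",
                                             "ssc_h", "f405", "f488"]))


class TestGateSinglets:
    def test_pure_singlets_mostly_retained(self):
        t = make_events()
        gated, _ = gate_singlets(t)
        assert len(gated) / len(t) >= 0.99

    def test_planted_doublets_removed(self, planted_sample):
        _, table = planted_sample
        gated, _ = standard_gating(table)
        n_in = (table.data.truth == "doublet").sum()
        n_out = (gated.data.truth == "doublet").sum()
        assert 1 - n_out / n_in >= 0.90

    def test_single_event_retained(self):
        t = make_events(n=1)
        gated, _ = gate_singlets(t)
        assert len(gated) == 1


class TestFluorescenceOutliers:
    def test_gaussian_channels_almost_fully_retained(self):
        rng = np.random.default_rng(0)
        n = 50_000
        df = pd.DataFrame({
            "fsc_a": np.ones(n), "fsc_h": np.ones(n),
            "ssc_a": np.ones(n), "ssc_h": np.ones(n),
            "f405": rng.normal(1000, 50, n).clip(0),
            "f488": rng.normal(1000, 50, n).clip(0),
        })
        gated, _ = exclude_fluorescence_outliers(EventTable(df))
        # 4-sd two-channel exclusion keeps essentially everything
        assert len(gated) / n >= 0.9995

    def test_planted_extreme_outliers_removed(self):
        t = make_events(n=5000)
        df = t.data.copy()
        mu, sd = df.f405.mean(), df.f405.std()
        df.loc[:9, "f405"] = mu + 6 * sd
        gated, _ = exclude_fluorescence_outliers(EventTable(df))
        assert (gated.data.f405 >= mu + 5.9 * sd).sum() == 0

    def test_invalid_n_sd_rejected(self):
        with pytest.raises(ValueError):
            exclude_fluorescence_outliers(make_events(), n_sd=0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            exclude_fluorescence_outliers(make_events(n=5))


class TestGateReportConservation:
    def test_counts_non_increasing_and_conserved(self, planted_sample):
        _, table = planted_sample
        gated, report = standard_gating(table)
        counts = [s["n_in"] for s in report.stages] + [report.stages[-1]["n_out"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert report.stages[0]["n_in"] == len(table)
        assert report.stages[-1]["n_out"] == len(gated)

    def test_chain_contiguity_enforced(self):
        report = GateReport()
        report.add("a", 100, 90, {})
        with pytest.raises(ValueError):
            report.add("b", 80, 70, {})


class TestPerEventRatio:
    def test_exact_double_ratio(self):
        summary = per_event_ratio_summary(make_events(r=2.0))
        assert summary["median_r"] == pytest.approx(2.0, rel=1e-12)

    def test_gain_invariance(self):
        t = make_events(seed=3)
        scaled = EventTable(t.data.assign(
            f405=t.data.f405 * 10, f488=t.data.f488 * 10))
        s1 = per_event_ratio_summary(t)
        s2 = per_event_ratio_summary(scaled)
        assert s1["median_r"] == pytest.approx(s2["median_r"], rel=1e-12)

    def test_generator_sample_median_matches_model(self, planted_sample):
        cfg, table = planted_sample
        gated, _ = standard_gating(table)
        summary = per_event_ratio_summary(gated)
        expected = ratio_from_concentration(5.0, cfg.calibration)
        assert summary["median_r"] == pytest.approx(expected, rel=0.02)

    def test_median_robust_to_lognormal_skew(self, rng):
        # median tracks the model ratio; the mean is inflated by skew
        r_true = 2.0
        r = r_true * np.exp(rng.normal(0, 0.5, 20000))
        f488 = np.ones(20000) * 100
        t = EventTable(pd.DataFrame({
            "fsc_a": np.ones(20000), "fsc_h": np.ones(20000),
            "ssc_a": np.ones(20000), "ssc_h": np.ones(20000),
            "f405": r * 100, "f488": f488,
        }))
        s = per_event_ratio_summary(t)
        assert abs(s["median_r"] - r_true) < abs(np.mean(r) - r_true)


class TestFacsCalibration:
    def test_noiseless_samples_recover_anchors(self, hela_cal):
        c = np.linspace(1, 8, 10)
        r = ratio_from_concentration(c, hela_cal)
        cm, _ = fit_facs_calibration(list(zip(r, c)))
        assert cm.r_min == pytest.approx(hela_cal.r_min, rel=1e-6)
        assert cm.r_max == pytest.approx(hela_cal.r_max, rel=1e-6)

    def test_bso_series_recovers_hela_anchors(self):
        """Full chain: events -> gates -> medians -> calibration fit."""
        cfg = bso_dose_series_config(seed=4)
        tables, manifest = gen_event_tables(cfg)
        samples = []
        for tbl, (_, row) in zip(tables, manifest.iterrows()):
            gated, _ = standard_gating(tbl)
            samples.append(
                (per_event_ratio_summary(gated)["median_r"], row.true_gsh_mM)
            )
        cm, _ = fit_facs_calibration(samples)
        assert cm.r_min == pytest.approx(1.65, rel=0.05)
        assert cm.r_max == pytest.approx(2.98, rel=0.05)


class TestComparisons:
    def test_identical_vectors_correlate_perfectly(self):
        c = np.linspace(1, 8, 8)
        r2, slope, intercept = compare_facs_to_lysate(c, c)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_shuffled_pairing_destroys_correlation(self, rng):
        c = np.linspace(1, 8, 10)
        shuffled = rng.permutation(c)
        r2, *_ = compare_facs_to_lysate(c, shuffled)
        assert r2 < 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_facs_to_lysate([1, 2, 3], [1, 2])

    def test_identical_noisy_groups_not_significant(self, rng):
        a = rng.normal(5, 1, 100)
        t, p = group_comparison(a, a)
        assert p == pytest.approx(1.0)

    def test_erastin_collapse_is_significant(self):
        """24-h ferroptotic GSH depletion at study-scale n is detectable."""
        cfg = erastin_timecourse_config(seed=8)
        tables, manifest = gen_event_tables(cfg)
        concs = []
        for tbl in tables:
            gated, _ = standard_gating(tbl)
            f405 = gated.data.f405.to_numpy()
            f488 = gated.data.f488.to_numpy()
            c, _ = concentration_from_ratio(
                np.clip(f405 / f488, None, cfg.calibration.r_max - 1e-9),
                cfg.calibration,
            )
            concs.append(c[np.isfinite(c)])
        t0h, t24h = concs[0], concs[2]
        tstat, p = group_comparison(t0h, t24h)
        assert p < 1e-4
        assert np.median(t24h) < np.median(t0h)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison([1.0], [1.0, 2.0])


class TestEventCsv:
    def test_roundtrip(self, tmp_path):
        t = make_events(n=50)
        path = tmp_path / "events.csv"
        t.to_csv(path)
        back = EventTable.from_csv(path, condition="x")
        pd.testing.assert_frame_equal(
            back.data, t.data[back.data.columns], check_exact=False
        )
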