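"""Synthetic data generators with known ground truth.

Every input the analysis pipelines consume can be generated here under
the forward models the estimators invert, at the study's stated
conditions: titrations of a 10 μM probe against 0–50 mM GSH with
multiplicative readout noise; pseudo-first-order kinetic traces at
post-mixing GSH 2.5/5/10 mM plus two-fold dilution-relaxation traces;
two-channel confocal frames of ~46 elliptical cells whose ground-truth
GSH follows an oxidative-stress/recovery schedule (5.0 → 4.1 mM step,
then ramp back), rendered with Poisson shot noise and Gaussian read
noise; cytometry event clouds of 10,000 events per sample with planted
debris, dead cells, doublets and per-channel outliers; and enzymatic
recycling / LC-MS assay tables.

One global seed fans out to fixed per-generator streams, so each data
type is reproducible independently of the others.  Each generator
returns a machine-readable truth record sufficient to score any
downstream estimate.  A ``gain_drift`` model-mismatch switch (default
off) perturbs the two channel gains for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import (
    FLUORIMETER_PHOTOPHYSICS,
    HELA_FACS_PHOTOPHYSICS,
    BindingParameters,
    Photophysics,
    TitrationCurve,
    simulate_titration,
)
from .calibration import HELA_CALIBRATION, CalibrationModel, ratio_from_concentration
from .kinetics import KineticParameters, KineticTrace, dilution_relaxation, simulate_timecourse

__all__ = [
    "GeneratorConfig",
    "gen_titration",
    "gen_kinetic_traces",
    "gen_image_series",
    "gen_event_tables",
    "gen_assay_data",
    "bso_dose_series_config",
    "erastin_timecourse_config",
]

# fixed stream offsets fanning the global seed out to sub-generators
_STREAMS = {"titration": 1, "kinetics": 2, "images": 3, "events": 4, "assays": 5}


@dataclass
class GeneratorConfig:
    """All scenario parameters and noise levels, with the study defaults."""

    seed: int = 0

    # --- binding titration (fluorimeter) ---
    true_kd_mM: float = 3.7
    titration_p_total_uM: float = 10.0
    titration_grid_mM: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 35.0, 50.0)
    titration_noise_cv: float = 0.01  # multiplicative
    titration_photophysics: Photophysics = FLUORIMETER_PHOTOPHYSICS

    # --- kinetics (post-mixing totals) ---
    true_kf: float = 7.5  # M^-1 s^-1
    true_kr: float = 20.3e-3  # s^-1
    kinetics_p_total_uM: float = 5.0
    kinetics_g_totals_mM: tuple = (2.5, 5.0, 10.0)
    kinetics_times_s: tuple = tuple(float(t) for t in range(0, 121))
    kinetics_noise_cv: float = 0.02  # additive, relative to trace amplitude
    dilution_p_total_uM: float = 20.0
    dilution_g_totals_mM: tuple = (10.0, 5.0)
    dilution_factor: float = 2.0
    dilution_times_s: tuple = tuple(float(t) for t in range(0, 301, 2))

    # --- imaging (Fig-4-style time lapse) ---
    n_cells: int = 46
    image_shape: tuple = (512, 512)
    cell_radius_px: tuple = (8, 14)
    photon_budget: float = 500.0
    background_level: float = 30.0
    read_noise_sd: float = 3.0
    cell_cv: float = 0.03  # cell-to-cell spread of true C
    calibration: CalibrationModel = HELA_CALIBRATION
    imaging_photophysics: Photophysics = HELA_FACS_PHOTOPHYSICS
    # (time_s, population GSH mM) breakpoints: baseline 5.0, oxidative step
    # to 4.1 completed within 90 s of the insult, ester-driven recovery
    schedule: tuple = ((0.0, 5.0), (120.0, 5.0), (210.0, 4.1), (270.0, 4.1), (450.0, 5.0), (480.0, 5.0))
    frame_times_s: tuple = tuple(float(t) for t in range(0, 481, 30))

    # --- cytometry events ---
    n_events: int = 10_000
    ratio_cv: float = 0.10
    debris_frac: float = 0.05
    dead_frac: float = 0.05
    doublet_frac: float = 0.05
    outlier_frac: float = 0.01
    sample_true_c_mM: tuple = tuple(np.linspace(8.0, 1.0, 10).round(3))
    sample_labels: tuple = ()

    # --- lysate assays ---
    assay_noise_cv: float = 0.02
    n_cells_lysed: int = 1_000_000
    lysate_volume_mL: float = 1.0
    cell_volume_um3: float = 4000.0
    assay_gain_au_per_M_s: float = 20.0
    lcms_gain_per_mM: float = 2.0e4
    lcms_dilution: float = 100.0

    # --- model mismatch (robustness switch, default off) ---
    gain_drift: float = 0.0  # fractional drift applied to the 405 channel

    def __post_init__(self) -> None:
        for name in ("debris_frac", "dead_frac", "doublet_frac", "outlier_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def gen_titration(cfg: GeneratorConfig):
    """Noisy ratio titration plus its generating truth."""
    rng = cfg.rng("titration")
    bp = BindingParameters(kd=cfg.true_kd_mM * 1e-3)
    grid = np.asarray(cfg.titration_grid_mM, float) * 1e-3
    clean = simulate_titration(grid, cfg.titration_p_total_uM * 1e-6, bp,
                               cfg.titration_photophysics)
    noise = rng.normal(0.0, cfg.titration_noise_cv, size=grid.size) if cfg.titration_noise_cv else 0.0
    curve = TitrationCurve(grid, clean.ratios * (1.0 + noise),
                           noise_model=f"multiplicative cv={cfg.titration_noise_cv}")
    truth = {"kd_mM": cfg.true_kd_mM, "p_total_uM": cfg.titration_p_total_uM,
             "photophysics": cfg.titration_photophysics}
    return curve, truth


def gen_kinetic_traces(cfg: GeneratorConfig):
    """Forward pseudo-first-order traces and dilution-relaxation traces.

    Noise is additive Gaussian with standard deviation equal to
    ``kinetics_noise_cv`` times each trace's amplitude.
    """
    rng = cfg.rng("kinetics")
    kp = KineticParameters(kf=cfg.true_kf, kr=cfg.true_kr)
    p_tot = cfg.kinetics_p_total_uM * 1e-6
    forward = []
    for g_mM in cfg.kinetics_g_totals_mM:
        tr = simulate_timecourse(p_tot, g_mM * 1e-3, 0.0, kp, cfg.kinetics_times_s)
        amp = np.ptp(tr.signal)
        sig = tr.signal + rng.normal(0.0, cfg.kinetics_noise_cv * amp, tr.signal.size)
        forward.append(KineticTrace(tr.times, sig, p_total=tr.p_total,
                                    g_total=tr.g_total, meta={"kind": "forward"}))
    dilution = []
    for g_mM in cfg.dilution_g_totals_mM:
        tr = dilution_relaxation(cfg.dilution_p_total_uM * 1e-6, g_mM * 1e-3, kp,
                                 cfg.dilution_factor, cfg.dilution_times_s)
        amp = np.ptp(tr.signal)
        sig = tr.signal + rng.normal(0.0, cfg.kinetics_noise_cv * amp, tr.signal.size)
        dilution.append(
            KineticTrace(tr.times, sig, p_total=tr.p_total, g_total=tr.g_total,
                         meta={"kind": "dilution", "a0": float(tr.signal[0])})
        )
    truth = {"kf": cfg.true_kf, "kr": cfg.true_kr,
             "kobs": [cfg.true_kf * g * 1e-3 + cfg.true_kr for g in cfg.kinetics_g_totals_mM]}
    return forward, dilution, truth


def _channel_intensities(c_mM: float, cfg: GeneratorConfig):
    """Expected per-pixel photon counts for a cell at concentration C.

    Uses the two-state bound fraction at the calibration's implied Kd
    (midpoint C = 1/k) so that the pixel ratio reproduces the
    calibration model exactly; the 488 channel of a fully free probe
    receives the full photon budget.
    """
    ph = cfg.imaging_photophysics
    # occupancy u = C/Kd with the calibration's implied Kd = w488/k
    u = cfg.calibration.k * c_mM / ph.w488
    x = u / (1.0 + u)  # bound probe fraction
    e405 = cfg.photon_budget * (ph.s405_free * (1 - x) + ph.s405_bound * x) / ph.s488_free
    e488 = cfg.photon_budget * (ph.s488_free * (1 - x) + ph.s488_bound * x) / ph.s488_free
    return e405 * (1.0 + cfg.gain_drift), e488


def _place_cells(rng, cfg: GeneratorConfig):
    """Non-overlapping ellipse parameters (cy, cx, ry, rx, angle)."""
    h, w = cfg.image_shape
    rmin, rmax = cfg.cell_radius_px
    cells = []
    attempts = 0
    while len(cells) < cfg.n_cells:
        attempts += 1
        if attempts > 200 * cfg.n_cells:
            raise RuntimeError("could not place cells without overlap")
        ry = rng.uniform(rmin, rmax)
        rx = rng.uniform(rmin, rmax)
        margin = max(ry, rx) + 2
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - c[0]) ** 2 + (cx - c[1]) ** 2 > (max(ry, rx) + max(c[2], c[3]) + 3) ** 2
               for c in cells):
            cells.append((cy, cx, ry, rx, rng.uniform(0, np.pi)))
    return cells


def _render_frame(rng, cfg: GeneratorConfig, cells, cell_c_mM):
    h, w = cfg.image_shape
    e405 = np.zeros((h, w))
    e488 = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx, ry, rx, ang), c in zip(cells, cell_c_mM):
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        i405, i488 = _channel_intensities(c, cfg)
        e405[inside] = i405
        e488[inside] = i488
    e405 += cfg.background_level
    e488 += cfg.background_level
    ch405 = rng.poisson(e405).astype(float) + rng.normal(0, cfg.read_noise_sd, (h, w))
    ch488 = rng.poisson(e488).astype(float) + rng.normal(0, cfg.read_noise_sd, (h, w))
    return np.clip(ch405, 0, None), np.clip(ch488, 0, None)


def gen_image_series(cfg: GeneratorConfig, noise: bool = True):
    """Two-channel time-lapse frames plus the per-cell truth table.

    Returns ``(frames, times, truth)`` where ``frames`` is a list of
    ``(ch405, ch488)`` arrays, and ``truth`` a DataFrame with one row per
    (frame, cell) carrying the generating concentration.  With
    ``noise=False`` the expected (Poisson-mean) images are returned.
    """
    from .imaging import TwoChannelImage

    rng = cfg.rng("images")
    cells = _place_cells(rng, cfg)
    sched_t = np.array([p[0] for p in cfg.schedule])
    sched_c = np.array([p[1] for p in cfg.schedule])
    cell_factors = np.exp(rng.normal(0.0, cfg.cell_cv, cfg.n_cells)) if cfg.cell_cv else np.ones(cfg.n_cells)

    frames, truth_rows = [], []
    for fi, t in enumerate(cfg.frame_times_s):
        pop_c = float(np.interp(t, sched_t, sched_c))
        cell_c = pop_c * cell_factors
        if noise:
            ch405, ch488 = _render_frame(rng, cfg, cells, cell_c)
        else:
            h, w = cfg.image_shape
            e405 = np.full((h, w), cfg.background_level)
            e488 = np.full((h, w), cfg.background_level)
            yy, xx = np.mgrid[0:h, 0:w]
            for (cy, cx, ry, rx, ang), c in zip(cells, cell_c):
                ca, sa = np.cos(ang), np.sin(ang)
                u = (xx - cx) * ca + (yy - cy) * sa
                v = -(xx - cx) * sa + (yy - cy) * ca
                inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
                i405, i488 = _channel_intensities(c, cfg)
                e405[inside] = i405 + cfg.background_level
                e488[inside] = i488 + cfg.background_level
            ch405, ch488 = e405, e488
        frames.append(TwoChannelImage(ch405, ch488))
        for ci, c in enumerate(cell_c):
            truth_rows.append({"frame": fi, "time_s": t, "cell": ci,
                               "true_gsh_mM": float(c), "population_gsh_mM": pop_c})
    truth = pd.DataFrame(truth_rows)
    return frames, np.asarray(cfg.frame_times_s), truth


def _gen_events_one_sample(rng, cfg: GeneratorConfig, true_c_mM: float) -> pd.DataFrame:
    n = cfg.n_events
    n_debris = int(round(cfg.debris_frac * n))
    n_dead = int(round(cfg.dead_frac * n))
    n_doublet = int(round(cfg.doublet_frac * n))
    n_singlet = n - n_debris - n_dead - n_doublet

    def scatter_pair(n, fsc_scale=1.0, ssc_scale=1.0, ah_ratio=1.0):
        fsc_a = fsc_scale * rng.lognormal(np.log(1e5), 0.15, n)
        ssc_a = ssc_scale * rng.lognormal(np.log(5e4), 0.20, n)
        fsc_h = fsc_a / (ah_ratio * np.exp(rng.normal(0, 0.05, n)))
        ssc_h = ssc_a / (ah_ratio * np.exp(rng.normal(0, 0.05, n)))
        return fsc_a, fsc_h, ssc_a, ssc_h

    def fluor_pair(n, c_mM, dim=1.0, ratio_sigma=None):
        sigma = ratio_sigma if ratio_sigma is not None else np.sqrt(np.log1p(cfg.ratio_cv**2))
        r_true = ratio_from_concentration(c_mM, cfg.calibration)
        r = r_true * np.exp(rng.normal(0, sigma, n))
        f488 = dim * rng.lognormal(np.log(1e3), 0.30, n)
        f405 = r * f488 * (1.0 + cfg.gain_drift)
        return f405, f488

    parts = []
    # singlets
    fa, fh, sa, sh = scatter_pair(n_singlet)
    f405, f488 = fluor_pair(n_singlet, true_c_mM)
    parts.append(dict(fsc_a=fa, fsc_h=fh, ssc_a=sa, ssc_h=sh, f405=f405, f488=f488,
                      truth="singlet"))
    # doublets: twice the area per unit height
    if n_doublet:
        fa, fh, sa, sh = scatter_pair(n_doublet, fsc_scale=2.0, ssc_scale=2.0, ah_ratio=1.9)
        f405, f488 = fluor_pair(n_doublet, true_c_mM)
        parts.append(dict(fsc_a=fa, fsc_h=fh, ssc_a=sa, ssc_h=sh,
                          f405=2 * f405, f488=2 * f488, truth="doublet"))
    # debris: tiny scatter, dim fluorescence
    if n_debris:
        fa, fh, sa, sh = scatter_pair(n_debris, fsc_scale=0.03, ssc_scale=0.05)
        f405, f488 = fluor_pair(n_debris, true_c_mM, dim=0.05, ratio_sigma=0.5)
        parts.append(dict(fsc_a=fa, fsc_h=fh, ssc_a=sa, ssc_h=sh, f405=f405, f488=f488,
                          truth="debris"))
    # dead cells: shrunken FSC, granular (high) SSC
    if n_dead:
        fa, fh, sa, sh = scatter_pair(n_dead, fsc_scale=0.3, ssc_scale=3.5)
        f405, f488 = fluor_pair(n_dead, true_c_mM, dim=0.4, ratio_sigma=0.5)
        parts.append(dict(fsc_a=fa, fsc_h=fh, ssc_a=sa, ssc_h=sh, f405=f405, f488=f488,
                          truth="dead"))

    frames = []
    for p in parts:
        truth = p.pop("truth")
        df = pd.DataFrame(p)
        df["truth"] = truth
        frames.append(df)
    events = pd.concat(frames, ignore_index=True)

    # per-channel outliers planted on singlets
    n_out = int(round(cfg.outlier_frac * n))
    if n_out:
        idx = rng.choice(np.flatnonzero(events["truth"] == "singlet"), n_out, replace=False)
        chan = rng.choice(["f405", "f488"], n_out)
        for i, ch in zip(idx, chan):
            events.loc[i, ch] *= 8.0
            events.loc[i, "truth"] = "outlier"
    return events.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


def gen_event_tables(cfg: GeneratorConfig):
    """Per-sample cytometry event tables plus a truth manifest.

    Returns ``(tables, manifest)`` where ``tables`` is a list of
    :class:`~gshquant.cytometry.EventTable` (each with an extra ``truth``
    column labelling planted artifacts) and ``manifest`` a DataFrame of
    per-sample conditions and generating concentrations.
    """
    from .cytometry import EventTable

    rng = cfg.rng("events")
    labels = cfg.sample_labels or tuple(f"sample{i}" for i in range(len(cfg.sample_true_c_mM)))
    tables, rows = [], []
    for label, c in zip(labels, cfg.sample_true_c_mM):
        events = _gen_events_one_sample(rng, cfg, c)
        tables.append(EventTable(events, condition=str(label)))
        rows.append({"condition": str(label), "true_gsh_mM": float(c),
                     "true_median_r": ratio_from_concentration(c, cfg.calibration),
                     "n_events": len(events)})
    return tables, pd.DataFrame(rows)


def bso_dose_series_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset: 10-sample BSO dose series, GSH 8 → 1 mM with dose."""
    doses_uM = (0.9, 1.9, 3.9, 7.8, 15.6, 31.3, 62.5, 125.0, 250.0, 500.0)
    labels = tuple(f"BSO_{d}uM" for d in doses_uM)
    return GeneratorConfig(seed=seed, sample_labels=labels, **overrides)


def erastin_timecourse_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset: ferroptosis time course (0/6/24 h erastin) in HT1080-like cells.

    GSH holds near baseline through 6 h and collapses by 24 h.
    """
    defaults = dict(
        sample_true_c_mM=(4.5, 4.2, 1.2),
        sample_labels=("erastin_0h", "erastin_6h", "erastin_24h"),
    )
    defaults.update(overrides)
    return GeneratorConfig(seed=seed, **defaults)


def gen_assay_data(cfg: GeneratorConfig, true_c_mM=None):
    """Recycling-assay runs, standards and LC-MS areas for given truths.

    The lysis model: ``n_cells_lysed`` cells of volume
    ``cell_volume_um3`` lysed into ``lysate_volume_mL``; lysate
    concentration is therefore the intracellular concentration scaled by
    the volume ratio.  Returns a dict with standards, per-sample runs,
    LC-MS records and the truth table.
    """
    from .assays import RecyclingAssayRun

    rng = cfg.rng("assays")
    if true_c_mM is None:
        true_c_mM = cfg.sample_true_c_mM
    true_c_mM = np.asarray(true_c_mM, float)
    vol_ratio = cfg.n_cells_lysed * cfg.cell_volume_um3 * 1e-15 / (cfg.lysate_volume_mL * 1e-3)

    # standards in lysate-concentration units (mM), spanning the samples
    std_c_mM = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0]) * vol_ratio
    std_resp = cfg.assay_gain_au_per_M_s * std_c_mM * 1e-3
    std_resp = std_resp * (1.0 + rng.normal(0, cfg.assay_noise_cv, std_resp.size))

    times = np.arange(0.0, 121.0, 30.0)  # read every 30 s for 2 min
    runs = []
    for c in true_c_mM:
        lysate_mM = c * vol_ratio
        slope = cfg.assay_gain_au_per_M_s * lysate_mM * 1e-3
        slope *= 1.0 + rng.normal(0, cfg.assay_noise_cv)
        a412 = 0.05 + slope * times + rng.normal(0, 1e-4, times.size)
        runs.append(RecyclingAssayRun(times=times, absorbance_412=a412))

    # LC-MS: areas linear in vial concentration (lysate / dilution)
    lcms_std_c = std_c_mM / cfg.lcms_dilution
    lcms = {
        "standards": {
            "gsh": (lcms_std_c, cfg.lcms_gain_per_mM * lcms_std_c
                    * (1.0 + rng.normal(0, cfg.assay_noise_cv, lcms_std_c.size))),
        },
        "samples": [
            {"gsh": cfg.lcms_gain_per_mM * (c * vol_ratio / cfg.lcms_dilution)
             * (1.0 + rng.normal(0, cfg.assay_noise_cv))}
            for c in true_c_mM
        ],
    }
    truth = pd.DataFrame({"true_gsh_mM": true_c_mM, "lysate_gsh_mM": true_c_mM * vol_ratio})
    return {
        "standards_c_mM": std_c_mM,
        "standards_response": std_resp,
        "runs": runs,
        "lcms": lcms,
        "truth": truth,
        "volume_ratio": vol_ratio,
    }
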