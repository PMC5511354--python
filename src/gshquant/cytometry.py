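"""Flow-cytometry gating and per-cell ratiometric GSH quantification.

Events arrive as tables of forward/side scatter (area and height) plus
two fluorescence channels: f405 (Pacific Blue detector, adduct) and f488
(PE detector, free probe).  The gating chain mirrors standard practice
for this assay: (1) a scatter gate on (FSC-A, SSC-A) removes debris and
dead cells, (2) singlet gates on FSC-A/FSC-H and SSC-A/SSC-H remove
doublets, (3) per-channel mean ± 4 s.d. exclusion removes fluorescence
outliers.  The per-event ratio R = f405/f488 is summarised per sample by
its median (event distributions are skewed), calibrated against
lysate-derived concentrations, and compared across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import fit_calibration

__all__ = [
    "EventTable",
    "GateReport",
    "CHANNEL_COLUMNS",
    "gate_scatter",
    "gate_singlets",
    "exclude_fluorescence_outliers",
    "standard_gating",
    "per_event_ratio_summary",
    "fit_facs_calibration",
    "compare_facs_to_lysate",
    "group_comparison",
]

CHANNEL_COLUMNS = ["fsc_a", "fsc_h", "ssc_a", "ssc_h", "f405", "f488"]


@dataclass
class EventTable:
    """Cytometry events plus per-sample metadata."""

    data: pd.DataFrame
    condition: str = ""
    lysate_gsh_mM: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing channel columns: {missing}")
        if len(self.data) < 1:
            raise ValueError("event table is empty")
        vals = self.data[CHANNEL_COLUMNS].to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("channels must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.data)

    def _with(self, df: pd.DataFrame) -> "EventTable":
        out = EventTable.__new__(EventTable)
        out.data = df
        out.condition = self.condition
        out.lysate_gsh_mM = self.lysate_gsh_mM
        return out

    def to_csv(self, path) -> None:
        self.data[CHANNEL_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str = "", lysate_gsh_mM: float | None = None):
        return cls(pd.read_csv(path), condition=condition, lysate_gsh_mM=lysate_gsh_mM)


@dataclass
class GateReport:
    """Counts surviving each gate stage, plus the thresholds applied."""

    stages: list = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, params: dict) -> None:
        if self.stages and n_in != self.stages[-1]["n_out"]:
            raise ValueError("gate chain is not contiguous")
        if n_out > n_in:
            raise ValueError("gate cannot add events")
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out), "params": params}
        )

    @property
    def fraction_retained(self) -> float:
        if not self.stages:
            return 1.0
        return self.stages[-1]["n_out"] / self.stages[0]["n_in"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def _robust_log_box(x: np.ndarray, n_mad: float) -> tuple[float, float]:
    lx = np.log10(np.maximum(x, 1e-12))
    med = np.median(lx)
    mad = stats.median_abs_deviation(lx, scale="normal")
    return 10 ** (med - n_mad * mad), 10 ** (med + n_mad * mad)


def gate_scatter(
    t: EventTable,
    bounds: dict | None = None,
    reference: EventTable | None = None,
    n_mad: float = 4.0,
    report: GateReport | None = None,
):
    """Rectangular live-cell gate on (FSC-A, SSC-A).

    The region comes from, in order of preference: explicit ``bounds``
    (``{"fsc_a": (lo, hi), "ssc_a": (lo, hi)}``); the 2nd–98th percentile
    box of a clean ``reference`` sample; or a robust median ± ``n_mad``·MAD
    box on log10 scatter of the sample itself (robust default — a
    self-computed percentile box would absorb planted debris).
    """
    if report is None:
        report = GateReport()
    if bounds is not None:
        box = {ch: tuple(bounds[ch]) for ch in ("fsc_a", "ssc_a")}
        for lo, hi in box.values():
            if not hi > lo:
                raise ValueError("invalid scatter bounds")
    elif reference is not None:
        box = {
            ch: (
                float(np.percentile(reference.data[ch], 2)),
                float(np.percentile(reference.data[ch], 98)),
            )
            for ch in ("fsc_a", "ssc_a")
        }
    else:
        box = {
            ch: _robust_log_box(t.data[ch].to_numpy(), n_mad)
            for ch in ("fsc_a", "ssc_a")
        }
    keep = np.ones(len(t), bool)
    for ch, (lo, hi) in box.items():
        v = t.data[ch].to_numpy()
        keep &= (v >= lo) & (v <= hi)
    out = t._with(t.data[keep].reset_index(drop=True))
    report.add("scatter", len(t), int(keep.sum()), {"box": box})
    if keep.sum() == 0:
        warnings.warn("scatter gate removed every event", stacklevel=2)
    return out, report


def gate_singlets(
    t: EventTable, tol: float = 1.3, report: GateReport | None = None
):
    """Retain events near the singlet area-vs-height diagonal.

    For each of FSC and SSC, the per-event area/height ratio must lie in
    ``[r0/tol, r0·tol]`` around the robust (median) singlet ratio;
    doublets carry roughly twice the area per unit height and fall
    outside the band.
    """
    if report is None:
        report = GateReport()
    if tol <= 1.0:
        raise ValueError("tol must exceed 1")
    keep = np.ones(len(t), bool)
    params = {}
    for pref in ("fsc", "ssc"):
        a = t.data[f"{pref}_a"].to_numpy()
        h = np.maximum(t.data[f"{pref}_h"].to_numpy(), 1e-12)
        ratio = a / h
        r0 = float(np.median(ratio))
        keep &= (ratio >= r0 / tol) & (ratio <= r0 * tol)
        params[pref] = {"r0": r0, "tol": tol}
    out = t._with(t.data[keep].reset_index(drop=True))
    report.add("singlets", len(t), int(keep.sum()), params)
    return out, report


def exclude_fluorescence_outliers(
    t: EventTable, n_sd: float = 4.0, report: GateReport | None = None
):
    """Drop events beyond mean ± n_sd standard deviations in f405 or f488.

    Thresholds are computed once per channel on the incoming (already
    scatter/singlet-gated) set, not iteratively, and on raw intensities.
    """
    if report is None:
        report = GateReport()
    if n_sd < 1:
        raise ValueError("n_sd must be >= 1")
    if len(t) < 10:
        raise ValueError("need at least 10 events to estimate channel spread")
    keep = np.ones(len(t), bool)
    params = {}
    for ch in ("f405", "f488"):
        v = t.data[ch].to_numpy()
        mu, sd = float(np.mean(v)), float(np.std(v))
        keep &= np.abs(v - mu) <= n_sd * sd
        params[ch] = {"mean": mu, "sd": sd, "n_sd": n_sd}
    out = t._with(t.data[keep].reset_index(drop=True))
    report.add("fluorescence-outliers", len(t), int(keep.sum()), params)
    return out, report


def standard_gating(t: EventTable, n_sd: float = 4.0, **scatter_kwargs):
    """Scatter → singlet → fluorescence-outlier chain with one report."""
    report = GateReport()
    g, report = gate_scatter(t, report=report, **scatter_kwargs)
    g, report = gate_singlets(g, report=report)
    g, report = exclude_fluorescence_outliers(g, n_sd=n_sd, report=report)
    return g, report


def per_event_ratio_summary(t: EventTable, denominator_floor: float = 0.0) -> dict:
    """Robust per-sample summary of the per-event ratio R = f405/f488."""
    f405 = t.data["f405"].to_numpy()
    f488 = t.data["f488"].to_numpy()
    ok = f488 > denominator_floor
    r = f405[ok] / f488[ok]
    if r.size == 0:
        raise ValueError("no events with usable 488 signal")
    q1, q3 = np.percentile(r, [25, 75])
    return {
        "median_r": float(np.median(r)),
        "iqr": float(q3 - q1),
        "n": int(r.size),
        "n_dropped": int((~ok).sum()),
    }


def fit_facs_calibration(samples):
    """Calibrate sample median ratios against lysate concentrations.

    ``samples`` is a list of ``(median_R, lysate_C_mM)`` pairs; delegates
    to :func:`gshquant.calibration.fit_calibration`.
    """
    r = [s[0] for s in samples]
    c = [s[1] for s in samples]
    return fit_calibration(r, c)


def compare_facs_to_lysate(facs_c_mM, lysate_c_mM):
    """OLS of cytometry-derived on lysate-derived concentrations.

    Returns ``(r_squared, slope, intercept)``.
    """
    f = np.asarray(facs_c_mM, float)
    l = np.asarray(lysate_c_mM, float)
    if f.shape != l.shape:
        raise ValueError("length mismatch")
    if f.size < 3:
        raise ValueError("need at least 3 paired samples")
    fit = stats.linregress(l, f)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def group_comparison(sample_a, sample_b):
    """Two-sided unpaired t-test between per-event concentration samples."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("degenerate variance: identical constant groups")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)
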