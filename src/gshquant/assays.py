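"""Lysate-based ground-truth GSH quantification.

Two orthogonal lysate assays anchor the cytometry and imaging readouts:

* the enzymatic recycling (DTNB/glutathione-reductase) assay, whose
  412-nm absorbance slope is proportional to total GSH in the well, and
* LC-MS quantification of N-methylmaleimide (NMM) thiol adducts
  (GSH-NMM at m/z 419.1, Cys-NMM at m/z 233.0) against standard curves.

Amounts are converted to intracellular concentrations by dividing by the
total cell volume (counted cells × a mean single-cell volume of
4,000 μm³ for HeLa/HT1080).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RecyclingAssayRun",
    "StandardCurve",
    "DEFAULT_CELL_VOLUME_UM3",
    "GSH_NMM_MZ",
    "CYS_NMM_MZ",
    "assay_slope",
    "fit_standard_curve",
    "lysate_concentration",
    "intracellular_concentration",
    "lcms_quantify",
]

DEFAULT_CELL_VOLUME_UM3 = 4000.0
GSH_NMM_MZ = 419.1
CYS_NMM_MZ = 233.0


@dataclass
class RecyclingAssayRun:
    """One well's 412-nm absorbance time series (times in s)."""

    times: np.ndarray
    absorbance_412: np.ndarray
    dilution: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.absorbance_412 = np.asarray(self.absorbance_412, float)
        if self.times.shape != self.absorbance_412.shape:
            raise ValueError("times and absorbance differ in length")
        if self.times.size < 4:
            raise ValueError("need at least 4 readings over the assay window")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class StandardCurve:
    """Linear response = slope·C + intercept with its fit quality."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            warnings.warn("standard curve slope is non-positive", stacklevel=3)


def assay_slope(run: RecyclingAssayRun) -> float:
    """OLS slope of A412 on time (AU/s); the GSH-proportional readout."""
    if run.times.size < 3:
        raise ValueError("need at least 3 points")
    fit = stats.linregress(run.times, run.absorbance_412)
    if fit.slope < 0:
        warnings.warn("decreasing absorbance: assay failure suspected", stacklevel=2)
    return float(fit.slope)


def fit_standard_curve(responses, concentrations) -> StandardCurve:
    """Linear standard curve of response on known concentration."""
    r = np.asarray(responses, float)
    c = np.asarray(concentrations, float)
    if r.shape != c.shape:
        raise ValueError("responses and concentrations differ in length")
    if r.size < 3:
        raise ValueError("need at least 3 standards")
    if np.unique(c).size < 2:
        raise ValueError("standards must span distinct concentrations")
    fit = stats.linregress(c, r)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def lysate_concentration(response: float, sc: StandardCurve, dilution: float = 1.0):
    """Invert a standard curve; returns ``(concentration, flag)``.

    Concentration is in the standard curve's units times the dilution
    factor.  Sub-blank responses clamp to zero with flag
    ``"below-blank"``.
    """
    if sc.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    c = dilution * (response - sc.intercept) / sc.slope
    if c < 0:
        return 0.0, "below-blank"
    return float(c), "ok"


def intracellular_concentration(
    amount_mol: float,
    n_cells: int,
    cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3,
) -> float:
    """Convert a molar amount to intracellular concentration in mM.

    ``C = amount / (n_cells × cell_volume)`` with 1 μm³ = 1e-15 L.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if cell_volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    volume_L = n_cells * cell_volume_um3 * 1e-15
    return amount_mol / volume_L * 1e3  # mol/L -> mM


def lcms_quantify(
    peak_areas: dict[str, float],
    standards: dict[str, StandardCurve],
    dilution: float = 100.0,
) -> dict[str, tuple[float, str] | None]:
    """Per-ion standard-curve inversion for NMM thiol adducts.

    ``peak_areas`` maps analyte names (e.g. ``"gsh"``, ``"cys"``) to
    integrated areas; each analyte needs a matching standard curve.  The
    sample dilution factor (samples are typically measured at 100×
    dilution) is applied.  Analytes with no peak are reported as None.
    """
    out: dict[str, tuple[float, str] | None] = {}
    for analyte, curve in standards.items():
        if analyte not in peak_areas or peak_areas[analyte] is None:
            out[analyte] = None
            continue
        out[analyte] = lysate_concentration(peak_areas[analyte], curve, dilution)
    return out
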