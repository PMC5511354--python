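"""Ratio-to-concentration calibration for the ratiometric GSH readout.

Intracellular calibration follows the Grynkiewicz-style saturation form

    (R − Rmin) / (Rmax − R) = k · C_GSH

where Rmin and Rmax are the limiting ratios at zero and saturating GSH and
k (mM⁻¹) absorbs the channel brightness ratio and the binding constant.
Neither limit is directly measurable in cells, so all three parameters are
obtained by fitting paired (ratio, lysate concentration) observations; the
fitted model is then inverted to convert ratios into concentrations.

The forward map ``R(C) = (Rmin + k C Rmax) / (1 + k C)`` is exactly the
dilute-probe limit of the two-state spectral model in :mod:`.binding`,
with ``k = (s488_bound / s488_free) / Kd``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "CalibrationModel",
    "HELA_CALIBRATION",
    "HT1080_CALIBRATION",
    "fit_calibration",
    "ratio_from_concentration",
    "concentration_from_ratio",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted calibration: limiting ratios and the response constant.

    ``k`` is expressed per mM so that inverted concentrations come out in
    mM, the unit of all reported intracellular GSH levels.
    """

    r_min: float
    r_max: float
    k: float
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")
        if not self.k > 0:
            raise ValueError("k must be positive")


#: Published anchors for the HeLa FACS calibration; k chosen so the
#: calibration midpoint (C = 1/k) coincides with the in-vitro Kd of
#: 3.7 mM through a bound/free 488-channel brightness ratio of 0.7.
HELA_CALIBRATION = CalibrationModel(r_min=1.65, r_max=2.98, k=0.7 / 3.7, cell_line="HeLa")
#: Published anchors for the HT1080 FACS calibration (same k convention).
HT1080_CALIBRATION = CalibrationModel(r_min=1.60, r_max=6.01, k=0.7 / 3.7, cell_line="HT1080")


def ratio_from_concentration(c_mM, cm: CalibrationModel):
    """Forward calibration map; C in mM, saturating to Rmax as C → ∞."""
    c = np.asarray(c_mM, float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    u = cm.k * c
    r = (cm.r_min + u * cm.r_max) / (1.0 + u)
    return float(r) if r.ndim == 0 else r


def concentration_from_ratio(r, cm: CalibrationModel):
    """Invert the calibration: C = (R − Rmin) / (k (Rmax − R)).

    Ratios at or below Rmin map to 0 mM with flag ``"below-range"``;
    ratios at or above Rmax map to ``inf`` with flag ``"saturated"``
    (live-cell pixels and events routinely stray past fitted limits, so
    out-of-range values are clamped and flagged rather than rejected).

    Returns ``(concentration_mM, flag)``; arrays in, arrays out.
    """
    r_arr = np.asarray(r, float)
    if not np.all(np.isfinite(r_arr)):
        raise ValueError("ratio must be finite")
    below = r_arr <= cm.r_min
    above = r_arr >= cm.r_max
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (r_arr - cm.r_min) / (cm.k * (cm.r_max - r_arr))
    c = np.where(below, 0.0, np.where(above, np.inf, c))
    flags = np.where(below, "below-range", np.where(above, "saturated", "ok"))
    if r_arr.ndim == 0:
        return float(c), str(flags)
    return c, flags


def fit_calibration(ratios, concentrations_mM, eps: float = 0.05):
    """Fit (Rmin, Rmax, k) to paired ratio/known-concentration samples.

    Nonlinear least squares with residuals in R-space (the linearizing
    transform diverges near Rmax, so fitting the transform would let the
    highest samples dominate).  Initialization: Rmin just below the lowest
    observed ratio, Rmax just above the highest, k from the linearized
    transform.  Rmax is bounded above the largest observation; if the
    unconstrained optimum pushes against that bound the fit is retried
    with an expanded bound and a warning.

    Returns ``(CalibrationModel, diagnostics)``.
    """
    r = np.asarray(ratios, float)
    c = np.asarray(concentrations_mM, float)
    if r.shape != c.shape:
        raise ValueError("ratios and concentrations differ in length")
    if r.size < 4:
        raise ValueError("need at least 4 calibration samples")
    pos = c[c > 0]
    if pos.size and pos.max() / pos.min() < 3.0:
        warnings.warn("calibration samples span < 3-fold in concentration", stacklevel=2)
    if np.ptp(r) < 1e-12 * max(abs(r).max(), 1.0):
        raise ValueError("degenerate calibration: all ratios equal")

    rmin0 = r.min() - eps
    rmax0 = r.max() + eps
    if rmin0 <= 0:
        rmin0 = 0.5 * r.min()
    t = (r - rmin0) / (rmax0 - r)
    k0 = max(np.sum(t * c) / np.sum(c * c), 1e-6)

    def model(cc, rmin, rmax, k):
        u = k * cc
        return (rmin + u * rmax) / (1.0 + u)

    margin = 1e-9
    lo = [1e-12, r.max() + margin, 1e-12]
    hi = [r.min(), np.inf, np.inf]
    popt, pcov = optimize.curve_fit(
        model, c, r, p0=[rmin0, rmax0, k0], bounds=(lo, hi), maxfev=20000
    )
    if popt[1] <= r.max() + 10 * margin:
        warnings.warn(
            "fitted Rmax pinned at the largest observed ratio; "
            "refitting with expanded bound",
            stacklevel=2,
        )
        lo[1] = r.max() + 1e-12
        popt, pcov = optimize.curve_fit(
            model, c, r, p0=popt, bounds=(lo, hi), maxfev=20000
        )
    resid = model(c, *popt) - r
    ss_tot = np.sum((r - r.mean()) ** 2)
    diagnostics = {
        "stderr": np.sqrt(np.diag(pcov)),
        "r_squared": 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan,
        "n": int(r.size),
    }
    cm = CalibrationModel(r_min=float(popt[0]), r_max=float(popt[1]), k=float(popt[2]))
    return cm, diagnostics


def save_calibration(cm: CalibrationModel, path) -> None:
    """Serialize as a flat TOML key-value file."""
    with open(path, "w") as fh:
        fh.write(f"r_min = {cm.r_min!r}\n")
        fh.write(f"r_max = {cm.r_max!r}\n")
        fh.write(f"k_per_mM = {cm.k!r}\n")
        fh.write(f'cell_line = "{cm.cell_line}"\n')


def load_calibration(path) -> CalibrationModel:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return CalibrationModel(
        r_min=data["r_min"],
        r_max=data["r_max"],
        k=data["k_per_mM"],
        cell_line=data.get("cell_line", ""),
    )
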