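"""Two-state reversible probe–thiol binding and the spectral ratio model.

The probe P reacts reversibly with glutathione G to form a 1:1 Michael
adduct A, with dissociation constant ``Kd = [P][G]/[A]``.  The sensing
readout is the ratio R of fluorescence excited at 405 nm (dominated by the
adduct) to fluorescence excited at 488 nm (dominated by the free probe).
This module solves the mass-action equilibrium, evaluates the spectral
ratio forward model, simulates titrations, estimates Kd from titration
data, and partitions the probe among competing thiols.

All concentrations are handled internally in mol/L; CSV interfaces use mM
because intracellular glutathione lives in the 1–10 mM range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BindingParameters",
    "Photophysics",
    "ChemicalState",
    "TitrationCurve",
    "FLUORIMETER_PHOTOPHYSICS",
    "HELA_FACS_PHOTOPHYSICS",
    "GPC_GSH_FRACTION",
    "GPC_PROTEIN_FRACTION",
    "adduct_concentration",
    "equilibrium_state",
    "ratio_from_state",
    "simulate_titration",
    "fit_kd",
    "competitive_partition",
    "linearity_check",
]

#: Empirical partition of reacted probe between glutathione and protein
#: thiols in cells, from gel-permeation chromatography; not derivable from
#: the competition model (no protein-thiol Kd is available).
GPC_GSH_FRACTION = 0.90
GPC_PROTEIN_FRACTION = 0.10


@dataclass(frozen=True)
class BindingParameters:
    """Equilibrium description of the probe–GSH adduct.

    Parameters
    ----------
    kd : float
        Dissociation constant in mol/L.  The probe operates around
        3.7e-3 M, the midpoint of the physiological GSH range.
    kd_stderr : float, optional
        Standard error of a fitted ``kd``, mol/L.
    """

    kd: float
    kd_stderr: float | None = None

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")

    @property
    def kd_mM(self) -> float:
        return self.kd * 1e3


@dataclass(frozen=True)
class Photophysics:
    """Per-species, per-channel brightness coefficients.

    ``s405_*`` / ``s488_*`` are fluorescence per unit concentration
    (arbitrary units / M) for the free probe and the adduct under 405-nm
    and 488-nm excitation; ``bg405`` / ``bg488`` are additive backgrounds.
    The adduct dominates the 405 channel and the free probe the 488
    channel, so ``s405_bound > s405_free`` and ``s488_free > s488_bound``.
    """

    s405_free: float
    s405_bound: float
    s488_free: float
    s488_bound: float
    bg405: float = 0.0
    bg488: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s405_free", "s405_bound", "s488_free", "s488_bound"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.s405_bound > self.s405_free:
            raise ValueError("adduct must dominate the 405 channel")
        if not self.s488_free > self.s488_bound:
            raise ValueError("free probe must dominate the 488 channel")

    @property
    def r_min(self) -> float:
        """Limiting ratio with no adduct (background-free)."""
        return self.s405_free / self.s488_free

    @property
    def r_max(self) -> float:
        """Limiting ratio at saturating GSH (background-free)."""
        return self.s405_bound / self.s488_bound

    @property
    def w488(self) -> float:
        """Bound/free brightness ratio in the 488 channel."""
        return self.s488_bound / self.s488_free


#: In-vitro fluorimeter-like fixture: the free probe is nearly dark under
#: 405-nm excitation and the adduct nearly dark under 488-nm excitation,
#: giving the wide, near-linear ratio response observed on a fluorimeter
#: over 1-10 mM GSH.
FLUORIMETER_PHOTOPHYSICS = Photophysics(
    s405_free=0.02, s405_bound=1.0, s488_free=1.0, s488_bound=0.04
)

#: Intracellular FACS-anchored fixture for HeLa cells: limiting ratios
#: reproduce the fitted calibration anchors Rmin=1.65, Rmax=2.98.
HELA_FACS_PHOTOPHYSICS = Photophysics(
    s405_free=1.65, s405_bound=2.98 * 0.7, s488_free=1.0, s488_bound=0.7
)


@dataclass(frozen=True)
class ChemicalState:
    """Equilibrium composition of a probe/GSH mixture (all mol/L)."""

    p_total: float
    g_total: float
    adduct: float

    def __post_init__(self) -> None:
        ub = min(self.p_total, self.g_total)
        if not (-1e-12 <= self.adduct <= ub + 1e-12 * max(ub, 1.0)):
            raise ValueError("adduct outside [0, min(p_total, g_total)]")

    @property
    def free_probe(self) -> float:
        return self.p_total - self.adduct

    @property
    def free_gsh(self) -> float:
        return self.g_total - self.adduct

    def mass_action_residual(self, kd: float) -> float:
        return self.free_probe * self.free_gsh - kd * self.adduct


@dataclass
class TitrationCurve:
    """Ratio readouts over a grid of total GSH concentrations (mol/L)."""

    gsh_concentrations: np.ndarray
    ratios: np.ndarray
    noise_model: str = "none"

    def __post_init__(self) -> None:
        self.gsh_concentrations = np.asarray(self.gsh_concentrations, float)
        self.ratios = np.asarray(self.ratios, float)
        if self.gsh_concentrations.shape != self.ratios.shape:
            raise ValueError("concentration and ratio arrays differ in length")
        if np.any(np.diff(self.gsh_concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.ratios)):
            raise ValueError("ratios must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"gsh_mM": self.gsh_concentrations * 1e3, "ratio": self.ratios}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TitrationCurve":
        df = pd.read_csv(path)
        return cls(df["gsh_mM"].to_numpy() * 1e-3, df["ratio"].to_numpy())


def adduct_concentration(p_total, g_total, kd):
    """Equilibrium adduct concentration from the 1:1 mass balance.

    Solves ``A**2 - (P_T + G_T + Kd) A + P_T G_T = 0`` for the physically
    admissible (smaller) root, using the numerically stable quadratic form
    ``A = 2c / (b + sqrt(b**2 - 4c))`` so that the micromolar-probe /
    millimolar-ligand regime does not suffer catastrophic cancellation.

    Accepts scalars or arrays (broadcast); concentrations in mol/L.
    """
    p = np.asarray(p_total, float)
    g = np.asarray(g_total, float)
    if np.any(p < 0) or np.any(g < 0):
        raise ValueError("total concentrations must be non-negative")
    if not np.all(np.asarray(kd) > 0):
        raise ValueError("kd must be positive")
    b = p + g + kd
    c = p * g
    disc = np.sqrt(np.maximum(b * b - 4.0 * c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(b > 0, 2.0 * c / (b + disc), 0.0)
    if a.ndim == 0:
        return float(a)
    return a


def equilibrium_state(p_total: float, g_total: float, bp: BindingParameters) -> ChemicalState:
    """Convenience wrapper returning a full :class:`ChemicalState`."""
    a = adduct_concentration(p_total, g_total, bp.kd)
    return ChemicalState(p_total=p_total, g_total=g_total, adduct=a)


def ratio_from_state(state: ChemicalState, ph: Photophysics) -> float:
    """Spectral ratio R = F405/F488 for an equilibrium composition."""
    num = ph.s405_bound * state.adduct + ph.s405_free * state.free_probe + ph.bg405
    den = ph.s488_bound * state.adduct + ph.s488_free * state.free_probe + ph.bg488
    if den <= 0:
        raise ZeroDivisionError("488-channel signal is zero; ratio undefined")
    return num / den


def _model_ratios(gsh_grid, p_total, kd, ph: Photophysics):
    """Vectorized forward model R(C) through the full mass balance."""
    a = adduct_concentration(p_total, np.asarray(gsh_grid, float), kd)
    p = p_total - a
    num = ph.s405_bound * a + ph.s405_free * p + ph.bg405
    den = ph.s488_bound * a + ph.s488_free * p + ph.bg488
    return num / den


def simulate_titration(
    gsh_grid,
    p_total: float,
    bp: BindingParameters,
    ph: Photophysics = FLUORIMETER_PHOTOPHYSICS,
) -> TitrationCurve:
    """Noise-free titration of the ratio readout over a GSH grid (mol/L)."""
    grid = np.asarray(gsh_grid, float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return TitrationCurve(grid, _model_ratios(grid, p_total, bp.kd, ph))


def fit_kd(
    curve: TitrationCurve,
    p_total: float,
    ph: Photophysics = FLUORIMETER_PHOTOPHYSICS,
    fit_limits: bool = False,
    kd_init: float = 3.7e-3,
):
    """Estimate Kd from a ratio titration by nonlinear least squares.

    The ratio of a dilute probe constrains only the combination
    ``w488 / Kd``, so Kd estimation requires the channel brightnesses to
    be known; ``ph`` supplies them.  By default only Kd is free, with the
    limiting ratio Rmin pinned from the curve's zero-concentration extreme
    when present (Rmax is unobservable on a non-saturating curve and comes
    from ``ph``).  With ``fit_limits=True`` both limiting ratios are freed
    alongside Kd, keeping ``w488`` fixed.

    Returns ``(BindingParameters, diagnostics)`` where diagnostics carry
    the standard error, residual norm and identifiability warnings.
    """
    conc = curve.gsh_concentrations
    robs = curve.ratios
    if conc.size < 5:
        raise ValueError("need at least 5 titration points")

    ph_eff = ph
    if conc[0] == 0.0 and not fit_limits:
        # pin Rmin from the zero-GSH extreme, preserving w488
        scale = robs[0] / ph.r_min if ph.r_min > 0 else 1.0
        ph_eff = replace(ph, s405_free=ph.s405_free * scale)

    w = ph_eff.w488

    def model(theta):
        if fit_limits:
            log_kd, rmin, rmax = theta
            ph_t = Photophysics(
                s405_free=rmin * ph_eff.s488_free,
                s405_bound=rmax * ph_eff.s488_bound,
                s488_free=ph_eff.s488_free,
                s488_bound=ph_eff.s488_bound,
                bg405=ph_eff.bg405,
                bg488=ph_eff.bg488,
            )
        else:
            (log_kd,) = theta
            ph_t = ph_eff
        return _model_ratios(conc, p_total, np.exp(log_kd), ph_t)

    if fit_limits:
        x0 = [np.log(kd_init), ph_eff.r_min, ph_eff.r_max]
    else:
        x0 = [np.log(kd_init)]
    res = optimize.least_squares(lambda t: model(t) - robs, x0, method="lm")
    if not res.success:
        raise RuntimeError(f"Kd fit did not converge: {res.message}")
    kd_hat = float(np.exp(res.x[0]))

    # covariance from the Jacobian (Gauss-Newton approximation)
    dof = max(conc.size - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        kd_se = kd_hat * float(np.sqrt(cov[0, 0]))  # delta method on log-Kd
    except np.linalg.LinAlgError:
        kd_se = np.inf

    diagnostics = {
        "kd_stderr": kd_se,
        "residual_norm": float(np.sqrt(2.0 * res.cost)),
        "n_points": int(conc.size),
        "warnings": [],
    }
    # identifiability: with the limiting ratios free, only curvature in the
    # response separates Kd from the limits, so the data must bracket the
    # ratio-response midpoint (C = Kd / w488 for a dilute probe)
    c_mid = kd_hat / w if w > 0 else np.inf
    if fit_limits and conc.max() < c_mid:
        msg = "ill-conditioned: titration does not bracket the response midpoint"
        diagnostics["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)
    if not np.isfinite(kd_se) or kd_se > 0.5 * kd_hat:
        msg = "wide confidence interval: Kd poorly identified"
        diagnostics["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)
    return BindingParameters(kd=kd_hat, kd_stderr=kd_se), diagnostics


def competitive_partition(thiols, p_total: float, full_solve: bool = False):
    """Fraction of the adduct pool formed with each competing thiol.

    ``thiols`` is a list of ``(concentration, kd)`` pairs in mol/L.  In
    the dilute-probe regime the partition is analytic:
    ``f_i = (C_i/Kd_i) / sum_j (C_j/Kd_j)``.  With ``full_solve=True`` the
    coupled mass balances are solved exactly by bracketing the free-probe
    concentration.
    """
    if len(thiols) == 0:
        raise ValueError("at least one thiol required")
    conc = np.array([c for c, _ in thiols], float)
    kds = np.array([k for _, k in thiols], float)
    if np.any(conc < 0) or np.any(kds <= 0):
        raise ValueError("concentrations must be >= 0 and kds > 0")
    if not full_solve:
        if np.any(conc > 0) and p_total > 0.01 * conc[conc > 0].min():
            warnings.warn(
                "probe not dilute relative to every thiol; "
                "consider full_solve=True",
                stacklevel=2,
            )
        load = conc / kds
        total = load.sum()
        if total == 0:
            raise ValueError("all thiol concentrations are zero")
        return load / total

    def bound_total(p_free):
        return np.sum(p_free * conc / (kds + p_free))

    f = lambda p_free: p_free + bound_total(p_free) - p_total
    p_free = optimize.brentq(f, 0.0, p_total, xtol=1e-18, rtol=1e-14)
    adducts = p_free * conc / (kds + p_free)
    return adducts / adducts.sum()


def linearity_check(curve: TitrationCurve, c_lo: float, c_hi: float) -> float:
    """R-squared of an ordinary least-squares line of R on C in a window."""
    sel = (curve.gsh_concentrations >= c_lo) & (curve.gsh_concentrations <= c_hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points inside the window")
    fit = stats.linregress(curve.gsh_concentrations[sel], curve.ratios[sel])
    return float(fit.rvalue**2)
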