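"""Reversible association kinetics of the probe–GSH adduct.

The adduct forms by a second-order forward reaction (rate constant ``kf``,
M⁻¹ s⁻¹) and dissociates by a first-order reverse reaction (``kr``, s⁻¹):

    dA/dt = kf (P_T − A)(G_T − A) − kr A

With GSH in large excess the relaxation is single-exponential with
observed rate ``kobs = kf·G_T + kr``; this is how the constants are
measured experimentally (exponential fits at several GSH concentrations,
then a line of kobs on G_T whose slope is kf and intercept kr, with the
reverse rate also accessible from dilution-relaxation experiments).

Because the rate law is quadratic with constant coefficients, it also has
an exact closed-form solution (two-root Riccati form), used here both as
the fast simulation path and as an oracle for the numerical integrator.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .binding import adduct_concentration

__all__ = [
    "KineticParameters",
    "KineticTrace",
    "simulate_timecourse",
    "dilution_relaxation",
    "fit_observed_rate",
    "fit_forward_reverse",
    "rate_ratio",
    "pseudo_first_order_kobs",
]


@dataclass(frozen=True)
class KineticParameters:
    """Forward (kf, M⁻¹ s⁻¹) and reverse (kr, s⁻¹) rate constants."""

    kf: float
    kr: float

    def __post_init__(self) -> None:
        if not self.kf > 0:
            raise ValueError("kf must be positive")
        if self.kr < 0:
            raise ValueError("kr must be non-negative")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant implied by the rates, mol/L."""
        return self.kr / self.kf


@dataclass
class KineticTrace:
    """A time series of adduct concentration or fluorescence signal."""

    times: np.ndarray
    signal: np.ndarray
    p_total: float | None = None
    g_total: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.signal = np.asarray(self.signal, float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal differ in length")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        """Write `time_s, signal` with `#`-prefixed metadata header lines."""
        buf = io.StringIO()
        if self.p_total is not None:
            buf.write(f"# p_total_M = {self.p_total!r}\n")
        if self.g_total is not None:
            buf.write(f"# g_total_M = {self.g_total!r}\n")
        for k, v in self.meta.items():
            buf.write(f"# {k} = {v!r}\n")
        pd.DataFrame({"time_s": self.times, "signal": self.signal}).to_csv(
            buf, index=False
        )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "KineticTrace":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = eval(val.strip(), {"__builtins__": {}})
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        return cls(
            df["time_s"].to_numpy(),
            df["signal"].to_numpy(),
            p_total=meta.pop("p_total_M", None),
            g_total=meta.pop("g_total_M", None),
            meta=meta,
        )


def pseudo_first_order_kobs(kp: KineticParameters, g_total: float) -> float:
    """Observed relaxation rate in the excess-GSH regime: kf·G_T + kr."""
    return kp.kf * g_total + kp.kr


def _closed_form(p_tot, g_tot, a0, kp: KineticParameters, times):
    """Exact solution of dA/dt = kf(P−A)(G−A) − kr·A.

    The right-hand side is kf·(A − A1)(A − A2) with A1 < A2 the roots of
    the equilibrium quadratic; integrating the Riccati equation gives
    (A−A1)/(A−A2) = ((a0−A1)/(a0−A2))·exp(−kf(A2−A1) t).  A1 is the
    physical equilibrium and kf·(A2−A1) the exact relaxation rate, which
    reduces to kf·G_T + kr when GSH is in large excess.
    """
    kd = kp.kd
    b = p_tot + g_tot + kd
    if kp.kr == 0:
        # irreversible limit: roots are min/max of (P_T, G_T)
        a1, a2 = min(p_tot, g_tot), max(p_tot, g_tot)
    else:
        a1 = adduct_concentration(p_tot, g_tot, kd)
        a2 = b - a1  # root sum
    t = np.asarray(times, float)
    if a2 - a1 < 1e-15 * max(a2, 1.0):
        # degenerate double root: algebraic approach A = a1 - u0/(1 + kf u0 t)
        u0 = a1 - a0
        return a1 - u0 / (1.0 + kp.kf * u0 * t)
    rate = kp.kf * (a2 - a1)
    if a0 == a2:
        return np.full_like(t, a0)
    q0 = (a0 - a1) / (a0 - a2)
    e = q0 * np.exp(-rate * t)
    return (a1 - a2 * e) / (1.0 - e)


def simulate_timecourse(
    p0: float,
    g0: float,
    a0: float,
    kp: KineticParameters,
    times,
    method: str = "auto",
) -> KineticTrace:
    """Adduct concentration over time from initial free/bound composition.

    ``p0``/``g0`` are initial *free* probe and GSH, ``a0`` the initial
    adduct (all mol/L); totals are ``P_T = p0 + a0``, ``G_T = g0 + a0``.
    ``method`` is ``"auto"`` (closed form), ``"closed"``, or ``"ode"``
    (adaptive LSODA at rtol 1e-9, kept as an independent numerical path).
    """
    times = np.asarray(times, float)
    if np.any(times < 0):
        raise ValueError("negative time")
    if min(p0, g0, a0) < 0:
        raise ValueError("negative concentration")
    p_tot, g_tot = p0 + a0, g0 + a0

    if method in ("auto", "closed"):
        sig = _closed_form(p_tot, g_tot, a0, kp, times)
    elif method == "ode":
        def rhs(_t, y):
            a = y[0]
            return [kp.kf * (p_tot - a) * (g_tot - a) - kp.kr * a]

        # stiff when kf·G_T >> kr; LSODA switches automatically
        tmax = times[-1] if times.size else 0.0
        sol = integrate.solve_ivp(
            rhs,
            (0.0, max(tmax, 1e-12)),
            [a0],
            t_eval=np.maximum(times, 0.0),
            method="LSODA",
            rtol=1e-9,
            atol=1e-15,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        sig = sol.y[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    return KineticTrace(times, sig, p_total=p_tot, g_total=g_tot)


def dilution_relaxation(
    eq_p_total: float,
    eq_g_total: float,
    kp: KineticParameters,
    dilution_factor: float,
    times,
) -> KineticTrace:
    """Relaxation after diluting a pre-equilibrated probe/GSH mixture.

    The mixture is first equilibrated at ``(eq_p_total, eq_g_total)`` with
    Kd = kr/kf, then all species are divided by ``dilution_factor`` and the
    net adduct dissociation toward the new equilibrium is simulated.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    a_eq = adduct_concentration(eq_p_total, eq_g_total, kp.kd) if kp.kr > 0 else None
    if a_eq is None:
        a_eq = min(eq_p_total, eq_g_total)  # irreversible limit
    a0 = a_eq / dilution_factor
    p0 = (eq_p_total - a_eq) / dilution_factor
    g0 = (eq_g_total - a_eq) / dilution_factor
    return simulate_timecourse(p0, g0, a0, kp, times)


def fit_observed_rate(trace: KineticTrace):
    """Single-exponential fit y(t) = y_inf + (y0 − y_inf)·exp(−kobs·t).

    Initialization comes from a log-linearization of the approach to the
    terminal value.  Returns ``(kobs, amplitude, offset, diagnostics)``
    where amplitude = y0 − y_inf and offset = y_inf.
    """
    t, y = trace.times, trace.signal
    if t.size < 8:
        raise ValueError("need at least 8 time points")
    span = y.max() - y.min()
    if span == 0 or span < 1e-12 * max(abs(y).max(), 1e-300):
        warnings.warn("constant trace: kobs unidentifiable", stacklevel=2)
        return np.nan, 0.0, float(y[0]), {"flag": "unidentifiable"}

    y_inf0 = float(y[-1])
    y00 = float(y[0])
    resid = y - y_inf0
    sign = np.sign(y00 - y_inf0) or 1.0
    ok = sign * resid > 0.05 * abs(span)
    if ok.sum() >= 2:
        slope = stats.linregress(t[ok], np.log(sign * resid[ok])).slope
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)

    def model(tt, k, amp, off):
        return off + amp * np.exp(-k * tt)

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[k0, y00 - y_inf0, y_inf0], maxfev=10000
        )
    except RuntimeError as err:
        raise RuntimeError(f"exponential fit did not converge: {err}") from err
    kobs, amp, off = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    diag = {"kobs_stderr": float(perr[0]), "flag": "ok"}
    if kobs <= 0:
        diag["flag"] = "nonpositive-rate"
        warnings.warn("fitted kobs is non-positive", stacklevel=2)
    return kobs, amp, off, diag


def fit_forward_reverse(
    traces: list[KineticTrace],
    dilution_traces: list[KineticTrace] | None = None,
    refine: bool = False,
) -> tuple[KineticParameters, dict]:
    """Estimate (kf, kr) from pseudo-first-order traces at several G_T.

    Each trace is fit for its observed rate; a weighted linear regression
    of kobs on G_T then gives kf (slope) and kr (intercept).  With
    ``refine=True`` the estimates are polished by a joint least-squares
    fit of the full reversible rate law to all traces, including any
    dilution-relaxation traces (the experiment that isolates kr).
    """
    g_vals = [tr.g_total for tr in traces]
    if any(g is None for g in g_vals):
        raise ValueError("traces must carry g_total metadata")
    if len(set(g_vals)) < 3:
        raise ValueError("need traces at >= 3 distinct GSH concentrations")
    for tr in traces:
        if tr.p_total is not None and tr.g_total < 100 * tr.p_total:
            warnings.warn(
                "trace outside the pseudo-first-order regime "
                f"(G_T/P_T = {tr.g_total / tr.p_total:.1f})",
                stacklevel=2,
            )

    kobs, weights = [], []
    for tr in traces:
        k, _, _, diag = fit_observed_rate(tr)
        kobs.append(k)
        se = diag.get("kobs_stderr", 0.0)
        weights.append(1.0 / se**2 if se and np.isfinite(se) and se > 0 else 1.0)
    kobs = np.asarray(kobs)
    g = np.asarray(g_vals, float)
    w = np.asarray(weights)
    w = w / w.max()
    # weighted least squares line kobs = kf*G + kr
    W = np.diag(w)
    X = np.column_stack([g, np.ones_like(g)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ kobs)
    kf_hat, kr_hat = float(beta[0]), max(float(beta[1]), 0.0)

    diag = {"kobs": kobs, "g_totals": g, "refined": False}
    if refine:
        all_traces = list(traces) + list(dilution_traces or [])

        amps = [max(np.ptp(tr.signal), 1e-300) for tr in all_traces]

        def residuals(theta):
            kf, kr = np.exp(theta[0]), np.exp(theta[1])
            kp = KineticParameters(kf=kf, kr=kr)
            out = []
            for tr, amp in zip(all_traces, amps):
                a0 = tr.meta.get("a0", 0.0)
                pred = _closed_form(tr.p_total, tr.g_total, a0, kp, tr.times)
                scale = tr.meta.get("signal_scale", 1.0)
                offset = tr.meta.get("signal_offset", 0.0)
                # normalize per trace so μM-scale signals don't trip
                # absolute convergence tolerances
                out.append(((scale * pred + offset) - tr.signal) / amp)
            return np.concatenate(out)

        x0 = [np.log(kf_hat), np.log(max(kr_hat, 1e-8))]
        res = optimize.least_squares(residuals, x0, ftol=1e-13, xtol=1e-13, gtol=1e-13)
        if res.success:
            kf_hat, kr_hat = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
            diag["refined"] = True
    return KineticParameters(kf=kf_hat, kr=kr_hat), diag


def rate_ratio(k_a: float, k_b: float) -> float:
    """Fold difference between two rate constants."""
    if k_b == 0:
        raise ZeroDivisionError("reference rate constant is zero")
    return k_a / k_b
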