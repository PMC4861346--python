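"""Isotope/analogue tracer kinetics on a balanced background.

A tracer (e.g. 22Na) is carried by the same machinery as its parent ion
but is present at trace level, so the background state stays put while
the tracer equilibrates monoexponentially.  The tracer occupies the model
"Li slot": a channel permeability, a Cl-cotransport coefficient, an
optional pump rate and a countertransport coefficient against Na — the
last is what turns coupled Na/Na self-exchange into an observable
(22Na/Na exchange speeds up tracer equilibration without moving any net
flux).

Two simulation modes are provided: the default clamps the background
(trace amounts cannot perturb it, and the curve is then exactly
monoexponential), while ``mode="full"`` integrates the tracer through
the full model in the Li slot for cross-validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from . import integrator as _integrator
from .model import (CellState, Medium, TransportParams, _solve_u,
                    _voltage_factor)


@dataclass(frozen=True)
class TracerSpec:
    """Transport coefficients of the tracer species.

    ``p``: channel permeability (min-1); ``ic``: Cl-cotransport
    coefficient (ml umol-1 min-1); ``alpha``: pump rate (min-1, zero for
    ions the pump does not carry); ``kp``: countertransport coefficient
    against Na (ml umol-1 min-1) — the self-exchange knob.
    """

    p: float
    ic: float
    alpha: float = 0.0
    kp: float = 0.0

    @classmethod
    def na_like(cls, params: TransportParams, kp: float = 0.0,
                include_pump: bool = True) -> "TracerSpec":
        """22Na-style tracer: Na-carrier coefficients, optional pump."""
        return cls(p=params.pna, ic=params.inc,
                   alpha=params.beta if include_pump else 0.0, kp=kp)


@dataclass
class TracerCurve:
    """Tracer content (mM equivalents in cell water) vs time (min)."""

    times: np.ndarray
    content: np.ndarray
    direction: str     # "gain" | "loss"


@dataclass
class RateFit:
    """Monoexponential fit y = y_inf*(1-exp(-kt)) or y = y_0*exp(-kt)."""

    k: float
    amplitude: float
    residual: float


def _tracer_rate_coefficients(cell: CellState, medium: Medium,
                              params: TransportParams,
                              tracer: TracerSpec) -> tuple[float, float]:
    """(efflux rate per internal tracer mM, influx rate per external
    tracer mM) on the frozen background."""
    u = _solve_u(cell.na, cell.k, cell.l, cell.cl, medium, params)
    e = math.exp(u)
    h = _voltage_factor(u)   # < 0
    k_out = (tracer.alpha
             - tracer.p * h * e
             + tracer.ic * cell.cl
             + tracer.kp * medium.na0)
    j_in = (-tracer.p * h
            + tracer.ic * medium.cl0
            + tracer.kp * cell.na)
    return k_out, j_in


def simulate_tracer(cell: CellState, medium: Medium, params: TransportParams,
                    tracer: TracerSpec, direction: str, times,
                    *, external_conc: float = 1.0, internal_conc: float = 1.0,
                    mode: str = "frozen", balance_tol: float = 0.01,
                    dt: float = 0.1) -> TracerCurve:
    """Tracer gain or loss curve on a balanced background.

    ``direction="gain"`` starts with zero internal tracer and
    ``external_conc`` outside; ``direction="loss"`` starts with
    ``internal_conc`` inside and tracer-free medium.  Raises ValueError
    when the background is not balanced.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    if not _integrator.is_balanced(cell, medium, params, tol=balance_tol):
        raise ValueError("background system is not at a balanced state")
    times = np.asarray(sorted(times), dtype=float)
    tau_o = external_conc if direction == "gain" else 0.0
    tau_0 = 0.0 if direction == "gain" else internal_conc

    if mode == "frozen":
        k_out, j_in = _tracer_rate_coefficients(cell, medium, params, tracer)
        if k_out <= 0:
            content = np.full_like(times, tau_0) + j_in * tau_o * times
        else:
            tau_inf = j_in * tau_o / k_out
            content = tau_inf + (tau_0 - tau_inf) * np.exp(-k_out * times)
        return TracerCurve(times=times, content=content, direction=direction)

    if mode == "full":
        # tracer rides the Li slot of the full model
        tr_params = TransportParams(
            beta=params.beta, alpha=tracer.alpha, gamma=params.gamma,
            pna=params.pna, pk=params.pk, pl=tracer.p, pcl=params.pcl,
            inc=params.inc, ikc=params.ikc, ilc=tracer.ic,
            inkcc=params.inkcc, ilkcc=params.ilkcc, kp=tracer.kp)
        tr_medium = Medium(na0=medium.na0, k0=medium.k0, l0=tau_o,
                           cl0=medium.cl0, B0=medium.B0 + medium.l0 - tau_o)
        tr_cell = CellState.from_concentrations(
            cell.na, cell.k, tau_0, cell.cl, tr_medium, A=cell.A)
        content = _integrator.simulate_timeseries(
            tr_cell, tr_medium, tr_params, times, dt=dt, variable="l")
        return TracerCurve(times=times, content=np.asarray(content),
                           direction=direction)

    raise ValueError("mode must be 'frozen' or 'full'")


def fit_rate_coefficient(curve: TracerCurve) -> RateFit:
    """Least-squares monoexponential rate coefficient from >= 3 points.

    Loss curves are fitted log-linearly; gain curves by nonlinear least
    squares on y_inf*(1-exp(-kt)).  Non-monotone data triggers a warning,
    not a failure.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.content, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    diffs = np.diff(y)
    if curve.direction == "loss" and np.any(diffs > 1e-9 + 0.05 * y[0]):
        warnings.warn("loss curve is not monotone decreasing")
    if curve.direction == "gain" and np.any(diffs < -1e-9 - 0.05 * y[-1]):
        warnings.warn("gain curve is not monotone increasing")

    if curve.direction == "loss":
        if np.any(y <= 0):
            raise ValueError("loss curve must be positive for a log fit")
        slope, intercept = np.polyfit(t, np.log(y), 1)
        k = -slope
        amplitude = math.exp(intercept)
        pred = amplitude * np.exp(-k * t)
    else:
        y_inf0 = y[-1] if y[-1] > 0 else 1.0
        k0 = 1.0 / max(t[t > 0].min(), 1e-6)
        popt, _ = curve_fit(lambda tt, yi, kk: yi * (1 - np.exp(-kk * tt)),
                            t, y, p0=(y_inf0, k0), maxfev=10000)
        amplitude, k = float(popt[0]), float(popt[1])
        pred = amplitude * (1 - np.exp(-k * t))
    residual = float(np.sqrt(np.mean((pred - y) ** 2)))
    return RateFit(k=k, amplitude=amplitude, residual=residual)


def estimate_kp_na(target_rate: float, cell: CellState, medium: Medium,
                   params: TransportParams, *, include_pump: bool = True,
                   times=(5.0, 10.0, 20.0), kp_max: float = 0.05,
                   xtol: float = 1e-6) -> float:
    """Self-exchange coefficient kpNa matching an observed tracer rate.

    Simulates the 22Na loss curve as a function of kpNa, fits the rate
    coefficient, and root-finds kpNa so the simulated rate equals
    ``target_rate``.  Raises ValueError when the target is below the
    kpNa = 0 rate (no exchange needed to explain it).
    """

    def rate(kp):
        tracer = TracerSpec.na_like(params, kp=kp, include_pump=include_pump)
        curve = simulate_tracer(cell, medium, params, tracer, "loss", times)
        return fit_rate_coefficient(curve).k

    base = rate(0.0)
    if target_rate < base - 1e-12:
        raise ValueError(
            f"target rate {target_rate:.4g}/min is below the zero-exchange "
            f"rate {base:.4g}/min")
    if abs(target_rate - base) <= 1e-12:
        return 0.0
    hi = kp_max
    for _ in range(20):
        if rate(hi) >= target_rate:
            break
        hi *= 2
    else:
        raise ValueError("target rate not reachable within kp bounds")
    return float(brentq(lambda kp: rate(kp) - target_rate, 0.0, hi,
                        xtol=xtol))


def beta_from_rb_influx(ouabain_sensitive_influx: float, na_i: float,
                        gamma: float = 1.5) -> float:
    """Pump rate coefficient from the measured ouabain-sensitive Rb(K)
    influx: beta = influx*gamma/[Na]i (inverse of the pump K-influx law).
    """
    if na_i <= 0:
        raise ValueError("internal Na concentration must be > 0")
    if ouabain_sensitive_influx < 0:
        raise ValueError("influx must be >= 0")
    return ouabain_sensitive_influx * gamma / na_i
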