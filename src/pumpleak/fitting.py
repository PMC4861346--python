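"""Inverse problem: rate coefficients from a measured balanced state.

The forward map (parameters -> balanced concentrations, water content,
OSOR) is smooth and low-dimensional, so a derivative-free simplex search
on relative residuals suffices — the same trial-and-error logic the
original program supported interactively, automated.  The balanced
state alone cannot separate the Li-carrier pair (ilc, kp): many
combinations give the same [Li]i, and only transient Li kinetics breaks
the degeneracy (:func:`resolve_ilc_kp`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import fluxes as _fluxes
from . import integrator as _integrator
from .io import DatapParams

#: observables the residual understands; va1000 is (V/A)x1000
OBSERVABLES = ("na", "k", "l", "cl", "va1000", "osor")

#: residual entry used when a run fails to balance
SENTINEL = 1.0e3

#: DATAP fields that may be freed in a fit
FITTABLE = ("alpha", "beta", "gamma", "pna", "pk", "pl", "pcl",
            "inc", "ikc", "ilc", "inkcc", "ilkcc", "kp")


def forward_observables(datap: DatapParams, *, dt: float = 0.1,
                        balance_tol: float = 0.005,
                        max_outputs: int = 100) -> dict[str, float]:
    """Run to balance and report the observable dictionary.

    Keys: the balanced concentrations, (V/A)x1000, OSOR, plus a
    ``balanced`` flag.
    """
    system = _integrator.initialize_run(datap, dt=dt,
                                        balance_tol=balance_tol,
                                        max_outputs=max_outputs)
    traj = _integrator.run(system)
    cell = traj.cell
    table = _fluxes.unidirectional_decomposition(
        cell, traj.medium, traj.params, traj.potential.u)
    try:
        osor_val = _fluxes.osor(table)
    except ValueError:
        osor_val = float("nan")
    return {"na": cell.na, "k": cell.k, "l": cell.l, "cl": cell.cl,
            "va1000": cell.water_per_impermeant * 1000.0,
            "osor": osor_val, "balanced": traj.balanced}


def balanced_state_residual(datap: DatapParams,
                            targets: Mapping[str, float],
                            **run_kwargs) -> tuple[np.ndarray, bool]:
    """Relative residual vector (computed - target)/target per observable.

    Returns ``(residuals, balanced)``; when the run does not reach a
    balanced state every entry is the large sentinel.
    """
    bad = [k for k in targets if k not in OBSERVABLES]
    if bad:
        raise ValueError(f"unknown target keys {bad}; allowed {OBSERVABLES}")
    obs = forward_observables(datap, **run_kwargs)
    if not obs["balanced"]:
        return np.full(len(targets), SENTINEL), False
    res = np.array([(obs[k] - v) / v if v != 0 else obs[k] - v
                    for k, v in targets.items()])
    return res, True


@dataclass
class BalancedFit:
    params: DatapParams
    values: dict[str, float]
    residual_norm: float
    success: bool
    non_identifiable: bool
    nfev: int
    message: str


def fit_balanced(datap: DatapParams, free_names: Sequence[str],
                 targets: Mapping[str, float],
                 bounds: Mapping[str, tuple[float, float]] | None = None,
                 *, xtol: float = 1e-4, maxiter: int = 400,
                 **run_kwargs) -> BalancedFit:
    """Nelder-Mead fit of the named rate coefficients to balanced targets.

    Free parameters are optimized as multipliers of their initial values
    (which must be nonzero), with optional bound clipping.  Deterministic
    for a fixed starting point.  When there are fewer targets than free
    parameters the result is flagged non-identifiable.
    """
    free_names = list(free_names)
    for name in free_names:
        if name not in FITTABLE:
            raise ValueError(f"{name!r} is not a fittable coefficient")
        if getattr(datap, name) == 0:
            raise ValueError(
                f"free parameter {name!r} needs a nonzero initial guess")
    non_identifiable = len(targets) < len(free_names)
    if not free_names:
        res, _ = balanced_state_residual(datap, targets, **run_kwargs)
        return BalancedFit(params=datap,
                           values={},
                           residual_norm=float(np.sqrt(np.mean(res ** 2))),
                           success=True, non_identifiable=False, nfev=0,
                           message="no free parameters")
    init = np.array([getattr(datap, n) for n in free_names])

    def clip(values: np.ndarray) -> np.ndarray:
        values = np.maximum(values, 0.0)
        if bounds:
            for i, n in enumerate(free_names):
                if n in bounds:
                    lo, hi = bounds[n]
                    values[i] = min(max(values[i], lo), hi)
        return values

    def objective(x: np.ndarray) -> float:
        values = clip(x * init)
        trial = datap.replace(**dict(zip(free_names, values)))
        res, _ = balanced_state_residual(trial, targets, **run_kwargs)
        return float(np.sqrt(np.mean(res ** 2)))

    result = minimize(objective, np.ones(len(free_names)),
                      method="Nelder-Mead",
                      options={"xatol": xtol, "fatol": xtol ** 2,
                               "maxiter": maxiter, "maxfev": 3 * maxiter})
    best = clip(result.x * init)
    values = dict(zip(free_names, (float(v) for v in best)))
    return BalancedFit(params=datap.replace(**values), values=values,
                       residual_norm=float(result.fun),
                       success=bool(result.success),
                       non_identifiable=non_identifiable,
                       nfev=int(result.nfev), message=str(result.message))


@dataclass
class IlcKpFit:
    ilc: float
    kp: float
    residual_norm: float
    success: bool
    ambiguous: bool
    nfev: int


def resolve_ilc_kp(datap: DatapParams, li_target: float,
                   times: Sequence[float] | None = None,
                   li_curve: Sequence[float] | None = None,
                   *, start: tuple[float, float] = (1e-4, 1e-4),
                   xtol: float = 1e-4, maxiter: int = 400,
                   dt: float = 0.1, **run_kwargs) -> IlcKpFit:
    """Disambiguate the Li-carrier pair (ilc, kp) with transient kinetics.

    Matches both the balanced [Li]i and the [Li]i(t) transient sampled at
    ``times`` (min, from the kv-adjusted start).  With the balanced
    target alone the pair is under-determined and the result is flagged
    ambiguous (the start point is returned unrefined).
    """
    have_curve = times is not None and li_curve is not None and len(times) >= 3
    if not have_curve:
        return IlcKpFit(ilc=start[0], kp=start[1],
                        residual_norm=float("nan"), success=False,
                        ambiguous=True, nfev=0)
    times = np.asarray(times, dtype=float)
    curve = np.asarray(li_curve, dtype=float)
    scale = float(np.max(np.abs(curve))) or 1.0

    def objective(x: np.ndarray) -> float:
        ilc, kp = np.maximum(x, 0.0) * start
        trial = datap.replace(ilc=float(ilc), kp=float(kp))
        system = _integrator.initialize_run(trial, dt=dt)
        try:
            sim = _integrator.simulate_timeseries(
                system.cell, system.medium, system.params, times, dt=dt)
        except Exception:
            return SENTINEL
        res, ok = balanced_state_residual(trial, {"l": li_target},
                                          dt=dt, **run_kwargs)
        kin = (np.asarray(sim) - curve) / scale
        full = np.concatenate([res if ok else [SENTINEL], kin])
        return float(np.sqrt(np.mean(full ** 2)))

    result = minimize(objective, np.ones(2), method="Nelder-Mead",
                      options={"xatol": xtol, "fatol": xtol ** 2,
                               "maxiter": maxiter, "maxfev": 3 * maxiter})
    ilc, kp = np.maximum(result.x, 0.0) * start
    return IlcKpFit(ilc=float(ilc), kp=float(kp),
                    residual_norm=float(result.fun),
                    success=bool(result.success), ambiguous=False,
                    nfev=int(result.nfev))
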