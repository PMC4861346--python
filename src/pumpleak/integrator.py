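"""Explicit-Euler integration of the pump-leak flux equations.

A run starts from a DATAP parameter set.  The ``kv`` osmotic adjustment is
applied first: the cell arrives pre-balanced with a medium of osmolarity
``S_o/kv``, so switching media shifts water instantaneously and scales all
internal concentrations by ``kv``.  The valence ``z`` and the impermeant
amount ``A`` are then fixed for the whole run.

Each Euler step solves the membrane potential, advances the ion contents,
and recomputes the volume from the osmotic balance; electroneutrality is
maintained automatically because the summed signed content derivatives
vanish at the solved potential (contents are never renormalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from . import model
from .errors import LowSodium, RangeLimit
from .io import DatapParams
from .model import (CellState, Medium, MembranePotential, TransportParams,
                    _concentration_rates, _solve_u)

#: the original executable stops when internal Na falls below this (mM)
LOW_SODIUM_LIMIT = 0.1


@dataclass(frozen=True)
class RunConfig:
    """Integration schedule.

    ``dt`` is the Euler step (min); ``hp`` the number of steps between
    output rows (so one row every ``hp*dt`` min, matching the DATAP field);
    ``balance_tol`` the stationarity criterion on the concentration
    derivatives (mM/min), or None to run the fixed schedule to
    ``max_outputs`` rows regardless.
    """

    dt: float = 0.1
    hp: int = 500
    max_outputs: int = 100
    balance_tol: float | None = 0.005
    kv: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.hp < 1:
            raise ValueError("hp must be >= 1")
        if self.balance_tol is not None and self.balance_tol <= 0:
            raise ValueError("balance_tol must be > 0 (or None)")
        if self.kv <= 0:
            raise ValueError("kv must be > 0")


class System(NamedTuple):
    cell: CellState
    medium: Medium
    params: TransportParams
    config: RunConfig


class TrajectoryRow(NamedTuple):
    t: float
    U: float
    na: float
    k: float
    l: float
    cl: float
    va1000: float          # (V/A) x 1000, ml per mol of A
    mun: float
    muk: float
    mul: float
    mucl: float
    prna: float            # instantaneous d[Na]i/dt, mM/min
    prk: float
    prl: float
    prcl: float


@dataclass
class Trajectory:
    rows: list[TrajectoryRow]
    cell: CellState
    medium: Medium
    params: TransportParams
    config: RunConfig
    balanced: bool
    potential: MembranePotential

    @property
    def final(self) -> TrajectoryRow:
        return self.rows[-1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=TrajectoryRow._fields)


def initialize_run(datap: DatapParams, *, dt: float = 0.1,
                   balance_tol: float | None = 0.005,
                   max_outputs: int = 100) -> System:
    """Build the initial system from a DATAP parameter set.

    Internal concentrations are multiplied by ``kv`` (the instantaneous
    osmotic water shift), then ``z`` and ``V/A`` are computed so the
    adjusted state satisfies both constraint equations exactly.  Raises
    :class:`BadInitialData` when no physical state exists.
    """
    medium = Medium(na0=datap.na0, k0=datap.k0, l0=datap.l0,
                    cl0=datap.cl0, B0=datap.B0)
    kv = datap.kv
    cell = CellState.from_concentrations(
        datap.na * kv, datap.k * kv, datap.l * kv, datap.cl * kv, medium)
    params = TransportParams(
        beta=datap.beta, alpha=datap.alpha, gamma=datap.gamma,
        pna=datap.pna, pk=datap.pk, pl=datap.pl, pcl=datap.pcl,
        inc=datap.inc, ikc=datap.ikc, ilc=datap.ilc,
        inkcc=datap.inkcc, ilkcc=datap.ilkcc, kp=datap.kp)
    config = RunConfig(dt=dt, hp=int(datap.hp), max_outputs=max_outputs,
                       balance_tol=balance_tol, kv=kv)
    return System(cell=cell, medium=medium, params=params, config=config)


def concentration_derivatives(cell: CellState, medium: Medium,
                              params: TransportParams, u: float
                              ) -> tuple[float, float, float, float]:
    """Instantaneous d[ion]/dt (mM/min), volume change included.

    With V = (sum of contents + A)/S_o, d[c]/dt = r_c - c * (sum r)/S_o
    where r are the per-volume content rates.
    """
    rna, rk, rl, rcl = _concentration_rates(
        cell.na, cell.k, cell.l, cell.cl, u, medium, params)
    dlogV = (rna + rk + rl + rcl) / medium.osmolarity
    return (rna - cell.na * dlogV, rk - cell.k * dlogV,
            rl - cell.l * dlogV, rcl - cell.cl * dlogV)


def is_balanced(cell: CellState, medium: Medium, params: TransportParams,
                tol: float = 0.005) -> bool:
    """True when every concentration derivative is below ``tol`` (mM/min)."""
    u = _solve_u(cell.na, cell.k, cell.l, cell.cl, medium, params)
    derivs = concentration_derivatives(cell, medium, params, u)
    return max(abs(d) for d in derivs) < tol


def euler_step(cell: CellState, medium: Medium, params: TransportParams,
               dt: float, u_hint: float | None = None
               ) -> tuple[CellState, MembranePotential]:
    """Advance one explicit-Euler step.

    Solves the potential, updates the ion contents, recomputes V from the
    osmotic balance, and returns the new state with the potential used.
    """
    u = _solve_u(cell.na, cell.k, cell.l, cell.cl, medium, params, u_hint)
    rna, rk, rl, rcl = _concentration_rates(
        cell.na, cell.k, cell.l, cell.cl, u, medium, params)
    V = cell.V
    cn = cell.na * V + dt * V * rna
    ck = cell.k * V + dt * V * rk
    clc = cell.l * V + dt * V * rl
    ccl = cell.cl * V + dt * V * rcl
    V_new = (cn + ck + clc + ccl + cell.A) / medium.osmolarity
    new = CellState(na=cn / V_new, k=ck / V_new, l=clc / V_new,
                    cl=ccl / V_new, V=V_new, A=cell.A, z=cell.z)
    if new.na < LOW_SODIUM_LIMIT:
        raise LowSodium()
    return new, MembranePotential(u=u, U=u * model.RTF)


def _make_row(t: float, cell: CellState, medium: Medium,
              params: TransportParams, u: float) -> TrajectoryRow:
    mu = model.electrochemical_potentials(cell, medium, u * model.RTF)
    pr = concentration_derivatives(cell, medium, params, u)
    return TrajectoryRow(t=t, U=u * model.RTF, na=cell.na, k=cell.k,
                         l=cell.l, cl=cell.cl,
                         va1000=cell.water_per_impermeant * 1000.0,
                         mun=mu.mun, muk=mu.muk, mul=mu.mul, mucl=mu.mucl,
                         prna=pr[0], prk=pr[1], prl=pr[2], prcl=pr[3])


def run(system: System, config: RunConfig | None = None) -> Trajectory:
    """Integrate until the balanced state or ``max_outputs`` rows.

    Emits one trajectory row every ``hp`` steps (plus the t=0 row).  The
    diagnostics RANGE LIMIT and LOW SODIUM abort the run with the failure
    time attached to the exception.
    """
    cell, medium, params, cfg = system
    if config is not None:
        cfg = config
    dt, hp = cfg.dt, cfg.hp
    na, k, l, cl, V, A = cell.na, cell.k, cell.l, cell.cl, cell.V, cell.A
    So = medium.osmolarity
    t = 0.0
    u = _solve_u(na, k, l, cl, medium, params)
    state = CellState(na=na, k=k, l=l, cl=cl, V=V, A=A, z=cell.z)
    rows = [_make_row(0.0, state, medium, params, u)]
    balanced = False
    for _ in range(cfg.max_outputs):
        for _ in range(hp):
            try:
                u = _solve_u(na, k, l, cl, medium, params, u)
            except RangeLimit as err:
                err.time = t
                raise
            rna, rk, rl, rcl = _concentration_rates(
                na, k, l, cl, u, medium, params)
            cn = na * V + dt * V * rna
            ck = k * V + dt * V * rk
            clc = l * V + dt * V * rl
            ccl = cl * V + dt * V * rcl
            V = (cn + ck + clc + ccl + A) / So
            na, k, l, cl = cn / V, ck / V, clc / V, ccl / V
            t += dt
            if na < LOW_SODIUM_LIMIT:
                raise LowSodium(time=t)
        state = CellState(na=na, k=k, l=l, cl=cl, V=V, A=A, z=cell.z)
        u = _solve_u(na, k, l, cl, medium, params, u)
        row = _make_row(t, state, medium, params, u)
        rows.append(row)
        if cfg.balance_tol is not None:
            if max(abs(row.prna), abs(row.prk),
                   abs(row.prl), abs(row.prcl)) < cfg.balance_tol:
                balanced = True
                break
    return Trajectory(rows=rows, cell=state, medium=medium, params=params,
                      config=cfg, balanced=balanced,
                      potential=MembranePotential(u=u, U=u * model.RTF))


def simulate_timeseries(cell: CellState, medium: Medium,
                        params: TransportParams, times, *, dt: float = 0.1,
                        variable: str = "l") -> list[float]:
    """Integrate and sample one state variable at the requested times (min).

    Times are snapped to the nearest Euler step.  Used for kinetic-curve
    fitting and for the full-model tracer mode.
    """
    want = sorted(set(round(t / dt) for t in times))
    if want and want[0] < 0:
        raise ValueError("times must be >= 0")
    out = {}
    step = 0
    u_hint = None
    cur = cell
    if 0 in want:
        out[0] = getattr(cur, variable)
    last = want[-1] if want else 0
    while step < last:
        cur, pot = euler_step(cur, medium, params, dt, u_hint)
        u_hint = pot.u
        step += 1
        if step in want:
            out[step] = getattr(cur, variable)
    return [out[round(t / dt)] for t in times]
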