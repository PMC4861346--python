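"""Domain types and flux laws of the whole-cell pump-leak model.

The cell is described by intracellular concentrations of Na+, K+, Li+ and
Cl- (mM), its water volume ``V`` (ml), and a fixed amount ``A`` (mmol) of
membrane-impermeant osmolytes with mean valence ``z``.  Two constraints
hold at all times:

* macroscopic electroneutrality:  ``na + k + l - cl + z*(A/V) = 0``
* osmotic balance:  ``na0 + k0 + l0 + cl0 + B0 = na + k + l + cl + A/V``

Transmembrane traffic goes through electroconductive channels (GHK-type
constant-field fluxes), the electrogenic Na/K pump (stoichiometry
``gamma``, with an optional Li/K mode), the electroneutral cotransporters
NC, KC, LC, NKCC, LKCC, and the Li/Na countertransporter LN.  Rate laws
are first order in the driving concentration products (no saturation).

All fluxes are expressed per ml of cell water (umol min-1 ml-1) and are
positive inward.  Temperature is fixed at 37 C, so RT/F = 26.7 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import BadInitialData, RangeLimit

#: RT/F at 37 C, mV per unit of dimensionless potential.
RTF = 26.7

#: Search window for the membrane potential, mV.
U_MIN = -173.0
U_MAX = 5.0

IONS = ("na", "k", "li", "cl")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Medium:
    """External bathing solution (concentrations in mM).

    ``B0`` is the concentration of membrane-impermeant external osmolytes
    (e.g. the non-electrolyte fraction of the culture medium).
    """

    na0: float
    k0: float
    l0: float
    cl0: float
    B0: float

    def __post_init__(self):
        for name in ("na0", "k0", "l0", "cl0", "B0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.osmolarity <= 0:
            raise ValueError("total external osmolarity must be > 0")

    @property
    def osmolarity(self) -> float:
        """Total external osmolarity S_o (mM)."""
        return self.na0 + self.k0 + self.l0 + self.cl0 + self.B0


@dataclass(frozen=True)
class TransportParams:
    """Rate coefficients of all transport pathways.

    Units: ``beta``/``alpha`` and the channel permeabilities are min-1;
    ``inc``/``ikc``/``ilc``/``kp`` are ml umol-1 min-1; ``inkcc``/``ilkcc``
    are ml3 umol-3 min-1.  ``gamma`` is the pump Na:K (Li:K) stoichiometry.
    """

    beta: float = 0.0
    alpha: float = 0.0
    gamma: float = 1.5
    pna: float = 0.0
    pk: float = 0.0
    pl: float = 0.0
    pcl: float = 0.0
    inc: float = 0.0
    ikc: float = 0.0
    ilc: float = 0.0
    inkcc: float = 0.0
    ilkcc: float = 0.0
    kp: float = 0.0

    def __post_init__(self):
        for name in ("beta", "alpha", "pna", "pk", "pl", "pcl", "inc",
                     "ikc", "ilc", "inkcc", "ilkcc", "kp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma <= 1.0:
            raise ValueError("gamma must be > 1")


@dataclass
class CellState:
    """Intracellular state: concentrations (mM), water volume V (ml),
    impermeant amount A (mmol) and its mean valence z.

    ``A`` is normalized to 1 mmol; only V/A and A/V carry physical
    meaning.  ``z`` and ``A`` are fixed at initialization and never change
    during a run.
    """

    na: float
    k: float
    l: float
    cl: float
    V: float
    A: float = 1.0
    z: float = 0.0

    @classmethod
    def from_concentrations(cls, na: float, k: float, l: float, cl: float,
                            medium: Medium, A: float = 1.0) -> "CellState":
        """Build a state whose z and V satisfy both constraint equations."""
        z = compute_impermeant_valence((na, k, l, cl), medium)
        va = compute_water_per_impermeant((na, k, l, cl), medium)
        return cls(na=na, k=k, l=l, cl=cl, V=va * A, A=A, z=z)

    @property
    def concentrations(self) -> tuple[float, float, float, float]:
        return (self.na, self.k, self.l, self.cl)

    @property
    def contents(self) -> tuple[float, float, float, float]:
        """Ion contents na*V, k*V, l*V, cl*V (umol, for A in mmol)."""
        return (self.na * self.V, self.k * self.V,
                self.l * self.V, self.cl * self.V)

    @property
    def charge_content(self) -> float:
        """Total intracellular charge, zero at electroneutrality (umol)."""
        return ((self.na + self.k + self.l - self.cl) * self.V
                + self.z * self.A)

    @property
    def water_per_impermeant(self) -> float:
        """V/A, ml per mmol of impermeant osmolyte."""
        return self.V / self.A


class MembranePotential(NamedTuple):
    u: float        # dimensionless
    U: float        # mV, U = 26.7*u


class PathwayFluxes(NamedTuple):
    """Net co-/countertransport fluxes, positive inward (for the cation)."""
    JNC: float
    JKC: float
    JLC: float
    JNKCC: float
    JLKCC: float
    JLN: float


class PumpFluxes(NamedTuple):
    na_efflux: float   # -beta*na  (<= 0)
    li_efflux: float   # -alpha*l  (<= 0)
    k_influx: float    # beta*na/gamma + alpha*l/gamma  (>= 0)


class PotentialDiffs(NamedTuple):
    """Transmembrane electrochemical potential differences, mV."""
    mun: float
    muk: float
    mul: float
    mucl: float


class ContentDerivatives(NamedTuple):
    """d(concentration*V)/dt per ion, umol/min."""
    na: float
    k: float
    l: float
    cl: float


# ---------------------------------------------------------------------------
# Constraint equations
# ---------------------------------------------------------------------------


def _osmotic_gap(conc: Sequence[float], medium: Medium) -> float:
    na, k, l, cl = conc
    return medium.osmolarity - (na + k + l + cl)


def compute_impermeant_valence(conc: Sequence[float], medium: Medium) -> float:
    """Mean valence z of the impermeant osmolytes from the internal state.

    z = (cl - na - k - l) / (S_o - na - k - l - cl); the denominator is
    A/V's reciprocal and must be positive for a physical state.
    """
    na, k, l, cl = conc
    den = _osmotic_gap(conc, medium)
    if den <= 0:
        raise BadInitialData(
            f"internal osmolarity {na + k + l + cl:.3f} mM is not below the "
            f"external osmolarity {medium.osmolarity:.3f} mM")
    return (cl - na - k - l) / den


def compute_water_per_impermeant(conc: Sequence[float], medium: Medium) -> float:
    """Cell water per impermeant osmolyte, V/A (ml/mmol)."""
    den = _osmotic_gap(conc, medium)
    if den <= 0:
        raise BadInitialData(
            f"internal osmolarity {sum(conc):.3f} mM is not below the "
            f"external osmolarity {medium.osmolarity:.3f} mM")
    return 1.0 / den


# ---------------------------------------------------------------------------
# Flux laws (scalar kernels kept module-level for the integrator hot loop)
# ---------------------------------------------------------------------------


def _voltage_factor(u: float) -> float:
    """u / (1 - exp(u)), continuous through u = 0 where it equals -1.

    Strictly negative for all u, which keeps the GHK influx/efflux split
    sign-definite.
    """
    if abs(u) < 1e-6:
        return -(1.0 - u / 2.0 + u * u / 12.0)
    return u / (1.0 - math.exp(u))


def _channel_fluxes(na, k, l, cl, u, na0, k0, l0, cl0, pna, pk, pl, pcl):
    """Net GHK channel fluxes (Na, K, Li, Cl), positive inward."""
    e = math.exp(u)
    h = _voltage_factor(u)
    jna = pna * h * (na * e - na0)
    jk = pk * h * (k * e - k0)
    jl = pl * h * (l * e - l0)
    # anion constant-field form: zero when cl == cl0*exp(u)
    jcl = pcl * h * (cl - cl0 * e)
    return jna, jk, jl, jcl


def _cotransport(na, k, l, cl, na0, k0, l0, cl0,
                 inc, ikc, ilc, inkcc, ilkcc, kp):
    jnc = inc * (na0 * cl0 - na * cl)
    jkc = ikc * (k0 * cl0 - k * cl)
    jlc = ilc * (l0 * cl0 - l * cl)
    jnkcc = inkcc * (na0 * k0 * cl0 * cl0 - na * k * cl * cl)
    jlkcc = ilkcc * (l0 * k0 * cl0 * cl0 - l * k * cl * cl)
    jln = kp * (na0 * l - na * l0)
    return jnc, jkc, jlc, jnkcc, jlkcc, jln


def _concentration_rates(na, k, l, cl, u, m: Medium, p: TransportParams):
    """Right-hand sides of the content equations divided by V:
    the net flux sums per ml cell water (mM/min at constant volume)."""
    cna, ck, cli, ccl = _channel_fluxes(
        na, k, l, cl, u, m.na0, m.k0, m.l0, m.cl0, p.pna, p.pk, p.pl, p.pcl)
    jnc, jkc, jlc, jnkcc, jlkcc, jln = _cotransport(
        na, k, l, cl, m.na0, m.k0, m.l0, m.cl0,
        p.inc, p.ikc, p.ilc, p.inkcc, p.ilkcc, p.kp)
    g = p.gamma
    rna = cna - p.beta * na + jnc + jnkcc + jln
    rk = ck + p.beta * na / g + p.alpha * l / g + jnkcc + jlkcc + jkc
    rl = cli - p.alpha * l + jlc + jlkcc - jln
    rcl = ccl + jnc + jkc + 2.0 * jnkcc + jlc + 2.0 * jlkcc
    return rna, rk, rl, rcl


def _charge_flux(na, k, l, cl, u, m: Medium, p: TransportParams) -> float:
    """Total transmembrane charge flux; its root defines the potential.

    Equals the signed sum of the content-equation right-hand sides
    (Na + K + Li - Cl); the electroneutral cotransporters cancel, leaving
    the channel fluxes and the electrogenic pump term.  Algebraically
    equivalent to the classical transcendental potential equation but
    finite at u = 0.
    """
    cna, ck, cli, ccl = _channel_fluxes(
        na, k, l, cl, u, m.na0, m.k0, m.l0, m.cl0, p.pna, p.pk, p.pl, p.pcl)
    pump = (p.beta * na + p.alpha * l) * (1.0 - 1.0 / p.gamma)
    return cna + ck + cli - ccl - pump


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def channel_net_flux(ion: str, cell: CellState, medium: Medium,
                     params: TransportParams, u: float) -> float:
    """Net constant-field channel flux of one ion, positive inward.

    Cations: ``p*u*(c_i*exp(u) - c_o)/g`` with ``g = 1 - exp(u)``;
    Cl uses the anion form, zero when ``cl_i = cl_o*exp(u)``.
    """
    fluxes = _channel_fluxes(
        cell.na, cell.k, cell.l, cell.cl, u,
        medium.na0, medium.k0, medium.l0, medium.cl0,
        params.pna, params.pk, params.pl, params.pcl)
    try:
        return fluxes[IONS.index(ion.lower())]
    except ValueError:
        raise ValueError(f"unknown ion {ion!r}; expected one of {IONS}") from None


def cotransport_fluxes(cell: CellState, medium: Medium,
                       params: TransportParams) -> PathwayFluxes:
    """Net fluxes of the electroneutral co-/countertransporters.

    Each flux is bilinear in the stated concentration products and is
    exactly zero when the inside and outside products are equal.
    """
    return PathwayFluxes(*_cotransport(
        cell.na, cell.k, cell.l, cell.cl,
        medium.na0, medium.k0, medium.l0, medium.cl0,
        params.inc, params.ikc, params.ilc,
        params.inkcc, params.ilkcc, params.kp))


def pump_fluxes(cell: CellState, params: TransportParams) -> PumpFluxes:
    """Active fluxes of the Na/K (and Li/K) pump."""
    na_eff = -params.beta * cell.na
    li_eff = -params.alpha * cell.l
    k_in = (params.beta * cell.na + params.alpha * cell.l) / params.gamma
    return PumpFluxes(na_eff, li_eff, k_in)


def total_charge_flux(cell: CellState, medium: Medium,
                      params: TransportParams, u: float) -> float:
    """Signed sum of all charge-carrying fluxes at potential u."""
    return _charge_flux(cell.na, cell.k, cell.l, cell.cl, u, medium, params)


def _solve_u(na, k, l, cl, m: Medium, p: TransportParams,
             u_hint: float | None = None) -> float:
    """Root of the charge-flux balance in dimensionless potential.

    A secant iteration warm-started from ``u_hint`` handles the integrator
    hot path; a 200-interval bracket scan over the physiological window
    plus Brent refinement is the robust fallback.
    """
    lo, hi = U_MIN / RTF, U_MAX / RTF

    def f(u):
        return _charge_flux(na, k, l, cl, u, m, p)

    if u_hint is not None and lo <= u_hint <= hi:
        u0, u1 = u_hint, u_hint + 1e-5
        f0, f1 = f(u0), f(u1)
        for _ in range(50):
            if f1 == f0:
                break
            u2 = u1 - f1 * (u1 - u0) / (f1 - f0)
            if not (lo - 0.5 <= u2 <= hi + 0.5):
                break
            u0, f0, u1 = u1, f1, u2
            f1 = f(u1)
            if abs(u1 - u0) < 1e-13:
                if lo <= u1 <= hi and abs(f1) < 1e-9:
                    return u1
                break

    grid = np.linspace(lo, hi, 201)
    vals = [f(u) for u in grid]
    for i in range(200):
        if vals[i] == 0.0:
            return float(grid[i])
        if vals[i] * vals[i + 1] < 0.0:
            return float(brentq(f, grid[i], grid[i + 1], xtol=1e-14))
    if vals[-1] == 0.0:
        return float(grid[-1])
    raise RangeLimit(
        f"no membrane-potential root in [{U_MIN}, {U_MAX}] mV")


def solve_membrane_potential(cell: CellState, medium: Medium,
                             params: TransportParams,
                             u_hint: float | None = None) -> MembranePotential:
    """Solve the transcendental potential equation on U in [-173, +5] mV.

    Raises :class:`RangeLimit` when the charge-flux balance has no sign
    change inside the window.
    """
    u = _solve_u(cell.na, cell.k, cell.l, cell.cl, medium, params, u_hint)
    return MembranePotential(u=u, U=u * RTF)


def electrochemical_potentials(cell: CellState, medium: Medium,
                               U: float) -> PotentialDiffs:
    """Per-ion driving forces in mV: 26.7*ln(c_i/c_o) + U for cations,
    26.7*ln(cl_i/cl_o) - U for Cl.

    A zero concentration yields -inf (the stored trace concentration is
    used as-is; nothing is clamped).
    """

    def _ratio_term(ci, co):
        if ci == 0.0:
            return -math.inf
        if co == 0.0:
            return math.inf
        return RTF * math.log(ci / co)

    return PotentialDiffs(
        mun=_ratio_term(cell.na, medium.na0) + U,
        muk=_ratio_term(cell.k, medium.k0) + U,
        mul=_ratio_term(cell.l, medium.l0) + U,
        mucl=_ratio_term(cell.cl, medium.cl0) - U,
    )


def content_derivatives(cell: CellState, medium: Medium,
                        params: TransportParams, u: float) -> ContentDerivatives:
    """Rates of change of the ion contents, d(c*V)/dt = V * (net fluxes).

    For the u solving the potential equation the signed sum
    ``na + k + l - cl`` of these derivatives vanishes (charge
    conservation).
    """
    rates = _concentration_rates(cell.na, cell.k, cell.l, cell.cl, u,
                                 medium, params)
    V = cell.V
    return ContentDerivatives(*(V * r for r in rates))
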