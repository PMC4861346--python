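"""Unidirectional flux decomposition and derived transport indices.

Every pathway flux splits into an inward and an outward component:

* channels — the two additive terms of the constant-field expression
  (the term carrying the external concentration is the influx, the term
  carrying the internal one the efflux);
* co-/countertransporters — the outside-product and inside-product terms
  of the bilinear rate law;
* the pump — pure Na/Li efflux and pure K influx.

Influx + efflux = net holds exactly, cell by cell, by construction.
Self-exchange (Na/Na, Cl/Cl) moves ions one-for-one in both directions:
it adds equally to the influx and efflux sums ("turnover") but to no net
flux, which is why it is invisible to the balanced state and only shows
up in tracer kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .model import (CellState, Medium, TransportParams, _voltage_factor)

#: RESP Part C column order.
PATHWAYS = ("PUMPN", "PUMPL", "Channel", "NC", "LC", "LN",
            "KC", "NKCC", "LKCC")
IONS = ("Na", "K", "Li", "Cl")


@dataclass
class FluxTable:
    """Net / influx / efflux for each ion x pathway (umol min-1 ml-1).

    The three frames share the ion index and RESP Part C column order.
    ``cell``/``medium``/``params``/``u`` record the state the table was
    computed at.
    """

    net: pd.DataFrame
    influx: pd.DataFrame
    efflux: pd.DataFrame
    cell: CellState
    medium: Medium
    params: TransportParams
    u: float

    def ion_net(self, ion: str) -> float:
        """Summed net flux of one ion over all pathways."""
        return float(self.net.loc[ion].sum())

    def ion_influx(self, ion: str) -> float:
        return float(self.influx.loc[ion].sum())

    def ion_efflux(self, ion: str) -> float:
        return float(self.efflux.loc[ion].sum())

    def round(self, ndigits: int = 4) -> "FluxTable":
        """Copy with report rounding (4 decimals in RESP Part C)."""
        return FluxTable(net=self.net.round(ndigits),
                         influx=self.influx.round(ndigits),
                         efflux=self.efflux.round(ndigits),
                         cell=self.cell, medium=self.medium,
                         params=self.params, u=self.u)


def unidirectional_decomposition(cell: CellState, medium: Medium,
                                 params: TransportParams,
                                 u: float) -> FluxTable:
    """Split every pathway into influx (>= 0) and efflux (<= 0) components."""
    influx = {ion: dict.fromkeys(PATHWAYS, 0.0) for ion in IONS}
    efflux = {ion: dict.fromkeys(PATHWAYS, 0.0) for ion in IONS}

    e = math.exp(u)
    h = _voltage_factor(u)          # strictly negative
    na, k, l, cl = cell.na, cell.k, cell.l, cell.cl
    na0, k0, l0, cl0 = medium.na0, medium.k0, medium.l0, medium.cl0
    p = params

    # pump: Na and Li rows carry only efflux, K only influx
    efflux["Na"]["PUMPN"] = -p.beta * na
    influx["K"]["PUMPN"] = p.beta * na / p.gamma
    efflux["Li"]["PUMPL"] = -p.alpha * l
    influx["K"]["PUMPL"] = p.alpha * l / p.gamma

    # channels: cation flux p*h*(c_i*e - c_o), anion flux p*h*(cl_i - cl_o*e)
    for ion, perm, ci, co in (("Na", p.pna, na, na0), ("K", p.pk, k, k0),
                              ("Li", p.pl, l, l0)):
        influx[ion]["Channel"] = -perm * h * co
        efflux[ion]["Channel"] = perm * h * ci * e
    influx["Cl"]["Channel"] = -p.pcl * h * cl0 * e
    efflux["Cl"]["Channel"] = p.pcl * h * cl

    # electroneutral cotransporters: outside product in, inside product out
    nc_in, nc_out = p.inc * na0 * cl0, -p.inc * na * cl
    kc_in, kc_out = p.ikc * k0 * cl0, -p.ikc * k * cl
    lc_in, lc_out = p.ilc * l0 * cl0, -p.ilc * l * cl
    nkcc_in = p.inkcc * na0 * k0 * cl0 * cl0
    nkcc_out = -p.inkcc * na * k * cl * cl
    lkcc_in = p.ilkcc * l0 * k0 * cl0 * cl0
    lkcc_out = -p.ilkcc * l * k * cl * cl
    for ion in ("Na", "Cl"):
        influx[ion]["NC"], efflux[ion]["NC"] = nc_in, nc_out
    for ion in ("K", "Cl"):
        influx[ion]["KC"], efflux[ion]["KC"] = kc_in, kc_out
    for ion in ("Li", "Cl"):
        influx[ion]["LC"], efflux[ion]["LC"] = lc_in, lc_out
    for ion in ("Na", "K"):
        influx[ion]["NKCC"], efflux[ion]["NKCC"] = nkcc_in, nkcc_out
    for ion in ("Li", "K"):
        influx[ion]["LKCC"], efflux[ion]["LKCC"] = lkcc_in, lkcc_out
    # Cl moves twice per NKCC/LKCC cycle
    influx["Cl"]["NKCC"], efflux["Cl"]["NKCC"] = 2 * nkcc_in, 2 * nkcc_out
    influx["Cl"]["LKCC"], efflux["Cl"]["LKCC"] = 2 * lkcc_in, 2 * lkcc_out

    # Li/Na countertransport: Na in is coupled to Li out and vice versa
    influx["Na"]["LN"] = p.kp * na0 * l
    efflux["Na"]["LN"] = -p.kp * na * l0
    influx["Li"]["LN"] = p.kp * na * l0
    efflux["Li"]["LN"] = -p.kp * na0 * l

    inf = pd.DataFrame(influx).T.reindex(index=IONS, columns=PATHWAYS)
    eff = pd.DataFrame(efflux).T.reindex(index=IONS, columns=PATHWAYS)
    return FluxTable(net=inf + eff, influx=inf, efflux=eff,
                     cell=cell, medium=medium, params=params, u=u)


def osor(table: FluxTable) -> float:
    """Ratio of ouabain-sensitive to ouabain-resistant K influx.

    Pump-mediated K influx over the summed K influx through every other
    pathway.
    """
    pump = table.influx.loc["K", "PUMPN"] + table.influx.loc["K", "PUMPL"]
    rest = table.influx.loc["K"].sum() - pump
    if rest == 0:
        raise ValueError("no ouabain-resistant K influx; OSOR undefined")
    return float(pump / rest)


def self_exchange_flux(kp_x: float, conc_out: float, conc_in: float) -> float:
    """One-for-one coupled self-exchange flux J = kp_x * c_o * c_i.

    Contributes equally to influx and efflux (hence to turnover) but to
    no net flux.
    """
    if min(kp_x, conc_out, conc_in) < 0:
        raise ValueError("self-exchange arguments must be >= 0")
    return kp_x * conc_out * conc_in


def turnover_flux(table: FluxTable,
                  self_exchange: Mapping[str, float] | None = None
                  ) -> pd.Series:
    """Total unidirectional traffic per ion: all influxes plus coupled
    self-exchange (umol min-1 ml-1).

    At a balanced state the analogous efflux sum gives the same numbers.
    """
    total = table.influx.sum(axis=1)
    if self_exchange:
        for ion, j in self_exchange.items():
            total[ion] = total[ion] + j
    return total


def equilibration_rate(turnover: float, conc_in: float) -> float:
    """Tracer equilibration rate coefficient k = turnover/[ion]_i (min-1)."""
    if conc_in <= 0:
        raise ValueError("internal concentration must be > 0")
    return turnover / conc_in


def discrimination_coefficient(l_i: float, na_i: float,
                               l_o: float, na_o: float) -> float:
    """Li/Na discrimination c_d = ([Li]i/[Na]i) * ([Na]o/[Li]o).

    A ratio of distribution ratios, hence insensitive to errors in the
    cell water estimate.
    """
    if min(l_i, na_i, l_o, na_o) <= 0:
        raise ValueError("all concentrations must be > 0")
    return (l_i / na_i) * (na_o / l_o)
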