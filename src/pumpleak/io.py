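"""DATAP parameter files and RESP result files.

DATAP is a small whitespace/tab-delimited file holding the 24 run
parameters in a fixed order (two header+value line groups; the headers
are optional and matched case-insensitively).  RESP mirrors the original
program's three-part report: A) parameter echo with the computed valence
z and final A/V, B) the trajectory table, C) the Net/Influx/Efflux flux
matrix with the OSOR line.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DatapFormatError

#: DATAP field order (note cl0 before l0, cl before alpha).
DATAP_FIELDS = (
    "na0", "k0", "cl0", "l0", "B0", "kv", "na", "k", "l", "cl",
    "alpha", "beta", "gamma", "pna", "pk",
    "pl", "pcl", "inc", "ikc", "ilc", "inkcc", "ilkcc", "kp", "hp",
)
#: line grouping used when writing (the original program's layout)
_GROUP1 = DATAP_FIELDS[:15]
_GROUP2 = DATAP_FIELDS[15:]


@dataclass(frozen=True)
class DatapParams:
    """The 24 DATAP values: medium, initial internal state, kv, rate
    coefficients and the output interval hp."""

    na0: float
    k0: float
    cl0: float
    l0: float
    B0: float
    kv: float
    na: float
    k: float
    l: float
    cl: float
    alpha: float
    beta: float
    gamma: float
    pna: float
    pk: float
    pl: float
    pcl: float
    inc: float
    ikc: float
    ilc: float
    inkcc: float
    ilkcc: float
    kp: float
    hp: float = 500

    def replace(self, **changes) -> "DatapParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_datap(path) -> DatapParams:
    """Parse a DATAP file (header+value layout or values-only dialect).

    Lines whose tokens are all numeric contribute values, in the fixed
    field order; any other line is treated as a header and checked
    loosely against the known field names.
    """
    text = Path(path).read_text()
    values: list[float] = []
    known = {f.lower() for f in DATAP_FIELDS}
    for lineno, line in enumerate(text.splitlines(), start=1):
        toks = line.replace(",", " ").split()
        if not toks:
            continue
        if all(_is_number(t) for t in toks):
            values.extend(float(t) for t in toks)
        else:
            for t in toks:
                name = t.strip("*").strip().lower()
                if name and name not in known:
                    raise DatapFormatError(
                        f"line {lineno}: unrecognized field name {t!r}")
    n = len(values)
    if n < len(DATAP_FIELDS):
        missing = ", ".join(DATAP_FIELDS[n:])
        raise DatapFormatError(
            f"expected {len(DATAP_FIELDS)} values, got {n}; "
            f"missing trailing fields: {missing}")
    if n > len(DATAP_FIELDS):
        raise DatapFormatError(
            f"expected {len(DATAP_FIELDS)} values, got {n}")
    return DatapParams(**dict(zip(DATAP_FIELDS, values)))


def write_datap(params: DatapParams, path) -> None:
    """Write a DATAP file in the two-line-group header+value layout."""
    d = params.as_dict()
    with open(path, "w") as fh:
        for group in (_GROUP1, _GROUP2):
            fh.write("\t".join(group) + "\n")
            fh.write("\t".join(_fmt_param(d[f]) for f in group) + "\n")


def _fmt_param(x: float) -> str:
    """Compact, round-trip-exact parameter formatting."""
    return repr(x) if x != int(x) else str(int(x))


# ---------------------------------------------------------------------------
# RESP output
# ---------------------------------------------------------------------------

_PARTB_HEADER = ("t", "U", "na", "k", "l", "cl", "(V/A)x1000",
                 "mun", "muk", "mul", "mucl", "prna", "prk", "prl", "prcl")


def _fmt_row(row) -> str:
    vals = [
        f"{row.t:g}", f"{row.U:.1f}", f"{row.na:.1f}", f"{row.k:.1f}",
        f"{row.l:.3f}", f"{row.cl:.1f}", f"{row.va1000:.2f}",
        f"{row.mun:.1f}", f"{row.muk:.1f}", f"{row.mul:.1f}",
        f"{row.mucl:.1f}",
        f"{row.prna:.4f}", f"{row.prk:.4f}", f"{row.prl:.4f}",
        f"{row.prcl:.4f}",
    ]
    return "\t".join(vals)


def write_resp(trajectory, flux_table, params: DatapParams, path) -> None:
    """Write the three-part RESP report.

    ``trajectory`` may be None or empty (Parts A and C only);
    ``flux_table`` is a :class:`pumpleak.fluxes.FluxTable`.
    """
    from .fluxes import osor as _osor

    buf = _io.StringIO()
    d = params.as_dict()
    cell = flux_table.cell
    buf.write("A Parameter values\n")
    grp1 = ("na0", "k0", "cl0", "l0", "B0", "kv", "alpha", "beta", "gamma")
    buf.write("\t".join(grp1) + "\tz\tkp\thp\n")
    buf.write("\t".join(_fmt_param(d[f]) for f in grp1)
              + f"\t{cell.z:.2f}\t{_fmt_param(d['kp'])}\t{_fmt_param(d['hp'])}\n")
    grp2 = ("pna", "pk", "pl", "pcl", "inc", "ikc", "ilc", "inkcc", "ilkcc")
    buf.write("\t".join(grp2) + "\tA/V\n")
    buf.write("\t".join(_fmt_param(d[f]) for f in grp2)
              + f"\t{cell.A / cell.V:.2f}\n")

    rows = list(trajectory.rows) if trajectory is not None else []
    if rows:
        buf.write("B Time course of variables\n")
        buf.write("\t".join(_PARTB_HEADER) + "\n")
        for row in rows:
            buf.write(_fmt_row(row) + "\n")

    buf.write("C Flux balance\n")
    for label, frame in (("Net flux", flux_table.net),
                         ("Influx", flux_table.influx),
                         ("Efflux", flux_table.efflux)):
        buf.write(label + "\t" + "\t".join(frame.columns) + "\n")
        for ion in frame.index:
            buf.write(ion + "\t"
                      + "\t".join(f"{v:.4f}" for v in frame.loc[ion]) + "\n")
    try:
        buf.write(f"OSOR\t{_osor(flux_table):.2f}\n")
    except ValueError:
        buf.write("OSOR\tnan\n")
    Path(path).write_text(buf.getvalue())


@dataclass
class RespData:
    """Parsed RESP file: parameter echo, trajectory and flux tables."""

    params: dict[str, float]
    z: float
    av: float
    trajectory: pd.DataFrame
    net: pd.DataFrame
    influx: pd.DataFrame
    efflux: pd.DataFrame
    osor: float


def read_resp(path) -> RespData:
    """Re-read a RESP file written by :func:`write_resp`."""
    lines = Path(path).read_text().splitlines()
    i = 0
    params: dict[str, float] = {}
    z = av = osor_val = float("nan")
    traj_rows: list[list[float]] = []
    frames = {"Net flux": {}, "Influx": {}, "Efflux": {}}
    columns: list[str] = []
    section = None
    flux_label = None
    while i < len(lines):
        line = lines[i]
        toks = line.split("\t")
        head = toks[0]
        if head.startswith("A "):
            section = "A"
        elif head.startswith("B "):
            section = "B"
            i += 1  # skip the column header line
        elif head.startswith("C "):
            section = "C"
        elif section == "A":
            names = toks
            i += 1
            vals = [float(v) for v in lines[i].split("\t")]
            for name, v in zip(names, vals):
                if name == "z":
                    z = v
                elif name == "A/V":
                    av = v
                else:
                    params[name] = v
        elif section == "B":
            traj_rows.append([float(v) for v in toks])
        elif section == "C":
            if head in frames:
                flux_label = head
                columns = toks[1:]
            elif head == "OSOR":
                osor_val = float(toks[1])
            else:
                frames[flux_label][head] = [float(v) for v in toks[1:]]
        i += 1
    traj = pd.DataFrame(traj_rows, columns=_PARTB_HEADER)

    def _frame(d):
        return pd.DataFrame.from_dict(d, orient="index", columns=columns)

    return RespData(params=params, z=z, av=av, trajectory=traj,
                    net=_frame(frames["Net flux"]),
                    influx=_frame(frames["Influx"]),
                    efflux=_frame(frames["Efflux"]),
                    osor=osor_val)
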