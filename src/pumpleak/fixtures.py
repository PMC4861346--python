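"""Published U937 parameter sets as ready-made DATAP objects.

``reference`` is the primary set (RPMI + 5 mM LiCl, balanced-state
study); ``ouabain_block``, ``li_substitution``, ``return_to_na`` and
``li_preload_recovery`` cover the transient experiments, and
``licl_medium`` applies the osmolarity-corrected media used for the
Li-distribution study at 1-10 mM external Li.
"""

from __future__ import annotations

from .io import DatapParams

#: osmolarity of the Li-free RPMI medium (mM): 140 Na + 5.8 K + 116 Cl + 48.2 B
RPMI_OSMOLARITY = 310.0


def reference() -> DatapParams:
    """Reference parameter set: U937 cells in RPMI + 5 mM LiCl."""
    return DatapParams(
        na0=140, k0=5.8, cl0=121, l0=5, B0=48.2, kv=1.032,
        na=37, k=158, l=0.0001, cl=63,
        alpha=0, beta=0.039, gamma=1.5, pna=0.00349, pk=0.0229,
        pl=0.00349, pcl=0.00426, inc=3e-5, ikc=0, ilc=0.00018,
        inkcc=0, ilkcc=0, kp=0.0002, hp=500)


def licl_medium(li_o: float, *, ilc: float | None = None,
                kp: float | None = None) -> DatapParams:
    """Reference set with X mM LiCl added to Li-free RPMI.

    Adding X mM LiCl sets l0 = X, cl0 = 116 + X and
    kv = (310 + 2X)/310 (the cells arrive balanced with plain RPMI).
    Optional ilc/kp overrides support the sensitivity grids.
    """
    base = reference()
    out = base.replace(l0=float(li_o), cl0=116.0 + li_o,
                       kv=(RPMI_OSMOLARITY + 2 * li_o) / RPMI_OSMOLARITY)
    if ilc is not None:
        out = out.replace(ilc=ilc)
    if kp is not None:
        out = out.replace(kp=kp)
    return out


def ouabain_block(beta: float = 0.0) -> DatapParams:
    """Pump block by ouabain at t = 0 (beta 0, or 0.001 for the 2.5%
    residual-activity variant)."""
    return DatapParams(
        na0=140, k0=5.8, cl0=116, l0=0, B0=48.2, kv=1,
        na=35, k=156, l=0.0001, cl=70,
        alpha=0, beta=beta, gamma=1.5, pna=0.00301, pk=0.023,
        pl=0.00301, pcl=0.00405, inc=3.4e-5, ikc=0, ilc=0,
        inkcc=0, ilkcc=0, kp=0, hp=400)


def li_substitution(alpha: float = 0.0, pl: float = 0.00353,
                    ilc: float = 3e-5) -> DatapParams:
    """Full external Na -> Li substitution at t = 0.

    Variants: alpha=0.004 adds a Li/K pump mode at 10% of the normal
    pump rate; (alpha=0.004, pl=0.0015, ilc=3.8e-5) is the reduced-
    permeability alternative.
    """
    return DatapParams(
        na0=0.01, k0=5.5, cl0=147, l0=140, B0=17.5, kv=1,
        na=37, k=155, l=0.0001, cl=65,
        alpha=alpha, beta=0.039, gamma=1.5, pna=0.00353, pk=0.023,
        pl=pl, pcl=0.00413, inc=3e-5, ikc=0, ilc=ilc,
        inkcc=0, ilkcc=0, kp=0.0002, hp=400)


def return_to_na() -> DatapParams:
    """Return of Li-loaded cells to the Na medium (both pumps activated)."""
    return DatapParams(
        na0=140, k0=5.8, cl0=116, l0=0.001, B0=48.2, kv=1,
        na=2, k=73, l=96, cl=76,
        alpha=0.04, beta=0.08, gamma=1.5, pna=0.00353, pk=0.023,
        pl=0.00353, pcl=0.00413, inc=3e-5, ikc=0, ilc=3e-5,
        inkcc=0, ilkcc=0, kp=0.0002, hp=150)


def li_preload_recovery(scenario: str = "D") -> DatapParams:
    """Recovery of Li-preloaded cells in Li-free media.

    Scenario B: Na-free medium; C: Na medium without Li/Na
    countertransport (kp 0); D: Na medium with kp 0.0002.
    """
    common = dict(kv=1, na=2, k=73, l=96, cl=76,
                  alpha=0, beta=0.039, gamma=1.5, pna=0.00349, pk=0.0229,
                  pl=0.00349, pcl=0.00426, inc=3e-5, ikc=0, ilc=0,
                  inkcc=0, ilkcc=0, hp=400)
    scenario = scenario.upper()
    if scenario == "B":
        return DatapParams(na0=0.01, k0=5.8, cl0=116, l0=0.01, B0=188.2,
                           kp=0, **common)
    if scenario == "C":
        return DatapParams(na0=140, k0=5.8, cl0=116, l0=0.01, B0=48.2,
                           kp=0, **common)
    if scenario == "D":
        return DatapParams(na0=140, k0=5.8, cl0=116, l0=0.01, B0=48.2,
                           kp=0.0002, **common)
    raise ValueError("scenario must be one of 'B', 'C', 'D'")
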