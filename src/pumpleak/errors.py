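"""Diagnostics raised by the solver and integrator.

The three messages mirror the diagnostics of the original executable so
that scripted pipelines can match on them verbatim.
"""


class PumpLeakError(Exception):
    """Base class for model diagnostics."""


class BadInitialData(PumpLeakError):
    """Initial state violates electroneutrality / osmotic balance."""

    def __init__(self, detail: str = ""):
        self.detail = detail
        super().__init__("BAD INITIAL DATA")


class RangeLimit(PumpLeakError):
    """No membrane-potential root inside the physiological search window."""

    def __init__(self, detail: str = "", time: float | None = None):
        self.detail = detail
        self.time = time
        super().__init__("RANGE LIMIT")


class LowSodium(PumpLeakError):
    """Intracellular Na dropped below 0.1 mM during integration."""

    def __init__(self, time: float | None = None):
        self.time = time
        super().__init__("LOW SODIUM")


class DatapFormatError(ValueError):
    """Malformed DATAP parameter file."""
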