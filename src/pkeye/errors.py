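"""Exception hierarchy shared by all pkeye modules."""


class PkEyeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PkEyeError, ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigurationError(PkEyeError, ValueError):
    """A model / run configuration is internally inconsistent."""


class ValidationError(ConfigurationError):
    """A telemetry plan or config exceeds platform limits."""


class FittingError(PkEyeError, RuntimeError):
    """A parameter fit cannot be performed on the given data."""


class ModeError(PkEyeError, ValueError):
    """An operation was requested in a mode that does not support it."""


class StabilityError(PkEyeError, ValueError):
    """Integration step too large for the fastest time constant."""


class WindowError(PkEyeError, ValueError):
    """A fit window contains unusable samples."""


class UndefinedHalfLifeError(PkEyeError, ValueError):
    """The trace does not decay, so no half-life exists."""


class ResolutionError(PkEyeError, ValueError):
    """Sample rate too low to resolve the shortest motion segment."""


class ScheduleError(PkEyeError, ValueError):
    """A switch schedule is degenerate (zero dwell, gaps, overlaps)."""


class RoutingError(PkEyeError, KeyError):
    """A schedule route label has no matching inlet."""


class AlignmentError(PkEyeError, ValueError):
    """Telemetry traces do not share timestamps."""


class SchemaError(PkEyeError, ValueError):
    """A telemetry file violates the CSV schema (e.g. unknown unit)."""


class MembraneRuptureError(PkEyeError, RuntimeError):
    """Applied pressure exceeded the membrane's rupture ceiling."""

    def __init__(self, pressure_pa: float, ceiling_pa: float):
        self.pressure_pa = pressure_pa
        self.ceiling_pa = ceiling_pa
        super().__init__(
            f"pressure {pressure_pa:.6g} Pa exceeds membrane rupture "
            f"ceiling {ceiling_pa:.6g} Pa"
        )
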