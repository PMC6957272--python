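"""Exception hierarchy shared across the analysis stages."""


class RckRingError(Exception):
    """Base class for all package errors."""


class UsageError(RckRingError, ValueError):
    """Invalid arguments or an unusable combination of options."""


class StructureParseError(RckRingError):
    """A coordinate file could not be parsed in the requested format."""


class RingAssemblyError(RckRingError):
    """The chain selection does not form an 8-subunit ring."""


class MarkerMissingError(RckRingError):
    """A marker residue/atom is absent from one or more subunits."""


class DegenerateTraceError(RckRingError):
    """A fluorescence trace cannot be normalized or fitted (flat/degenerate)."""


class FitFailureError(RckRingError):
    """A nonlinear fit failed to converge; carries the best attempt if any."""

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt
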