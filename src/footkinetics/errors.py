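"""Exception hierarchy shared across the package."""


class FootKineticsError(Exception):
    """Base class for all package errors."""


class ValidationError(FootKineticsError, ValueError):
    """Input violates a documented contract (shapes, ranges, duplicate labels...)."""


class FormatError(FootKineticsError):
    """Unknown or unreadable on-disk format."""


class DegenerateGeometryError(FootKineticsError):
    """Marker configuration cannot define the requested geometry
    (collinear or coincident points)."""


class MissingMarkerError(FootKineticsError, KeyError):
    """A recipe references a marker label absent from the trial."""

    def __init__(self, name: str):
        super().__init__(name)
        self.marker = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"marker {self.marker!r} not present in marker set"


class NoStanceError(FootKineticsError):
    """No force run satisfying the stance-detection criteria."""


class RegistrationError(FootKineticsError):
    """Insole-to-ground registration failed (no load at the matching instant)."""


class TrialRejectedError(FootKineticsError):
    """Trial does not meet minimal quality requirements (e.g. stance too short)."""
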