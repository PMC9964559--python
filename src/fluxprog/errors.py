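"""Exception hierarchy shared across the package."""


class FluxprogError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FluxprogError):
    """A domain object violates one of its invariants."""


class GprParseError(FluxprogError):
    """A gene-protein-reaction rule could not be parsed.

    Carries the 0-based character position of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ConfigError(FluxprogError):
    """An invalid or unknown configuration value."""


class InfeasibleError(FluxprogError):
    """The flux constraint set admits no solution."""


class DegenerateSplitError(FluxprogError):
    """A median split is undefined because all values are identical."""
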