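"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`SbmlKitError`,
so callers (and the CLI) can distinguish semantic failures from genuine bugs.
"""


class SbmlKitError(Exception):
    """Base class for all errors raised by sbmlkit."""


class ParseError(SbmlKitError):
    """The XML document cannot be read into a Model (malformed, missing
    required attribute, unsupported level...)."""

    def __init__(self, message: str, xml_path: str = ""):
        self.xml_path = xml_path
        super().__init__(f"{message}" + (f" (at {xml_path})" if xml_path else ""))


class SerializationError(SbmlKitError):
    """A Model violating its invariants cannot be written out."""


class UnsupportedFeatureError(SbmlKitError):
    """The document or model uses a feature outside the supported dynamic
    subset (packages, delays, factorials, compound event triggers...)."""

    def __init__(self, message: str, feature: str = ""):
        self.feature = feature
        super().__init__(message)


class UnsupportedOperatorError(UnsupportedFeatureError):
    """A math operator (factorial, delay) that parses but cannot be
    evaluated or compiled."""


class ResolutionError(SbmlKitError):
    """A symbol cannot be resolved, an arity mismatches, or a dependency
    cycle prevents evaluation."""


class MathEvalError(SbmlKitError):
    """Arithmetic failure during expression evaluation (division by zero,
    piecewise with no matching branch and no otherwise)."""


class ConflictError(SbmlKitError):
    """Entity classification conflict, e.g. a constant entity targeted by a
    rule, or a non-boundary species appearing in both reactions and rules."""


class ModelError(SbmlKitError):
    """The model is structurally valid but semantically broken at run time
    (e.g. a negative propensity)."""


class IntegrationError(SbmlKitError):
    """ODE integration failed (non-finite state, solver breakdown)."""

    def __init__(self, message: str, time: float | None = None):
        self.time = time
        super().__init__(message + (f" at t={time!r}" if time is not None else ""))


class RunawayEventError(IntegrationError):
    """More event firings than ``max_events`` during one integration."""
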