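"""Exception types shared across the package."""


class OvucycleError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OvucycleError):
    """A CSV/TOML input violates the expected dialect (names the offender)."""


class InvalidConfigError(OvucycleError, ValueError):
    """A configuration object violates its invariants."""


class HormoneLookupError(OvucycleError, KeyError):
    """An unknown or non-distinct hormone name was requested."""


class CoverageError(OvucycleError):
    """A series does not cover the relative-day range an operation needs."""


class ScenarioError(OvucycleError, KeyError):
    """An unknown scenario preset name."""


class NumericalInstabilityError(OvucycleError):
    """The integrator produced non-finite state; try a smaller time step."""
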