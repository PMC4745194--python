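"""Exception hierarchy for gliostem."""


class GliostemError(Exception):
    """Base class for all package errors."""


class DomainError(GliostemError, ValueError):
    """An input lies outside the mathematical domain of an operation
    (non-finite state, negative population, zero death rate, ...)."""


class ConfigurationError(GliostemError, ValueError):
    """A configuration file or functional-form bundle is malformed
    (unknown key, non-numeric value, missing functional form)."""


class RootNotFoundError(GliostemError, RuntimeError):
    """A bracketed root search failed to locate a sign change."""


class InversionError(GliostemError, RuntimeError):
    """Inversion of a monotone map failed (target below range, or the
    bracket could not be expanded to cover the target)."""


class IntegrationError(GliostemError, RuntimeError):
    """The ODE solver failed; carries the solver's diagnostic message."""
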