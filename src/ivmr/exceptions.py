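"""Exception hierarchy shared across the package."""


class IvmrError(Exception):
    """Base class for all package-specific errors."""


class DomainError(IvmrError, ValueError):
    """An argument is outside its mathematical domain (e.g. se <= 0)."""


class InconsistencyError(IvmrError, ValueError):
    """Inputs are individually valid but mutually contradictory."""


class ValidationError(IvmrError, ValueError):
    """A record violates the invariants of its domain type."""


class HarmonizationError(IvmrError):
    """Exposure and outcome allele sets cannot be reconciled."""


class FrequencyRequiredError(IvmrError):
    """An operation needs an effect-allele frequency that is absent."""


class WeakInstrumentError(IvmrError):
    """The instrument-exposure effect is zero; the Wald ratio is undefined."""


class ConfigurationError(IvmrError, ValueError):
    """A configuration object or column map is invalid."""


class EmptyIntersectionError(IvmrError):
    """No instrument rsID is shared between the exposure and outcome studies."""
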