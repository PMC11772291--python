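"""Exception hierarchy shared across the package."""


class EntnerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EntnerError, ValueError):
    """Invalid user-supplied configuration (negative weight, bad rate, unknown variant...)."""


class AnnotationError(EntnerError, ValueError):
    """Malformed standoff annotation: bad offsets, surface mismatch, ragged rows."""


class SchemeError(EntnerError, ValueError):
    """A label or tag outside the configured label scheme."""


class ContractError(EntnerError, RuntimeError):
    """An operation was called outside its contract (wrong mode, mixed documents...)."""


class IntegrityError(EntnerError, RuntimeError):
    """Internal data-structure corruption (broken origin map, NaN loss)."""
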