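"""Exception hierarchy shared across the package."""


class MabPKError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MabPKError):
    """An input table is missing a required column or has an invalid dialect."""


class IntegrityError(MabPKError):
    """Cross-references between tables are inconsistent (e.g. dangling subject id)."""


class ValidationError(MabPKError):
    """A field value violates a domain invariant (e.g. unknown route code)."""


class ConfigError(MabPKError):
    """A configuration or specification object is infeasible or self-contradictory."""


class EstimationError(MabPKError):
    """An estimation routine diverged or produced an invalid state."""
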