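"""Exception hierarchy for bcnkit.

All bcnkit-specific errors derive from :class:`BCNError` so callers can
catch the whole family; most also derive from the closest builtin
(``ValueError`` for bad inputs) so generic handling keeps working.
"""


class BCNError(Exception):
    """Base class for all bcnkit errors."""


class InvalidInputError(BCNError, ValueError):
    """An argument refers to unknown variables or violates a precondition."""


class CapacityError(BCNError, ValueError):
    """An exact/exhaustive routine was asked for a problem size it guards against."""


class DegenerateDataError(BCNError, ValueError):
    """Data is degenerate for the requested computation (e.g. a constant column)."""


class CollinearityError(BCNError, ValueError):
    """A regression/conditioning design matrix is rank deficient."""


class ExtensionFailureError(BCNError, RuntimeError):
    """A partially directed graph admits no consistent extension."""


class ConstraintConflictError(BCNError, ValueError):
    """Arc constraints are mutually inconsistent (e.g. whitelist forces a cycle)."""


class ConfigurationError(BCNError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class BootstrapFailureError(BCNError, RuntimeError):
    """Too many bootstrap replicates failed to learn a network."""
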