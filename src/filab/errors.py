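"""Exception hierarchy for the filab package."""


class FilabError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FilabError):
    """A simulation or pipeline configuration value is invalid."""


class RegistryError(FilabError):
    """An item registry file violates the item-spec invariants."""


class SpecificationError(FilabError):
    """An operation was requested with an incoherent specification
    (e.g. mean aggregation on a categorical item, too few spline knots)."""


class DataError(FilabError):
    """Input data violate a precondition (bad value type, missing stay...)."""


class FitError(FilabError):
    """A statistical model could not be estimated (zero events,
    degenerate exposure, non-convergence)."""
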