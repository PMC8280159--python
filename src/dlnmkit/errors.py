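"""Exception hierarchy shared across the package."""


class DlnmkitError(Exception):
    """Base class for all package errors."""


class SchemaError(DlnmkitError):
    """An input table is missing required columns."""


class ValidationError(DlnmkitError):
    """A record violates a domain invariant."""


class MissingPanelDataError(DlnmkitError):
    """A prevalence panel lookup failed for a (year, age band) cell."""


class DegenerateRangeError(DlnmkitError):
    """Knot placement requested on constant (zero-range) values."""


class RankDeficiencyError(DlnmkitError):
    """The design matrix is not of full column rank."""


class ComparisonError(DlnmkitError):
    """Model fits being compared were not obtained on the same data."""


class ConfigError(DlnmkitError):
    """A simulation or run configuration is invalid."""
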