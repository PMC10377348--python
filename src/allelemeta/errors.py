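"""Exception hierarchy shared across the package."""


class AlleleMetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AlleleMetaError):
    """A study table file does not match the documented column schema."""


class ParseError(AlleleMetaError):
    """A study table cell could not be parsed (e.g. non-integer count)."""


class DegenerateTableError(AlleleMetaError):
    """A 2x2 allele table has an entire zero margin; no odds ratio exists."""


class MonomorphicError(AlleleMetaError):
    """Only one allele is present; the HWE chi-squared test is undefined."""


class InsufficientStudiesError(AlleleMetaError):
    """Fewer studies than the operation requires."""


class DegenerateDesignError(AlleleMetaError):
    """Regression design is unidentifiable (e.g. constant precision in Egger's test)."""


class ConfigError(AlleleMetaError):
    """Invalid simulation or pipeline configuration."""
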