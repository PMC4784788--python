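"""Exception hierarchy shared across the pipeline.

``UsageError`` and ``ConfigurationError`` signal caller mistakes (CLI exit
code 2); everything else is a runtime failure (exit code 1).
"""


class IsopipeError(Exception):
    """Base class for all pipeline errors."""


class ParseError(IsopipeError):
    """Malformed input file; message names the offending line when known."""


class IntegrityError(IsopipeError):
    """Input parsed but violates a structural invariant (e.g. mixed strands)."""


class ConfigurationError(IsopipeError):
    """Inconsistent run configuration (e.g. sample missing from design)."""


class UsageError(IsopipeError):
    """An operation was called with arguments outside its contract."""


class ValidationError(IsopipeError):
    """A numeric argument is outside its admissible range."""


class NormalizationError(IsopipeError):
    """Normalization impossible (e.g. a library with all-zero counts)."""


class DesignError(IsopipeError):
    """Contrast design insufficient (e.g. fewer than two replicates a side)."""
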