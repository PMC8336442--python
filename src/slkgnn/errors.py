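"""Exception hierarchy for slkgnn.

Every domain-specific failure derives from :class:`SLKGError` so callers can
catch the package's errors with one clause; plain ``ValueError`` is reserved
for shape/argument mismatches on the numeric primitives.
"""


class SLKGError(Exception):
    """Base class for all slkgnn errors."""


class FormatError(SLKGError):
    """An input file does not match the documented layout (e.g. missing column)."""


class EmptyInputError(SLKGError):
    """An input file contains no usable rows."""


class ReferentialIntegrityError(SLKGError):
    """A record references an identifier that is not declared anywhere."""


class EntityTypeError(SLKGError):
    """An identifier resolves to an entity of the wrong type (e.g. non-gene in an SL pair)."""


class CapacityError(SLKGError):
    """A sampling request cannot be satisfied by the available population."""


class ConfigError(SLKGError):
    """A configuration value violates its documented constraints."""


class NumericError(SLKGError):
    """A numeric computation produced NaN/Inf or diverged."""


class UndefinedMetricError(SLKGError):
    """A requested evaluation metric is undefined for the given labels."""


class InvariantError(SLKGError):
    """An internal data-structure invariant was violated (indicates a bug upstream)."""
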