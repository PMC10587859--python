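"""Exception hierarchy shared across the package.

Each exception maps to a distinct CLI exit code (see :mod:`araskit.cli`).
"""


class AraskitError(Exception):
    """Base class for all package errors."""


class StructuralError(AraskitError):
    """Malformed input: ragged grids, dimension mismatches, bad shapes."""


class ConversionError(AraskitError):
    """A qualitative label cannot be resolved under its conversion rule."""


class ConfigError(AraskitError):
    """Invalid criterion-spec / run configuration."""


class DegenerateMatrixError(AraskitError):
    """Every criterion column is constant: entropy dispersion sums to zero.

    Entropy weighting is undefined here; equal weighting is the sensible
    fallback and the message says so.
    """


class DomainError(AraskitError):
    """A numeric precondition is violated (non-positive score, m < 2, ...)."""
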