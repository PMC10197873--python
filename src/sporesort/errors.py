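"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`SporesortError`
so callers (and the CLI) can catch domain failures without masking bugs.
"""


class SporesortError(Exception):
    """Base class for all sporesort domain errors."""


class SpectrumParseError(SporesortError):
    """A spectrum file could not be parsed; the message names the offending row."""


class SpectrumValidationError(SporesortError):
    """A spectrum violates a structural invariant (axis order, lengths, finiteness)."""


class DegenerateSpectrumError(SporesortError):
    """An operation required intensity contrast but the spectrum is constant."""


class EmptyWindowError(SporesortError):
    """A spectral window contains no samples of the spectrum."""


class InsufficientSamplesError(SporesortError):
    """Fewer in-window samples than the operation needs (integration needs >= 2)."""


class OutOfSpanError(SporesortError):
    """A requested axis lies (partly) outside the source spectrum's span."""


class InvalidReferenceError(SporesortError):
    """The medium/reference spectrum has non-positive integrated intensity."""


class InvalidDenominatorError(SporesortError):
    """The denominator window statistic of a ratio is zero or negative."""


class CatalogMissError(SporesortError):
    """A phenotype was requested that no catalog marker carries."""


class PresetMissError(SporesortError):
    """An unknown synthetic phenotype preset was requested."""


class OutOfBoundsError(SporesortError):
    """A profile line (or its averaging band) leaves the image."""


class FeatureNotFoundError(SporesortError):
    """No half-depth crossing pair brackets a feature in a density profile."""


class AmbiguousFeatureError(SporesortError):
    """More than one candidate envelope feature crosses the half-depth level."""

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class GeometryError(SporesortError):
    """A synthetic band does not fit inside the requested image."""


class EmptyInputError(SporesortError):
    """A summary operation received no measurements."""
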