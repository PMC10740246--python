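"""Exception types shared across the package."""


class ConfrankError(Exception):
    """Base class for package errors."""


class StructureParseError(ConfrankError):
    """A structure could not be parsed into a valid valence model."""


class DimensionError(ConfrankError):
    """Coordinate array does not match the molecule's heavy-atom count."""


class GenerationError(ConfrankError):
    """Conformer embedding failed for every attempt."""


class VocabularyError(ConfrankError):
    """An atomic number is outside the model's embedding table."""


class UndefinedMetricError(ConfrankError):
    """A metric is undefined for the given inputs (e.g. single-class BEDROC)."""
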