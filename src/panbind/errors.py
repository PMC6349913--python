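"""Exception hierarchy for panbind.

All errors derive from :class:`PanbindError` so callers can catch the
package's failures with one clause; most also derive from the matching
builtin (ValueError) so generic handling keeps working.
"""


class PanbindError(Exception):
    """Base class for every panbind-specific error."""


class SequenceLengthError(PanbindError, ValueError):
    """A sequence has the wrong length for the requested encoding."""


class AlphabetError(PanbindError, ValueError):
    """A character is outside the accepted alphabet."""


class MalformedTensorError(PanbindError, ValueError):
    """A tensor violates its one-hot invariants."""


class TableFormatError(PanbindError, ValueError):
    """An affinity table is missing required columns or is unreadable."""


class EmptyDatasetError(PanbindError, ValueError):
    """No usable samples remain after parsing/filtering."""


class DatasetSizeError(PanbindError, ValueError):
    """A dataset is too small for the requested split or training run."""


class FoldError(PanbindError, ValueError):
    """Cross-validation folds cannot be formed (e.g. a single allele)."""


class DomainError(PanbindError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class NetworkShapeError(PanbindError, ValueError):
    """An input tensor does not match the shape the network expects."""


class ConstructionError(PanbindError, ValueError):
    """A network configuration's stage shapes do not compose."""


class UnknownAlleleError(PanbindError, KeyError):
    """A sample references an allele absent from the allele index."""


class UndefinedMetricError(PanbindError, ValueError):
    """A metric is undefined for the given input (single class, constant)."""


class CoverageError(PanbindError, ValueError):
    """A benchmark table shares no alleles with the allele index."""
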