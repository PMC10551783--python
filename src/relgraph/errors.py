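"""Exception hierarchy shared across the package.

Every error raised deliberately by relgraph derives from :class:`RelgraphError`
so callers can catch the package's failures without catching programming bugs.
"""


class RelgraphError(Exception):
    """Base class for all relgraph errors."""


class ConfigurationError(RelgraphError, ValueError):
    """A configuration object violates its invariants."""


class ParseError(RelgraphError, ValueError):
    """A file or field could not be parsed; carries location context."""


class IntegrityError(RelgraphError, ValueError):
    """Input data violates a uniqueness or consistency constraint."""


class SpanError(RelgraphError, ValueError):
    """Entity mention spans are invalid or overlap."""


class DimensionError(RelgraphError, ValueError):
    """Array shapes or sequence lengths are inconsistent."""


class InvalidWeightsError(RelgraphError, ValueError):
    """Ensemble weights are unusable (e.g. all zero)."""


class UnknownRelationError(RelgraphError, KeyError):
    """A relation label is missing from the inverse-pair map (strict mode)."""


class InvalidInputError(RelgraphError, ValueError):
    """An operation received empty or otherwise unusable input."""


class MissingNodeError(RelgraphError, KeyError):
    """A referenced node is absent from the graph."""


class InvalidPairError(RelgraphError, ValueError):
    """A node pair is invalid for the requested statistic (e.g. x == y)."""


class PlantingConflictError(RelgraphError, ValueError):
    """A requested planted drug is already directly linked to the target."""


class InvalidPatternError(RelgraphError, ValueError):
    """Unknown drug-path pattern identifier."""


class DegenerateInputError(RelgraphError, ValueError):
    """Too few distinct observations for the requested decomposition."""
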