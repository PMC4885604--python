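"""Exception hierarchy for metminer."""


class MetMinerError(Exception):
    """Base class for all metminer errors."""


class LexiconError(MetMinerError):
    """Raised when a lexicon, trigger or pattern file fails validation."""


class BioCError(MetMinerError):
    """Raised on malformed or inconsistent BioC input/output."""


class DocumentError(MetMinerError):
    """Raised on invalid document content (e.g. empty abstract)."""


class ExtractionError(MetMinerError):
    """Raised when tagging/matching preconditions are violated."""


class EvaluationError(MetMinerError):
    """Raised on invalid gold/prediction sets."""


class FixtureError(MetMinerError):
    """Raised when synthetic-corpus generation cannot proceed."""
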