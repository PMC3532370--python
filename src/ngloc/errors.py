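"""Exception hierarchy.

Everything raised on bad user input or misuse derives from :class:`NglocError`
so callers (and the CLI) can catch one type; genuine I/O failures propagate
as ``OSError``.
"""


class NglocError(Exception):
    """Base class for all ngloc errors."""


class SequenceTooShort(NglocError):
    """Sequence shorter than the n-gram length (or a stated minimum)."""


class UnknownClass(NglocError):
    """A label or class code outside the active species profile."""


class NoCanonicalGrams(NglocError):
    """Every window of the query contained a non-canonical residue."""


class NegativeCount(NglocError):
    """Leave-one-out removal of a record that is not in the model."""


class InsufficientData(NglocError):
    """Not enough sequences per class for the requested validation."""


class InfeasibleSpec(NglocError):
    """A synthetic-corpus spec that cannot be satisfied (e.g. motif
    alphabet exhaustion)."""


class MalformedFasta(NglocError):
    """Structurally invalid FASTA input."""


class DuplicateId(NglocError):
    """Two records in one file share an identifier."""


class ConfigError(NglocError):
    """Invalid or unknown configuration key/value."""
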