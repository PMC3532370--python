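"""Sequence records, species profiles, n-gram extraction and dataset filters.

The classifier treats a protein as a bag of overlapping fixed-length
peptides (n-grams).  This module owns that extraction step plus the
dataset-preparation filters applied before training: a minimum sequence
length and exact-duplicate removal.

Species profiles name the subcellular compartment sets the four shipped
models predict (11 classes for animal and plant, 5 for gram-negative and
4 for gram-positive bacteria) together with the default n-gram length for
that species group (7 for animal, 6 otherwise).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

from .errors import ConfigError, SequenceTooShort

#: The 20 canonical amino acids.  Windows containing anything else
#: (B, Z, X, U, O, J, gaps, stops) are skipped, not remapped.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)


@dataclass(frozen=True)
class SpeciesProfile:
    """A named class set plus the default n-gram length for that group."""

    name: str
    class_codes: tuple[str, ...]
    default_n: int

    def __post_init__(self) -> None:
        if not self.class_codes:
            raise ConfigError("a species profile needs at least one class code")
        if len(set(self.class_codes)) != len(self.class_codes):
            raise ConfigError(f"duplicate class codes in profile {self.name!r}")
        if self.default_n < 1:
            raise ConfigError("default_n must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_codes)


#: The four shipped species groups.  Class codes are three-letter
#: compartment abbreviations (CYT cytoplasm, NUC nucleus, CHL chloroplast,
#: PLA plasma membrane, WAL cell wall, ...).
PROFILES: dict[str, SpeciesProfile] = {
    "animal": SpeciesProfile(
        "animal",
        ("CYT", "CSK", "END", "EXC", "GOL", "LYS", "MIT", "NUC", "PLA", "POX", "JNC"),
        default_n=7,
    ),
    "plant": SpeciesProfile(
        "plant",
        ("CYT", "CSK", "END", "EXC", "GOL", "MIT", "NUC", "PLA", "POX", "CHL", "VAC"),
        default_n=6,
    ),
    "gram_negative": SpeciesProfile(
        "gram_negative", ("CYT", "EXC", "IN", "OUT", "PER"), default_n=6
    ),
    "gram_positive": SpeciesProfile(
        "gram_positive", ("CYT", "EXC", "IN", "WAL"), default_n=6
    ),
}


def get_profile(name: str) -> SpeciesProfile:
    """Look up one of the shipped species profiles by name."""
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigError(
            f"unknown species profile {name!r}; choose from {sorted(PROFILES)}"
        ) from None


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with an identifier and 0+ localization labels.

    The sequence is canonicalized to upper case on construction.  Labels
    are an ordered, duplicate-free tuple of class codes; they may be empty
    at prediction time but must be non-empty for training.
    """

    id: str
    sequence: str
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)
        # de-duplicate labels, keeping first occurrence order
        labels = tuple(dict.fromkeys(self.labels))
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(eq=True)
class NgramBag:
    """The overlapping length-n windows of one sequence, in order.

    ``n_skipped`` counts windows discarded because they contained a
    non-canonical residue; for a fully canonical sequence of length L,
    ``len(grams) == L - n + 1``.
    """

    grams: tuple[str, ...]
    n: int
    n_skipped: int = 0

    @cached_property
    def counts(self) -> Counter[str]:
        """Multiset view of the bag (gram -> multiplicity)."""
        return Counter(self.grams)

    @property
    def total(self) -> int:
        return len(self.grams)

    def __len__(self) -> int:
        return len(self.grams)


def extract_ngrams(seq: str, n: int) -> NgramBag:
    """Slide a length-``n`` window over ``seq`` and collect the peptides.

    Windows containing any character outside the 20 canonical amino acids
    are excluded and tallied in ``n_skipped``.  Lower-case input is treated
    as upper case.

    Raises
    ------
    SequenceTooShort
        If ``len(seq) < n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    s = seq.upper()
    if len(s) < n:
        raise SequenceTooShort(
            f"sequence of length {len(s)} is shorter than n={n}"
        )
    grams: list[str] = []
    skipped = 0
    last_bad = -1  # index of the most recent non-canonical residue
    for i, c in enumerate(s):
        if c not in _CANONICAL_SET:
            last_bad = i
        start = i - n + 1  # window ending at position i
        if start >= 0:
            if last_bad < start:
                grams.append(s[start : i + 1])
            else:
                skipped += 1
    return NgramBag(tuple(grams), n, skipped)


def prepare_dataset(
    records: Iterable[SequenceRecord], min_len: int = 10
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Apply the training-data filters: minimum length and deduplication.

    Records shorter than ``min_len`` residues are dropped with reason
    ``"too_short"``; exact duplicate sequences are dropped with reason
    ``"duplicate"``, keeping the first occurrence in input order.  Input
    order of kept records is preserved and the operation is idempotent.

    Returns ``(kept, dropped)`` where ``dropped`` is a list of
    ``(record_id, reason)`` pairs.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[SequenceRecord] = []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if len(rec.sequence) < min_len:
            dropped.append((rec.id, "too_short"))
        elif rec.sequence in seen:
            dropped.append((rec.id, "duplicate"))
        else:
            seen.add(rec.sequence)
            kept.append(rec)
    return kept, dropped
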