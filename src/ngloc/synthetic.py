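"""Labelled synthetic protein corpora with controllable class separability.

The generative model is intentionally the simplest one whose class
structure an n-gram count classifier can represent exactly: every class
owns a small set of signature motifs (disjoint across classes), and each
sequence is an i.i.d.-background string with a Poisson-distributed number
of copies of its class's motifs written in at uniform positions.  The
motif density dial moves the corpus continuously from pure noise
(density 0: classes indistinguishable, chance-level accuracy) to strongly
separated signatures.

A ``multi_label_fraction`` share of sequences receives a second class
label and carries both classes' motifs, emulating multi-localized
proteins that shuttle between compartments.  The motif count is drawn
once per sequence and applied to each of its labels, so a dual-resident
sequence carries both signatures at the same strength — the balanced
evidence that a multi-localization confidence score is meant to detect.

No attempt is made at realistic protein evolution — no substitution
matrices, no homology structure, no compositional bias beyond the stated
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import InfeasibleSpec
from .sequences import (
    CANONICAL_AA,
    SequenceRecord,
    SpeciesProfile,
    get_profile,
)

__all__ = ["SyntheticSpec", "generate_corpus", "make_fixture", "Fixture"]

_ALPHABET = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    ``seqs_per_class`` supports heavy imbalance (real compartment class
    sizes span two orders of magnitude).  ``motif_length`` must be at
    least the n used downstream so signatures are detectable as n-grams.
    ``background`` is a 20-vector of residue probabilities in the order
    of the canonical alphabet; ``None`` means uniform.
    """

    profile: SpeciesProfile
    seqs_per_class: Mapping[str, int]
    length_range: tuple[int, int] = (60, 120)
    signature_motifs_per_class: int = 3
    motif_length: int = 8
    motif_density: float = 3.0
    background: tuple[float, ...] | None = None
    multi_label_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range must satisfy 10 <= min <= max")
        if any(c < 0 for c in self.seqs_per_class.values()):
            raise ValueError("sequence counts must be >= 0")
        unknown = set(self.seqs_per_class) - set(self.profile.class_codes)
        if unknown:
            raise ValueError(f"seqs_per_class keys not in profile: {sorted(unknown)}")
        if self.signature_motifs_per_class < 0 or self.motif_length < 1:
            raise ValueError("motif parameters must be non-negative / positive")
        if self.motif_density < 0:
            raise ValueError("motif_density must be >= 0")
        if not 0.0 <= self.multi_label_fraction < 1.0:
            raise ValueError("multi_label_fraction must be in [0, 1)")
        if self.motif_density > 0 and self.motif_length > lo:
            raise InfeasibleSpec(
                f"motif_length {self.motif_length} exceeds minimum sequence "
                f"length {lo}; motifs would not fit"
            )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 20 non-negative probs summing to 1")


def _draw_motifs(
    rng: np.random.Generator, codes: Sequence[str], m: int, length: int
) -> dict[str, list[str]]:
    """Draw ``m`` signature motifs per class, globally disjoint."""
    needed = m * len(codes)
    if needed == 0:
        return {c: [] for c in codes}
    space = 20.0 ** length
    if space < 4 * needed:
        raise InfeasibleSpec(
            f"cannot draw {needed} disjoint motifs of length {length} "
            f"from a space of {space:.0f}"
        )
    seen: set[str] = set()
    motifs: dict[str, list[str]] = {c: [] for c in codes}
    attempts = 0
    for code in codes:
        while len(motifs[code]) < m:
            cand = "".join(rng.choice(_ALPHABET, size=length))
            attempts += 1
            if attempts > 1000 * needed:
                raise InfeasibleSpec("motif alphabet exhausted while drawing signatures")
            if cand in seen:
                continue
            seen.add(cand)
            motifs[code].append(cand)
    return motifs


def generate_corpus(spec: SyntheticSpec) -> list[SequenceRecord]:
    """Generate a labelled corpus; byte-identical for identical specs.

    Each sequence draws its length uniformly from ``length_range``, its
    residues from the background composition, then overwrites
    ``Poisson(motif_density)`` stretches with class motifs at uniform
    start positions (later insertions may clip earlier ones — overlap is
    treated as noise).  Multi-labelled sequences repeat the insertion
    step for the partner class.
    """
    rng = np.random.default_rng(spec.seed)
    codes = [c for c in spec.profile.class_codes if spec.seqs_per_class.get(c, 0) > 0]
    motifs = _draw_motifs(
        rng, codes, spec.signature_motifs_per_class, spec.motif_length
    )
    bg = (
        None
        if spec.background is None
        else np.asarray(spec.background, dtype=float)
    )
    lo, hi = spec.length_range
    ell = spec.motif_length
    m = spec.signature_motifs_per_class
    records: list[SequenceRecord] = []
    for code in codes:
        for i in range(spec.seqs_per_class[code]):
            labels = (code,)
            if (
                spec.multi_label_fraction > 0
                and len(codes) > 1
                and rng.random() < spec.multi_label_fraction
            ):
                others = [c for c in codes if c != code]
                partner = others[int(rng.integers(len(others)))]
                labels = (code, partner)
            length = int(rng.integers(lo, hi + 1))
            seq = rng.choice(_ALPHABET, size=length, p=bg)
            if spec.motif_density > 0 and m > 0:
                k = rng.poisson(spec.motif_density)
                for lab in labels:
                    for _ in range(k):
                        motif = motifs[lab][int(rng.integers(m))]
                        pos = int(rng.integers(0, length - ell + 1))
                        seq[pos : pos + ell] = list(motif)
            records.append(
                SequenceRecord(f"{code.lower()}_{i:04d}", "".join(seq), labels)
            )
    return records


class Fixture(NamedTuple):
    """A ready-made corpus plus the profile and n it was built for."""

    records: list[SequenceRecord]
    profile: SpeciesProfile
    n: int


# Scaled-down class sizes (~1% of the real training corpora) preserving
# the rank order of compartment sizes: secreted proteins dominate the
# animal set, chloroplast the plant set, cytoplasm the bacterial sets.
_ANIMAL_LIKE = {
    "CYT": 25, "CSK": 8, "END": 9, "EXC": 96, "GOL": 3, "LYS": 2,
    "MIT": 23, "NUC": 42, "PLA": 60, "POX": 2, "JNC": 1,
}
_PLANT_LIKE = {
    "CYT": 5, "CSK": 6, "END": 1, "EXC": 2, "GOL": 1, "MIT": 5,
    "NUC": 6, "PLA": 4, "POX": 1, "CHL": 49, "VAC": 1,
}
_GRAMNEG_LIKE = {"CYT": 41, "EXC": 3, "IN": 14, "OUT": 3, "PER": 4}


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Small labelled corpora for examples and tests.

    ``tiny2`` is the two-class hand corpus used in the worked scoring
    example; the ``*_like`` fixtures carry the real class sets with
    scaled-down, imbalanced class sizes and a realistic multi-label share.
    """
    if name == "tiny2":
        profile = SpeciesProfile("tiny2", ("A", "B"), default_n=2)
        records = [
            SequenceRecord("a1", "AAAA", ("A",)),
            SequenceRecord("b1", "CCCC", ("B",)),
        ]
        return Fixture(records, profile, 2)
    if name == "animal_like":
        profile = get_profile("animal")
        spec = SyntheticSpec(
            profile, _ANIMAL_LIKE, multi_label_fraction=0.10, seed=seed
        )
        return Fixture(generate_corpus(spec), profile, profile.default_n)
    if name == "plant_like":
        profile = get_profile("plant")
        spec = SyntheticSpec(
            profile, _PLANT_LIKE, multi_label_fraction=0.04, seed=seed
        )
        return Fixture(generate_corpus(spec), profile, profile.default_n)
    if name == "gramneg_like":
        profile = get_profile("gram_negative")
        spec = SyntheticSpec(profile, _GRAMNEG_LIKE, seed=seed)
        return Fixture(generate_corpus(spec), profile, profile.default_n)
    raise ValueError(
        f"unknown fixture {name!r}; choose from tiny2, animal_like, "
        "plant_like, gramneg_like"
    )
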