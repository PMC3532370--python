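"""The n-gram naive Bayes localization classifier.

Training builds, for every localization class L, a table of n-gram counts
c(g, L) with total C(L), a sequence-count prior P(L), and a corpus-wide
vocabulary size V.  A query sequence S with gram bag {g} is scored per
class in log space::

    log score(L) = log P(L) + sum_g  log[ (c(g, L) + a) / (C(L) + a * V) ]

with Lidstone smoothing constant ``a`` (default 1.0) and
V = (distinct grams observed in the whole training corpus) + 1.  The +1
reserves smoothing mass for never-seen grams; the full 20^n gram space is
NOT used as V because for n = 7 it would be ~1.28e9 and the smoothing mass
would swamp the real counts.

Posteriors come from a log-sum-exp normalization.  Two derived scores are
reported on a 0-100 scale:

* CS (confidence score) = 100 * p1, the top posterior;
* MLCS (multi-localization confidence score) = 100 * (p1 + p2) * (p2 / p1),
  which is 100 exactly when the top two classes split the mass evenly and
  decays as the margin widens.  When MLCS >= the threshold (default 60.0)
  the call is reported as a dual location "TOP1/TOP2".

Multi-labelled training sequences contribute their full gram counts to
every class in their label set, and increment each of those classes'
sequence counts for the empirical prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import (
    NegativeCount,
    NglocError,
    NoCanonicalGrams,
    SequenceTooShort,
    UnknownClass,
)
from .sequences import NgramBag, SequenceRecord, SpeciesProfile, extract_ngrams, get_profile

MODEL_FORMAT_VERSION = 1

__all__ = [
    "NgramModel",
    "Prediction",
    "train",
    "score",
    "predict_top_k",
    "loo_remove",
    "loo_restore",
    "compute_mlcs",
]


def compute_mlcs(p1: float, p2: float) -> float:
    """Multi-localization confidence score from the top two posteriors.

    ``100 * (p1 + p2) * (p2 / p1)`` for ``p1 >= p2``; equals 100 iff the
    top two posteriors are each exactly 0.5, and is monotonically
    increasing in ``p2`` for fixed ``p1``.
    """
    if p1 <= 0.0:
        return 0.0
    return 100.0 * (p1 + p2) * (p2 / p1)


@dataclass(frozen=True)
class Prediction:
    """The full scoring result for one query sequence.

    ``ranked`` holds ``(class_code, cs_score)`` pairs sorted by posterior
    descending (ties broken by class-code lexicographic order), where
    ``cs_score = 100 * posterior``.  ``call`` is either the top class code
    or ``"TOP1/TOP2"`` when the MLCS reaches the dual-call threshold.
    """

    seq_id: str
    posteriors: dict[str, float]
    ranked: tuple[tuple[str, float], ...]
    cs: float
    mlcs: float
    call: str
    n_skipped: int = 0

    @property
    def top(self) -> str:
        return self.ranked[0][0]

    def top_k(self, k: int) -> tuple[tuple[str, float], ...]:
        return self.ranked[:k]


class NgramModel:
    """Per-class n-gram count tables plus priors and smoothing.

    Use :meth:`train` to build one from labelled records; :meth:`score`
    and :meth:`predict_top_k` to classify; :meth:`loo_remove` /
    :meth:`loo_restore` for the leave-one-out decrement trick; and
    :meth:`save` / :meth:`load` for the flat text serialization.
    """

    def __init__(
        self,
        profile: SpeciesProfile,
        n: int | None = None,
        alpha: float = 1.0,
        priors: str = "empirical",
        mlcs_threshold: float = 60.0,
    ):
        if alpha <= 0:
            raise ValueError("smoothing constant alpha must be > 0")
        if priors not in ("empirical", "uniform"):
            raise ValueError("priors must be 'empirical' or 'uniform'")
        self.profile = profile
        self.n = int(n) if n is not None else profile.default_n
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.alpha = float(alpha)
        self.priors_mode = priors
        self.mlcs_threshold = float(mlcs_threshold)
        self.counts: dict[str, dict[str, int]] = {c: {} for c in profile.class_codes}
        self.class_totals: dict[str, int] = {c: 0 for c in profile.class_codes}
        self.class_seq_counts: dict[str, int] = {c: 0 for c in profile.class_codes}
        self.vocab_size: int = 1
        self.training_skipped: list[tuple[str, str]] = []

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------

    @classmethod
    def train(
        cls,
        records: Iterable[SequenceRecord],
        profile: SpeciesProfile,
        n: int | None = None,
        alpha: float = 1.0,
        priors: str = "empirical",
        mlcs_threshold: float = 60.0,
    ) -> "NgramModel":
        """Build a model from labelled records.

        Every record contributes its gram counts to each class in its
        label set.  Records shorter than ``n`` are excluded (recorded in
        ``training_skipped``) and training continues; an unknown label
        raises :class:`UnknownClass`.
        """
        model = cls(profile, n=n, alpha=alpha, priors=priors, mlcs_threshold=mlcs_threshold)
        valid = set(profile.class_codes)
        vocab: set[str] = set()
        for rec in records:
            if not rec.labels:
                raise UnknownClass(f"training record {rec.id!r} has no labels")
            for lab in rec.labels:
                if lab not in valid:
                    raise UnknownClass(
                        f"record {rec.id!r}: label {lab!r} not in profile "
                        f"{profile.name!r} ({'/'.join(profile.class_codes)})"
                    )
            try:
                bag = extract_ngrams(rec.sequence, model.n)
            except SequenceTooShort:
                model.training_skipped.append((rec.id, "too_short"))
                warnings.warn(
                    f"record {rec.id!r} shorter than n={model.n}; excluded from training",
                    stacklevel=2,
                )
                continue
            vocab.update(bag.counts)
            for lab in rec.labels:
                table = model.counts[lab]
                for g, c in bag.counts.items():
                    table[g] = table.get(g, 0) + c
                model.class_totals[lab] += bag.total
                model.class_seq_counts[lab] += 1
        model.vocab_size = len(vocab) + 1
        return model

    @property
    def priors(self) -> dict[str, float]:
        """Class prior P(L): empirical sequence-count share, or uniform."""
        codes = self.profile.class_codes
        if self.priors_mode == "uniform":
            p = 1.0 / len(codes)
            return {c: p for c in codes}
        total = sum(self.class_seq_counts.values())
        if total == 0:
            raise NglocError("model has no training data")
        return {c: self.class_seq_counts[c] / total for c in codes}

    # ------------------------------------------------------------------
    # scoring
    # ------------------------------------------------------------------

    def score(self, seq: str, seq_id: str = "query") -> Prediction:
        """Posterior over all classes for one amino-acid sequence."""
        bag = extract_ngrams(seq, self.n)
        if bag.total == 0:
            raise NoCanonicalGrams(
                f"{seq_id!r}: all {bag.n_skipped} windows contained "
                "non-canonical residues"
            )
        return self.score_bag(bag, seq_id=seq_id)

    def score_bag(self, bag: NgramBag, seq_id: str = "query") -> Prediction:
        """Score an already-extracted gram bag (log-space, log-sum-exp)."""
        priors = self.priors
        alpha, V = self.alpha, self.vocab_size
        log_scores: dict[str, float] = {}
        # canonical (sorted) class order so posteriors are bit-identical
        # under any permutation of the profile's class list
        for code in sorted(self.profile.class_codes):
            prior = priors[code]
            if prior == 0.0:
                log_scores[code] = -math.inf
                continue
            table = self.counts[code]
            log_denom = math.log(self.class_totals[code] + alpha * V)
            s = math.log(prior)
            for g, m in bag.counts.items():
                s += m * (math.log(table.get(g, 0) + alpha) - log_denom)
            log_scores[code] = s
        # log-sum-exp normalization
        m_max = max(log_scores.values())
        exps = {c: math.exp(v - m_max) for c, v in log_scores.items()}
        z = sum(exps.values())
        posteriors = {c: v / z for c, v in exps.items()}
        ranked = tuple(
            (c, 100.0 * posteriors[c])
            for c in sorted(posteriors, key=lambda c: (-posteriors[c], c))
        )
        p1 = posteriors[ranked[0][0]]
        cs = 100.0 * p1
        if len(ranked) < 2:
            mlcs = 0.0
            call = ranked[0][0]
        else:
            p2 = posteriors[ranked[1][0]]
            mlcs = compute_mlcs(p1, p2)
            if mlcs >= self.mlcs_threshold:
                call = f"{ranked[0][0]}/{ranked[1][0]}"
            else:
                call = ranked[0][0]
        return Prediction(
            seq_id=seq_id,
            posteriors=posteriors,
            ranked=ranked,
            cs=cs,
            mlcs=mlcs,
            call=call,
            n_skipped=bag.n_skipped,
        )

    def predict_top_k(self, record: SequenceRecord, k: int = 3) -> Prediction:
        """Score a record and truncate the ranking to the top ``k`` classes.

        ``k`` larger than the number of classes is clamped with a warning.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        n_classes = self.profile.n_classes
        if k > n_classes:
            warnings.warn(
                f"k={k} exceeds the {n_classes} classes of profile "
                f"{self.profile.name!r}; clamping",
                stacklevel=2,
            )
            k = n_classes
        pred = self.score(record.sequence, seq_id=record.id)
        return replace(pred, ranked=pred.ranked[:k])

    # ------------------------------------------------------------------
    # leave-one-out decrement trick
    # ------------------------------------------------------------------

    def _loo_delta(self, record: SequenceRecord) -> NgramBag:
        valid = set(self.profile.class_codes)
        for lab in record.labels:
            if lab not in valid:
                raise UnknownClass(f"label {lab!r} not in profile {self.profile.name!r}")
        return extract_ngrams(record.sequence, self.n)

    def loo_remove(self, record: SequenceRecord) -> "NgramModel":
        """Subtract one training record's contribution, in place.

        The empirical priors follow automatically (they are derived from
        the sequence counts); the vocabulary size V is deliberately NOT
        recomputed, so it stays fixed across a leave-one-out loop.
        Raises :class:`NegativeCount`, without mutating, if the record's
        counts are not present in the model.
        """
        bag = self._loo_delta(record)
        # validate fully before mutating
        for lab in record.labels:
            if self.class_seq_counts[lab] < 1:
                raise NegativeCount(
                    f"class {lab} has no sequences to remove ({record.id!r})"
                )
            table = self.counts[lab]
            for g, c in bag.counts.items():
                if table.get(g, 0) < c:
                    raise NegativeCount(
                        f"record {record.id!r} was not in the model "
                        f"(gram {g!r} count underflow in class {lab})"
                    )
        for lab in record.labels:
            table = self.counts[lab]
            for g, c in bag.counts.items():
                left = table[g] - c
                if left:
                    table[g] = left
                else:
                    del table[g]
            self.class_totals[lab] -= bag.total
            self.class_seq_counts[lab] -= 1
        return self

    def loo_restore(self, record: SequenceRecord) -> "NgramModel":
        """Exact inverse of :meth:`loo_remove`."""
        bag = self._loo_delta(record)
        for lab in record.labels:
            table = self.counts[lab]
            for g, c in bag.counts.items():
                table[g] = table.get(g, 0) + c
            self.class_totals[lab] += bag.total
            self.class_seq_counts[lab] += 1
        return self

    # ------------------------------------------------------------------
    # equality / serialization
    # ------------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NgramModel):
            return NotImplemented
        return (
            self.profile == other.profile
            and self.n == other.n
            and self.alpha == other.alpha
            and self.priors_mode == other.priors_mode
            and self.mlcs_threshold == other.mlcs_threshold
            and self.vocab_size == other.vocab_size
            and self.class_totals == other.class_totals
            and self.class_seq_counts == other.class_seq_counts
            and self.counts == other.counts
        )

    def save(self, path) -> None:
        """Write the model as a versioned, self-describing flat text file.

        Header lines carry the format version, profile, n, alpha, V and
        the per-class totals/priors; then one ``count class gram n`` line
        per stored gram, sorted for byte-stable output.
        """
        priors = self.priors
        with open(path, "w", encoding="ascii") as fh:
            fh.write(f"#ngloc-model\t{MODEL_FORMAT_VERSION}\n")
            fh.write(f"profile\t{self.profile.name}\n")
            fh.write(f"classes\t{','.join(self.profile.class_codes)}\n")
            fh.write(f"default_n\t{self.profile.default_n}\n")
            fh.write(f"n\t{self.n}\n")
            fh.write(f"alpha\t{self.alpha!r}\n")
            fh.write(f"priors\t{self.priors_mode}\n")
            fh.write(f"mlcs_threshold\t{self.mlcs_threshold!r}\n")
            fh.write(f"vocab_size\t{self.vocab_size}\n")
            for code in self.profile.class_codes:
                fh.write(
                    f"class\t{code}\t{self.class_seq_counts[code]}\t"
                    f"{self.class_totals[code]}\t{priors[code]!r}\n"
                )
            for code in self.profile.class_codes:
                for g in sorted(self.counts[code]):
                    fh.write(f"count\t{code}\t{g}\t{self.counts[code][g]}\n")

    @classmethod
    def load(cls, path) -> "NgramModel":
        """Read a model written by :meth:`save` (round-trip safe)."""
        header: dict[str, str] = {}
        class_lines: list[tuple[str, int, int]] = []
        count_lines: list[tuple[str, str, int]] = []
        with open(path, encoding="ascii") as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith("#ngloc-model\t"):
                raise NglocError(f"{path}: not an ngloc model file")
            version = int(first.split("\t")[1])
            if version != MODEL_FORMAT_VERSION:
                raise NglocError(f"{path}: unsupported model format version {version}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "class":
                    class_lines.append((parts[1], int(parts[2]), int(parts[3])))
                elif parts[0] == "count":
                    count_lines.append((parts[1], parts[2], int(parts[3])))
                else:
                    header[parts[0]] = parts[1]
        codes = tuple(header["classes"].split(","))
        name = header["profile"]
        default_n = int(header["default_n"])
        from .sequences import PROFILES  # local to avoid cycle at import time

        profile = PROFILES.get(name)
        if profile is None or profile.class_codes != codes or profile.default_n != default_n:
            profile = SpeciesProfile(name, codes, default_n)
        model = cls(
            profile,
            n=int(header["n"]),
            alpha=float(header["alpha"]),
            priors=header["priors"],
            mlcs_threshold=float(header["mlcs_threshold"]),
        )
        model.vocab_size = int(header["vocab_size"])
        for code, seqs, total in class_lines:
            if code not in model.counts:
                raise NglocError(f"{path}: class line for unknown code {code!r}")
            model.class_seq_counts[code] = seqs
            model.class_totals[code] = total
        for code, gram, c in count_lines:
            model.counts[code][gram] = c
        for code in codes:  # consistency: sum of counts must equal the total
            if sum(model.counts[code].values()) != model.class_totals[code]:
                raise NglocError(f"{path}: count/total mismatch for class {code}")
        return model


# ----------------------------------------------------------------------
# functional aliases mirroring the operation names
# ----------------------------------------------------------------------

def train(
    records: Iterable[SequenceRecord],
    profile: SpeciesProfile | str,
    n: int | None = None,
    alpha: float = 1.0,
    **kwargs,
) -> NgramModel:
    if isinstance(profile, str):
        profile = get_profile(profile)
    return NgramModel.train(records, profile, n=n, alpha=alpha, **kwargs)


def score(model: NgramModel, seq: str, seq_id: str = "query") -> Prediction:
    return model.score(seq, seq_id=seq_id)


def predict_top_k(model: NgramModel, record: SequenceRecord, k: int = 3) -> Prediction:
    return model.predict_top_k(record, k=k)


def loo_remove(model: NgramModel, record: SequenceRecord) -> NgramModel:
    return model.loo_remove(record)


def loo_restore(model: NgramModel, record: SequenceRecord) -> NgramModel:
    return model.loo_restore(record)
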