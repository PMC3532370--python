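"""Independent oracles the implementation is checked against.

These deliberately avoid the package's scoring path: the naive Bayes
oracle works in exact rational arithmetic straight from the definition
(no logs, no smoothing-in-log-space), and the leave-one-out oracle
retrains a fresh model for every fold instead of using the count
decrement trick.
"""

from collections import Counter
from fractions import Fraction

from ngloc import NgramModel
from ngloc.sequences import CANONICAL_AA

_CANON = set(CANONICAL_AA)


def _windows(seq: str, n: int) -> list[str]:
    s = seq.upper()
    return [
        s[i : i + n]
        for i in range(len(s) - n + 1)
        if all(ch in _CANON for ch in s[i : i + n])
    ]


def rational_posteriors(records, class_codes, query: str, n: int, alpha: int = 1):
    """Exact-arithmetic naive Bayes posterior, straight from the definition.

    ``alpha`` must be an integer (or Fraction) so the computation stays
    rational end to end.
    """
    counts = {c: Counter() for c in class_codes}
    seq_counts = {c: 0 for c in class_codes}
    vocab: set[str] = set()
    for rec in records:
        ws = _windows(rec.sequence, n)
        vocab.update(ws)
        for lab in rec.labels:
            counts[lab].update(ws)
            seq_counts[lab] += 1
    V = len(vocab) + 1
    total_seqs = sum(seq_counts.values())
    joint = {}
    for c in class_codes:
        p = Fraction(seq_counts[c], total_seqs)
        denom = sum(counts[c].values()) + alpha * V
        for w in _windows(query, n):
            p *= Fraction(counts[c][w] + alpha, denom)
        joint[c] = p
    z = sum(joint.values())
    return {c: joint[c] / z for c in class_codes}


def retrain_loo_predictions(records, profile, n: int, alpha: float = 1.0):
    """Leave-one-out by full retraining per fold, vocabulary size frozen
    at the all-records value."""
    full = NgramModel.train(records, profile, n=n, alpha=alpha)
    V = full.vocab_size
    pairs = []
    for i, rec in enumerate(records):
        fold = NgramModel.train(records[:i] + records[i + 1 :], profile, n=n, alpha=alpha)
        fold.vocab_size = V
        pairs.append((fold.score(rec.sequence, seq_id=rec.id), rec.labels))
    return pairs


def random_small_corpora(n_corpora: int = 20, seed: int = 0):
    """Seeded stream of tiny labelled corpora over a 4-letter alphabet
    (collisions guaranteed), with 2-4 classes, <=10 sequences, n<=3."""
    import numpy as np

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDE"))
    out = []
    for _ in range(n_corpora):
        n_classes = int(rng.integers(2, 5))
        codes = tuple(f"C{j}" for j in range(n_classes))
        n_seqs = int(rng.integers(n_classes, 11))
        n = int(rng.integers(1, 4))
        from ngloc import SequenceRecord, SpeciesProfile

        records = []
        for i in range(n_seqs):
            # cycle classes so every class has at least one sequence
            lab = codes[i % n_classes]
            length = int(rng.integers(max(n, 5), 13))
            seq = "".join(rng.choice(alphabet, size=length))
            records.append(SequenceRecord(f"s{i}", seq, (lab,)))
        query = "".join(rng.choice(alphabet, size=int(rng.integers(n, 10))))
        out.append((SpeciesProfile(f"rand{n_classes}", codes, n), records, query, n))
    return out
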