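import math
import warnings
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ngloc import (
    NgramBag,
    NgramModel,
    SequenceRecord,
    SpeciesProfile,
    compute_mlcs,
    train,
)
from ngloc.errors import (
    NegativeCount,
    NoCanonicalGrams,
    SequenceTooShort,
    UnknownClass,
)

from _oracles import random_small_corpora, rational_posteriors


def two_class_model(n=2, alpha=1.0, **kw):
    profile = SpeciesProfile("tiny2", ("A", "B"), default_n=n)
    records = [
        SequenceRecord("a1", "AAAA", ("A",)),
        SequenceRecord("b1", "CCCC", ("B",)),
    ]
    return NgramModel.train(records, profile, n=n, alpha=alpha, **kw)


class TestTraining:
    def test_single_sequence_counts(self):
        profile = SpeciesProfile("one", ("A",), default_n=2)
        model = NgramModel.train(
            [SequenceRecord("s", "AAAA", ("A",))], profile, n=2
        )
        assert model.counts["A"] == {"AA": 3}
        assert model.class_totals["A"] == 3

    def test_vocab_and_priors(self):
        model = two_class_model()
        assert model.vocab_size == 3  # {AA, CC} observed, +1
        assert model.priors == {"A": 0.5, "B": 0.5}

    def test_multilabel_record_trains_both_classes(self):
        profile = SpeciesProfile("p", ("CYT", "NUC"), default_n=2)
        model = NgramModel.train(
            [SequenceRecord("s", "MKMK", ("CYT", "NUC"))], profile, n=2
        )
        assert model.counts["CYT"] == model.counts["NUC"] == {"MK": 2, "KM": 1}
        assert model.class_seq_counts == {"CYT": 1, "NUC": 1}

    def test_unknown_label_rejected(self):
        profile = SpeciesProfile("p", ("CYT",), default_n=2)
        with pytest.raises(UnknownClass, match="NUC"):
            NgramModel.train([SequenceRecord("s", "MKMK", ("NUC",))], profile, n=2)

    def test_too_short_record_excluded_training_continues(self):
        profile = SpeciesProfile("p", ("A", "B"), default_n=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NgramModel.train(
                [
                    SequenceRecord("ok", "AAAA", ("A",)),
                    SequenceRecord("tiny", "CC", ("B",)),
                ],
                profile,
                n=3,
            )
        assert model.training_skipped == [("tiny", "too_short")]
        assert model.class_seq_counts == {"A": 1, "B": 0}

    def test_class_total_is_sum_of_counts(self):
        corpora = random_small_corpora(5, seed=3)
        for profile, records, _, n in corpora:
            model = NgramModel.train(records, profile, n=n)
            for code in profile.class_codes:
                assert sum(model.counts[code].values()) == model.class_totals[code]
            assert abs(sum(model.priors.values()) - 1.0) < 1e-9


class TestScoring:
    def test_worked_example(self):
        """Query 'AA' on the hand corpus: P(AA|A)=2/3, P(AA|B)=1/6 -> 0.8/0.2."""
        model = two_class_model()
        pred = model.score("AA")
        assert pred.posteriors["A"] == pytest.approx(0.8, abs=1e-12)
        assert pred.posteriors["B"] == pytest.approx(0.2, abs=1e-12)
        assert pred.cs == pytest.approx(80.0, abs=1e-9)
        assert pred.mlcs == pytest.approx(25.0, abs=1e-9)
        assert pred.call == "A"

    def test_symmetric_classes_tie(self):
        """Identical counts and priors: exact 0.5/0.5, dual call, lexicographic order."""
        profile = SpeciesProfile("sym", ("B", "A"), default_n=2)
        records = [
            SequenceRecord("a1", "AAAA", ("A",)),
            SequenceRecord("b1", "AAAA", ("B",)),
        ]
        model = NgramModel.train(records, profile, n=2)
        pred = model.score("AAA")
        assert pred.posteriors == {"A": 0.5, "B": 0.5}
        assert pred.cs == 50.0
        assert pred.mlcs == 100.0
        assert pred.call == "A/B"  # tie broken lexicographically

    def test_single_class_degenerate(self):
        profile = SpeciesProfile("one", ("Z",), default_n=2)
        model = NgramModel.train([SequenceRecord("s", "MKMK", ("Z",))], profile, n=2)
        pred = model.score("MK")
        assert pred.posteriors == {"Z": 1.0}
        assert pred.cs == 100.0
        assert pred.mlcs == 0.0
        assert pred.call == "Z"

    def test_matches_rational_oracle(self):
        """Log-space scoring equals exact rational-arithmetic naive Bayes."""
        for profile, records, query, n in random_small_corpora(20, seed=0):
            model = NgramModel.train(records, profile, n=n)
            pred = model.score(query)
            oracle = rational_posteriors(records, profile.class_codes, query, n)
            for code in profile.class_codes:
                assert pred.posteriors[code] == pytest.approx(
                    float(oracle[code]), abs=1e-10
                )

    def test_posteriors_normalized(self):
        for profile, records, query, n in random_small_corpora(10, seed=1):
            model = NgramModel.train(records, profile, n=n)
            assert sum(model.score(query).posteriors.values()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_class_order_invariance(self):
        """Permuting class insertion order never changes the posteriors."""
        for profile, records, query, n in random_small_corpora(6, seed=2):
            flipped = SpeciesProfile(
                profile.name + "_rev", tuple(reversed(profile.class_codes)), n
            )
            p1 = NgramModel.train(records, profile, n=n).score(query).posteriors
            p2 = NgramModel.train(records, flipped, n=n).score(query).posteriors
            assert p1 == p2

    def test_monotone_evidence(self):
        """Adding a gram seen only in class L never decreases p(L)."""
        model = two_class_model()
        base = NgramBag(("AA",), 2)
        more = NgramBag(("AA", "AA"), 2)
        pA_base = model.score_bag(base).posteriors["A"]
        pA_more = model.score_bag(more).posteriors["A"]
        assert pA_more >= pA_base

    def test_no_canonical_grams(self):
        model = two_class_model()
        with pytest.raises(NoCanonicalGrams):
            model.score("XXX")

    def test_query_shorter_than_n(self):
        model = two_class_model()
        with pytest.raises(SequenceTooShort):
            model.score("A")

    def test_uniform_priors_switch(self):
        profile = SpeciesProfile("p", ("A", "B"), default_n=2)
        records = [
            SequenceRecord("a1", "AAAA", ("A",)),
            SequenceRecord("a2", "AAAA", ("A",)),
            SequenceRecord("b1", "CCCC", ("B",)),
        ]
        emp = NgramModel.train(records, profile, n=2).priors
        uni = NgramModel.train(records, profile, n=2, priors="uniform").priors
        assert emp == {"A": 2 / 3, "B": 1 / 3}
        assert uni == {"A": 0.5, "B": 0.5}


class TestMlcs:
    def test_equals_100_iff_even_split(self):
        assert compute_mlcs(0.5, 0.5) == 100.0
        assert compute_mlcs(0.6, 0.4) < 100.0

    @given(
        p1=st.floats(0.01, 1.0),
        delta=st.floats(0.0, 1.0),
        eps=st.floats(0.001, 0.5),
    )
    def test_bounded_and_monotone_in_p2(self, p1, delta, eps):
        p2 = p1 * delta  # p2 <= p1
        if p1 + p2 > 1.0:
            return
        m = compute_mlcs(p1, p2)
        assert 0.0 <= m <= 100.0 + 1e-9
        p2_hi = min(p1, p2 + eps)
        if p1 + p2_hi <= 1.0:
            assert compute_mlcs(p1, p2_hi) >= m


class TestTopK:
    def test_truncates_ranking(self):
        model = two_class_model()
        rec = SequenceRecord("q", "AA")
        assert len(model.predict_top_k(rec, k=1).ranked) == 1
        assert model.predict_top_k(rec, k=1).ranked[0][0] == "A"

    def test_k_clamped_with_warning(self):
        model = two_class_model()
        rec = SequenceRecord("q", "AA")
        with pytest.warns(UserWarning, match="clamp"):
            pred = model.predict_top_k(rec, k=5)
        assert len(pred.ranked) == 2

    def test_invalid_k(self):
        model = two_class_model()
        with pytest.raises(ValueError):
            model.predict_top_k(SequenceRecord("q", "AA"), k=0)


class TestLeaveOneOut:
    def test_remove_then_restore_is_identity(self):
        for profile, records, _, n in random_small_corpora(8, seed=4):
            model = NgramModel.train(records, profile, n=n)
            reference = NgramModel.train(records, profile, n=n)
            for rec in records:
                model.loo_remove(rec)
                model.loo_restore(rec)
            assert model == reference

    def test_hand_count_decrement(self):
        profile = SpeciesProfile("p", ("A",), default_n=2)
        records = [
            SequenceRecord("s1", "AAAA", ("A",)),
            SequenceRecord("s2", "AAA", ("A",)),
        ]
        model = NgramModel.train(records, profile, n=2)
        assert model.counts["A"]["AA"] == 5
        model.loo_remove(records[1])
        assert model.counts["A"]["AA"] == 3

    def test_remove_foreign_record_guarded(self):
        model = two_class_model()
        with pytest.raises(NegativeCount):
            model.loo_remove(SequenceRecord("ghost", "GGGG", ("A",)))
        # failed removal must not have mutated the model
        assert model == two_class_model()

    def test_decrement_equals_retrain_with_frozen_vocab(self):
        """loo_remove + score == full retrain on the rest (V frozen)."""
        for profile, records, _, n in random_small_corpora(6, seed=5):
            if len(records) < 3:
                continue
            model = NgramModel.train(records, profile, n=n)
            V = model.vocab_size
            for i, rec in enumerate(records):
                rest = records[:i] + records[i + 1 :]
                if any(
                    lab not in {l for r in rest for l in r.labels}
                    for lab in rec.labels
                ):
                    continue  # class would empty: prior 0 either way
                retrained = NgramModel.train(rest, profile, n=n)
                retrained.vocab_size = V
                model.loo_remove(rec)
                p_trick = model.score(rec.sequence).posteriors
                model.loo_restore(rec)
                p_oracle = retrained.score(rec.sequence).posteriors
                for code in profile.class_codes:
                    assert p_trick[code] == pytest.approx(p_oracle[code], abs=1e-12)


class TestSerialization:
    def test_round_trip_models_equal(self, tmp_path):
        for profile, records, query, n in random_small_corpora(4, seed=6):
            model = NgramModel.train(records, profile, n=n)
            path = tmp_path / f"{profile.name}.ngl"
            model.save(path)
            loaded = NgramModel.load(path)
            assert loaded == model
            assert loaded.score(query).posteriors == model.score(query).posteriors

    def test_round_trip_byte_exact(self, tmp_path):
        model = two_class_model(alpha=0.75)
        p1, p2 = tmp_path / "m1.ngl", tmp_path / "m2.ngl"
        model.save(p1)
        NgramModel.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()
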