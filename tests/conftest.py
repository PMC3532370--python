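import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ngloc import SpeciesProfile, SequenceRecord, make_fixture  # noqa: E402


@pytest.fixture
def tiny2():
    """Two-class hand corpus: A='AAAA', B='CCCC', n=2."""
    return make_fixture("tiny2")


@pytest.fixture
def separable_corpus():
    """Hand-built two-class corpus with unambiguous class motifs.

    Every class-A sequence carries a WWWWW stretch, every class-B
    sequence a YYYYY stretch, over otherwise shared backgrounds, so any
    working classifier separates them perfectly under leave-one-out.
    """
    profile = SpeciesProfile("toy2", ("AAA", "BBB"), default_n=3)
    records = [
        SequenceRecord("a1", "WWWWWACDEF", ("AAA",)),
        SequenceRecord("a2", "GHIKWWWWWL", ("AAA",)),
        SequenceRecord("a3", "MNPQWWWWWR", ("AAA",)),
        SequenceRecord("b1", "YYYYYACDEF", ("BBB",)),
        SequenceRecord("b2", "GHIKYYYYYL", ("BBB",)),
        SequenceRecord("b3", "MNPQYYYYYR", ("BBB",)),
    ]
    return records, profile
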