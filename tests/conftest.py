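import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from patchem import (
    Corpus,
    MentionSpan,
    PatentRecord,
    SimulationConfig,
    build_lexicon,
    make_compounds,
    make_corpus,
    merge_lexicons,
)


@pytest.fixture(scope="session")
def clean_world():
    """Corpus with zero homographs and zero unseen terms: every implant is a
    unique lexicon term, so dictionary tagging should be perfect."""
    config = SimulationConfig(
        seed=101, n_records=60,
        ambiguous_homograph_fraction=0.0, unseen_chemical_fraction=0.0,
    )
    src_a, src_b = make_compounds(config)
    lexicon = build_lexicon(merge_lexicons([src_a, src_b]))
    corpus, pool = make_corpus(lexicon, config)
    return corpus, lexicon, pool, config


@pytest.fixture(scope="session")
def noisy_world():
    """Corpus with homograph ambiguity and unseen chemicals (defaults)."""
    config = SimulationConfig(seed=202, n_records=120)
    src_a, src_b = make_compounds(config)
    lexicon = build_lexicon(merge_lexicons([src_a, src_b]))
    corpus, pool = make_corpus(lexicon, config)
    return corpus, lexicon, pool, config


@pytest.fixture()
def tiny_corpus():
    return Corpus(
        records=[
            PatentRecord("P1", "Aspirin works", "The aspirin dose was low."),
            PatentRecord("P2", "No chemicals here", "Just plain language."),
        ],
        gold=[
            MentionSpan("P1", "T", 0, 7, "Aspirin", source="gold"),
            MentionSpan("P1", "A", 4, 11, "aspirin", source="gold"),
        ],
    )
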