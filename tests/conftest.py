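import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def aspirin_doc():
    """One hand-built abstract with entities and a gold relation."""
    from chemrel.corpus import (Abstract, CprGroup, EntityKind, EntityMention,
                                RelationGold)
    ab = Abstract("D1", "Aspirin study", "Aspirin inhibits COX-2 in cells.")
    # text = "Aspirin study\tAspirin inhibits COX-2 in cells."
    text = ab.text
    ents = [
        EntityMention("D1", "T1", EntityKind.CHEMICAL, 0, 7, "Aspirin"),
        EntityMention("D1", "T2", EntityKind.CHEMICAL, 14, 21, "Aspirin"),
        EntityMention("D1", "T3", EntityKind.GENE, 31, 36, "COX-2"),
    ]
    for e in ents:
        assert text[e.char_start:e.char_end] == e.surface
    gold = [RelationGold("D1", CprGroup.CPR4, "T2", "T3")]
    return ab, ents, gold


@pytest.fixture
def small_synth():
    """A small generated corpus shared across tests."""
    from chemrel.synthetic import SynthConfig, generate_corpus
    cfg = SynthConfig(n_abstracts=15, min_sentences=3, max_sentences=5)
    return cfg, generate_corpus(cfg, seed=123)


@pytest.fixture
def small_vocab(small_synth):
    from chemrel.tokenize import tokenize_with_spans
    from chemrel.vocab import build_vocab
    _, (abstracts, _, _) = small_synth
    return build_vocab([[t.surface for t in tokenize_with_spans(a.text)]
                        for a in abstracts])
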