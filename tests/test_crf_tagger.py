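import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from patchem import (
    LinearChainCRF,
    MentionSpan,
    bio_decode,
    bio_encode,
    build_clusters,
    token_features,
    tokenize,
    transliterate,
    sanitize_bars,
)
from patchem.crf_tagger import CRFTagger, FeatureConfig, lemmatize, pos_tag, stem


# -- pre-processing -----------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("α-pinene", "a-pinene"),
        ("water", "water"),
        ("β‐blocker", "b-blocker"),
        ("café", "cafe"),
    ],
)
def test_transliterate_examples(text, expected):
    out, offset_map = transliterate(text)
    assert out == expected
    assert offset_map == list(range(len(text)))


@given(st.text(max_size=60))
def test_transliterate_preserves_length_and_ascii(text):
    out, _ = transliterate(text)
    assert len(out) == len(text)
    assert all(ord(c) < 128 for c in out)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("[|]", "[ ]"),
        ("a|b", "a|b"),
        ("(|)", "( )"),
        ("{|}", "{ }"),
        ("||", "||"),
    ],
)
def test_sanitize_bars(text, expected):
    assert sanitize_bars(text) == expected
    assert len(sanitize_bars(text)) == len(text)


# -- features -----------------------------------------------------------------

def feats_for(text):
    tokens = tokenize(text)
    return tokens, token_features(tokens, FeatureConfig())


def test_character_count_features():
    _, feats = feats_for("H2SO4")
    f = feats[0]
    # counts bucketed as 0,1,2,3+: two digits, three uppers, zero lowers
    assert "ndigit=2" in f and "nupper=3+" in f and "nlower=0" in f


def test_affix_and_ring_features():
    _, feats = feats_for("ethanol")
    f = feats[0]
    assert "suf2=ol" in f and "pre3=eth" in f and "ring=True" in f


def test_element_gazetteer_feature():
    _, feats = feats_for("Fe plus motor")
    assert "elem=True" in feats[0]
    assert "elem=False" in feats[2]


def test_unknown_word_cluster_is_unk():
    clusters = build_clusters([["alpha", "beta"], ["alpha", "gamma"]],
                              dim=2, k=2, seed=0)
    tokens = tokenize("alpha zzz")
    feats = token_features(tokens, FeatureConfig(), clusters=clusters)
    assert any(f.startswith("clu=") and f != "clu=UNK" for f in feats[0])
    assert "clu=UNK" in feats[1]


def test_window_copies_have_positional_prefixes():
    _, feats = feats_for("one two three")
    assert any(f.startswith("+1:w=") for f in feats[0])
    assert any(f.startswith("-1:w=") for f in feats[1])
    assert "-1:pad=True" in feats[0]


def test_feature_extraction_pure():
    tokens = tokenize("stable text here")
    a = token_features(tokens, FeatureConfig())
    b = token_features(tokens, FeatureConfig())
    assert a == b


def test_pos_lemma_length_mismatch_rejected():
    tokens = tokenize("a b c")
    with pytest.raises(ValueError):
        token_features(tokens, FeatureConfig(), pos_tags=["NN"])


def test_builtin_linguistics_smoke():
    assert stem("treating") == "treat"
    assert lemmatize("tablets") == "tablet"
    assert pos_tag("120") == "CD"
    assert pos_tag("quickly") == "RB"


# -- clusters -----------------------------------------------------------------

def test_clusters_deterministic():
    sents = [["red", "apple"], ["red", "berry"], ["blue", "sky"], ["blue", "sea"]]
    m1 = build_clusters(sents, dim=2, k=2, seed=3)
    m2 = build_clusters(sents, dim=2, k=2, seed=3)
    assert m1.word_to_cluster == m2.word_to_cluster
    assert all(0 <= cid < 2 for cid in m1.word_to_cluster.values())


def test_clusters_separate_cooccurrence_blocks():
    """Two disjoint co-occurrence blocks with K=2: words of a block share a
    cluster, checked against a brute-force 2-means on one dimension."""
    rng = random.Random(0)
    block_a = ["acidone", "basole", "metharene"]
    block_b = ["lawyer", "court", "filing"]
    sents = []
    for _ in range(200):
        block = block_a if rng.random() < 0.5 else block_b
        sents.append(rng.sample(block, 3))
    model = build_clusters(sents, dim=4, k=2, seed=1)
    a_ids = {model.word_to_cluster[w] for w in block_a}
    b_ids = {model.word_to_cluster[w] for w in block_b}
    assert len(a_ids) == 1 and len(b_ids) == 1 and a_ids != b_ids


def test_clusters_k_exceeding_vocab_rejected():
    with pytest.raises(ValueError):
        build_clusters([["a", "b"]], dim=2, k=5, seed=0)


def test_cluster_model_file_round_trip(tmp_path):
    sents = [["red", "apple"], ["blue", "sky"], ["red", "berry"], ["blue", "sea"]]
    model = build_clusters(sents, dim=2, k=2, seed=3)
    path = tmp_path / "clusters.tsv"
    model.save(path)
    from patchem.crf_tagger import ClusterModel

    again = ClusterModel.load(path)
    assert again.word_to_cluster == model.word_to_cluster
    assert again.k == model.k


# -- BIO ----------------------------------------------------------------------

def test_bio_encode_basic():
    tokens = tokenize("ethyl acetate buffer")
    span = MentionSpan("D", "T", 0, 13, "ethyl acetate", source="gold")
    assert bio_encode([span], tokens) == ["B", "I", "O"]


def test_bio_decode_all_outside():
    tokens = tokenize("a b c")
    assert bio_decode(["O", "O", "O"], tokens, "a b c", "D", "T") == []


def test_bio_decode_repairs_bare_inside():
    text = "a b c"
    tokens = tokenize(text)
    spans = bio_decode(["O", "I", "O"], tokens, text, "D", "T")
    assert [(s.start, s.end) for s in spans] == [(2, 3)]


@given(st.integers(min_value=0, max_value=5000))
def test_bio_round_trip_random_token_aligned_spans(seed):
    rng = random.Random(seed)
    words = ["w%d" % i for i in range(rng.randint(1, 12))]
    text = " ".join(words)
    tokens = tokenize(text)
    # random non-overlapping token-aligned spans
    spans = []
    i = 0
    while i < len(tokens):
        if rng.random() < 0.4:
            j = min(len(tokens), i + rng.randint(1, 3))
            spans.append(
                MentionSpan("D", "T", tokens[i].start, tokens[j - 1].end,
                            text[tokens[i].start : tokens[j - 1].end],
                            source="gold")
            )
            i = j
        else:
            i += 1
    labels = bio_encode(spans, tokens)
    decoded = bio_decode(labels, tokens, text, "D", "T")
    assert [(s.start, s.end) for s in decoded] == [(s.start, s.end) for s in spans]


# -- CRF ----------------------------------------------------------------------

def synth_sequences(n, rng, flag_rate=0.3):
    """Separable data: tokens carrying flag=chem are exactly the B tokens."""
    X, y = [], []
    for _ in range(n):
        feats, labels = [], []
        for _ in range(rng.randint(3, 9)):
            if rng.random() < flag_rate:
                feats.append(["flag=chem", "w=x%d" % rng.randint(0, 30)])
                labels.append("B")
            else:
                feats.append(["flag=plain", "w=y%d" % rng.randint(0, 30)])
                labels.append("O")
        X.append(feats)
        y.append(labels)
    return X, y


def test_crf_learns_separable_data():
    rng = random.Random(7)
    X, y = synth_sequences(40, rng)
    Xh, yh = synth_sequences(15, rng)
    crf = LinearChainCRF(c2=0.01, max_iter=80, seed=0).fit(X, y)
    pred = crf.predict(Xh)
    total = correct = 0
    for p, g in zip(pred, yh):
        for a, b in zip(p, g):
            total += 1
            correct += a == b
    assert correct / total == 1.0


def test_crf_overfits_training_data():
    rng = random.Random(3)
    X, y = synth_sequences(30, rng)
    crf = LinearChainCRF(c2=0.01, max_iter=80, seed=0).fit(X, y)
    pred = crf.predict(X)
    total = sum(len(s) for s in y)
    correct = sum(a == b for p, g in zip(pred, y) for a, b in zip(p, g))
    assert correct / total >= 0.95


def test_crf_refuses_empty_features():
    X = [[[], [], []]]
    y = [["B", "I", "O"]]
    with pytest.raises(ValueError, match="empty"):
        LinearChainCRF().fit(X, y)


def test_crf_refuses_no_b_labels():
    X = [[["w=a"], ["w=b"]]]
    y = [["O", "O"]]
    with pytest.raises(ValueError, match="no B label"):
        LinearChainCRF().fit(X, y)


def test_crf_unseen_namespace_rejected():
    rng = random.Random(1)
    X, y = synth_sequences(10, rng)
    crf = LinearChainCRF(max_iter=20, seed=0).fit(X, y)
    with pytest.raises(ValueError, match="namespace 'mystery'"):
        crf.predict([[["mystery=1"]]])


def test_crf_predict_deterministic_with_marginals():
    rng = random.Random(5)
    X, y = synth_sequences(20, rng)
    crf = LinearChainCRF(max_iter=40, seed=0).fit(X, y)
    assert crf.predict(X) == crf.predict(X)
    margs = crf.predict_marginals(X[:3])
    for m in margs:
        assert m.shape[1] == 3
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-8)
        assert (m >= 0).all() and (m <= 1).all()


def test_crf_tagger_end_to_end(clean_world):
    """Mention F-score ≥ 90% on a held-out synthetic half with a fixed seed."""
    from patchem import Corpus, evaluate_mentions

    corpus, _, _, _ = clean_world
    half = len(corpus.records) // 2
    train_ids = {r.doc_id for r in corpus.records[:half]}
    train = Corpus(records=corpus.records[:half],
                   gold=[s for s in corpus.gold if s.doc_id in train_ids])
    test = Corpus(records=corpus.records[half:],
                  gold=[s for s in corpus.gold if s.doc_id not in train_ids])
    tagger = CRFTagger(seed=1, max_iter=60).train(train)
    _, report = evaluate_mentions(tagger.tag(test), test.gold)
    assert report.f_score is not None and report.f_score >= 90.0
    # spans valid in original coordinates even with pre-processing applied
    for s in tagger.tag(test):
        assert test.passage_text(s.doc_id, s.passage)[s.start : s.end] == s.surface
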