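import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from patchem import (
    DetectionCounts,
    MentionSpan,
    accuracy_from_rates,
    classify_passage,
    ensemble_union,
    evaluate_cpd,
    evaluate_mentions,
    f_score,
    metrics_from_counts,
)
from patchem.ensemble_eval import render_pct


def mk(doc, passage, start, end, source="dict", conf=1.0):
    return MentionSpan(doc, passage, start, end, "x" * (end - start),
                       source=source, confidence=conf)


# -- metric arithmetic ----------------------------------------------------------

def test_metrics_from_counts_worked_example():
    report = metrics_from_counts(DetectionCounts(tp=2, fp=1, fn=2, tn=5))
    r = report.rendered()
    assert r["precision"] == "66.67"
    assert r["recall"] == "50.00"
    assert r["f_score"] == "57.14"
    assert r["specificity"] == "83.33"
    assert r["accuracy"] == "70.00"


def test_f_score_reproduces_published_rounding():
    # precision 84.88, recall 85.55 must render as F = 85.21
    assert render_pct(f_score(84.88, 85.55)) == "85.21"


def test_cpd_accuracy_from_rates_reproduces_published_rounding():
    # sensitivity 97.00, specificity 82.74 at 8937 positive / 5063 negative
    # passages renders as accuracy 91.84
    acc = accuracy_from_rates(97.00, 82.74, n_pos=8937, n_neg=5063)
    assert render_pct(acc) == "91.84"


def test_perfect_counts_give_100():
    r = metrics_from_counts(DetectionCounts(tp=5, fp=0, fn=0)).rendered()
    assert r["precision"] == r["recall"] == r["f_score"] == "100.00"


def test_all_zero_counts_give_absent_metrics():
    report = metrics_from_counts(DetectionCounts())
    assert report.precision is None and report.recall is None
    assert report.f_score is None and report.accuracy is None


def test_f_between_p_and_r_property():
    rng = random.Random(1)
    for _ in range(200):
        tp, fp, fn = rng.randint(1, 50), rng.randint(0, 50), rng.randint(0, 50)
        rep = metrics_from_counts(DetectionCounts(tp=tp, fp=fp, fn=fn))
        assert min(rep.precision, rep.recall) <= rep.f_score <= max(
            rep.precision, rep.recall
        )
        assert 0 <= rep.f_score <= 100


# -- mention evaluation ---------------------------------------------------------

def test_evaluate_mentions_exact_match_only():
    gold = [mk("d1", "T", 0, 7, "gold"), mk("d1", "A", 5, 10, "gold")]
    pred = [mk("d1", "T", 0, 7), mk("d1", "A", 4, 10)]
    counts, report = evaluate_mentions(pred, gold)
    assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)
    r = report.rendered()
    assert r["precision"] == r["recall"] == r["f_score"] == "50.00"


def test_evaluate_mentions_identity():
    gold = [mk("d1", "T", 0, 7, "gold")]
    pred = [mk("d1", "T", 0, 7)]
    _, report = evaluate_mentions(pred, gold)
    assert report.rendered()["f_score"] == "100.00"


def test_duplicate_predictions_collapse():
    gold = [mk("d1", "T", 0, 7, "gold")]
    pred = [mk("d1", "T", 0, 7, conf=0.5), mk("d1", "T", 0, 7, conf=0.9)]
    counts, _ = evaluate_mentions(pred, gold)
    assert (counts.tp, counts.fp) == (1, 0)


def test_document_order_irrelevant():
    gold = [mk("d1", "T", 0, 3, "gold"), mk("d2", "T", 0, 3, "gold")]
    pred = [mk("d2", "T", 0, 3), mk("d1", "T", 0, 3), mk("d1", "A", 1, 4)]
    c1, _ = evaluate_mentions(pred, gold)
    c2, _ = evaluate_mentions(list(reversed(pred)), list(reversed(gold)))
    assert (c1.tp, c1.fp, c1.fn) == (c2.tp, c2.fp, c2.fn)


def brute_force_counts(pred, gold):
    pred_keys = sorted({p.key for p in pred})
    gold_keys = {g.key for g in gold}
    tp = sum(1 for k in pred_keys if k in gold_keys)
    return tp, len(pred_keys) - tp, len(gold_keys) - tp


@given(st.integers(min_value=0, max_value=10_000))
def test_mention_evaluation_agrees_with_brute_force(seed):
    rng = random.Random(seed)

    def random_spans(n, source):
        spans = []
        for _ in range(n):
            start = rng.randint(0, 20)
            spans.append(mk(f"d{rng.randint(0, 3)}", rng.choice("TA"),
                            start, start + rng.randint(1, 5), source=source))
        return spans

    gold_unique = {s.key: s for s in random_spans(rng.randint(0, 8), "gold")}
    gold = list(gold_unique.values())
    pred = random_spans(rng.randint(0, 8), "dict")
    counts, report = evaluate_mentions(pred, gold)
    tp, fp, fn = brute_force_counts(pred, gold)
    assert (counts.tp, counts.fp, counts.fn) == (tp, fp, fn)
    assert counts.tp + counts.fn == len(gold)
    if tp + fp > 0:
        assert report.precision == pytest.approx(100 * tp / (tp + fp))
    if tp + fn > 0:
        assert report.recall == pytest.approx(100 * tp / (tp + fn))


# -- ensemble union -------------------------------------------------------------

def test_union_keeps_both_disjoint_spans():
    out = ensemble_union([mk("d", "T", 0, 7)], [mk("d", "T", 10, 15, "crf")])
    assert {(s.start, s.end) for s in out} == {(0, 7), (10, 15)}
    assert all(s.source == "ensemble" for s in out)


def test_union_merges_identical_spans_max_confidence():
    out = ensemble_union(
        [mk("d", "T", 0, 7, conf=1.0)], [mk("d", "T", 0, 7, "crf", conf=0.6)]
    )
    assert len(out) == 1 and out[0].confidence == 1.0


def test_union_keeps_overlapping_different_spans():
    out = ensemble_union([mk("d", "T", 0, 7)], [mk("d", "T", 3, 9, "crf")])
    assert len(out) == 2


def test_union_recall_at_least_members(noisy_world):
    from patchem import CRFTagger, Corpus, tag_corpus

    corpus, lexicon, _, _ = noisy_world
    half = len(corpus.records) // 2
    ids = {r.doc_id for r in corpus.records[:half]}
    train = Corpus(records=corpus.records[:half],
                   gold=[s for s in corpus.gold if s.doc_id in ids])
    test = Corpus(records=corpus.records[half:],
                  gold=[s for s in corpus.gold if s.doc_id not in ids])
    dict_spans = tag_corpus(test, lexicon)
    crf_spans = CRFTagger(seed=2, max_iter=50).train(train).tag(test)
    union = ensemble_union(dict_spans, crf_spans)

    def recall(spans):
        _, r = evaluate_mentions(spans, test.gold)
        return r.recall or 0.0

    assert recall(union) >= max(recall(dict_spans), recall(crf_spans))


# -- CPD --------------------------------------------------------------------------

def test_classify_passage_rule():
    assert classify_passage([mk("d", "T", 0, 3)] * 3) == "chemical"
    assert classify_passage([]) == "non-chemical"


def test_evaluate_cpd_hand_count():
    gold = {("d1", "T"): "chemical", ("d2", "T"): "chemical",
            ("d3", "T"): "non-chemical"}
    pred = {("d1", "T"): "chemical", ("d2", "T"): "non-chemical",
            ("d3", "T"): "non-chemical"}
    counts, report = evaluate_cpd(pred, gold)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 0, 1, 1)
    assert report.rendered()["accuracy"] == "66.67"


def test_evaluate_cpd_all_correct():
    labels = {("d1", "T"): "chemical", ("d1", "A"): "non-chemical"}
    _, report = evaluate_cpd(labels, labels)
    assert report.rendered()["accuracy"] == "100.00"


def test_evaluate_cpd_key_mismatch():
    with pytest.raises(ValueError, match="keys differ"):
        evaluate_cpd({("d1", "T"): "chemical"}, {("d2", "T"): "chemical"})
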