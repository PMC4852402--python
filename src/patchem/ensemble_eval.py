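"""Ensemble combination, passage classification and challenge metrics.

The ensemble output is the union of the dictionary and CRF span sets; spans
identical on (doc, passage, start, end) merge keeping the larger confidence,
while overlapping-but-different spans are both kept.

Mention evaluation is micro-averaged exact-offset matching: a prediction is
a true positive iff a gold span has the same (doc, passage, start, end), each
gold span matches at most one prediction, and counts pool over all documents.
Passage classification (chemical vs non-chemical) calls a title or abstract
chemical iff at least one span falls in it, and is scored with sensitivity,
specificity and accuracy:

    recall = TP/(TP+FN)            precision   = TP/(TP+FP)
    F      = 2PR/(P+R)             specificity = TN/(TN+FP)
    accuracy = (TP+TN)/(TP+FN+FP+TN)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .corpus_io import Corpus, MentionSpan

logger = logging.getLogger(__name__)


@dataclass
class DetectionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None  # undefined for mention-level evaluation

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    """Percentages in [0,100]; None where the denominator is zero."""

    precision: float | None = None
    recall: float | None = None
    f_score: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None

    def rendered(self) -> dict[str, str | None]:
        """Two-decimal half-up rendering, as in the challenge tables."""
        return {k: render_pct(v) for k, v in self.__dict__.items()}


def render_pct(value: float | None) -> str | None:
    if value is None:
        return None
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (both on the % scale)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def accuracy_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> float:
    """Accuracy implied by sensitivity/specificity at given class sizes.

    All rates on the % scale: TP = sens·P/100, TN = spec·N/100,
    accuracy = (TP+TN)/(P+N)·100.
    """
    tp = sensitivity / 100.0 * n_pos
    tn = specificity / 100.0 * n_neg
    return (tp + tn) / (n_pos + n_neg) * 100.0


def metrics_from_counts(counts: DetectionCounts) -> MetricsReport:
    """Challenge metrics from confusion counts; absent where undefined."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    report = MetricsReport()
    if tp + fp > 0:
        report.precision = 100.0 * tp / (tp + fp)
    if tp + fn > 0:
        report.recall = 100.0 * tp / (tp + fn)
        report.sensitivity = report.recall
    if report.precision is not None and report.recall is not None:
        report.f_score = f_score(report.precision, report.recall)
    if tn is not None:
        if tn + fp > 0:
            report.specificity = 100.0 * tn / (tn + fp)
        denom = tp + fn + fp + tn
        if denom > 0:
            report.accuracy = 100.0 * (tp + tn) / denom
    return report


def dedupe(spans: Sequence[MentionSpan]) -> list[MentionSpan]:
    """Collapse spans with identical keys, keeping the larger confidence."""
    best: dict[tuple[str, str, int, int], MentionSpan] = {}
    for s in spans:
        cur = best.get(s.key)
        if cur is None or s.confidence > cur.confidence:
            best[s.key] = s
    if len(best) < len(spans):
        logger.debug("collapsed %d duplicate spans", len(spans) - len(best))
    return sorted(best.values())


def ensemble_union(
    dict_spans: Sequence[MentionSpan], crf_spans: Sequence[MentionSpan]
) -> list[MentionSpan]:
    """Union of both systems' spans; identical spans merge at max confidence."""
    merged = dedupe(list(dict_spans) + list(crf_spans))
    return [
        MentionSpan(
            s.doc_id, s.passage, s.start, s.end, s.surface,
            source="ensemble", confidence=s.confidence,
        )
        for s in merged
    ]


def classify_passage(spans_in_passage: Sequence[MentionSpan]) -> str:
    """A passage is chemical-related iff it contains at least one mention."""
    return "chemical" if len(spans_in_passage) > 0 else "non-chemical"


def passage_labels(
    spans: Sequence[MentionSpan], corpus: Corpus
) -> dict[tuple[str, str], str]:
    """Chemical/non-chemical label for every (doc, passage) of the corpus."""
    tagged: set[tuple[str, str]] = {(s.doc_id, s.passage) for s in spans}
    return {
        (rec.doc_id, passage):
            "chemical" if (rec.doc_id, passage) in tagged else "non-chemical"
        for rec in corpus.records
        for passage in ("T", "A")
    }


def evaluate_mentions(
    pred_spans: Sequence[MentionSpan], gold_spans: Sequence[MentionSpan]
) -> tuple[DetectionCounts, MetricsReport]:
    """Micro-averaged exact-match mention evaluation."""
    pred = dedupe(pred_spans)
    gold_keys = {s.key for s in gold_spans}
    if len(gold_keys) < len(gold_spans):
        raise ValueError("gold spans contain duplicates")
    tp = sum(1 for s in pred if s.key in gold_keys)
    counts = DetectionCounts(tp=tp, fp=len(pred) - tp, fn=len(gold_keys) - tp)
    return counts, metrics_from_counts(counts)


def evaluate_cpd(
    pred_labels: Mapping[tuple[str, str], str],
    gold_labels: Mapping[tuple[str, str], str],
) -> tuple[DetectionCounts, MetricsReport]:
    """Passage-classification evaluation against gold chemical labels."""
    missing = set(gold_labels) ^ set(pred_labels)
    if missing:
        raise ValueError(
            f"prediction/gold passage keys differ; e.g. {sorted(missing)[:5]}"
        )
    tp = fp = fn = tn = 0
    for key, gold in gold_labels.items():
        pred = pred_labels[key]
        if gold == "chemical":
            if pred == "chemical":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "chemical":
                fp += 1
            else:
                tn += 1
    counts = DetectionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    return counts, metrics_from_counts(counts)


def gold_passage_labels(corpus: Corpus) -> dict[tuple[str, str], str]:
    """Gold label: chemical iff the passage holds at least one gold mention."""
    return passage_labels(corpus.gold, corpus)
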