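"""Corpus-driven term exclusion and inclusion for the dictionary tagger.

On a tuning corpus with gold annotations, every dictionary detection is
scored as a true positive (exact offset match with a gold span) or a false
positive.  Counts aggregate per lexicon lookup key (casefolded unless the
term is an abbreviation).  A term's exclusion ratio is TP/FP, taken as
+infinity when it never fired falsely.

* Exclusion: terms with at least one false positive and ratio < 0.3 are
  removed from the dictionary.
* Inclusion: gold surfaces the tagger missed entirely are trial-indexed and
  the corpus re-tagged; a candidate is admitted when its re-tag produces no
  false positives or a ratio > 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_io import Corpus, MentionSpan
from .dict_tagger import match, tokenize
from .lexicon import Lexicon, is_abbreviation


@dataclass
class TermStats:
    """Per-term true/false-positive counts on a tuning corpus."""

    term: str
    tp_count: int = 0
    fp_count: int = 0

    @property
    def ratio(self) -> float:
        if self.fp_count == 0:
            return math.inf
        return self.tp_count / self.fp_count


@dataclass
class TuningConfig:
    exclusion_threshold: float = 0.3
    inclusion_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.exclusion_threshold <= 0 or self.inclusion_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _stats_key(surface: str, lexicon: Lexicon | None) -> str:
    """Aggregation key: the lexicon's stored key when known, else the
    partial case-sensitivity rule applied directly."""
    if lexicon is not None:
        key = lexicon.lookup_key(" ".join(surface.split()))
        if key is not None:
            return key
    normalized = " ".join(surface.split())
    return normalized if is_abbreviation(normalized) else normalized.casefold()


def collect_term_stats(
    predictions: Sequence[MentionSpan],
    gold: Sequence[MentionSpan],
    corpus: Corpus,
    lexicon: Lexicon | None = None,
) -> dict[str, TermStats]:
    """Score each predicted span against gold and aggregate counts per term."""
    doc_ids = {r.doc_id for r in corpus.records}
    gold_keys = {s.key for s in gold}
    stats: dict[str, TermStats] = {}
    for span in predictions:
        if span.doc_id not in doc_ids:
            raise ValueError(f"prediction references unknown doc {span.doc_id!r}")
        key = _stats_key(span.surface, lexicon)
        entry = stats.setdefault(key, TermStats(term=key))
        if span.key in gold_keys:
            entry.tp_count += 1
        else:
            entry.fp_count += 1
    return stats


def derive_exclusions(
    stats: Mapping[str, TermStats], config: TuningConfig | None = None
) -> set[str]:
    """Terms that fired falsely and whose TP/FP ratio is below threshold."""
    config = config or TuningConfig()
    return {
        term
        for term, st in stats.items()
        if st.fp_count > 0 and st.ratio < config.exclusion_threshold
    }


def apply_exclusions(lexicon: Lexicon, excluded: Iterable[str]) -> int:
    """Remove excluded terms from the lexicon in place; returns removals."""
    return sum(1 for term in excluded if lexicon.remove_term(term))


def _missed_surfaces(
    gold: Sequence[MentionSpan], predictions: Sequence[MentionSpan]
) -> set[str]:
    """Gold surfaces with no overlapping prediction in the same passage."""
    by_passage: dict[tuple[str, str], list[MentionSpan]] = {}
    for span in predictions:
        by_passage.setdefault((span.doc_id, span.passage), []).append(span)
    missed: set[str] = set()
    for g in gold:
        overlapping = any(
            p.start < g.end and g.start < p.end
            for p in by_passage.get((g.doc_id, g.passage), [])
        )
        if not overlapping:
            missed.add(" ".join(g.surface.split()))
    return missed


def derive_inclusions(
    gold: Sequence[MentionSpan],
    predictions: Sequence[MentionSpan],
    corpus: Corpus,
    lexicon: Lexicon,
    config: TuningConfig | None = None,
) -> set[str]:
    """Missed gold surfaces that survive re-indexing on the tuning corpus.

    Each candidate is added to a scratch copy of the lexicon alone, the
    corpus is re-tagged, and the candidate's own TP/FP counts decide
    admission: kept iff it produced no false positives or its ratio exceeds
    the inclusion threshold.
    """
    config = config or TuningConfig()
    candidates = sorted(_missed_surfaces(gold, predictions))
    gold_keys = {s.key for s in gold}
    # tokenize once; each candidate only changes the lexicon, not the text
    passages = [
        (rec.doc_id, passage, text, tokenize(text))
        for rec in corpus.records
        for passage, text in (("T", rec.title), ("A", rec.abstract))
    ]
    admitted: set[str] = set()
    for surface in candidates:
        trial = Lexicon(
            exact_entries=dict(lexicon.exact_entries),
            folded_entries=dict(lexicon.folded_entries),
        )
        trial.add_term(surface, {"~candidate~"})
        key = trial.lookup_key(surface)
        tp = fp = 0
        for doc_id, passage, text, tokens in passages:
            for span in match(tokens, text, trial, doc_id=doc_id, passage=passage):
                if trial.lookup_key(" ".join(span.surface.split())) != key:
                    continue
                if span.key in gold_keys:
                    tp += 1
                else:
                    fp += 1
        if fp == 0 or tp / fp > config.inclusion_threshold:
            admitted.add(surface)
    return admitted


def apply_inclusions(lexicon: Lexicon, included: Iterable[str]) -> int:
    """Add admitted surfaces to the lexicon as structure-less terms."""
    n = 0
    for term in included:
        lexicon.add_term(term, {"~included~"})
        n += 1
    return n
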