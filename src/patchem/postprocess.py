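"""Post-processing of statistical tagger output within one passage.

Four rules, applied in order:

1. tagging consistency — a surface tagged at least twice gains spans at all
   its other token-aligned, case-sensitive occurrences in the passage;
2. abbreviation resolution — ``long form (SF)`` definitions are detected by
   rightward letter alignment of the short form into the long form; if
   either side carries a tag, the other side and all later short-form
   occurrences are tagged too;
3. boundary revision — spans with unbalanced brackets are extended by one
   character when that balances them, otherwise the unbalanced edge bracket
   is trimmed;
4. identifier tagging — database-identifier regexes (CAS registry numbers by
   default) fire as additional spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Pattern, Sequence

from .corpus_io import Corpus, MentionSpan

logger = logging.getLogger(__name__)

_BRACKETS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}

CAS_NUMBER = re.compile(r"\b[1-9]\d{1,6}-\d{2}-\d\b")


@dataclass
class PostprocessConfig:
    consistency_min_count: int = 2
    identifier_patterns: dict[str, Pattern[str]] = field(
        default_factory=lambda: {"cas": CAS_NUMBER}
    )
    validate_cas_checksum: bool = False
    steps: tuple[str, ...] = (
        "consistency", "abbreviations", "boundaries", "identifiers"
    )

    def __post_init__(self) -> None:
        if self.consistency_min_count < 2:
            raise ValueError("consistency_min_count must be ≥ 2")


def _token_aligned(text: str, start: int, end: int) -> bool:
    """True when [start,end) does not cut into an adjacent word."""
    before_ok = start == 0 or not (text[start - 1].isalnum() and text[start].isalnum())
    after_ok = end == len(text) or not (text[end - 1].isalnum() and text[end].isalnum())
    return before_ok and after_ok


def enforce_consistency(
    spans: Sequence[MentionSpan],
    passage_text: str,
    config: PostprocessConfig | None = None,
) -> list[MentionSpan]:
    """Propagate surfaces tagged ≥ min_count times to untagged occurrences."""
    config = config or PostprocessConfig()
    existing = {(s.start, s.end) for s in spans}
    by_surface: dict[str, list[MentionSpan]] = {}
    for s in spans:
        by_surface.setdefault(s.surface, []).append(s)
    out = list(spans)
    for surface, members in sorted(by_surface.items()):
        if len(members) < config.consistency_min_count or not surface:
            continue
        mean_conf = sum(m.confidence for m in members) / len(members)
        proto = members[0]
        for m in re.finditer(re.escape(surface), passage_text):
            start, end = m.start(), m.end()
            if (start, end) in existing:
                continue
            if not _token_aligned(passage_text, start, end):
                continue
            out.append(
                MentionSpan(
                    proto.doc_id, proto.passage, start, end, surface,
                    source=proto.source, confidence=mean_conf,
                )
            )
            existing.add((start, end))
    return sorted(out)


# -- abbreviation resolution -------------------------------------------------

def _align_short_form(short: str, long_candidate: str) -> int | None:
    """Classic rightward alignment of a short form into preceding text.

    Returns the start index of the long form inside ``long_candidate``
    (which ends where the definition's '(' begins), or None if no alignment
    exists.  Each short-form character must match, scanning right to left;
    the first character must match the start of a word.
    """
    s_idx = len(short) - 1
    l_idx = len(long_candidate) - 1
    while s_idx >= 0:
        ch = short[s_idx].lower()
        if not ch.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (
            long_candidate[l_idx].lower() != ch
            or (s_idx == 0 and l_idx > 0 and long_candidate[l_idx - 1].isalnum())
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        s_idx -= 1
        l_idx -= 1
    return l_idx + 1


def find_abbreviation_definitions(text: str) -> list[tuple[int, int, int, int]]:
    """Detect ``long form (SF)`` patterns.

    Returns (long_start, long_end, short_start, short_end) per definition.
    Short forms are at most 10 non-space characters, contain a letter, and
    are shorter than their long form.
    """
    defs: list[tuple[int, int, int, int]] = []
    for m in re.finditer(r"\(([^()]{1,10})\)", text):
        short = m.group(1).strip()
        if not short or not any(c.isalpha() for c in short) or " " in short:
            continue
        window_start = max(0, m.start() - 60)
        candidate = text[window_start : m.start()].rstrip()
        long_start_rel = _align_short_form(short, candidate)
        if long_start_rel is None:
            continue
        long_start = window_start + long_start_rel
        long_end = window_start + len(candidate)
        if long_end - long_start <= len(short):
            continue
        short_start = m.start() + 1 + m.group(1).index(short)
        defs.append((long_start, long_end, short_start, short_start + len(short)))
    return defs


def resolve_abbreviations(
    spans: Sequence[MentionSpan], passage_text: str
) -> list[MentionSpan]:
    """Tag both sides of a definition when either side is already tagged,
    plus all later occurrences of the short form."""
    if "(" not in passage_text:
        return list(spans)
    out = list(spans)
    existing = {(s.start, s.end) for s in spans}
    if not spans:
        return out
    proto = spans[0]

    def overlaps(a: int, b: int) -> MentionSpan | None:
        for s in out:
            if s.start < b and a < s.end:
                return s
        return None

    for long_start, long_end, short_start, short_end in find_abbreviation_definitions(
        passage_text
    ):
        long_hit = overlaps(long_start, long_end)
        short_hit = overlaps(short_start, short_end)
        if long_hit is None and short_hit is None:
            continue
        conf = (long_hit or short_hit).confidence
        additions = [(long_start, long_end), (short_start, short_end)]
        short = passage_text[short_start:short_end]
        for m in re.finditer(re.escape(short), passage_text[short_end:]):
            start = short_end + m.start()
            if _token_aligned(passage_text, start, start + len(short)):
                additions.append((start, start + len(short)))
        for start, end in additions:
            if (start, end) in existing:
                continue
            out.append(
                MentionSpan(
                    proto.doc_id, proto.passage, start, end,
                    passage_text[start:end], source=proto.source, confidence=conf,
                )
            )
            existing.add((start, end))
    return sorted(out)


# -- boundary revision --------------------------------------------------------

def _imbalance(s: str) -> dict[str, int]:
    """Net count per bracket pair: positive = unmatched openers."""
    net = {}
    for opener, closer in _BRACKETS.items():
        net[opener] = s.count(opener) - s.count(closer)
    return net


def _balanced(s: str) -> bool:
    return all(v == 0 for v in _imbalance(s).values())


def revise_boundaries(
    span: MentionSpan, passage_text: str, config: PostprocessConfig | None = None
) -> MentionSpan:
    """Balance brackets by extending one character, else trimming the edge."""
    surface = span.surface
    if _balanced(surface):
        return span
    start, end = span.start, span.end
    # try one-character extension on either side
    if end < len(passage_text) and _balanced(passage_text[start : end + 1]):
        end += 1
    elif start > 0 and _balanced(passage_text[start - 1 : end]):
        start -= 1
    else:
        # trim unbalanced bracket at an edge
        if surface and surface[-1] in _CLOSERS and not _balanced(surface):
            net = _imbalance(surface)
            if net[_CLOSERS[surface[-1]]] < 0:
                end -= 1
        surface2 = passage_text[start:end]
        if surface2 and surface2[0] in _BRACKETS and not _balanced(surface2):
            net = _imbalance(surface2)
            if net[surface2[0]] > 0:
                start += 1
    if start >= end or not _balanced(passage_text[start:end]):
        logger.debug("could not balance span %r; left unchanged", span.surface)
        return span
    return MentionSpan(
        span.doc_id, span.passage, start, end, passage_text[start:end],
        source=span.source, confidence=span.confidence,
    )


# -- identifier tagging -------------------------------------------------------

def _cas_checksum_ok(cas: str) -> bool:
    digits = cas.replace("-", "")
    body, check = digits[:-1], int(digits[-1])
    total = sum(int(d) * (i + 1) for i, d in enumerate(reversed(body)))
    return total % 10 == check


def tag_identifiers(
    passage_text: str,
    config: PostprocessConfig | None = None,
    doc_id: str = "",
    passage: str = "T",
) -> list[MentionSpan]:
    """Spans for database-identifier regex matches (CAS numbers by default)."""
    config = config or PostprocessConfig()
    spans: list[MentionSpan] = []
    for name, pattern in config.identifier_patterns.items():
        for m in pattern.finditer(passage_text):
            if (
                name == "cas"
                and config.validate_cas_checksum
                and not _cas_checksum_ok(m.group())
            ):
                continue
            spans.append(
                MentionSpan(
                    doc_id, passage, m.start(), m.end(), m.group(),
                    source="crf", confidence=1.0,
                )
            )
    return sorted(spans)


# -- pipeline -----------------------------------------------------------------

def postprocess_corpus(
    spans: Sequence[MentionSpan],
    corpus: Corpus,
    config: PostprocessConfig | None = None,
) -> list[MentionSpan]:
    """Run the configured post-processing steps passage by passage."""
    config = config or PostprocessConfig()
    by_passage: dict[tuple[str, str], list[MentionSpan]] = {}
    for s in spans:
        by_passage.setdefault((s.doc_id, s.passage), []).append(s)
    out: list[MentionSpan] = []
    for rec in corpus.records:
        for passage, text in (("T", rec.title), ("A", rec.abstract)):
            current = sorted(by_passage.get((rec.doc_id, passage), []))
            if "boundaries" in config.steps:
                revised = [revise_boundaries(s, text, config) for s in current]
                seen: set[tuple[int, int]] = set()
                current = []
                for s in sorted(revised):
                    if (s.start, s.end) not in seen:
                        seen.add((s.start, s.end))
                        current.append(s)
            if "consistency" in config.steps:
                current = enforce_consistency(current, text, config)
            if "abbreviations" in config.steps:
                current = resolve_abbreviations(current, text)
            if "identifiers" in config.steps:
                ids = tag_identifiers(text, config, rec.doc_id, passage)
                existing = {(s.start, s.end) for s in current}
                current.extend(
                    s for s in ids if (s.start, s.end) not in existing
                )
            out.extend(sorted(current))
    return out
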