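"""Dictionary-based mention tagging.

Passages are tokenized with a whitespace-first tokenizer that peels leading
and trailing punctuation off each whitespace chunk while keeping internal
hyphens, digits, commas and parentheses attached, so systematic names like
``1,2-dichloroethane`` or ``2-(chloroethyl)ether`` stay single tokens.

Matching is leftmost-longest and greedy over token windows: at each token the
longest window (up to ``max_len`` tokens) whose space-joined surface is in
the lexicon wins, and scanning resumes after its last token.  Lookup applies
the partial case-sensitivity rule of the lexicon (verbatim for
abbreviations, casefolded otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import Corpus, MentionSpan
from .lexicon import Lexicon

logger = logging.getLogger(__name__)

# Punctuation split off token edges.  Hyphens are deliberately absent: they
# bind chemical name fragments together.
_EDGE_PUNCT = set("()[]{}<>.,;:!?\"'`" + "‘’“”")


@dataclass(frozen=True)
class Token:
    """A token with its character interval in the passage."""

    surface: str
    start: int
    end: int


def _peel(chunk: str, start: int) -> list[Token]:
    """Split edge punctuation off one whitespace-delimited chunk."""
    tokens: list[Token] = []
    left = 0
    right = len(chunk)
    lead: list[Token] = []
    while left < right and chunk[left] in _EDGE_PUNCT:
        lead.append(Token(chunk[left], start + left, start + left + 1))
        left += 1
    trail: list[Token] = []
    while right > left and chunk[right - 1] in _EDGE_PUNCT:
        # a closing bracket whose opener lives inside the core stays attached,
        # resolved below once the core is known
        trail.append(Token(chunk[right - 1], start + right - 1, start + right))
        right -= 1
    core = chunk[left:right]
    # re-attach trailing closers balanced by an opener inside the core,
    # e.g. "(pure)" peels both, but "2-(chloroethyl)" keeps ")" attached
    while trail and trail[-1].surface in ")]}":
        closer = trail[-1].surface
        opener = {")": "(", "]": "[", "}": "{"}[closer]
        if core.count(opener) > core.count(closer):
            core = core + closer
            right += 1
            trail.pop()
        else:
            break
    tokens.extend(lead)
    if core:
        tokens.append(Token(core, start + left, start + right))
    tokens.extend(reversed(trail))
    return tokens


def tokenize(text: str) -> list[Token]:
    """Tokenize a passage; token surfaces always equal their text slice."""
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        tokens.extend(_peel(text[i:j], i))
        i = j
    return tokens


def match(
    tokens: Sequence[Token],
    text: str,
    lexicon: Lexicon,
    max_len: int = 8,
    doc_id: str = "",
    passage: str = "T",
) -> list[MentionSpan]:
    """Find lexicon terms in tokenized text by leftmost-longest matching.

    Candidate surfaces are token windows joined by single spaces, so lexicon
    terms with multiple internal spaces still match text with normal spacing.
    Emitted spans cover the original text from the first to the last token of
    the window and carry confidence 1.0.
    """
    spans: list[MentionSpan] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = 0
        for width in range(min(max_len, n - i), 0, -1):
            window = tokens[i : i + width]
            candidate = " ".join(t.surface for t in window)
            if lexicon.lookup(candidate):
                start, end = window[0].start, window[-1].end
                spans.append(
                    MentionSpan(
                        doc_id=doc_id,
                        passage=passage,
                        start=start,
                        end=end,
                        surface=text[start:end],
                        source="dict",
                        confidence=1.0,
                    )
                )
                matched = width
                break
        i += matched if matched else 1
    return spans


def tag_corpus(
    corpus: Corpus, lexicon: Lexicon, max_len: int = 8
) -> list[MentionSpan]:
    """Apply dictionary matching to every title and abstract of a corpus."""
    unreachable = [t for t in lexicon.terms() if len(t.split()) > max_len]
    if unreachable:
        logger.info(
            "%d lexicon terms exceed the %d-token window and cannot match",
            len(unreachable), max_len,
        )
    spans: list[MentionSpan] = []
    for rec in corpus.records:
        for passage, text in (("T", rec.title), ("A", rec.abstract)):
            spans.extend(
                match(
                    tokenize(text), text, lexicon,
                    max_len=max_len, doc_id=rec.doc_id, passage=passage,
                )
            )
    return spans
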