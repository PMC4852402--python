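"""Reading and writing patent corpora, gold annotations and predictions.

The on-disk dialect is plain UTF-8 tab-separated text:

* record file   — ``doc_id <TAB> title <TAB> abstract``
* annotation    — ``doc_id <TAB> T|A <TAB> start <TAB> end <TAB> surface[ <TAB> class]``
* prediction    — ``doc_id <TAB> T|A:start:end <TAB> rank <TAB> confidence``

Character offsets are 0-based, end-exclusive, counted in Unicode code points
within a single passage (title and abstract are offset independently).  Every
span read from disk is validated against the slice invariant
``surface == passage_text[start:end]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

PASSAGES = ("T", "A")
SOURCES = ("dict", "crf", "ensemble", "gold")


class CorpusError(ValueError):
    """Malformed corpus, annotation or prediction input."""


@dataclass(frozen=True)
class PatentRecord:
    """One patent record: identifier, title text and abstract text."""

    doc_id: str
    title: str
    abstract: str

    def passage_text(self, passage: str) -> str:
        if passage == "T":
            return self.title
        if passage == "A":
            return self.abstract
        raise CorpusError(f"unknown passage code {passage!r} (expected T or A)")


@dataclass(frozen=True, order=True)
class MentionSpan:
    """A chemical mention, predicted or gold, located by character offsets."""

    doc_id: str
    passage: str
    start: int
    end: int
    surface: str = field(compare=False)
    source: str = field(default="dict", compare=False)
    confidence: float = field(default=1.0, compare=False)
    mention_class: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.passage not in PASSAGES:
            raise CorpusError(f"passage must be T or A, got {self.passage!r}")
        if self.source not in SOURCES:
            raise CorpusError(f"unknown span source {self.source!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid offsets [{self.start},{self.end}) for {self.doc_id}"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise CorpusError(f"confidence {self.confidence} outside [0,1]")

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Identity used for exact-match evaluation and deduplication."""
        return (self.doc_id, self.passage, self.start, self.end)


@dataclass
class Corpus:
    """An ordered collection of records plus optional gold annotations."""

    records: list[PatentRecord]
    gold: list[MentionSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if not rec.doc_id:
                raise CorpusError("empty doc_id")
            if rec.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {rec.doc_id!r}")
            seen.add(rec.doc_id)
        for span in self.gold:
            if span.doc_id not in seen:
                raise CorpusError(f"gold span references unknown doc {span.doc_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def record(self, doc_id: str) -> PatentRecord:
        try:
            return self._index[doc_id]
        except AttributeError:
            self._index = {r.doc_id: r for r in self.records}
            return self._index[doc_id]

    def passage_text(self, doc_id: str, passage: str) -> str:
        return self.record(doc_id).passage_text(passage)


def validate_span(span: MentionSpan, corpus: Corpus, where: str = "") -> None:
    """Check the slice invariant of one span against its passage text."""
    text = corpus.passage_text(span.doc_id, span.passage)
    if span.end > len(text):
        raise CorpusError(
            f"{where}offset {span.end} beyond passage length {len(text)} "
            f"({span.doc_id}/{span.passage})"
        )
    actual = text[span.start : span.end]
    if actual != span.surface:
        raise CorpusError(
            f"{where}surface mismatch in {span.doc_id}/{span.passage} "
            f"[{span.start},{span.end}): file says {span.surface!r}, "
            f"text says {actual!r}"
        )


def _split_line(line: str, n_min: int, lineno: int, path: Path) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise CorpusError(
            f"{path}:{lineno}: expected at least {n_min} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def read_records(path: str | Path) -> Corpus:
    """Read a tab-separated record file into a Corpus (records only)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[PatentRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            doc_id, title, abstract, *_ = _split_line(line, 3, lineno, path)
            records.append(PatentRecord(doc_id, title, abstract))
    return Corpus(records=records)


def write_records(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus.records:
            for text in (rec.title, rec.abstract):
                if "\t" in text or "\n" in text:
                    raise CorpusError(
                        f"record {rec.doc_id!r} contains a TAB or newline; "
                        "the tab-separated dialect cannot represent it"
                    )
            fh.write(f"{rec.doc_id}\t{rec.title}\t{rec.abstract}\n")


def read_annotations(path: str | Path, corpus: Corpus) -> list[MentionSpan]:
    """Read gold mention annotations and validate them against the corpus.

    An optional sixth column (mention class) is preserved on the span but
    plays no role in evaluation.
    """
    path = Path(path)
    spans: list[MentionSpan] = []
    seen: set[tuple[str, str, int, int]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, 5, lineno, path)
            doc_id, passage, start_s, end_s, surface = fields[:5]
            mention_class = fields[5] if len(fields) > 5 else None
            try:
                span = MentionSpan(
                    doc_id, passage, int(start_s), int(end_s), surface,
                    source="gold", mention_class=mention_class,
                )
            except (ValueError, CorpusError) as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            validate_span(span, corpus, where=f"{path}:{lineno}: ")
            if span.key in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate gold span {span.key}")
            seen.add(span.key)
            spans.append(span)
    return spans


def write_annotations(spans: Iterable[MentionSpan], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for span in sorted(spans):
            extra = f"\t{span.mention_class}" if span.mention_class else ""
            fh.write(
                f"{span.doc_id}\t{span.passage}\t{span.start}\t{span.end}"
                f"\t{span.surface}{extra}\n"
            )


def rank_spans(spans: Sequence[MentionSpan]) -> list[tuple[MentionSpan, int]]:
    """Assign per-document ranks 1..n in descending confidence.

    Ties break on (passage, start, end) so output order is deterministic.
    """
    by_doc: dict[str, list[MentionSpan]] = {}
    for span in spans:
        by_doc.setdefault(span.doc_id, []).append(span)
    ranked: list[tuple[MentionSpan, int]] = []
    for doc_id in sorted(by_doc):
        ordered = sorted(
            by_doc[doc_id],
            key=lambda s: (-s.confidence, s.passage, s.start, s.end),
        )
        for rank, span in enumerate(ordered, start=1):
            ranked.append((span, rank))
    return ranked


def write_predictions(
    spans: Sequence[MentionSpan], path: str | Path, corpus: Corpus | None = None
) -> None:
    """Write prediction spans in the submission format.

    If a corpus is supplied every span is re-validated before writing; spans
    that fail the slice invariant are refused.
    """
    if corpus is not None:
        for span in spans:
            validate_span(span, corpus)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for span, rank in rank_spans(spans):
            fh.write(
                f"{span.doc_id}\t{span.passage}:{span.start}:{span.end}"
                f"\t{rank}\t{span.confidence:g}\n"
            )


def read_predictions(path: str | Path, corpus: Corpus) -> list[MentionSpan]:
    """Read a prediction file back into spans (surfaces recovered from text)."""
    path = Path(path)
    spans: list[MentionSpan] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            doc_id, loc, _rank, conf = _split_line(line, 4, lineno, path)
            try:
                passage, start_s, end_s = loc.split(":")
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: bad location {loc!r}") from exc
            text = corpus.passage_text(doc_id, passage)
            span = MentionSpan(
                doc_id, passage, start, end, text[start:end],
                source="ensemble", confidence=float(conf),
            )
            validate_span(span, corpus, where=f"{path}:{lineno}: ")
            spans.append(span)
    return spans
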