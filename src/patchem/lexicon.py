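"""Chemical term dictionaries keyed by compound identity.

A lexicon maps surface terms to compound identifiers.  Compounds coming from
different source dictionaries are considered identical when their InChI
strings are byte-identical, in which case their identifier sets and terms are
merged.  Matching is partially case-sensitive: terms whose characters are in
the majority capitals and digits are treated as abbreviations and matched
case-sensitively; all other terms are matched case-insensitively (full
Unicode case folding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


@dataclass
class CompoundEntry:
    """Terms attached to one compound, identified by its InChI string."""

    compound_id: str
    inchi: str
    terms: set[str]
    source_db: str = ""

    def __post_init__(self) -> None:
        self.terms = {t.strip() for t in self.terms if t.strip()}
        if not self.terms:
            raise ValueError(f"compound {self.compound_id!r} has no terms")


@dataclass
class Stoplist:
    """Terms never emitted as mentions; matched case-insensitively, whole-term."""

    terms: set[str]

    def __post_init__(self) -> None:
        self.terms = {t.strip().casefold() for t in self.terms if t.strip()}

    def __contains__(self, term: str) -> bool:
        return term.strip().casefold() in self.terms


# The three words the challenge guidelines single out, plus common function
# words that frequently collide with dictionary synonyms.
DEFAULT_STOPLIST = Stoplist(
    {
        "about", "all", "make",
        "a", "an", "and", "as", "at", "be", "by", "for", "from", "in", "is",
        "it", "of", "on", "or", "the", "to", "was", "were", "with",
        "same", "new", "one", "can", "may", "more", "most", "each",
    }
)


def is_abbreviation(term: str) -> bool:
    """True when capitals and digits form a strict majority of the term.

    Whitespace is ignored in the count; the majority is strict (``>`` half),
    so a 50/50 split such as ``"Ab"`` is not an abbreviation.
    """
    if not term or not term.strip():
        raise ValueError("empty term")
    chars = [c for c in term if not c.isspace()]
    upper_digit = sum(1 for c in chars if ("A" <= c <= "Z") or ("0" <= c <= "9"))
    return upper_digit * 2 > len(chars)


@dataclass
class Lexicon:
    """Term → compound-id index with the partial case-sensitivity split.

    ``exact_entries`` holds abbreviations keyed verbatim; ``folded_entries``
    holds everything else keyed by their Unicode casefold.  No term lives in
    both maps.
    """

    exact_entries: dict[str, set[str]] = field(default_factory=dict)
    folded_entries: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def lookup(self, surface: str) -> set[str]:
        """Compound ids for a candidate surface, or an empty set."""
        hit = self.exact_entries.get(surface)
        if hit:
            return hit
        return self.folded_entries.get(surface.casefold(), set())

    def lookup_key(self, surface: str) -> str | None:
        """The stored key a surface resolves to (used by corpus tuning)."""
        if surface in self.exact_entries:
            return surface
        folded = surface.casefold()
        if folded in self.folded_entries:
            return folded
        return None

    def __contains__(self, surface: str) -> bool:
        return bool(self.lookup(surface))

    def __len__(self) -> int:
        return len(self.exact_entries) + len(self.folded_entries)

    def terms(self) -> set[str]:
        return set(self.exact_entries) | set(self.folded_entries)

    def max_term_tokens(self) -> int:
        longest = 0
        for term in self.terms():
            longest = max(longest, len(term.split()))
        return longest

    def add_term(self, term: str, compound_ids: set[str], source: str = "") -> None:
        term = " ".join(term.split())
        if not term:
            return
        if is_abbreviation(term):
            self.exact_entries.setdefault(term, set()).update(compound_ids)
            key = term
        else:
            key = term.casefold()
            self.folded_entries.setdefault(key, set()).update(compound_ids)
        if source:
            self.provenance.setdefault(key, set()).add(source)

    def remove_term(self, term: str) -> bool:
        """Remove a term in whichever map holds it; True if something left."""
        if term in self.exact_entries:
            del self.exact_entries[term]
            return True
        folded = term.casefold()
        if folded in self.folded_entries:
            del self.folded_entries[folded]
            return True
        return False


def build_lexicon(
    entries: Iterable[CompoundEntry], stoplist: Stoplist | None = None
) -> Lexicon:
    """Index compound entries into a lexicon, dropping stoplisted terms.

    Stoplist removal is whole-term and case-insensitive: ``lead`` is dropped
    while ``lead acetate`` survives.
    """
    stoplist = DEFAULT_STOPLIST if stoplist is None else stoplist
    lex = Lexicon()
    for entry in entries:
        for term in sorted(entry.terms):
            if term in stoplist:
                continue
            lex.add_term(term, {entry.compound_id}, source=entry.source_db)
    return lex


def merge_lexicons(
    sources: Sequence[Iterable[CompoundEntry]],
) -> list[CompoundEntry]:
    """Merge dictionary sources, collapsing entries with identical InChI.

    The surviving compound id is the lexicographically smallest member id;
    terms and source labels are unioned.  Entries without an InChI carry no
    structure identity and are skipped with a warning.  The operation is
    idempotent and order-independent.
    """
    by_inchi: dict[str, CompoundEntry] = {}
    for source in sources:
        for entry in source:
            if not entry.inchi:
                logger.warning(
                    "skipping compound %r: no InChI string", entry.compound_id
                )
                continue
            existing = by_inchi.get(entry.inchi)
            if existing is None:
                by_inchi[entry.inchi] = CompoundEntry(
                    compound_id=entry.compound_id,
                    inchi=entry.inchi,
                    terms=set(entry.terms),
                    source_db=entry.source_db,
                )
            else:
                existing.compound_id = min(existing.compound_id, entry.compound_id)
                existing.terms |= entry.terms
                labels = {s for s in (existing.source_db, entry.source_db) if s}
                existing.source_db = "+".join(sorted(labels))
    return sorted(by_inchi.values(), key=lambda e: e.compound_id)


def read_lexicon_file(path: str | Path, source_db: str = "") -> list[CompoundEntry]:
    """Read ``compound_id <TAB> inchi <TAB> term1|term2|…`` lines."""
    path = Path(path)
    entries: list[CompoundEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            compound_id, inchi, terms = fields[0], fields[1], fields[2]
            entries.append(
                CompoundEntry(
                    compound_id=compound_id,
                    inchi=inchi,
                    terms=set(terms.split("|")),
                    source_db=source_db or path.stem,
                )
            )
    return entries


def write_lexicon_file(entries: Iterable[CompoundEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for entry in sorted(entries, key=lambda e: e.compound_id):
            terms = "|".join(sorted(entry.terms))
            fh.write(f"{entry.compound_id}\t{entry.inchi}\t{terms}\n")


def read_stoplist(path: str | Path) -> Stoplist:
    """Read a one-term-per-line stoplist; '#' starts a comment line."""
    path = Path(path)
    terms: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.add(line)
    return Stoplist(terms)


def write_stoplist(stoplist: Stoplist, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{t}\n" for t in sorted(stoplist.terms)), encoding="utf-8"
    )
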