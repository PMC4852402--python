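"""Deterministic synthetic lexicons and patent corpora with known gold spans.

The generator emulates the statistical structure that makes patent chemical
NER hard with a dictionary alone:

* pseudo-systematic names built from a morpheme grammar
  (prefix + ring + suffix, e.g. ``dichlorobenzol``), with synonyms and
  all-caps abbreviations per compound;
* ambiguous homographs — lexicon terms that are also ordinary English words
  (``lead``, ``crystal`` …) and occur in text both as chemicals (gold) and as
  plain words (not gold), so term-exclusion ratios have something to learn;
* unseen chemicals — morphologically chemical-looking words absent from the
  lexicon, implanted as gold mentions, so the dictionary misses them but a
  sequence tagger can generalize to them.

Everything is driven by one seed; the same config yields byte-identical
corpora.  Mention surfaces are whitespace-delimited and never contain tabs,
so gold offsets survive tokenization and the tab-separated file dialect.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import Corpus, MentionSpan, PatentRecord
from .lexicon import CompoundEntry, Lexicon

_PREFIXES = [
    "meth", "eth", "prop", "but", "pent", "hex", "chloro", "bromo", "fluoro",
    "iodo", "hydroxy", "amino", "nitro", "cyclo", "iso", "neo", "di", "tri",
    "tetra", "oxo", "thio", "acetyl", "carboxy", "sulfo", "phospho",
]
_RINGS = [
    "benz", "phen", "pyrid", "imidazol", "naphthal", "tolu", "furan",
    "thiazol", "quinol", "indol", "pyrrol", "oxazol", "pyrimid", "azepin",
]
_SUFFIXES = [
    "ol", "ane", "ene", "yl", "ate", "ide", "ine", "one", "amide", "oxide",
    "ic acid", "aldehyde", "amine", "ester",
]

# Fixed homograph pool: chemical synonyms that collide with everyday words.
_HOMOGRAPHS = [
    "lead", "gold", "crystal", "acid", "salt", "iron", "mercury", "base",
    "compound", "solution", "tablet", "agent", "oil", "spirit", "ether",
]

# Filler vocabulary for patent-flavoured prose; disjoint from everything the
# morpheme grammar can produce and from the homograph pool.
_FILLER = (
    "the present invention relates method treating patients using novel "
    "formulation wherein said composition comprises effective amount thereof "
    "preparation process described herein provides improved stability under "
    "ambient conditions further embodiments include dosage forms suitable "
    "administration topical oral preferred carrier optionally combined "
    "excipient mixture obtained yield purity measured analysis disclosed "
    "claims cover derivatives useful therapy disorders related symptoms"
).split()


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; the seed is mandatory."""

    seed: int
    n_compounds: int = 150
    synonyms_per_compound: int = 2
    abbreviation_fraction: float = 0.15
    n_records: int = 300
    mentions_per_passage: float = 2.0
    ambiguous_homograph_fraction: float = 0.1
    unseen_chemical_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "abbreviation_fraction",
            "ambiguous_homograph_fraction",
            "unseen_chemical_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")


def _systematic_name(rng: random.Random, used: set[str]) -> str:
    """One pseudo-systematic name, unique within this generator run."""
    for _ in range(1000):
        parts = rng.sample(_PREFIXES, rng.randint(1, 3))
        name = "".join(parts) + rng.choice(_RINGS) + rng.choice(_SUFFIXES)
        if rng.random() < 0.25:
            locant = ",".join(str(rng.randint(1, 6)) for _ in range(rng.randint(1, 2)))
            name = f"{locant}-{name}"
        if name not in used:
            used.add(name)
            return name
    raise RuntimeError("morpheme grammar exhausted")


def _abbreviation(rng: random.Random, used: set[str]) -> str:
    for _ in range(1000):
        abbr = "".join(rng.choice("ABCDEFGHKLMNPQRSTUVWXYZ") for _ in range(3))
        abbr += str(rng.randint(1, 99)) if rng.random() < 0.5 else ""
        if abbr not in used:
            used.add(abbr)
            return abbr
    raise RuntimeError("abbreviation space exhausted")


def make_compounds(
    config: SimulationConfig, overlap_fraction: float = 0.3
) -> tuple[list[CompoundEntry], list[CompoundEntry]]:
    """Two overlapping dictionary sources sharing InChI identity.

    ``overlap_fraction`` of compounds appears in both sources under the same
    synthetic InChI string (possibly with different local ids), exercising
    structure-identity merging.
    """
    rng = random.Random(config.seed)
    used: set[str] = set()
    homographs = list(_HOMOGRAPHS)
    rng.shuffle(homographs)
    n_homograph = round(config.ambiguous_homograph_fraction * config.n_compounds)
    n_homograph = min(n_homograph, len(homographs))

    source_a: list[CompoundEntry] = []
    source_b: list[CompoundEntry] = []
    for i in range(config.n_compounds):
        terms = {_systematic_name(rng, used)}
        for _ in range(config.synonyms_per_compound - 1):
            terms.add(_systematic_name(rng, used))
        if rng.random() < config.abbreviation_fraction:
            terms.add(_abbreviation(rng, used))
        if i < n_homograph:
            terms.add(homographs[i])
        inchi = f"InChI=1S/SYN{i:05d}/c{rng.randint(1, 9)}-{rng.randint(1, 9)}"
        in_both = rng.random() < overlap_fraction
        entry_a = CompoundEntry(f"A{i:05d}", inchi, set(terms), source_db="srcA")
        if in_both:
            source_a.append(entry_a)
            source_b.append(
                CompoundEntry(f"B{i:05d}", inchi, set(terms), source_db="srcB")
            )
        elif rng.random() < 0.5:
            source_a.append(entry_a)
        else:
            source_b.append(
                CompoundEntry(f"B{i:05d}", inchi, set(terms), source_db="srcB")
            )
    return source_a, source_b


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth sampler; means here are small."""
    import math

    limit = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


@dataclass
class _MentionPool:
    """Bookkeeping of what the generator may implant."""

    lexicon_terms: list[str]
    homograph_terms: list[str]
    unseen_terms: list[str]
    implant_counts: dict[str, int] = field(default_factory=dict)


def _build_pool(
    lexicon: Lexicon, config: SimulationConfig, rng: random.Random
) -> _MentionPool:
    homographs = sorted(t for t in lexicon.terms() if t in set(_HOMOGRAPHS))
    plain = sorted(t for t in lexicon.terms() if t not in set(_HOMOGRAPHS))
    used = set(lexicon.terms())
    n_unseen = max(20, config.n_compounds // 2)
    unseen = [_systematic_name(rng, used) for _ in range(n_unseen)]
    return _MentionPool(plain, homographs, unseen)


def _compose_passage(
    pool: _MentionPool, config: SimulationConfig, rng: random.Random
) -> tuple[str, list[tuple[int, int, str]]]:
    """One passage: text plus (start, end, surface) gold triples."""
    n_mentions = _poisson(rng, config.mentions_per_passage)
    words: list[tuple[str, bool]] = []  # (word, is_gold_mention)
    n_filler = rng.randint(6, 14) + 2 * n_mentions
    for _ in range(n_filler):
        words.append((rng.choice(_FILLER), False))
    # non-gold homograph usage (ordinary-word sense)
    if pool.homograph_terms and rng.random() < 4 * config.ambiguous_homograph_fraction:
        words.append((rng.choice(pool.homograph_terms), False))
    # implant gold mentions at random slots, each separated by ≥1 filler word
    slots = sorted(rng.sample(range(len(words) + 1), min(n_mentions, len(words) + 1)),
                   reverse=True)
    for slot in slots:
        u = rng.random()
        if u < config.unseen_chemical_fraction:
            term = rng.choice(pool.unseen_terms)
        elif pool.homograph_terms and u < config.unseen_chemical_fraction + \
                config.ambiguous_homograph_fraction:
            term = rng.choice(pool.homograph_terms)
        else:
            term = rng.choice(pool.lexicon_terms)
        words.insert(slot, (term, True))
        pool.implant_counts[term] = pool.implant_counts.get(term, 0) + 1
    # render with offsets
    parts: list[str] = []
    gold: list[tuple[int, int, str]] = []
    pos = 0
    for idx, (word, is_gold) in enumerate(words):
        if idx:
            parts.append(" ")
            pos += 1
        if is_gold:
            gold.append((pos, pos + len(word), word))
        parts.append(word)
        pos += len(word)
    parts.append(".")
    return "".join(parts), gold


def make_corpus(
    lexicon: Lexicon, config: SimulationConfig
) -> tuple[Corpus, _MentionPool]:
    """Generate a patent-like corpus with recorded gold mentions.

    Returns the corpus (gold attached) and the mention pool, whose
    ``implant_counts`` and term lists let tests reason about composition
    (e.g. expected dictionary recall = share of implants drawn from the
    lexicon).
    """
    if not lexicon.terms():
        raise ValueError("lexicon is empty")
    rng = random.Random(config.seed + 1)
    pool = _build_pool(lexicon, config, rng)
    records: list[PatentRecord] = []
    gold: list[MentionSpan] = []
    for r in range(config.n_records):
        doc_id = f"SYN{r:05d}"
        title, title_gold = _compose_passage(pool, config, rng)
        abstract, abs_gold = _compose_passage(pool, config, rng)
        records.append(PatentRecord(doc_id, title, abstract))
        for passage, triples in (("T", title_gold), ("A", abs_gold)):
            for start, end, surface in triples:
                gold.append(
                    MentionSpan(doc_id, passage, start, end, surface, source="gold")
                )
    return Corpus(records=records, gold=gold), pool


def default_stoplist_file(path: str | Path) -> None:
    """Write the shipped default stoplist next to generated fixtures."""
    from .lexicon import DEFAULT_STOPLIST, write_stoplist

    write_stoplist(DEFAULT_STOPLIST, path)
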