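# Methods

This note documents the models and procedures implemented in `patchem`, the
defaults chosen where the design was open, and what the synthetic evaluation
does and does not demonstrate.

## Task and data model

The system detects chemical entity mentions in patent records, each a title
(`T`) and an abstract (`A`). Offsets are 0-based, end-exclusive, counted in
Unicode code points within a single passage; every span must satisfy
`surface == passage_text[start:end]`, and all I/O validates this invariant.
The on-disk formats are plain UTF-8 TSV (records, annotations, predictions);
embedded tabs are rejected rather than escaped, keeping the dialect trivially
parseable and byte-stable. An optional sixth annotation column (a mention
class such as systematic/family) is carried through but ignored by
evaluation, which is class-blind.

Two evaluations are supported. Mention-level: micro-averaged exact-offset
matching, where a prediction is a true positive iff a gold span shares
(doc, passage, start, end), each gold span matches at most one prediction,
and TP/FP/FN pool over documents before computing precision, recall and F.
Passage-level: a passage is chemical-related iff it contains at least one
mention; predictions are scored with sensitivity, specificity and accuracy.
Metrics are kept at full precision internally and rendered at two decimals,
half-up, only for display.

## Dictionary tagger

**Compound identity.** Lexicon sources provide (compound id, InChI string,
terms). InChI strings are compared as opaque bytes — no chemistry-aware
normalization — and entries with identical InChI merge, unioning terms and
keeping the lexicographically smallest id. Entries lacking an InChI carry no
structure identity and are skipped with a warning. Merging is idempotent and
order-independent.

**Abbreviation rule.** A term is an abbreviation when its count of capitals
and digits strictly exceeds half of its non-whitespace characters. The strict
majority resolves the tie case (`Ab` with 1 of 2 is *not* an abbreviation);
counting over non-whitespace characters extends the rule naturally to
multi-word terms. Abbreviations are matched verbatim; all other terms are
matched under full Unicode case folding.

**Matching.** Passages are tokenized by whitespace, peeling leading/trailing
punctuation into separate tokens while keeping internal hyphens, digits,
commas and brackets attached (so `1,2-dichloroethane` and
`2-(chloroethyl)ether` stay single tokens); a trailing closer whose opener
lies inside the word is kept attached. Matching is leftmost-longest and
greedy over token windows of up to 8 tokens (longer terms are indexed but
unreachable, logged at build time), joining window tokens with single spaces;
after a match, scanning resumes after its last token, so emitted spans never
overlap. Hyphen/space interchange is deliberately off: it keeps matching
deterministic and auditable. Dictionary spans carry confidence 1.0.

**Stoplist.** Whole-term, case-insensitive. The shipped default contains the
classic problem words (*about*, *all*, *make*) plus common function words; it
is user-replaceable and removal never touches multi-word terms containing a
stoplisted word (*lead acetate* survives the removal of *lead*).

## Corpus tuning

Detections on an annotated tuning corpus are scored exact-match against gold
and aggregated per lexicon lookup key — the casefolded term for
non-abbreviations — so an exclusion removes every case variant at once. The
exclusion ratio is TP/FP, +∞ when FP = 0.

- **Exclusion** removes terms with at least one false positive and ratio
  below 0.3. Applying the derived exclusions and re-tagging the same corpus
  yields zero detections for every excluded term, and a second derivation
  pass removes nothing new (both properties are tested).
- **Inclusion** considers gold surfaces with *no overlapping* prediction
  (not merely no exact match — a boundary-mismatched hit should not nominate
  a near-duplicate term). Each candidate is added to a scratch copy of the
  lexicon, the corpus re-tagged (tokenization is cached; only the lexicon
  changes), and the candidate admitted iff its own re-tag counts show FP = 0
  or TP/FP > 0.5. Admitted terms are re-audited against their own admission
  condition in the tests.

The 0.3 and 0.5 thresholds are plain configuration values with those
defaults. When tuning for a held-out evaluation, stats must come from the
training material only; the CLI therefore takes the stats corpus and target
corpus as separate arguments.

## Statistical tagger

**Pre-processing** is 1:1 per character so offsets never shift: Greek
letters map to the first Latin letter of their name (α→a), typographic
dashes/quotes to ASCII, accented Latin letters to their NFKD base, anything
else to `?`; a vertical bar immediately enclosed by a bracket pair (`[|]`,
`(|)`, `{|}`) becomes a space. Mapping α to `a` rather than `alpha` trades
richer transliteration for coordinate safety — a deliberate deviation from
systems that expand Greek names and then need offset maps.

**Features** per token: lowercased surface, suffix-stripped stem, word shape
and collapsed shape, digit/upper/lower counts bucketed 0/1/2/3+, prefixes
and suffixes of lengths 1–4, a chemical-element gazetteer hit (symbols and
English names), a ring/functional-group morpheme hit (`benz`, `phen`, `yl`,
`ol`, `ane`, …), a rule-based POS tag, a rule-based lemma, and a word-vector
cluster id (`UNK` for unmapped words). All features are copied from
neighbors within a ±2 token window with positional prefixes, with `pad`
features past sequence edges. POS and lemma providers are pluggable; the
built-in suffix-heuristic providers require no model download and are what
the tests exercise.

**Word clusters.** Embeddings are the truncated SVD (default 50 dimensions)
of the positive-PMI word/context co-occurrence matrix (context = words
within ±2), followed by K-means with a fixed seed; the cluster id of the
lowercased word is the feature. The construction is deterministic given
(stream, dim, K, seed) and K must not exceed the vocabulary. K defaults to
1000 for realistic corpora; tests and the synthetic pipeline use smaller K
consistent with their vocabularies.

**CRF.** Labels are B/I/O over a single entity class (the evaluation is
class-blind, and BIO suffices when mentions never touch). Training maximizes
the exact conditional log-likelihood with an L2 penalty (default c2 = 0.1)
via L-BFGS; gradients use forward–backward in log space, with the emission
terms computed as one sparse feature-matrix product per evaluation. With
three labels the per-token recursions are 3-vectors, so exact training is
fast at the corpus sizes used here (a few hundred passages train in
seconds). Prediction is Viterbi; per-token posterior marginals come from
forward–backward, and a decoded span's confidence is the minimum marginal of
its member tokens. Initialization draws small Gaussian noise from the config
seed; predictions are deterministic given a trained model. Applying the
model to features whose namespace was never seen in training is an error
(schema mismatch), while unseen values of known namespaces are simply
ignored. BIO decoding repairs a bare `I` by treating it as `B`; encoding
snaps spans that cross token boundaries outward with a warning.

**Post-processing** operates within one passage (titles are short enough
that cross-passage propagation would mostly import abstract noise into
titles; the consistency rule therefore does not cross the title/abstract
boundary). Consistency matching is case-sensitive and token-aligned, and
added spans take the mean confidence of the existing ones; the rule is
idempotent. Abbreviation definitions are found by the standard short-form /
long-form rightward letter alignment (short form ≤ 10 characters, must
contain a letter, long form must be longer); the rule fires only when one
side is already tagged. Boundary revision first tries a one-character
extension that balances the brackets, then trims an unbalanced edge bracket;
output is balanced or the span is returned unchanged. Identifier tagging
ships a CAS registry number pattern (`\b[1-9]\d{1,6}-\d{2}-\d\b`) with an
optional, default-off checksum validation.

## Ensemble and passage classification

The ensemble is the plain union of dictionary and CRF spans: spans identical
on (doc, passage, start, end) merge keeping the larger confidence;
overlapping-but-different spans are both kept (a `--resolve longest` style
policy was considered and rejected as default because exact-offset
evaluation rewards keeping both candidates). Union recall is therefore never
below either member's recall — asserted as a property test. Passage labels
derive directly from span presence, title and abstract separately.

## Synthetic data generator

The generator emulates the statistical structure that drives the method's
behaviour on real patents, under one mandatory seed:

- pseudo-systematic names from a morpheme grammar (prefix⁺ + ring + suffix,
  with optional locants like `1,2-`), synonyms and all-caps abbreviations
  per compound — default 150 compounds, 2 synonyms each, 15% with an
  abbreviation;
- two overlapping lexicon sources sharing InChI identity (overlap 0.3) to
  exercise merging;
- patent-boilerplate filler text, disjoint from everything the grammar can
  produce, so matching is exact by construction when ambiguity is disabled;
- ambiguous homographs (10% of compounds by default) drawn from a fixed
  embedded word list (*lead*, *gold*, *crystal*, …) implanted both as gold
  chemicals and as ordinary words, giving the exclusion-ratio machinery
  real false positives;
- unseen chemicals (30% of implants by default): grammar-generated names
  withheld from the lexicon, implanted as gold, so the dictionary's recall
  is 1 − unseen fraction in expectation — a known-composition recovery that
  the tests check within three binomial standard errors at ≥2000 mentions;
- 300 records by default, mentions per passage Poisson with mean 2.

Mentions are whitespace-delimited, never cross sentence boundaries, never
contain tabs, and their offsets are recorded at generation time, so gold
always passes annotation validation.

What passing on this generator shows: the matching, tuning, learning,
post-processing and evaluation machinery are correct, and the CRF really
does generalize from morphology to unseen names. What it does not show:
performance on real patent prose — real chemical names have richer grammar
(true IUPAC nesting, OCR noise, tokenization-hostile punctuation), real
homograph disambiguation depends on context the filler text lacks, and real
lexicon coverage is far lower than the synthetic 70%. Corpus-level scores on
synthetic data are therefore much higher than anything achievable on real
patent corpora and are not comparable to published challenge results.

## Problem sizes and numerical choices

The shipped pipelines use corpora of 80–600 records (tests) and 120–600
records (acceptance script), CRF training on half-corpora with L-BFGS capped
at 60–100 iterations, which converges on these sizes. All randomness — the
generator, embedding SVD, K-means and CRF initialization — flows from
explicit seeds; repeated runs are byte-identical, which the suite asserts at
the file level. Degenerate inputs are handled explicitly: empty corpora tag
to empty predictions, all-zero confusion counts yield absent (not zero)
metrics, empty feature maps refuse training, and K above the vocabulary size
is an error.

## Known limitations

- The tokenizer is a stated approximation of the challenge systems'
  tokenizers, isolated behind `dict_tagger.tokenize` so it can be swapped.
- The CRF trains exactly and in memory; it targets corpora of thousands of
  passages, not millions (no feature hashing, no mini-batching).
- Transliteration is single-character; multi-character expansions (α →
  `alpha`) are out of scope by design.
- Building lexicons from real chemical databases (structure files,
  per-database field extraction) is out of scope; the package consumes
  pre-extracted (id, InChI, terms) tables.
- The mention class column is preserved but unused; per-class scoring is not
  implemented.
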