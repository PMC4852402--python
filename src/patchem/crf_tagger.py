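"""Statistical mention tagger: a linear-chain CRF over hand-built features.

Pipeline per passage: length-preserving pre-processing (ASCII
transliteration, vertical-bar sanitation) → tokenization → per-token feature
extraction (stems, affixes, character counts, word shape, chemical-element
and ring-morpheme gazetteers, POS, lemma, word-vector cluster id, all copied
across a ±window) → BIO labels → CRF training / Viterbi decoding with
forward-backward marginals.

Because pre-processing never changes string length, spans decoded from the
processed text are valid character intervals in the original passage.

The CRF is trained by L-BFGS on the exact conditional log-likelihood with an
L2 penalty; with only three labels (O/B/I) the forward-backward recursions
are tiny dense operations and the emission terms are one sparse matrix
product per objective evaluation.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .corpus_io import Corpus, MentionSpan
from .dict_tagger import Token, tokenize

logger = logging.getLogger(__name__)

LABELS = ("O", "B", "I")
_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


# ---------------------------------------------------------------------------
# Pre-processing (length-preserving)
# ---------------------------------------------------------------------------

_GREEK = {
    "α": "a", "β": "b", "γ": "g", "δ": "d", "ε": "e", "ζ": "z", "η": "e",
    "θ": "t", "ι": "i", "κ": "k", "λ": "l", "μ": "m", "ν": "n", "ξ": "x",
    "ο": "o", "π": "p", "ρ": "r", "σ": "s", "ς": "s", "τ": "t", "υ": "u",
    "φ": "p", "χ": "c", "ψ": "p", "ω": "o",
}
_TYPOGRAPHIC = {
    "–": "-", "—": "-", "−": "-", "‐": "-", "‑": "-",
    "‘": "'", "’": "'", "“": '"', "”": '"', "´": "'", "`": "'",
    "×": "x", "·": ".", "°": "o", "µ": "u",
    " ": " ", " ": " ", " ": " ",
}


def transliterate(text: str) -> tuple[str, list[int]]:
    """Map non-ASCII characters to single ASCII stand-ins, 1:1 per character.

    Greek letters become the first Latin letter of their name, typographic
    dashes/quotes their ASCII forms, accented Latin letters their base
    letter, anything else ``?``.  Length is preserved, so the returned offset
    map is the identity and spans found in the output are valid in the input.
    """
    out: list[str] = []
    for ch in text:
        if ord(ch) < 128:
            out.append(ch)
            continue
        low = ch.lower()
        if low in _GREEK:
            rep = _GREEK[low]
            out.append(rep.upper() if ch.isupper() else rep)
        elif ch in _TYPOGRAPHIC:
            out.append(_TYPOGRAPHIC[ch])
        else:
            decomposed = unicodedata.normalize("NFKD", ch)
            base = next((c for c in decomposed if ord(c) < 128), None)
            out.append(base if base else "?")
    result = "".join(out)
    assert len(result) == len(text)
    return result, list(range(len(text)))


_BAR_RE = re.compile(r"(?<=[(\[{])\|(?=[)\]}])")


def sanitize_bars(text: str) -> str:
    """Replace ``|`` immediately enclosed by bracket pairs with a space."""
    return _BAR_RE.sub(" ", text)


def preprocess(text: str) -> str:
    ascii_text, _ = transliterate(text)
    return sanitize_bars(ascii_text)


# ---------------------------------------------------------------------------
# Lightweight linguistic helpers (no model download needed)
# ---------------------------------------------------------------------------

_STEM_SUFFIXES = ("ational", "ization", "fulness", "ousness", "iveness",
                  "tional", "encies", "ancies", "ations", "ingly",
                  "ation", "ments", "ness", "ible", "able", "ious",
                  "ment", "ions", "sses", "ies", "ing", "ion", "ed",
                  "es", "ly", "s")


def stem(word: str) -> str:
    """Suffix-stripping stemmer; crude but deterministic and dependency-free."""
    w = word.lower()
    for suf in _STEM_SUFFIXES:
        if w.endswith(suf) and len(w) - len(suf) >= 3:
            return w[: -len(suf)]
    return w


def pos_tag(word: str) -> str:
    """Rule-based part-of-speech tag from shape and suffix heuristics."""
    if re.fullmatch(r"[\d.,:%/-]+", word):
        return "CD"
    if not word[0].isalpha():
        return "SYM"
    lower = word.lower()
    if lower in {"the", "a", "an"}:
        return "DT"
    if lower in {"of", "in", "on", "for", "with", "under", "by", "to", "from"}:
        return "IN"
    if lower in {"and", "or", "but"}:
        return "CC"
    if lower in {"is", "are", "was", "were", "be", "been"}:
        return "VB"
    if lower.endswith(("ing",)):
        return "VBG"
    if lower.endswith(("ed",)):
        return "VBD"
    if lower.endswith(("ly",)):
        return "RB"
    if lower.endswith(("ous", "ive", "able", "ible", "al", "ic", "ful")):
        return "JJ"
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")):
        return "NNS"
    if word[0].isupper():
        return "NNP"
    return "NN"


def lemmatize(word: str) -> str:
    """Drop regular plural/inflection endings; lowercases the word."""
    w = word.lower()
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("es") and len(w) > 4 and w[-3] in "sxz":
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) > 3:
        return w[:-1]
    return w


ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba Pt Au Hg Tl Pb Bi U".split()
)
ELEMENT_NAMES = frozenset(
    "hydrogen helium lithium boron carbon nitrogen oxygen fluorine sodium "
    "magnesium aluminium silicon phosphorus sulfur chlorine potassium "
    "calcium iron copper zinc silver tin iodine platinum gold mercury lead "
    "bismuth uranium".split()
)
RING_MORPHEMES = frozenset(
    "benz phen yl ol ane ene ine ium oxy meth eth chlor brom fluor amin "
    "nitro pyrid imidazol furan thiazol quinol indol naphthal pyrrol oxazol "
    "pyrimid azepin amide oxide ester acid aldehyde".split()
)


def word_shape(word: str) -> str:
    return "".join(
        "A" if c.isupper() else "a" if c.islower() else "0" if c.isdigit() else c
        for c in word
    )


def _collapse(shape: str) -> str:
    out: list[str] = []
    for c in shape:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def _bucket(n: int) -> str:
    return str(n) if n < 3 else "3+"


# ---------------------------------------------------------------------------
# Word-vector clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Word → cluster-id map from embeddings K-means."""

    word_to_cluster: dict[str, int]
    k: int
    dim: int
    seed: int

    def cluster_of(self, word: str) -> str:
        cid = self.word_to_cluster.get(word.casefold())
        return "UNK" if cid is None else str(cid)

    def save(self, path) -> None:
        from pathlib import Path

        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"# k={self.k} dim={self.dim} seed={self.seed}\n")
            for word in sorted(self.word_to_cluster):
                fh.write(f"{word}\t{self.word_to_cluster[word]}\n")

    @classmethod
    def load(cls, path) -> "ClusterModel":
        from pathlib import Path

        mapping: dict[str, int] = {}
        k = dim = seed = 0
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    for kv in line[1:].split():
                        key, _, val = kv.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "dim":
                            dim = int(val)
                        elif key == "seed":
                            seed = int(val)
                    continue
                word, _, cid = line.rstrip("\n").partition("\t")
                mapping[word] = int(cid)
        return cls(mapping, k=k or (max(mapping.values()) + 1), dim=dim, seed=seed)


def build_clusters(
    sentences: Sequence[Sequence[str]],
    dim: int = 50,
    k: int = 1000,
    seed: int = 0,
    window: int = 2,
    min_count: int = 1,
) -> ClusterModel:
    """Train word embeddings on a token stream and K-means them into k ids.

    Embeddings are the truncated SVD of the positive-PMI word/context
    co-occurrence matrix (contexts = words within ±window), a standard dense
    embedding construction; K-means then assigns each vocabulary word a
    cluster id in [0, k).  Deterministic given (sentences, dim, k, seed).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import TruncatedSVD

    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            wl = w.casefold()
            counts[wl] = counts.get(wl, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty token stream")
    if k > len(vocab):
        raise ValueError(f"k={k} exceeds vocabulary size {len(vocab)}")
    index = {w: i for i, w in enumerate(vocab)}

    rows: list[int] = []
    cols: list[int] = []
    for sent in sentences:
        ids = [index.get(w.casefold()) for w in sent]
        for i, wi in enumerate(ids):
            if wi is None:
                continue
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                wj = ids[j]
                if j == i or wj is None:
                    continue
                rows.append(wi)
                cols.append(wj)
    cooc = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(vocab), len(vocab))
    ).tocsr()

    total = cooc.sum()
    row_sums = np.asarray(cooc.sum(axis=1)).ravel() + 1e-12
    col_sums = np.asarray(cooc.sum(axis=0)).ravel() + 1e-12
    cooc = cooc.tocoo()
    pmi = np.log((cooc.data * total) / (row_sums[cooc.row] * col_sums[cooc.col]))
    pmi = np.maximum(pmi, 0.0)
    ppmi = sp.coo_matrix((pmi, (cooc.row, cooc.col)), shape=cooc.shape).tocsr()

    n_comp = min(dim, len(vocab) - 1)
    svd = TruncatedSVD(n_components=n_comp, random_state=seed)
    emb = svd.fit_transform(ppmi)

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignment = km.fit_predict(emb)
    return ClusterModel(
        {w: int(assignment[i]) for w, i in index.items()}, k=k, dim=n_comp, seed=seed
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    affix_lengths: tuple[int, ...] = (1, 2, 3, 4)
    window: int = 2
    element_symbols: frozenset[str] = ELEMENT_SYMBOLS
    element_names: frozenset[str] = ELEMENT_NAMES
    ring_morphemes: frozenset[str] = RING_MORPHEMES
    cluster_count: int = 1000

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be ≥ 0")
        if self.cluster_count < 2:
            raise ValueError("cluster_count must be ≥ 2")


def _local_features(
    word: str,
    config: FeatureConfig,
    pos: str | None,
    lemma: str | None,
    clusters: ClusterModel | None,
) -> list[str]:
    lower = word.lower()
    feats = [
        f"w={lower}",
        f"stem={stem(word)}",
        f"shape={word_shape(word)}",
        f"shapec={_collapse(word_shape(word))}",
        f"ndigit={_bucket(sum(c.isdigit() for c in word))}",
        f"nupper={_bucket(sum(c.isupper() for c in word))}",
        f"nlower={_bucket(sum(c.islower() for c in word))}",
        f"elem={word in config.element_symbols or lower in config.element_names}",
        f"ring={any(m in lower for m in config.ring_morphemes)}",
    ]
    for n in config.affix_lengths:
        if len(word) >= n:
            feats.append(f"pre{n}={lower[:n]}")
            feats.append(f"suf{n}={lower[-n:]}")
    if pos is not None:
        feats.append(f"pos={pos}")
    if lemma is not None:
        feats.append(f"lemma={lemma}")
    if clusters is not None:
        feats.append(f"clu={clusters.cluster_of(word)}")
    return feats


def token_features(
    tokens: Sequence[Token],
    config: FeatureConfig | None = None,
    pos_tags: Sequence[str] | None = None,
    lemmas: Sequence[str] | None = None,
    clusters: ClusterModel | None = None,
) -> list[list[str]]:
    """Per-token feature strings, with neighbor copies across the window.

    ``pos_tags``/``lemmas`` default to the built-in rule-based providers;
    pass explicit sequences (same length as tokens) to plug in external
    taggers, or omit by passing empty behaviour via config.
    """
    config = config or FeatureConfig()
    words = [t.surface for t in tokens]
    if pos_tags is None:
        pos_tags = [pos_tag(w) for w in words]
    if lemmas is None:
        lemmas = [lemmatize(w) for w in words]
    if len(pos_tags) != len(words) or len(lemmas) != len(words):
        raise ValueError("pos_tags/lemmas length must match tokens")
    local = [
        _local_features(w, config, pos_tags[i], lemmas[i], clusters)
        for i, w in enumerate(words)
    ]
    out: list[list[str]] = []
    n = len(words)
    for i in range(n):
        feats = list(local[i])
        for off in range(-config.window, config.window + 1):
            j = i + off
            if off == 0:
                continue
            if 0 <= j < n:
                feats.extend(f"{off:+d}:{f}" for f in local[j])
            else:
                feats.append(f"{off:+d}:pad=True")
        out.append(feats)
    return out


# ---------------------------------------------------------------------------
# BIO encoding
# ---------------------------------------------------------------------------

def bio_encode(spans: Sequence[MentionSpan], tokens: Sequence[Token]) -> list[str]:
    """Project character spans onto tokens as B/I/O labels.

    Spans that cross token boundaries are snapped outward to the covering
    tokens (with a warning); spans overlapping no token are dropped.
    """
    labels = ["O"] * len(tokens)
    for span in spans:
        covered = [
            i for i, t in enumerate(tokens) if t.start < span.end and span.start < t.end
        ]
        if not covered:
            logger.warning("span %r covers no token; dropped", span.surface)
            continue
        first, last = covered[0], covered[-1]
        if tokens[first].start != span.start or tokens[last].end != span.end:
            logger.warning("span %r snapped to token boundaries", span.surface)
        labels[first] = "B"
        for i in range(first + 1, last + 1):
            labels[i] = "I"
    return labels


def bio_decode(
    labels: Sequence[str],
    tokens: Sequence[Token],
    text: str,
    doc_id: str = "",
    passage: str = "T",
    confidences: Sequence[float] | None = None,
) -> list[MentionSpan]:
    """Spans from maximal B/I runs; a bare I (after O or at start) acts as B."""
    spans: list[MentionSpan] = []
    i = 0
    n = len(tokens)
    while i < n:
        if labels[i] == "O":
            i += 1
            continue
        if labels[i] == "I":
            logger.debug("bare I at token %d repaired as B", i)
        j = i + 1
        while j < n and labels[j] == "I":
            j += 1
        start, end = tokens[i].start, tokens[j - 1].end
        conf = min(confidences[i:j]) if confidences is not None else 1.0
        spans.append(
            MentionSpan(
                doc_id, passage, start, end, text[start:end],
                source="crf", confidence=float(conf),
            )
        )
        i = j
    return spans


# ---------------------------------------------------------------------------
# Linear-chain CRF
# ---------------------------------------------------------------------------

def _logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis) if axis is not None else out.item()


@dataclass
class CRFModel:
    """Trained parameters plus the feature schema they were fit on."""

    feature_index: dict[str, int]
    namespaces: set[str]
    emission: np.ndarray      # (n_features, 3)
    transition: np.ndarray    # (3, 3)
    initial: np.ndarray       # (3,)


def _namespace(feat: str) -> str:
    return feat.split("=", 1)[0]


def _index_sequences(
    X: Sequence[Sequence[Sequence[str]]],
    feature_index: dict[str, int],
    grow: bool,
    namespaces: set[str] | None = None,
) -> list[list[list[int]]]:
    indexed: list[list[list[int]]] = []
    for seq in X:
        iseq: list[list[int]] = []
        for feats in seq:
            ids: list[int] = []
            for f in feats:
                idx = feature_index.get(f)
                if idx is None:
                    if grow:
                        idx = len(feature_index)
                        feature_index[f] = idx
                    else:
                        ns = _namespace(f)
                        if namespaces is not None and ns not in namespaces:
                            raise ValueError(
                                f"feature namespace {ns!r} unseen at training time"
                            )
                        continue
                ids.append(idx)
            iseq.append(ids)
        indexed.append(iseq)
    return indexed


def _stack(indexed: Sequence[Sequence[Sequence[int]]], n_features: int):
    """One CSR matrix over all tokens plus sequence offsets."""
    rows: list[int] = []
    cols: list[int] = []
    offsets = [0]
    r = 0
    for seq in indexed:
        for ids in seq:
            rows.extend([r] * len(ids))
            cols.extend(ids)
            r += 1
        offsets.append(r)
    data = np.ones(len(rows))
    mat = sp.csr_matrix((data, (rows, cols)), shape=(r, n_features))
    return mat, offsets


def _forward_backward(E: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Log-space forward-backward for one sequence.

    Returns (logZ, node marginals (T,3), expected transition counts (3,3)).
    """
    T = E.shape[0]
    alpha = np.empty((T, 3))
    beta = np.empty((T, 3))
    alpha[0] = init + E[0]
    for t in range(1, T):
        alpha[t] = E[t] + _logsumexp(alpha[t - 1][:, None] + trans, axis=0)
    beta[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[t] = _logsumexp(trans + (E[t + 1] + beta[t + 1])[None, :], axis=1)
    log_z = _logsumexp(alpha[T - 1], axis=0)
    node = np.exp(alpha + beta - log_z)
    pair = np.zeros((3, 3))
    for t in range(1, T):
        m = alpha[t - 1][:, None] + trans + (E[t] + beta[t])[None, :] - log_z
        pair += np.exp(m)
    return log_z, node, pair


class LinearChainCRF:
    """Exact-likelihood linear-chain CRF over the BIO label set."""

    def __init__(self, c2: float = 0.1, max_iter: int = 100, seed: int = 0):
        self.c2 = c2
        self.max_iter = max_iter
        self.seed = seed
        self.model: CRFModel | None = None

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X: Sequence[Sequence[Sequence[str]]],
        y: Sequence[Sequence[str]],
    ) -> "LinearChainCRF":
        if len(X) != len(y) or not X:
            raise ValueError("need equally many non-empty X and y sequences")
        if not any(lab == "B" for seq in y for lab in seq):
            raise ValueError("training data contains no B label")
        if all(not feats for seq in X for feats in seq):
            raise ValueError("all token feature maps are empty; refusing to train")

        feature_index: dict[str, int] = {}
        indexed = _index_sequences(X, feature_index, grow=True)
        n_feat = len(feature_index)
        F, offsets = _stack(indexed, n_feat)
        labels = np.array(
            [_LABEL_INDEX[lab] for seq in y for lab in seq], dtype=np.int64
        )
        if labels.shape[0] != F.shape[0]:
            raise ValueError("label/token count mismatch")
        Y = np.zeros((labels.shape[0], 3))
        Y[np.arange(labels.shape[0]), labels] = 1.0
        # empirical transition / initial counts
        emp_trans = np.zeros((3, 3))
        emp_init = np.zeros(3)
        for s in range(len(offsets) - 1):
            seq_labels = labels[offsets[s] : offsets[s + 1]]
            if len(seq_labels) == 0:
                continue
            emp_init[seq_labels[0]] += 1
            for a, b in zip(seq_labels[:-1], seq_labels[1:]):
                emp_trans[a, b] += 1
        emp_emit = F.T @ Y  # (n_feat, 3)

        n_emit = n_feat * 3

        def unpack(theta: np.ndarray):
            W = theta[:n_emit].reshape(n_feat, 3)
            trans = theta[n_emit : n_emit + 9].reshape(3, 3)
            init = theta[n_emit + 9 :]
            return W, trans, init

        def objective(theta: np.ndarray):
            W, trans, init = unpack(theta)
            E = F @ W
            nll = 0.0
            P = np.empty_like(E)
            exp_trans = np.zeros((3, 3))
            exp_init = np.zeros(3)
            for s in range(len(offsets) - 1):
                lo, hi = offsets[s], offsets[s + 1]
                if lo == hi:
                    continue
                log_z, node, pair = _forward_backward(E[lo:hi], trans, init)
                seq_labels = labels[lo:hi]
                gold = (
                    E[lo:hi][np.arange(hi - lo), seq_labels].sum()
                    + init[seq_labels[0]]
                    + trans[seq_labels[:-1], seq_labels[1:]].sum()
                )
                nll += log_z - gold
                P[lo:hi] = node
                exp_trans += pair
                exp_init += node[0]  # t=0 marginal is the initial-state expectation
            grad_W = np.asarray(F.T @ (P - Y))
            grad_trans = exp_trans - emp_trans
            grad_init = exp_init - emp_init
            nll += 0.5 * self.c2 * float(theta @ theta)
            grad = np.concatenate(
                [grad_W.ravel(), grad_trans.ravel(), grad_init]
            ) + self.c2 * theta
            return nll, grad

        rng = np.random.default_rng(self.seed)
        theta0 = rng.normal(scale=1e-3, size=n_emit + 9 + 3)
        res = scipy.optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxfun": 3 * self.max_iter},
        )
        W, trans, init = unpack(res.x)
        self.model = CRFModel(
            feature_index=feature_index,
            namespaces={_namespace(f) for f in feature_index},
            emission=W,
            transition=trans,
            initial=init,
        )
        logger.info(
            "CRF trained: %d features, final NLL %.2f, %d iterations",
            n_feat, res.fun, res.nit,
        )
        return self

    # -- inference ---------------------------------------------------------
    def _scores(self, X: Sequence[Sequence[Sequence[str]]]):
        if self.model is None:
            raise RuntimeError("model not trained")
        m = self.model
        indexed = _index_sequences(
            X, m.feature_index, grow=False, namespaces=m.namespaces
        )
        F, offsets = _stack(indexed, len(m.feature_index))
        E = F @ m.emission
        return E, offsets

    def predict(
        self, X: Sequence[Sequence[Sequence[str]]]
    ) -> list[list[str]]:
        """Viterbi decoding; deterministic given the model."""
        E, offsets = self._scores(X)
        m = self.model
        out: list[list[str]] = []
        for s in range(len(offsets) - 1):
            lo, hi = offsets[s], offsets[s + 1]
            T = hi - lo
            if T == 0:
                out.append([])
                continue
            delta = m.initial + E[lo]
            back = np.zeros((T, 3), dtype=np.int64)
            for t in range(1, T):
                cand = delta[:, None] + m.transition
                back[t] = np.argmax(cand, axis=0)
                delta = E[lo + t] + np.max(cand, axis=0)
            path = [int(np.argmax(delta))]
            for t in range(T - 1, 0, -1):
                path.append(int(back[t, path[-1]]))
            path.reverse()
            out.append([LABELS[i] for i in path])
        return out

    def predict_marginals(
        self, X: Sequence[Sequence[Sequence[str]]]
    ) -> list[np.ndarray]:
        """Per-token posterior label marginals, shape (T, 3) per sequence."""
        E, offsets = self._scores(X)
        m = self.model
        out: list[np.ndarray] = []
        for s in range(len(offsets) - 1):
            lo, hi = offsets[s], offsets[s + 1]
            if lo == hi:
                out.append(np.zeros((0, 3)))
                continue
            _, node, _ = _forward_backward(E[lo:hi], m.transition, m.initial)
            out.append(node)
        return out


# ---------------------------------------------------------------------------
# Corpus-level tagger
# ---------------------------------------------------------------------------

@dataclass
class CRFTagger:
    """End-to-end statistical tagger over a corpus.

    Wraps pre-processing, feature extraction and the CRF behind train/tag
    calls that speak corpora and mention spans.
    """

    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    clusters: ClusterModel | None = None
    c2: float = 0.1
    max_iter: int = 100
    seed: int = 0
    crf: LinearChainCRF | None = None

    def _passages(self, corpus: Corpus):
        for rec in corpus.records:
            for passage, text in (("T", rec.title), ("A", rec.abstract)):
                clean = preprocess(text)
                yield rec.doc_id, passage, text, tokenize(clean)

    def train(self, corpus: Corpus) -> "CRFTagger":
        gold_by_passage: dict[tuple[str, str], list[MentionSpan]] = {}
        for span in corpus.gold:
            gold_by_passage.setdefault((span.doc_id, span.passage), []).append(span)
        X: list[list[list[str]]] = []
        y: list[list[str]] = []
        for doc_id, passage, _text, tokens in self._passages(corpus):
            if not tokens:
                continue
            X.append(token_features(tokens, self.feature_config, clusters=self.clusters))
            y.append(bio_encode(gold_by_passage.get((doc_id, passage), []), tokens))
        self.crf = LinearChainCRF(c2=self.c2, max_iter=self.max_iter, seed=self.seed)
        self.crf.fit(X, y)
        return self

    def tag(self, corpus: Corpus) -> list[MentionSpan]:
        if self.crf is None:
            raise RuntimeError("train() first")
        items = list(self._passages(corpus))
        X = [
            token_features(tokens, self.feature_config, clusters=self.clusters)
            for _, _, _, tokens in items
        ]
        label_seqs = self.crf.predict(X)
        marginal_seqs = self.crf.predict_marginals(X)
        spans: list[MentionSpan] = []
        for (doc_id, passage, text, tokens), labels, marg in zip(
            items, label_seqs, marginal_seqs
        ):
            if not tokens:
                continue
            confs = [
                float(marg[t, _LABEL_INDEX[lab]]) for t, lab in enumerate(labels)
            ]
            spans.extend(
                bio_decode(labels, tokens, text, doc_id, passage, confidences=confs)
            )
        return spans
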