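"""Text preprocessing: tokenization, TF-IDF statistics, and a compact
skip-gram Word2Vec trained on the cohort's own notes.

The TF-IDF weight of token w in a document is tf(w) * ln(N / (df(w) + 1)),
with N the corpus size and df the document frequency; document vectors are
the TF-IDF-weighted mean of the token embeddings.  The Word2Vec here is a
plain skip-gram with negative sampling, single-threaded and fully
deterministic under a fixed seed -- the corpora are small templated notes,
so a few epochs suffice to place co-occurring symptom terms together.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "tokenize", "TextCorpusStats", "build_corpus_stats", "tfidf_weights",
    "EmbeddingModel", "train_word2vec", "embed_text",
]

_TOKEN_RE = re.compile(r"[a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation/digits, drop English stop words."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in ENGLISH_STOP_WORDS]


@dataclass
class TextCorpusStats:
    N: int
    df: dict[str, int]
    tf: list[Counter]
    vocabulary: list[str]


def build_corpus_stats(corpus: list[list[str]]) -> TextCorpusStats:
    """Document/term frequencies over a tokenized corpus."""
    if not corpus:
        raise ValueError("empty corpus")
    tf = [Counter(doc) for doc in corpus]
    df: Counter = Counter()
    for counts in tf:
        df.update(counts.keys())
    return TextCorpusStats(N=len(corpus), df=dict(df), tf=tf,
                           vocabulary=sorted(df))


def tfidf_weights(stats: TextCorpusStats, doc_index: int) -> dict[str, float]:
    """Per-token TF-IDF weights of one document: tf * ln(N / (df + 1))."""
    if stats.N < 1:
        raise ValueError("empty corpus")
    if not 0 <= doc_index < len(stats.tf):
        raise IndexError(f"doc_index {doc_index} out of range")
    counts = stats.tf[doc_index]
    return {
        w: c * math.log(stats.N / (stats.df.get(w, 0) + 1))
        for w, c in counts.items()
    }


@dataclass
class EmbeddingModel:
    dim: int = 300
    window: int = 5
    min_count: int = 2
    token_limit: int = 200
    vectors: dict[str, np.ndarray] = field(default_factory=dict)


def train_word2vec(
    corpus: list[list[str]],
    dim: int = 300,
    window: int = 5,
    min_count: int = 2,
    token_limit: int = 200,
    negative: int = 5,
    epochs: int = 25,
    lr: float = 0.025,
    batch: int = 256,
    seed: int = 0,
) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling on the corpus.

    Tokens below ``min_count`` are dropped from the vocabulary.  Negative
    samples are drawn from the unigram^0.75 distribution; the learning rate
    decays linearly to lr/10 over training.  Updates are applied in small
    minibatches (scatter-add, reads within a batch see the batch-start
    weights), which keeps training deterministic and fast on small corpora.
    """
    if len(corpus) < 10:
        raise ValueError(f"need at least 10 documents, got {len(corpus)}")
    counts = Counter(t for doc in corpus for t in doc)
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("vocabulary empty after min_count filtering")
    index = {w: i for i, w in enumerate(vocab)}
    docs = [[index[t] for t in doc if t in index] for doc in corpus]
    docs = [d for d in docs if len(d) >= 2]

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = rng.uniform(-0.5 / dim, 0.5 / dim, (V, dim))
    W_out = np.zeros((V, dim))

    freq = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    neg_probs = freq / freq.sum()

    pairs = []
    for doc in docs:
        for pos, center in enumerate(doc):
            lo, hi = max(0, pos - window), min(len(doc), pos + window + 1)
            for ctx_pos in range(lo, hi):
                if ctx_pos != pos:
                    pairs.append((center, doc[ctx_pos]))
    pairs = np.array(pairs, dtype=np.int64)
    if len(pairs) == 0:
        raise ValueError("no training pairs (documents too short)")

    total = epochs * len(pairs)
    labels = np.zeros(negative + 1)
    labels[0] = 1.0
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        negs = rng.choice(V, size=(len(pairs), negative), p=neg_probs)
        for start in range(0, len(pairs), batch):
            sel = order[start:start + batch]
            centers = pairs[sel, 0]
            targets = np.column_stack([pairs[sel, 1], negs[sel]])  # (B, 1+neg)
            eta = lr * max(0.1, 1.0 - step / total)
            step += len(sel)
            v_c = W_in[centers]                    # (B, dim)
            v_t = W_out[targets]                   # (B, 1+neg, dim)
            scores = 1.0 / (1.0 + np.exp(-np.einsum("bnd,bd->bn", v_t, v_c)))
            delta = scores - labels                # (B, 1+neg)
            grad_c = np.einsum("bn,bnd->bd", delta, v_t)
            # scatter-add via indicator matmuls (vocabulary is small)
            contrib = (delta[..., None] * v_c[:, None, :]).reshape(-1, dim)
            rows = targets.size
            ind_t = np.zeros((rows, V))
            ind_t[np.arange(rows), targets.ravel()] = 1.0
            W_out -= eta * (ind_t.T @ contrib)
            ind_c = np.zeros((len(sel), V))
            ind_c[np.arange(len(sel)), centers] = 1.0
            W_in -= eta * (ind_c.T @ grad_c)

    vectors = {w: W_in[i].copy() for w, i in index.items()}
    return EmbeddingModel(dim=dim, window=window, min_count=min_count,
                          token_limit=token_limit, vectors=vectors)


def embed_text(note: str, stats: TextCorpusStats, model: EmbeddingModel) -> np.ndarray:
    """TF-IDF-weighted mean of token embeddings for one note.

    The note is truncated to ``token_limit`` tokens.  If the weights sum to
    (numerically) zero the unweighted mean is used; a note with no
    in-vocabulary tokens embeds to the zero vector.
    """
    tokens = tokenize(note)[: model.token_limit]
    in_vocab = [t for t in tokens if t in model.vectors]
    if not in_vocab:
        return np.zeros(model.dim)
    counts = Counter(in_vocab)
    weights, vecs = [], []
    for w, c in counts.items():
        weights.append(c * math.log(stats.N / (stats.df.get(w, 0) + 1)))
        vecs.append(model.vectors[w])
    weights = np.array(weights)
    vecs = np.array(vecs)
    denom = weights.sum()
    if abs(denom) < 1e-12:
        return vecs.mean(axis=0)
    return (weights[:, None] * vecs).sum(axis=0) / denom
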