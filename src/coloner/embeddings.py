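"""Word representations: pretrained CBOW embeddings and one-hot baselines.

The CBOW (continuous bag-of-words) model predicts a target word from the
mean of its context-window vectors and is trained with negative sampling
on the large unlabeled report corpus.  The resulting matrix seeds the
tagger's embedding layer, giving lexical variants of one concept
("D-colon", "DC", "Desc. colon") nearby vectors even when the annotated
data is too small to learn that.  The one-hot matrix is the
no-pretraining baseline: each word is its own unit basis vector.

Defaults follow the reference configuration: dimension 128, window 5,
minimum count 3.  The trainer is single-threaded, pure numpy and
bit-deterministic given its seed.  The context window is a fixed
symmetric window (no per-position window subsampling), recorded in the
matrix metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CorpusTooSmallError, ValidationError
from .nn import Embedding, _sigmoid
from .preprocess import PAD_WORD, UNK_WORD, Vocabulary, build_vocabulary


@dataclass
class EmbeddingMatrix:
    """Vocabulary-aligned dense word vectors.

    Row ``i`` is the vector of ``vocab.words[i]``; the PAD row is all
    zeros.  ``provenance`` is one of ``one-hot``, ``cbow-pretrained`` or
    ``random-init``; training metadata records window/min_count/seed and a
    corpus fingerprint so a matrix can be traced to its corpus.
    """

    matrix: np.ndarray
    vocab: Vocabulary
    provenance: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.vocab):
            raise ValidationError(
                f"matrix rows ({self.matrix.shape[0]}) != vocabulary size ({len(self.vocab)})"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("embedding matrix has non-finite entries")

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self.vocab.encode(word)]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))

    # -- word2vec text format ----------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.matrix.shape[0]} {self.dimension}\n")
            for word, row in zip(self.vocab.words, self.matrix):
                fh.write(word + " " + " ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path, provenance: str = "cbow-pretrained") -> "EmbeddingMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        matrix = np.array(rows)
        if matrix.shape != (n, dim):
            raise ValidationError("word2vec file header does not match contents")
        vocab = Vocabulary(index={w: i for i, w in enumerate(words)})
        return cls(matrix=matrix, vocab=vocab, provenance=provenance)


def one_hot_matrix(vocab: Vocabulary) -> EmbeddingMatrix:
    """Identity-like basis matrix: dimension = |V|, PAD row zero."""
    V = len(vocab)
    m = np.eye(V)
    m[vocab.pad_id] = 0.0
    return EmbeddingMatrix(matrix=m, vocab=vocab, provenance="one-hot")


def seed_embedding_layer(matrix: EmbeddingMatrix, trainable: bool = True,
                         vocab: Vocabulary | None = None) -> Embedding:
    """Build the tagger's first layer so lookups reproduce ``matrix`` exactly.

    If ``vocab`` is given it must equal the matrix's vocabulary (same words,
    same indices); a mismatch raises :class:`ValidationError`.
    """
    if vocab is not None and vocab.index != matrix.vocab.index:
        raise ValidationError("embedding matrix vocabulary does not match tagger vocabulary")
    return Embedding(matrix.matrix, trainable=trainable)


def align_to_vocabulary(matrix: EmbeddingMatrix, vocab: Vocabulary,
                        seed: int = 0, scale: float = 0.05) -> EmbeddingMatrix:
    """Re-index a pretrained matrix onto a (possibly larger) tagger vocabulary.

    Words present in the annotated data but missing from the pretrained
    vocabulary get small-variance random vectors (seeded); PAD stays zero.
    """
    rng = np.random.default_rng(seed)
    out = rng.normal(0.0, scale, size=(len(vocab), matrix.dimension))
    out[vocab.pad_id] = 0.0
    n_hit = 0
    for word, idx in vocab.index.items():
        if word == PAD_WORD:
            continue
        if word in matrix.vocab:
            out[idx] = matrix.matrix[matrix.vocab.encode(word)]
            n_hit += 1
    meta = dict(matrix.metadata)
    meta["aligned_hits"] = n_hit
    return EmbeddingMatrix(matrix=out, vocab=vocab, provenance=matrix.provenance,
                           metadata=meta)


# ---------------------------------------------------------------------------
# CBOW training (negative sampling)
# ---------------------------------------------------------------------------

def train_cbow(
    corpus: Iterable[Sequence[str]],
    dimension: int = 128,
    window: int = 5,
    min_count: int = 3,
    epochs: int = 5,
    negatives: int = 5,
    alpha: float = 0.05,
    min_alpha: float = 1e-4,
    seed: int = 0,
    batch_size: int = 512,
) -> EmbeddingMatrix:
    """Train CBOW word vectors with negative sampling on a tokenized corpus.

    Returns an :class:`EmbeddingMatrix` whose vocabulary holds every word
    with frequency >= ``min_count`` (plus PAD/UNK; UNK gets a small random
    vector).  Negative samples are drawn from the unigram distribution
    raised to 3/4.  Raises :class:`CorpusTooSmallError` when nothing
    survives the frequency threshold.
    """
    sentences = [list(s) for s in corpus]
    vocab = build_vocabulary(sentences, min_count=min_count)
    if len(vocab) <= 2:
        raise CorpusTooSmallError(
            f"no word reaches min_count={min_count}; corpus too small"
        )
    rng = np.random.default_rng(seed)
    V = len(vocab)

    # encode sentences, dropping sub-threshold words before windowing
    encoded = []
    n_tokens = 0
    for sent in sentences:
        ids = [vocab.index[w.lower()] for w in sent if w.lower() in vocab.index]
        if len(ids) >= 2:
            encoded.append(np.array(ids, dtype=np.int64))
            n_tokens += len(ids)

    # precompute fixed-window context table: (N, 2*window) ids + mask
    ctx_ids = []
    ctx_mask = []
    targets = []
    for ids in encoded:
        L = len(ids)
        for i in range(L):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            ctx = np.concatenate([ids[lo:i], ids[i + 1 : hi]])
            row = np.zeros(2 * window, dtype=np.int64)
            row[: len(ctx)] = ctx
            msk = np.zeros(2 * window)
            msk[: len(ctx)] = 1.0
            ctx_ids.append(row)
            ctx_mask.append(msk)
            targets.append(ids[i])
    ctx_ids = np.array(ctx_ids)
    ctx_mask = np.array(ctx_mask)
    targets = np.array(targets, dtype=np.int64)
    counts = ctx_mask.sum(axis=1, keepdims=True)
    N = len(targets)

    # unigram^0.75 negative-sampling table (PAD/UNK excluded)
    freqs = np.zeros(V)
    for w, i in vocab.index.items():
        if w not in (PAD_WORD, UNK_WORD):
            freqs[i] = vocab.frequencies.get(w, 0)
    noise = freqs ** 0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)

    W_in = rng.uniform(-0.5 / dimension, 0.5 / dimension, size=(V, dimension))
    W_out = np.zeros((V, dimension))

    total_batches = max(1, epochs * ((N + batch_size - 1) // batch_size))
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(N)
        for lo in range(0, N, batch_size):
            sel = order[lo : lo + batch_size]
            lr = max(min_alpha, alpha * (1 - step / total_batches))
            step += 1
            ctx = ctx_ids[sel]
            msk = ctx_mask[sel][:, :, None]
            h = (W_in[ctx] * msk).sum(axis=1) / counts[sel]       # (b, D)
            negs = np.searchsorted(noise_cdf, rng.random((len(sel), negatives)))
            outs = np.concatenate([targets[sel][:, None], negs], axis=1)  # (b, 1+k)
            vout = W_out[outs]                                     # (b, 1+k, D)
            scores = np.einsum("bd,bkd->bk", h, vout)
            labels = np.zeros_like(scores)
            labels[:, 0] = 1.0
            g = (labels - _sigmoid(scores)) * lr                   # (b, 1+k)
            dh = np.einsum("bk,bkd->bd", g, vout)
            np.add.at(W_out, outs, g[:, :, None] * h[:, None, :])
            upd = (dh / counts[sel])[:, None, :] * msk
            np.add.at(W_in, ctx, upd)
            W_in[vocab.pad_id] = 0.0

    W_in[vocab.unk_id] = rng.normal(0.0, 0.05, size=dimension)
    W_in[vocab.pad_id] = 0.0
    meta = {
        "window": window,
        "min_count": min_count,
        "epochs": epochs,
        "negatives": negatives,
        "seed": seed,
        "window_style": "fixed-symmetric",
        "corpus_fingerprint": f"{len(sentences)} sentences / {n_tokens} tokens",
    }
    return EmbeddingMatrix(matrix=W_in, vocab=vocab, provenance="cbow-pretrained",
                           metadata=meta)
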