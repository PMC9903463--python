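"""The Bi-LSTM-CRF sequence tagger and its LSTM/Bi-LSTM ablation variants.

Architecture: an embedding layer (seeded one-hot, pretrained CBOW, or
random), a recurrent encoder (unidirectional LSTM or Bi-LSTM), a dense
projection to per-tag emission scores, and -- for the ``bilstm-crf``
variant -- a linear-chain CRF whose negative log-likelihood is the loss
and whose Viterbi decode (hard-masked to the IOB2 constraints) produces
predictions.  The no-CRF variants train with a token-level softmax loss
(categorical cross-entropy, KL divergence or Poisson) and decode by
per-token argmax, with orphan ``I`` tags repaired at span extraction.

Reference defaults: embedding dimension 128, hidden dimension 256,
10 epochs, RMSProp.  Batch size 32 and learning rate 1e-3 are this
package's defaults (configurable, recorded in the bundle).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import crf as crf_mod
from .corpus_io import AnnotatedDocument, TaggedSentence, iob2_to_spans, spans_to_iob2
from .embeddings import EmbeddingMatrix, align_to_vocabulary, seed_embedding_layer
from .errors import ConfigError, SchemaError, ValidationError
from .nn import OPTIMIZERS, BiLSTM, Dense, Embedding, LSTM, token_loss
from .preprocess import EncodedBatch, Vocabulary, build_vocabulary, encode_and_pad, sentences_of
from .schema import TagVocabulary, transition_mask

ARCHITECTURES = ("lstm", "bilstm", "bilstm-crf")
LOSSES = ("crf", "cce", "kl", "poisson")


@dataclass
class TaggerConfig:
    """Hyperparameters of one training run."""

    architecture: str = "bilstm-crf"
    embedding_dim: int = 128
    hidden_dim: int = 256
    epochs: int = 10
    optimizer: str = "rmsprop"
    loss: str | None = None          # resolved: "crf" for CRF variants
    seed: int = 0
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.0
    max_len: int = 128
    trainable_embeddings: bool = True

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        if self.optimizer not in OPTIMIZERS:
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if min(self.embedding_dim, self.hidden_dim, self.epochs) <= 0:
            raise ConfigError("dimensions and epochs must be positive")
        uses_crf = self.architecture.endswith("-crf")
        if self.loss is None:
            self.loss = "crf" if uses_crf else "cce"
        if uses_crf and self.loss != "crf":
            raise ConfigError("the CRF architecture always uses the CRF loss")
        if not uses_crf and self.loss == "crf":
            raise ConfigError(f"loss 'crf' requires a CRF architecture, got {self.architecture!r}")
        if self.loss not in LOSSES:
            raise ConfigError(f"unknown loss {self.loss!r}")


class TaggerModel:
    """Wiring of the layers; computes emissions, loss gradients and decodes."""

    def __init__(
        self,
        config: TaggerConfig,
        vocab: Vocabulary,
        tag_vocab: TagVocabulary,
        embedding: EmbeddingMatrix | None = None,
    ):
        self.config = config
        self.vocab = vocab
        self.tag_vocab = tag_vocab
        self.n_tags = len(tag_vocab) - 1  # CRF/emission space excludes PAD
        rng = np.random.default_rng(config.seed)
        if embedding is None:
            W = rng.normal(0.0, 0.05, size=(len(vocab), config.embedding_dim))
            W[vocab.pad_id] = 0.0
            self.embedding = Embedding(W, trainable=config.trainable_embeddings)
            self.embedding_provenance = "random-init"
        else:
            trainable = config.trainable_embeddings and embedding.provenance != "one-hot"
            self.embedding = seed_embedding_layer(embedding, trainable=trainable, vocab=vocab)
            self.embedding_provenance = embedding.provenance
        in_dim = self.embedding.W.shape[1]
        if config.architecture == "lstm":
            self.encoder = LSTM(in_dim, config.hidden_dim, rng)
            feat = config.hidden_dim
        else:
            self.encoder = BiLSTM(in_dim, config.hidden_dim, rng)
            feat = 2 * config.hidden_dim
        self.dense = Dense(feat, self.n_tags, rng)
        self.crf = crf_mod.CrfParameters.zeros(self.n_tags) if config.loss == "crf" else None
        self.d_crf = None
        mask = transition_mask(tag_vocab)
        self.allowed_trans, self.allowed_start, _ = mask.nopad()
        self._rng = rng
        self._drop_mask = None

    # -- forward / backward -------------------------------------------------

    def emissions(self, token_ids: np.ndarray, lengths: np.ndarray,
                  training: bool = False) -> np.ndarray:
        x = self.embedding.forward(token_ids)
        if isinstance(self.encoder, BiLSTM):
            h = self.encoder.forward(x, lengths)
        else:
            h = self.encoder.forward(x)
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            self._drop_mask = (self._rng.random(h.shape) < keep) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        return self.dense.forward(h)

    def backward(self, d_emissions: np.ndarray) -> None:
        dh = self.dense.backward(d_emissions)
        if self._drop_mask is not None:
            dh = dh * self._drop_mask
        dx = self.encoder.backward(dh)
        self.embedding.backward(dx)

    def loss_and_backward(self, batch: EncodedBatch) -> float:
        """Compute the configured loss and accumulate all gradients."""
        em = self.emissions(batch.token_ids, batch.lengths, training=True)
        if self.crf is not None:
            tags = np.maximum(batch.tag_ids - 1, 0)  # shift out of PAD space
            loss, (d_em, d_trans, d_start, d_stop) = crf_mod.negative_log_likelihood(
                em, tags, batch.lengths, self.crf, with_grad=True
            )
            self.d_crf = (d_trans, d_start, d_stop)
            self.backward(d_em)
            return loss
        tags = np.maximum(batch.tag_ids - 1, 0)
        loss, d_em = token_loss(em, tags, batch.mask, kind=self.config.loss)
        self.backward(d_em)
        return loss

    def zero_grad(self) -> None:
        self.embedding.zero_grad()
        self.encoder.zero_grad()
        self.dense.zero_grad()
        self.d_crf = None

    def named_params(self):
        yield from self.embedding.params("emb_")
        yield from self.encoder.params("enc_")
        yield from self.dense.params("out_")
        if self.crf is not None and self.d_crf is not None:
            d_trans, d_start, d_stop = self.d_crf
            yield "crf_trans", self.crf.transitions, d_trans
            yield "crf_start", self.crf.start, d_start
            yield "crf_stop", self.crf.stop, d_stop

    # -- decoding -----------------------------------------------------------

    def decode(self, batch: EncodedBatch, constrained: bool = True) -> list[list[str]]:
        """Tag sequences (strings, non-PAD space) for a batch of sentences."""
        if len(batch) == 0:
            return []
        em = self.emissions(batch.token_ids, batch.lengths, training=False)
        out: list[list[str]] = []
        if self.crf is not None:
            paths, _ = crf_mod.viterbi_decode(
                em, batch.lengths, self.crf,
                allowed_transitions=self.allowed_trans if constrained else None,
                allowed_start=self.allowed_start if constrained else None,
            )
            for path in paths:
                out.append([self.tag_vocab.tag(i + 1) for i in path])
        else:
            best = np.argmax(em, axis=2)
            for b in range(len(batch)):
                L = int(batch.lengths[b])
                out.append([self.tag_vocab.tag(int(i) + 1) for i in best[b, :L]])
        return out


@dataclass
class TrainedTagger:
    """A trained model plus everything needed to reload and predict."""

    model: TaggerModel
    config: TaggerConfig
    vocab: Vocabulary
    tag_vocab: TagVocabulary
    loss_log: list[float] = field(default_factory=list)

    # -- prediction ---------------------------------------------------------

    def tag_sentences(self, sentences: Sequence[TaggedSentence]) -> list[TaggedSentence]:
        out: list[TaggedSentence] = []
        bs = self.config.batch_size
        for lo in range(0, len(sentences), bs):
            chunk = sentences[lo : lo + bs]
            batch = encode_and_pad(chunk, self.vocab, self.tag_vocab,
                                   max_len=self.config.max_len)
            for sent, tags in zip(chunk, self.model.decode(batch)):
                n = min(len(sent), len(tags))
                new_tags = tags[:n] + ["O"] * (len(sent) - n)
                out.append(TaggedSentence(
                    tokens=list(sent.tokens), tags=new_tags,
                    char_offsets=sent.char_offsets,
                    doc_id=sent.doc_id, sentence_index=sent.sentence_index,
                ))
        return out

    def predict(self, docs: Iterable[AnnotatedDocument]) -> list[AnnotatedDocument]:
        """Full pipeline on raw documents: split, tokenize, decode, extract spans."""
        strict = self.config.loss == "crf"  # constrained decode guarantees validity
        out = []
        for doc in docs:
            sents = sentences_of(doc.text, doc_id=doc.doc_id)
            spans = []
            for tagged in self.tag_sentences(sents):
                spans.extend(iob2_to_spans(tagged, text=doc.text,
                                           vocab=self.tag_vocab, strict=strict))
            out.append(doc.with_spans(spans, origin="predicted"))
        return out

    # -- model bundle -------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        arrays = {name: p for name, p, _ in _with_dummy_grads(self.model)}
        np.savez(outdir / "weights.npz", **arrays)
        self.vocab.save(outdir / "vocab.txt")
        (outdir / "schema.txt").write_text(self.tag_vocab.label_set.dumps())
        (outdir / "config.json").write_text(json.dumps(asdict(self.config), indent=2))
        (outdir / "training_log.json").write_text(json.dumps(
            {"epoch_mean_loss": self.loss_log,
             "embedding_provenance": self.model.embedding_provenance}, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "TrainedTagger":
        outdir = Path(outdir)
        config = TaggerConfig(**json.loads((outdir / "config.json").read_text()))
        vocab = Vocabulary.load(outdir / "vocab.txt")
        from .schema import LabelSet
        tag_vocab = TagVocabulary(LabelSet.loads((outdir / "schema.txt").read_text()))
        with np.load(outdir / "weights.npz") as data:
            arrays = {k: np.array(data[k]) for k in data.files}
        # seed with the saved embedding so layer widths match (e.g. one-hot = |V|)
        emb = EmbeddingMatrix(matrix=arrays["emb_W"], vocab=vocab, provenance="loaded")
        model = TaggerModel(config, vocab, tag_vocab, embedding=emb)
        for name, p, _ in _with_dummy_grads(model):
            p[...] = arrays[name]
        log = json.loads((outdir / "training_log.json").read_text())
        return cls(model=model, config=config, vocab=vocab, tag_vocab=tag_vocab,
                   loss_log=log["epoch_mean_loss"])


def _with_dummy_grads(model: TaggerModel):
    """Iterate all weight arrays (for save/load), trainable or not."""
    yield "emb_W", model.embedding.W, model.embedding.dW
    yield from model.encoder.params("enc_")
    yield from model.dense.params("out_")
    if model.crf is not None:
        yield "crf_trans", model.crf.transitions, np.zeros(0)
        yield "crf_start", model.crf.start, np.zeros(0)
        yield "crf_stop", model.crf.stop, np.zeros(0)


def train(
    config: TaggerConfig,
    sentences: Sequence[TaggedSentence],
    vocab: Vocabulary | None = None,
    embedding: EmbeddingMatrix | None = None,
    tag_vocab: TagVocabulary | None = None,
) -> TrainedTagger:
    """Train a tagger on IOB2-tagged sentences.

    The vocabulary defaults to one built from the training sentences
    (min_count 1); a pretrained embedding matrix, if given, is re-indexed
    onto that vocabulary with seeded random vectors for unseen words.
    Returns the trained model with its per-epoch mean-loss log.
    """
    if not sentences:
        raise ValidationError("training set is empty")
    tag_vocab = tag_vocab or TagVocabulary()
    for sent in sentences:
        for tag in sent.tags:
            tag_vocab.normalize(tag)  # raises SchemaError before training starts
    if vocab is None:
        vocab = build_vocabulary([s.tokens for s in sentences], min_count=1)
    if embedding is not None and embedding.provenance != "one-hot":
        embedding = align_to_vocabulary(embedding, vocab, seed=config.seed)
    model = TaggerModel(config, vocab, tag_vocab, embedding=embedding)
    opt = OPTIMIZERS[config.optimizer](lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    # length-sorted batches cut padding waste; batch order reshuffled per epoch
    order = sorted(range(len(sentences)), key=lambda i: len(sentences[i]))
    batches = [order[lo : lo + config.batch_size]
               for lo in range(0, len(order), config.batch_size)]
    loss_log: list[float] = []
    for _epoch in range(config.epochs):
        rng.shuffle(batches)
        epoch_losses = []
        for idxs in batches:
            batch = encode_and_pad([sentences[i] for i in idxs], vocab, tag_vocab,
                                   max_len=config.max_len)
            model.zero_grad()
            loss = model.loss_and_backward(batch)
            opt.step(model.named_params())
            epoch_losses.append(loss)
        loss_log.append(float(np.mean(epoch_losses)))
    return TrainedTagger(model=model, config=config, vocab=vocab,
                         tag_vocab=tag_vocab, loss_log=loss_log)


def sentences_from_documents(
    docs: Iterable[AnnotatedDocument],
    tag_vocab: TagVocabulary | None = None,
) -> list[TaggedSentence]:
    """Gold documents -> tokenized sentences with IOB2 tags (the training view)."""
    tag_vocab = tag_vocab or TagVocabulary()
    out: list[TaggedSentence] = []
    for doc in docs:
        sents = sentences_of(doc.text, doc_id=doc.doc_id)
        out.extend(spans_to_iob2(doc, sents, vocab=tag_vocab))
    return out
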