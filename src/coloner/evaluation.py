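"""Entity-level evaluation and cross-validation experiments.

Scoring is entity-level with *partial matching*: a predicted span counts
as a true positive when it has the same label as a still-unmatched gold
span and their character ranges overlap by at least one character
(matching is greedy left-to-right; each gold and each predicted span is
used at most once).  Exact mode additionally requires identical
boundaries.  Precision/recall/F1 are reported per label and
micro-averaged: micro metrics are always recomputed from summed counts
across labels (and across folds), never averaged from per-label metrics,
so frequent labels carry proportional weight.

Cross-validation partitions *documents* (not sentences) into k folds, so
sentences of one report can never straddle train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus_io import AnnotatedDocument, Span
from .embeddings import EmbeddingMatrix, one_hot_matrix
from .errors import ValidationError
from .preprocess import build_vocabulary
from .schema import TagVocabulary
from .tagger import TaggerConfig, sentences_from_documents, train


@dataclass
class MatchCounts:
    """Per-label TP/FP/FN tallies under one match mode."""

    mode: str = "partial"
    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)

    def add(self, other: "MatchCounts") -> "MatchCounts":
        if other.mode != self.mode:
            raise ValidationError("cannot pool counts across match modes")
        out = MatchCounts(mode=self.mode)
        for d_out, d_a, d_b in ((out.tp, self.tp, other.tp),
                                (out.fp, self.fp, other.fp),
                                (out.fn, self.fn, other.fn)):
            for k in set(d_a) | set(d_b):
                d_out[k] = d_a.get(k, 0) + d_b.get(k, 0)
        return out

    def totals(self) -> tuple[int, int, int]:
        return sum(self.tp.values()), sum(self.fp.values()), sum(self.fn.values())


def _check_disjoint(spans: Sequence[Span], who: str) -> None:
    prev = None
    for sp in sorted(spans, key=lambda s: (s.start, s.end)):
        if prev is not None and sp.start < prev.end:
            raise ValidationError(f"overlapping spans within {who} list at {sp.start}")
        prev = sp


def match_entities(gold: Sequence[Span], predicted: Sequence[Span],
                   mode: str = "partial") -> MatchCounts:
    """Tally TP/FP/FN between one document's gold and predicted spans."""
    if mode not in ("partial", "exact"):
        raise ValidationError(f"unknown match mode {mode!r}")
    _check_disjoint(gold, "gold")
    _check_disjoint(predicted, "predicted")
    counts = MatchCounts(mode=mode)
    gold_sorted = sorted(gold, key=lambda s: (s.start, s.end))
    used = [False] * len(gold_sorted)
    for pred in sorted(predicted, key=lambda s: (s.start, s.end)):
        hit = None
        for gi, g in enumerate(gold_sorted):
            if used[gi] or g.label != pred.label:
                continue
            if mode == "partial":
                if g.start < pred.end and pred.start < g.end:
                    hit = gi
                    break
            else:
                if g.start == pred.start and g.end == pred.end:
                    hit = gi
                    break
        if hit is not None:
            used[hit] = True
            counts.tp[pred.label] = counts.tp.get(pred.label, 0) + 1
        else:
            counts.fp[pred.label] = counts.fp.get(pred.label, 0) + 1
    for gi, g in enumerate(gold_sorted):
        if not used[gi]:
            counts.fn[g.label] = counts.fn.get(g.label, 0) + 1
    return counts


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    """Per-label and micro-averaged precision/recall/F1, with fold detail."""

    counts: MatchCounts
    per_label: dict[str, tuple[float, float, float]]
    micro: tuple[float, float, float]
    no_entities: bool = False
    folds: list["EvalReport"] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def micro_f1(self) -> float:
        return self.micro[2]

    def label_f1(self, label: str) -> float:
        return self.per_label.get(label, (0.0, 0.0, 0.0))[2]

    def section_mean_f1(self, section: str, tag_vocab: TagVocabulary | None = None) -> float:
        """Mean per-label F1 over the labels of one report section."""
        tv = tag_vocab or TagVocabulary()
        labels = tv.label_set.by_section(section)
        return float(np.mean([self.label_f1(lab) for lab in labels]))

    def to_table(self) -> str:
        lines = ["label\tprecision\trecall\tf1"]
        for lab in sorted(set(self.counts.tp) | set(self.counts.fp) | set(self.counts.fn)):
            p, r, f1 = self.per_label[lab]
            lines.append(f"{lab}\t{p:.4f}\t{r:.4f}\t{f1:.4f}")
        p, r, f1 = self.micro
        lines.append(f"MICROAVG\t{p:.4f}\t{r:.4f}\t{f1:.4f}")
        return "\n".join(lines)


def compute_metrics(counts: MatchCounts, metadata: dict | None = None) -> EvalReport:
    """Precision/recall/F1 per label plus micro metrics from summed counts."""
    labels = set(counts.tp) | set(counts.fp) | set(counts.fn)
    per_label = {}
    for lab in labels:
        per_label[lab] = _prf(counts.tp.get(lab, 0), counts.fp.get(lab, 0),
                              counts.fn.get(lab, 0))
    tp, fp, fn = counts.totals()
    return EvalReport(
        counts=counts,
        per_label=per_label,
        micro=_prf(tp, fp, fn),
        no_entities=(tp + fp + fn == 0),
        metadata=metadata or {},
    )


def evaluate_documents(gold_docs: Sequence[AnnotatedDocument],
                       pred_docs: Sequence[AnnotatedDocument],
                       mode: str = "partial") -> MatchCounts:
    """Pool match counts over aligned gold/predicted document lists."""
    counts = MatchCounts(mode=mode)
    for g, p in zip(gold_docs, pred_docs):
        counts = counts.add(match_entities(g.spans, p.spans, mode=mode))
    return counts


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded near-equal partition of ``range(n)`` into k folds."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < k:
        raise ValidationError(f"dataset of {n} documents is smaller than k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::k] for i in range(k)]


def crossvalidate(
    dataset: Sequence[AnnotatedDocument],
    config: TaggerConfig,
    k: int = 5,
    seed: int = 0,
    embedding: EmbeddingMatrix | None = None,
    representation: str = "random",
    mode: str = "partial",
    folds: list[np.ndarray] | None = None,
    tag_vocab: TagVocabulary | None = None,
) -> EvalReport:
    """k-fold cross-validation at document level.

    Each fold serves once as test set; the vocabulary is rebuilt from the
    training folds only, so test-fold words the training folds never saw
    map to UNK.  ``representation`` selects the embedding seeding:
    ``one-hot`` (basis vectors over the training vocabulary),
    ``pretrained`` (requires ``embedding``, trained on the separate
    unlabeled corpus), or ``random``.  The aggregate report pools counts
    over all folds; fold-level reports are attached.
    """
    tag_vocab = tag_vocab or TagVocabulary()
    if representation == "pretrained" and embedding is None:
        raise ValidationError("representation 'pretrained' requires an embedding matrix")
    if folds is None:
        folds = make_folds(len(dataset), k, seed)
    fold_reports: list[EvalReport] = []
    pooled = MatchCounts(mode=mode)
    for fi, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train_docs = [d for i, d in enumerate(dataset) if i not in test_set]
        test_docs = [dataset[int(i)] for i in test_idx]
        sentences = sentences_from_documents(train_docs, tag_vocab)
        vocab = build_vocabulary([s.tokens for s in sentences], min_count=1)
        emb = None
        if representation == "one-hot":
            emb = one_hot_matrix(vocab)
        elif representation == "pretrained":
            emb = embedding
        tagger = train(config, sentences, vocab=vocab, embedding=emb,
                       tag_vocab=tag_vocab)
        preds = tagger.predict(test_docs)
        counts = evaluate_documents(test_docs, preds, mode=mode)
        fold_reports.append(compute_metrics(counts, metadata={"fold": fi}))
        pooled = pooled.add(counts)
    report = compute_metrics(pooled, metadata={
        "k": k, "seed": seed, "representation": representation,
        "n_documents": len(dataset), "config": config.architecture,
    })
    report.folds = fold_reports
    return report


def run_experiment_grid(
    datasets: dict[str, Sequence[AnnotatedDocument]],
    configs: dict[str, TaggerConfig],
    representations: Sequence[str] = ("one-hot",),
    k: int = 5,
    seed: int = 0,
    embedding: EmbeddingMatrix | None = None,
    progress: Callable[[str], None] | None = None,
) -> dict[tuple[str, str, str], EvalReport]:
    """One CV report per (dataset, representation, config) cell.

    Fold assignments depend only on dataset size and seed, so paired cells
    (e.g. one-hot vs pretrained on the same dataset) see identical splits.
    """
    out: dict[tuple[str, str, str], EvalReport] = {}
    for ds_name, docs in datasets.items():
        folds = make_folds(len(docs), k, seed)
        for rep in representations:
            for cfg_name, cfg in configs.items():
                if progress:
                    progress(f"{ds_name} / {rep} / {cfg_name}")
                out[(ds_name, rep, cfg_name)] = crossvalidate(
                    docs, cfg, k=k, seed=seed, embedding=embedding,
                    representation=rep, folds=folds,
                )
    return out


def grid_to_table(results: dict[tuple[str, str, str], EvalReport]) -> str:
    lines = ["dataset\trepresentation\tconfig\tmicro_p\tmicro_r\tmicro_f1"]
    for (ds, rep, cfg), rep_ in sorted(results.items()):
        p, r, f1 = rep_.micro
        lines.append(f"{ds}\t{rep}\t{cfg}\t{p:.4f}\t{r:.4f}\t{f1:.4f}")
    return "\n".join(lines)
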