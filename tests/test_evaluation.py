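"""Partial-match scoring, micro-averaging and cross-validation."""

import numpy as np
import pytest

from coloner.corpus_io import AnnotatedDocument, Span
from coloner.errors import ValidationError
from coloner.evaluation import (
    EvalReport, MatchCounts, compute_metrics, crossvalidate, evaluate_documents,
    make_folds, match_entities, run_experiment_grid,
)
from coloner.tagger import TaggerConfig

FAST_CFG = dict(embedding_dim=16, hidden_dim=12, epochs=2, seed=0)


def independent_prf(tp, fp, fn):
    """Reference arithmetic, written separately from the implementation."""
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


class TestMatchEntities:
    def test_partial_overlap_same_label_counts_wrong_label_does_not(self):
        gold = [Span(10, 15, "LESION"), Span(20, 35, "LOCATION")]
        pred = [Span(12, 15, "LESION"), Span(20, 35, "SHAPE")]
        c = match_entities(gold, pred, mode="partial")
        assert c.totals() == (1, 1, 1)

    def test_identical_prediction_is_all_true_positives(self):
        gold = [Span(0, 4, "SIZE"), Span(6, 10, "SHAPE")]
        c = match_entities(gold, list(gold))
        assert c.totals() == (2, 0, 0)

    def test_empty_prediction_counts_all_gold_as_misses(self):
        gold = [Span(0, 4, "SIZE"), Span(6, 10, "SHAPE")]
        c = match_entities(gold, [])
        assert c.totals() == (0, 0, 2)

    def test_exact_mode_requires_identical_boundaries(self):
        gold = [Span(10, 15, "LESION")]
        pred = [Span(12, 15, "LESION")]
        assert match_entities(gold, pred, "partial").totals() == (1, 0, 0)
        assert match_entities(gold, pred, "exact").totals() == (0, 1, 1)

    def test_each_gold_matched_at_most_once(self):
        gold = [Span(0, 10, "LESION")]
        pred = [Span(0, 4, "LESION"), Span(5, 10, "LESION")]
        c = match_entities(gold, pred, "partial")
        assert c.totals() == (1, 1, 0)

    def test_overlapping_spans_within_one_list_rejected(self):
        bad = [Span(0, 5, "LESION"), Span(3, 8, "LESION")]
        with pytest.raises(ValidationError):
            match_entities(bad, [])

    def test_partial_tp_never_below_exact_tp(self, rng):
        """Relaxation monotonicity on random span configurations."""
        labels = ["LESION", "SIZE", "SHAPE"]
        for _ in range(200):
            def spans():
                out, pos = [], 0
                for _ in range(int(rng.integers(0, 6))):
                    pos += int(rng.integers(1, 6))
                    end = pos + int(rng.integers(1, 6))
                    out.append(Span(pos, end, labels[int(rng.integers(3))]))
                    pos = end
                return out
            g, p = spans(), spans()
            tp_partial = match_entities(g, p, "partial").totals()[0]
            tp_exact = match_entities(g, p, "exact").totals()[0]
            assert tp_partial >= tp_exact


class TestComputeMetrics:
    def test_balanced_counts_give_half(self):
        c = MatchCounts(tp={"LESION": 1}, fp={"SHAPE": 1}, fn={"LOCATION": 1})
        rep = compute_metrics(c)
        assert rep.micro == pytest.approx((0.5, 0.5, 0.5), abs=1e-12)

    def test_degenerate_no_entities_flagged(self):
        rep = compute_metrics(MatchCounts())
        assert rep.micro == (0.0, 0.0, 0.0)
        assert rep.no_entities

    def test_micro_from_summed_counts(self):
        c = MatchCounts(tp={"A": 2}, fp={"B": 1}, fn={"B": 1})
        rep = compute_metrics(c)
        assert rep.micro[0] == pytest.approx(2 / 3, abs=1e-12)
        assert rep.micro[1] == pytest.approx(2 / 3, abs=1e-12)

    def test_agrees_with_independent_arithmetic(self, rng):
        for _ in range(100):
            tp, fp, fn = (int(x) for x in rng.integers(0, 20, 3))
            rep = compute_metrics(MatchCounts(tp={"X": tp}, fp={"X": fp}, fn={"X": fn}))
            expect = independent_prf(tp, fp, fn)
            assert rep.per_label["X"] == pytest.approx(expect, abs=1e-12)
            assert rep.micro == pytest.approx(expect, abs=1e-12)

    def test_pooled_counts_equal_concatenated_documents(self, tiny_corpus):
        """Micro metrics from pooled per-document counts match metrics on
        one concatenated count set (pooling consistency)."""
        docs, _ = tiny_corpus
        preds = [d.with_spans(d.spans[:-1] if d.spans else []) for d in docs]
        pooled = evaluate_documents(docs, preds)
        merged = MatchCounts()
        for g, p in zip(docs, preds):
            merged = merged.add(match_entities(g.spans, p.spans))
        assert compute_metrics(pooled).micro == compute_metrics(merged).micro


class TestFolds:
    def test_five_folds_of_near_equal_size(self):
        folds = make_folds(1000, 5, seed=0)
        assert [len(f) for f in folds] == [200] * 5
        assert sorted(int(i) for f in folds for i in f) == list(range(1000))

    def test_two_documents_two_folds_each_tested_once(self):
        folds = make_folds(2, 2, seed=1)
        assert sorted(int(f[0]) for f in folds) == [0, 1]

    def test_fold_assignment_deterministic_per_seed(self):
        a = make_folds(50, 5, seed=9)
        b = make_folds(50, 5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_dataset_smaller_than_k_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(3, 5, seed=0)


class TestCrossValidation:
    def test_every_document_tested_exactly_once(self, tiny_corpus):
        docs, _ = tiny_corpus
        cfg = TaggerConfig(architecture="bilstm-crf", **FAST_CFG)
        report = crossvalidate(docs[:10], cfg, k=2, seed=0)
        tested = sum(r.counts.totals()[0] + r.counts.totals()[2] for r in report.folds)
        gold_total = sum(len(d.spans) for d in docs[:10])
        assert len(report.folds) == 2
        assert tested == gold_total  # TP+FN over folds covers every gold span

    def test_experiment_grid_cardinality_and_paired_folds(self, tiny_corpus):
        docs, _ = tiny_corpus
        cfg = TaggerConfig(architecture="bilstm-crf", **FAST_CFG)
        datasets = {f"D{i}": docs[: 6 + 2 * i] for i in range(5)}
        results = run_experiment_grid(datasets, {"crf": cfg}, k=2, seed=0)
        assert len(results) == 5
        assert all(isinstance(r, EvalReport) for r in results.values())
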