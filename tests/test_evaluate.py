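"""Evaluation metrics, fold construction, and the cross-validation loop."""
from __future__ import annotations

import numpy as np
import pytest

import ccipath as cp

CODE_POLICY = cp.TieBreakPolicy(mode="code")


def _ranking(qid: str, first_codes: list[int]) -> cp.RankedPrediction:
    """Build a ranking whose leading orders are ``first_codes``."""
    rest = [c for c in range(1, 12) if c not in first_codes]
    order = tuple(first_codes + rest)
    scores = tuple(float(11 - i) for i in range(11))
    return cp.RankedPrediction(qid, order, scores)


class TestLabelCountStatistics:
    def test_benchmark_multiplicity_lambda(self):
        """The reference multiplicity histogram gives lambda = 3606/3137 = 1.15."""
        tbl = cp.annotations_from_multiplicity()
        lam = cp.average_label_count(tbl)
        assert lam == pytest.approx(3606 / 3137)
        assert round(lam, 2) == 1.15

    def test_all_single_label(self):
        tbl = cp.AnnotationTable({"A": [1], "B": [5]})
        assert cp.average_label_count(tbl) == 1.0
        assert cp.random_baseline(tbl) == pytest.approx(1 / 11)
        assert cp.order_cutoff_k(tbl) == 1

    def test_two_compounds_arithmetic(self):
        tbl = cp.AnnotationTable({"A": [1, 2], "B": [3, 4, 5]})
        assert cp.average_label_count(tbl) == 2.5
        assert cp.order_cutoff_k(tbl) == 3

    def test_benchmark_baseline_and_k(self):
        tbl = cp.annotations_from_multiplicity()
        assert cp.random_baseline(tbl) == pytest.approx(0.1045, abs=5e-5)
        assert cp.order_cutoff_k(tbl) == 2

    def test_cutoff_at_exact_integer(self):
        tbl = cp.AnnotationTable({"A": [1, 2], "B": [3, 4]})  # lambda exactly 2.0
        assert cp.order_cutoff_k(tbl) == 2

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cp.average_label_count(cp.AnnotationTable({}))


class TestOrderAccuracy:
    def test_hand_built_toy(self):
        """3 of 4 first-order predictions hit their compound's true classes."""
        truths = cp.AnnotationTable({"a": [1], "b": [2], "c": [3, 4], "d": [5]})
        preds = [
            _ranking("a", [1]),    # hit
            _ranking("b", [2]),    # hit
            _ranking("c", [4]),    # hit (4 is one of c's true classes)
            _ranking("d", [6]),    # miss
        ]
        assert cp.order_accuracy(preds, truths, 1) == 0.75

    def test_perfect_first_order(self):
        truths = cp.AnnotationTable({"a": [3], "b": [7]})
        preds = [_ranking("a", [3]), _ranking("b", [7])]
        assert cp.order_accuracy(preds, truths, 1) == 1.0

    def test_accuracies_sum_to_lambda(self):
        """Any full ranking captures each true class at exactly one order."""
        rng = np.random.default_rng(3)
        truths = cp.AnnotationTable({
            f"c{i}": sorted(rng.choice(11, size=int(rng.integers(1, 5)), replace=False) + 1)
            for i in range(40)
        })
        pol = cp.TieBreakPolicy(mode="random", seed=9)
        preds = [
            cp.rank_classes(cp.ScoreVector(cid, rng.uniform(0, 3, 11)), pol)
            for cid in truths.ids
        ]
        total = sum(cp.order_accuracy(preds, truths, j) for j in range(1, 12))
        assert total == pytest.approx(cp.average_label_count(truths), abs=1e-12)

    def test_missing_truth_errors(self):
        truths = cp.AnnotationTable({"a": [1]})
        with pytest.raises(ValueError, match="without truth"):
            cp.order_accuracy([_ranking("zz", [1])], truths, 1)


class TestCoverage:
    def test_k11_is_total_under_both_semantics(self):
        truths = cp.AnnotationTable({"a": [1, 5], "b": [2]})
        preds = [_ranking("a", [3]), _ranking("b", [2])]
        assert cp.coverage(preds, truths, 11, "pair") == 1.0
        assert cp.coverage(preds, truths, 11, "subset") == 1.0

    def test_semantics_coincide_for_single_label(self):
        truths = cp.AnnotationTable({"a": [1], "b": [2], "c": [9]})
        preds = [_ranking("a", [1]), _ranking("b", [3]), _ranking("c", [9])]
        for k in range(1, 12):
            assert cp.coverage(preds, truths, k, "pair") == cp.coverage(preds, truths, k, "subset")

    def test_pair_coverage_identity_with_accuracies(self):
        rng = np.random.default_rng(11)
        truths = cp.AnnotationTable({
            f"c{i}": sorted(rng.choice(11, size=int(rng.integers(1, 4)), replace=False) + 1)
            for i in range(30)
        })
        preds = [
            cp.rank_classes(cp.ScoreVector(cid, rng.uniform(0, 1, 11)), CODE_POLICY)
            for cid in truths.ids
        ]
        lam = cp.average_label_count(truths)
        for k in (1, 2, 5):
            acc = [cp.order_accuracy(preds, truths, j) for j in range(1, k + 1)]
            assert cp.coverage(preds, truths, k, "pair") == pytest.approx(sum(acc) / lam)

    def test_published_overall_row_reconstruction(self):
        """First two order accuracies of 77.97% / 14.19% with lambda = 3606/3137
        put top-2 pair coverage just above 80%."""
        cov = cp.coverage_from_order_accuracies([0.7797, 0.1419], 3606 / 3137, 2)
        assert cov == pytest.approx(0.8017, abs=5e-4)
        assert cov > 0.80

    def test_k_out_of_range_errors(self):
        truths = cp.AnnotationTable({"a": [1]})
        with pytest.raises(ValueError):
            cp.coverage([_ranking("a", [1])], truths, 0)


class TestMakeFolds:
    def test_even_split_single_class(self):
        ann = cp.AnnotationTable({f"c{i}": [1] for i in range(100)})
        folds = cp.make_folds(ann, 5, seed=0)
        assert folds.sizes() == [20] * 5

    def test_determinism_and_seed_sensitivity(self):
        ann = cp.AnnotationTable({f"c{i}": [1 + i % 11] for i in range(60)})
        f1 = cp.make_folds(ann, 5, seed=4)
        f2 = cp.make_folds(ann, 5, seed=4)
        f3 = cp.make_folds(ann, 5, seed=5)
        assert f1.fold_of == f2.fold_of
        assert f1.fold_of != f3.fold_of

    def test_small_class_spreads_round_robin(self):
        """A 7-member class dealt into 5 folds lands 1 or 2 per fold."""
        labels = {f"r{i}": [7] for i in range(7)}
        labels.update({f"c{i}": [1] for i in range(43)})
        folds = cp.make_folds(cp.AnnotationTable(labels), 5, seed=2)
        per_fold = [sum(1 for i in range(7) if folds.fold_of[f"r{i}"] == f) for f in range(5)]
        assert set(per_fold) <= {1, 2}

    def test_every_compound_assigned_once(self):
        rng = np.random.default_rng(1)
        ann = cp.AnnotationTable({
            f"c{i}": sorted(rng.choice(11, size=int(rng.integers(1, 4)), replace=False) + 1)
            for i in range(57)
        })
        folds = cp.make_folds(ann, 5, seed=3)
        assert sorted(folds.fold_of) == list(ann.ids)
        assert max(folds.sizes()) - min(folds.sizes()) <= 5

    def test_too_many_folds_errors(self):
        ann = cp.AnnotationTable({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            cp.make_folds(ann, 5, seed=0)


class TestCrossValidate:
    def test_perfectly_assortative_world(self):
        """Neighbors that all share the query's single class give ACC_1 = L(1) = 1."""
        ann = cp.AnnotationTable(
            {f"a{i}": [1] for i in range(6)} | {f"b{i}": [2] for i in range(6)}
        )
        edges = [(f"a{i}", f"a{j}", 0.9) for i in range(6) for j in range(i + 1, 6)]
        edges += [(f"b{i}", f"b{j}", 0.8) for i in range(6) for j in range(i + 1, 6)]
        net = cp.InteractionNetwork.from_edges(edges)
        rep = cp.cross_validate(net, ann, n_folds=2, seed=0)
        assert rep.acc[0] == 1.0
        assert rep.coverage_pair[1] == 1.0
        assert rep.n_no_evidence == 0

    def test_identities_on_synthetic_run(self):
        cfg = cp.SyntheticConfig(n_compounds=250, seed=5)
        ann = cp.generate_annotations(cfg)
        net = cp.generate_network(ann, cfg)
        rep = cp.cross_validate(net, ann, n_folds=5, seed=5)
        assert rep.acc.sum() == pytest.approx(rep.lam, abs=1e-12)
        assert rep.coverage_pair[11] == pytest.approx(1.0, abs=1e-12)
        covs = [rep.coverage_pair[k] for k in range(1, 12)]
        assert all(a <= b + 1e-15 for a, b in zip(covs, covs[1:]))
        populated = rep.class_counts > 0
        assert rep.per_class_acc[populated].sum(axis=1) == pytest.approx(1.0)

    def test_edgeless_network_is_all_ties(self):
        ann = cp.generate_annotations(cp.SyntheticConfig(n_compounds=120, seed=8))
        rep = cp.cross_validate(cp.InteractionNetwork(), ann, n_folds=5, seed=8)
        assert rep.n_no_evidence == rep.n_evaluated == 120
        assert rep.acc.sum() == pytest.approx(rep.lam, abs=1e-12)

    def test_bit_identical_under_fixed_seed(self):
        cfg = cp.SyntheticConfig(n_compounds=150, seed=2)
        ann = cp.generate_annotations(cfg)
        net = cp.generate_network(ann, cfg)
        r1 = cp.cross_validate(net, ann, n_folds=5, seed=2, policy=CODE_POLICY)
        r2 = cp.cross_validate(net, ann, n_folds=5, seed=2, policy=CODE_POLICY)
        assert (r1.acc == r2.acc).all()
        assert (r1.per_class_acc == r2.per_class_acc).all()
        assert r1.coverage_pair == r2.coverage_pair

    def test_report_serialization(self, tmp_path):
        cfg = cp.SyntheticConfig(n_compounds=100, seed=1)
        ann = cp.generate_annotations(cfg)
        net = cp.generate_network(ann, cfg)
        rep = cp.cross_validate(net, ann, n_folds=5, seed=1)
        table, metrics = tmp_path / "t.tsv", tmp_path / "m.json"
        rep.write(table, metrics)
        lines = table.read_text().strip().split("\n")
        assert len(lines) == 13  # header + 11 class rows + overall
        assert lines[-1].startswith("overall\t")
        import json

        loaded = json.loads(metrics.read_text())
        assert loaded["lambda"] == pytest.approx(rep.lam)
        assert len(loaded["acc"]) == 11


class TestPredictIndependent:
    def test_novel_queries(self, novel_net, novel_ann):
        preds = cp.predict_independent(
            novel_net, novel_ann, ["C16265", "C14150"], CODE_POLICY
        )
        by_id = {p.query_id: p for p in preds}
        assert by_id["C16265"].order[:2] == (1, 2)
        assert by_id["C14150"].order[0] == 11
        assert not any(p.no_evidence for p in preds)

    def test_query_without_edges_flagged(self, novel_net, novel_ann):
        (pred,) = cp.predict_independent(novel_net, novel_ann, ["C99999"])
        assert pred.no_evidence
        assert sorted(pred.order) == list(range(1, 12))
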