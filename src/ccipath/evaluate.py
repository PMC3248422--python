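"""Evaluation framework: order accuracies, label-count statistics, coverage,
stratified fold construction, and the cross-validation orchestrator.

A ranking classifier over 11 classes is scored by its *order accuracies*:
ACC_j is the fraction of evaluated compounds whose j-th ranked class is one
of their true classes.  Because every prediction is a full permutation,
each true (compound, class) membership is captured at exactly one order, so
the 11 order accuracies sum exactly to the average label count lambda — an
identity this module asserts on every run.  Coverage L(k) is the fraction
of true memberships captured within the first k orders (pair semantics,
L(k) = sum_{j<=k} ACC_j / lambda); a stricter subset semantics — the whole
true set inside the top k — is available as an option.  The random-guess
baseline for ACC_1 is lambda/11.
"""
from __future__ import annotations

import json
import math
import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .datamodel import AnnotationTable, InteractionNetwork, RankedPrediction
from .predict import TieBreakPolicy, class_scores, rank_classes
from .registry import CLASS_CODES, N_CLASSES

COVERAGE_SEMANTICS = ("pair", "subset")

_SEED_MASK = 0x7FFFFFFF


def average_label_count(annotations: AnnotationTable) -> float:
    """Mean number of pathway classes per annotated compound (lambda)."""
    if len(annotations) == 0:
        raise ValueError("annotation table is empty")
    return float(annotations.multiplicities().mean())


def random_baseline(annotations: AnnotationTable) -> float:
    """Expected first-order accuracy of a uniformly random ranking, lambda/11."""
    return average_label_count(annotations) / N_CLASSES


def order_cutoff_k(annotations: AnnotationTable) -> int:
    """Smallest integer >= lambda: how many orders a user should inspect."""
    return math.ceil(average_label_count(annotations))


def _check_truths(predictions: Sequence[RankedPrediction], truths: AnnotationTable) -> None:
    missing = [p.query_id for p in predictions if p.query_id not in truths]
    if missing:
        raise ValueError(f"predictions without truth annotations: {missing[:5]}")


def order_accuracy(
    predictions: Sequence[RankedPrediction], truths: AnnotationTable, j: int
) -> float:
    """ACC_j: fraction of compounds whose j-th order class is a true class."""
    if not 1 <= j <= N_CLASSES:
        raise ValueError(f"order j must be in 1..{N_CLASSES}, got {j}")
    if not predictions:
        raise ValueError("no predictions to evaluate")
    _check_truths(predictions, truths)
    hits = sum(1 for p in predictions if truths.get(p.query_id)[p.order[j - 1] - 1] > 0)
    return hits / len(predictions)


def coverage(
    predictions: Sequence[RankedPrediction],
    truths: AnnotationTable,
    k: int,
    semantics: str = "pair",
) -> float:
    """L(k): how much of the truth the first k orders capture.

    ``pair`` (default): fraction of true (compound, class) memberships
    ranked at order <= k; identically sum_{j<=k} ACC_j / lambda.
    ``subset``: fraction of compounds whose *entire* true class set lies
    within the top k orders.
    """
    if not 1 <= k <= N_CLASSES:
        raise ValueError(f"k must be in 1..{N_CLASSES}, got {k}")
    if semantics not in COVERAGE_SEMANTICS:
        raise ValueError(f"semantics must be one of {COVERAGE_SEMANTICS}, got {semantics!r}")
    if not predictions:
        raise ValueError("no predictions to evaluate")
    _check_truths(predictions, truths)
    if semantics == "pair":
        captured = total = 0
        for p in predictions:
            true_codes = truths.subset([p.query_id]).classes_of(p.query_id)
            total += len(true_codes)
            captured += sum(1 for code in true_codes if p.rank_of(code) <= k)
        return captured / total
    covered = sum(
        1
        for p in predictions
        if all(p.rank_of(code) <= k for code in truths.subset([p.query_id]).classes_of(p.query_id))
    )
    return covered / len(predictions)


def coverage_from_order_accuracies(acc: Sequence[float], lam: float, k: int) -> float:
    """Pair-semantics L(k) from the first >=k order accuracies and lambda.

    Useful for recomputing coverage from a published accuracy table without
    access to the underlying per-compound rankings.
    """
    if not 1 <= k <= N_CLASSES or len(acc) < k:
        raise ValueError("need at least k order accuracies with 1 <= k <= 11")
    return float(sum(acc[:k]) / lam)


@dataclass(frozen=True)
class FoldAssignment:
    """A partition of annotated compounds into F cross-validation folds."""

    fold_of: Mapping[str, int]
    n_folds: int
    seed: int

    def members(self, fold: int) -> tuple[str, ...]:
        return tuple(sorted(c for c, f in self.fold_of.items() if f == fold))

    def sizes(self) -> list[int]:
        counts = [0] * self.n_folds
        for f in self.fold_of.values():
            counts[f] += 1
        return counts

    def __len__(self) -> int:
        return len(self.fold_of)


def make_folds(annotations: AnnotationTable, n_folds: int, seed: int) -> FoldAssignment:
    """Stratified fold assignment for multi-label compounds.

    Classes are processed from smallest to largest membership; each class's
    not-yet-assigned compounds are shuffled with the seeded generator and
    dealt round-robin across folds (a rolling cursor keeps overall fold
    sizes balanced).  Multi-label compounds are assigned when their rarest
    class is processed, so even classes with few members spread across all
    folds instead of piling into one.
    """
    if n_folds < 2:
        raise ValueError(f"need at least 2 folds, got {n_folds}")
    if len(annotations) < n_folds:
        raise ValueError(f"cannot split {len(annotations)} compounds into {n_folds} folds")
    rng = np.random.default_rng(seed & _SEED_MASK)
    members_of: dict[int, list[str]] = {code: [] for code in CLASS_CODES}
    for cid in annotations.ids:
        for code in annotations.classes_of(cid):
            members_of[code].append(cid)
    class_order = sorted(CLASS_CODES, key=lambda c: (len(members_of[c]), c))
    fold_of: dict[str, int] = {}
    cursor = 0
    for code in class_order:
        pending = [c for c in members_of[code] if c not in fold_of]
        rng.shuffle(pending)
        for cid in pending:
            fold_of[cid] = cursor % n_folds
            cursor += 1
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds, seed=seed)


@dataclass(frozen=True)
class CVReport:
    """Pooled results of a ranking cross-validation run.

    ``acc[j-1]`` is ACC_j over all pooled test predictions;
    ``per_class_acc[m-1, j-1]`` is, among compounds truly in class ``m``,
    the fraction whose j-th order prediction is class ``m`` (each row sums
    to 1 for populated classes).  ``coverage_pair[k]`` is L(k).
    """

    acc: np.ndarray
    per_class_acc: np.ndarray
    lam: float
    coverage_pair: Mapping[int, float]
    coverage_subset: Mapping[int, float]
    baseline: float
    k: int
    n_evaluated: int
    n_no_evidence: int
    n_folds: int
    seed: int
    class_counts: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))

    def to_dict(self) -> dict:
        """Machine-readable summary (JSON-serializable)."""
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "n_evaluated": self.n_evaluated,
            "n_no_evidence": self.n_no_evidence,
            "lambda": self.lam,
            "baseline": self.baseline,
            "k": self.k,
            "acc": [float(a) for a in self.acc],
            "coverage_pair": {str(k): float(v) for k, v in sorted(self.coverage_pair.items())},
            "coverage_subset": {str(k): float(v) for k, v in sorted(self.coverage_subset.items())},
            "per_class_acc": [[float(x) for x in row] for row in self.per_class_acc],
            "class_counts": [int(c) for c in self.class_counts],
        }

    def to_table(self) -> str:
        """Tab-separated accuracy table: one row per class plus an overall row.

        Percentages to 2 decimals, columns are the 11 prediction orders.
        """
        lines = ["class_code\t" + "\t".join(f"order_{j}" for j in range(1, N_CLASSES + 1))]
        for m in range(1, N_CLASSES + 1):
            row = "\t".join(f"{100 * self.per_class_acc[m - 1, j]:.2f}" for j in range(N_CLASSES))
            lines.append(f"{m}\t{row}")
        overall = "\t".join(f"{100 * a:.2f}" for a in self.acc)
        lines.append(f"overall\t{overall}")
        return "\n".join(lines) + "\n"

    def write(self, table_path: str | os.PathLike, metrics_path: str | os.PathLike | None = None) -> None:
        with open(table_path, "w", encoding="utf-8") as fh:
            fh.write(self.to_table())
        if metrics_path is not None:
            with open(metrics_path, "w", encoding="utf-8") as fh:
                json.dump(self.to_dict(), fh, indent=2)
                fh.write("\n")


def summarize_predictions(
    predictions: Sequence[RankedPrediction],
    truths: AnnotationTable,
    n_folds: int = 0,
    seed: int = 0,
) -> CVReport:
    """Pool ranked predictions against their truth table into a CVReport."""
    if not predictions:
        raise ValueError("no predictions to summarize")
    _check_truths(predictions, truths)
    n = len(predictions)
    truth_tbl = truths.subset([p.query_id for p in predictions])
    acc = np.zeros(N_CLASSES)
    per_class_hits = np.zeros((N_CLASSES, N_CLASSES))
    class_counts = np.zeros(N_CLASSES, dtype=np.int64)
    pair_captured = np.zeros(N_CLASSES)  # captured pairs per order
    total_pairs = 0
    for p in predictions:
        labels = truths.get(p.query_id)
        total_pairs += int(labels.sum())
        for j, code in enumerate(p.order):
            if labels[code - 1] > 0:
                acc[j] += 1
                per_class_hits[code - 1, j] += 1
                pair_captured[j] += 1
        for code in range(1, N_CLASSES + 1):
            if labels[code - 1] > 0:
                class_counts[code - 1] += 1
    acc /= n
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_acc = np.where(
            class_counts[:, None] > 0, per_class_hits / np.maximum(class_counts[:, None], 1), 0.0
        )
    lam = average_label_count(truth_tbl)
    cov_pair = {
        k: float(pair_captured[:k].sum() / total_pairs) for k in range(1, N_CLASSES + 1)
    }
    cov_subset = {
        k: coverage(predictions, truths, k, semantics="subset") for k in range(1, N_CLASSES + 1)
    }
    return CVReport(
        acc=acc,
        per_class_acc=per_class_acc,
        lam=lam,
        coverage_pair=cov_pair,
        coverage_subset=cov_subset,
        baseline=lam / N_CLASSES,
        k=math.ceil(lam),
        n_evaluated=n,
        n_no_evidence=sum(1 for p in predictions if p.no_evidence),
        n_folds=n_folds,
        seed=seed,
        class_counts=class_counts,
    )


def cross_validate(
    network: InteractionNetwork,
    annotations: AnnotationTable,
    n_folds: int = 5,
    seed: int = 0,
    policy: TieBreakPolicy | None = None,
) -> CVReport:
    """F-fold cross-validation of the ranking predictor.

    Each fold is held out in turn; test compounds are scored against the
    annotations of the training folds only, so an edge contributes evidence
    only when its partner endpoint is in the training folds.  Test compounds
    with no training-fold evidence are *kept* and ranked by the tie rule
    (their count is reported), which preserves the sum(ACC_j) = lambda
    identity.
    """
    policy = policy or TieBreakPolicy(mode="random", seed=seed)
    folds = make_folds(annotations, n_folds, seed)
    predictions: list[RankedPrediction] = []
    for f in range(n_folds):
        test_ids = folds.members(f)
        train_tbl = annotations.subset(
            [cid for cid in annotations.ids if folds.fold_of[cid] != f]
        )
        for qid in test_ids:
            predictions.append(rank_classes(class_scores(qid, network, train_tbl), policy))
    return summarize_predictions(predictions, annotations, n_folds=n_folds, seed=seed)


def predict_independent(
    network: InteractionNetwork,
    annotations: AnnotationTable,
    query_ids: Iterable[str],
    policy: TieBreakPolicy | None = None,
) -> list[RankedPrediction]:
    """Rank classes for query compounds against the full annotation table.

    The query itself never contributes evidence even if annotated.  Queries
    with no annotated interaction partner get an all-tie ranking flagged
    ``no_evidence``.
    """
    policy = policy or TieBreakPolicy()
    return [rank_classes(class_scores(qid, network, annotations), policy) for qid in query_ids]
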