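"""Guilt-by-association scoring and ranking of pathway classes for a query.

The model is first-shell weighted label voting: the likelihood score of
class ``j`` for a query compound is the sum of the interaction confidence
scores between the query and every annotated training compound belonging to
class ``j``.  A neighbor with several classes contributes its full weight
to each of them.  The 11 scores are then sorted in descending order to give
the 1st-, 2nd-, ..., 11th-order predicted classes; ties are broken either
by a seeded random order (the reference behaviour) or lowest-code-first
(deterministic, convenient in tests).
"""
from __future__ import annotations

import zlib
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .datamodel import AnnotationTable, InteractionNetwork, RankedPrediction, ScoreVector
from .registry import N_CLASSES

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


@dataclass(frozen=True)
class TieBreakPolicy:
    """How to order classes whose scores are exactly equal.

    ``random`` draws a per-query random order from a generator seeded by
    (seed, query id), so repeated runs with the same seed reproduce the
    same permutation while different queries with all-tied scores still
    receive decorrelated orders.  ``code`` orders ties lowest class code
    first.
    """

    mode: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "code"):
            raise ValueError(f"tie-break mode must be 'random' or 'code', got {self.mode!r}")

    def tie_keys(self, query_id: str) -> np.ndarray:
        """Secondary sort keys for the 11 classes (lower key wins a tie)."""
        if self.mode == "code":
            return np.arange(N_CLASSES)
        rng = np.random.default_rng(
            [self.seed & _SEED_MASK, zlib.crc32(query_id.encode("utf-8")) & _SEED_MASK]
        )
        return rng.permutation(N_CLASSES)


def neighbor_vector(
    query_id: str, network: InteractionNetwork, training_ids: Sequence[str]
) -> np.ndarray:
    """Confidence scores between the query and each training compound.

    Entry ``i`` is the edge weight between the query and ``training_ids[i]``
    (0 where no interaction is known).  The query's own entry is forced to
    zero: self-interaction is never evidence.
    """
    if len(set(training_ids)) != len(training_ids):
        raise ValueError("training_ids must not contain duplicates")
    nbrs = network.neighbors(query_id)
    vec = np.array([nbrs.get(cid, 0.0) for cid in training_ids], dtype=np.float64)
    for i, cid in enumerate(training_ids):
        if cid == query_id:
            vec[i] = 0.0
    return vec


def class_scores(
    query_id: str, network: InteractionNetwork, annotations: AnnotationTable
) -> ScoreVector:
    """Sum the query's interaction confidences per pathway class.

    Equivalent to the dot product of the neighbor vector with the label
    matrix of the annotated training compounds.  Accumulation runs in
    ascending training-id order so results are bit-reproducible.
    """
    if len(annotations) == 0:
        raise ValueError("annotation table is empty")
    scores = np.zeros(N_CLASSES, dtype=np.float64)
    for partner, w in sorted(network.neighbors(query_id).items()):
        if partner == query_id:
            continue
        labels = annotations.get(partner)
        if labels is not None:
            scores += w * labels
    return ScoreVector(query_id, scores)


def rank_classes(scores: ScoreVector, policy: TieBreakPolicy | None = None) -> RankedPrediction:
    """Sort the 11 class scores in descending order into a full ranking."""
    policy = policy or TieBreakPolicy()
    keys = policy.tie_keys(scores.query_id)
    idx = sorted(range(N_CLASSES), key=lambda i: (-scores.scores[i], keys[i]))
    return RankedPrediction(
        query_id=scores.query_id,
        order=tuple(i + 1 for i in idx),
        scores=tuple(float(scores.scores[i]) for i in idx),
        no_evidence=scores.no_evidence,
        tie_seed=policy.seed if policy.mode == "random" else None,
    )


def predict_top(scores: ScoreVector, policy: TieBreakPolicy | None = None) -> int:
    """The highest-scoring class code (the 1st-order prediction)."""
    return rank_classes(scores, policy).order[0]
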