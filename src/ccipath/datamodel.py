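"""In-memory containers: annotations, the interaction network, scores, rankings.

The prediction problem is multi-label: a compound may participate in several
of the 11 metabolic pathway classes.  Annotations are therefore binary
11-vectors, the network is an undirected graph whose edge weights are
interaction confidence scores in (0, 1], and a prediction is a full
descending-order permutation of the 11 class codes rather than a single
label.
"""
from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .registry import N_CLASSES, validate_code


class AnnotationTable:
    """Maps compound ids to binary pathway-class label vectors.

    Each compound carries an 11-vector with ones at the classes it belongs
    to; compounds without any class are rejected (unannotated compounds are
    excluded from benchmarks before they reach this container).
    """

    def __init__(self, labels: Mapping[str, Iterable[int]]):
        self._labels: dict[str, np.ndarray] = {}
        for cid, codes in labels.items():
            vec = np.zeros(N_CLASSES, dtype=np.float64)
            for code in codes:
                vec[validate_code(int(code)) - 1] = 1.0
            if not vec.any():
                raise ValueError(f"compound {cid!r} has no pathway class")
            self._labels[str(cid)] = vec

    @classmethod
    def from_vectors(cls, vectors: Mapping[str, np.ndarray]) -> "AnnotationTable":
        table = cls({})
        for cid, vec in vectors.items():
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (N_CLASSES,) or not set(np.unique(vec)) <= {0.0, 1.0}:
                raise ValueError(f"label vector for {cid!r} is not a binary {N_CLASSES}-vector")
            if not vec.any():
                raise ValueError(f"compound {cid!r} has no pathway class")
            table._labels[str(cid)] = vec.copy()
        return table

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, cid: str) -> bool:
        return cid in self._labels

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._labels))

    @property
    def ids(self) -> tuple[str, ...]:
        """All compound ids, sorted."""
        return tuple(sorted(self._labels))

    def get(self, cid: str) -> Optional[np.ndarray]:
        """Label vector of ``cid`` (read-only view), or None if unannotated."""
        vec = self._labels.get(cid)
        if vec is None:
            return None
        view = vec.view()
        view.flags.writeable = False
        return view

    def classes_of(self, cid: str) -> tuple[int, ...]:
        """The class codes of ``cid`` in ascending order."""
        vec = self._labels[cid]
        return tuple(int(j) + 1 for j in np.flatnonzero(vec))

    def multiplicities(self) -> np.ndarray:
        """Number of classes per compound, in sorted-id order."""
        return np.array([self._labels[c].sum() for c in sorted(self._labels)])

    def class_counts(self) -> np.ndarray:
        """Per-class compound counts (length 11); sums to N only if single-label."""
        if not self._labels:
            return np.zeros(N_CLASSES, dtype=np.int64)
        return np.sum(list(self._labels.values()), axis=0).astype(np.int64)

    def label_matrix(self, order: Iterable[str]) -> np.ndarray:
        """Stack label vectors row-wise for the given id order."""
        return np.array([self._labels[c] for c in order], dtype=np.float64)

    def subset(self, ids: Iterable[str]) -> "AnnotationTable":
        """Restriction to ``ids`` (silently dropping unknown ids)."""
        sub = AnnotationTable({})
        for cid in ids:
            if cid in self._labels:
                sub._labels[cid] = self._labels[cid]
        return sub


class InteractionNetwork:
    """Undirected weighted graph of chemical-chemical interaction confidences.

    Edge weights live in (0, 1]; a missing edge means confidence 0.
    Self-edges are never stored — a compound's interaction with itself does
    not count as evidence.  Duplicate or reversed listings of a pair merge
    to a single edge carrying the maximum reported weight.
    """

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractionNetwork":
        net = cls()
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    def add_edge(self, a: str, b: str, weight: float) -> bool:
        """Insert (or max-merge) an edge; returns True if a duplicate was merged."""
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-edge on {a!r} is not allowed")
        w = float(weight)
        if not 0.0 < w <= 1.0:
            raise ValueError(f"edge weight must be in (0, 1], got {w!r} for ({a!r}, {b!r})")
        existing = self._adj.get(a, {}).get(b)
        merged = existing is not None
        w = max(w, existing) if merged else w
        self._adj.setdefault(a, {})[b] = w
        self._adj.setdefault(b, {})[a] = w
        return merged

    def weight(self, a: str, b: str) -> float:
        """Confidence score of the pair, 0.0 if absent or a == b."""
        if a == b:
            return 0.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, cid: str) -> Mapping[str, float]:
        """Partners of ``cid`` with their confidence scores (possibly empty)."""
        return dict(self._adj.get(cid, {}))

    @property
    def compounds(self) -> tuple[str, ...]:
        """Compounds with at least one edge, sorted."""
        return tuple(sorted(self._adj))

    @property
    def n_compounds(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (a, b, w) with a < b, sorted."""
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield a, b, self._adj[a][b]

    def __len__(self) -> int:
        return self.n_edges


@dataclass(frozen=True)
class ScoreVector:
    """The 11 class likelihood scores of one query compound.

    ``scores[j-1]`` is the sum of the query's interaction confidences with
    annotated training compounds belonging to class ``j``; it is zero iff
    the query has no annotated neighbor in that class.
    """

    query_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} scores, got shape {scores.shape}")
        if (scores < 0).any():
            raise ValueError("class scores must be non-negative")
        scores.flags.writeable = False
        object.__setattr__(self, "scores", scores)

    def score_of(self, code: int) -> float:
        return float(self.scores[validate_code(code) - 1])

    @property
    def no_evidence(self) -> bool:
        """True when every class score is zero (no annotated neighbors)."""
        return not self.scores.any()


@dataclass(frozen=True)
class RankedPrediction:
    """A descending-order permutation of the 11 class codes for one query.

    ``order[r]`` is the class predicted at rank r+1 (the "(r+1)-th order"
    prediction); ``scores`` are the correspondingly sorted class scores.
    ``no_evidence`` flags full-tie rankings produced without any annotated
    neighbor, so reports can count unpredictable compounds.
    """

    query_id: str
    order: tuple[int, ...]
    scores: tuple[float, ...]
    no_evidence: bool = False
    tie_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(1, N_CLASSES + 1)):
            raise ValueError(f"order must be a permutation of 1..{N_CLASSES}, got {self.order}")
        if len(self.scores) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} sorted scores")
        if any(self.scores[i] < self.scores[i + 1] for i in range(N_CLASSES - 1)):
            raise ValueError("sorted scores must be non-increasing")

    def rank_of(self, code: int) -> int:
        """1-based rank at which ``code`` is predicted."""
        return self.order.index(validate_code(code)) + 1
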