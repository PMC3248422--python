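"""Readers and writers for interaction, annotation, and prediction tables.

All files are UTF-8, tab-separated, with optional ``#`` comment lines and an
optional header row.  Interaction tables follow the STITCH layout (two
chemical ids plus a confidence score, extra evidence-channel columns
ignored); confidence scores come either as floats in [0, 1] ("unit" scale)
or as the 0-999 integers STITCH distributes ("stitch999" scale, divided by
1000 on input).
"""
from __future__ import annotations

import logging
import math
import os
from collections.abc import Iterable

from .datamodel import AnnotationTable, InteractionNetwork, RankedPrediction
from .registry import N_CLASSES

logger = logging.getLogger(__name__)

ANNOTATION_DIALECTS = ("delimited", "pairs")
SCORE_SCALES = ("unit", "stitch999")

_CODE_SEPARATORS = str.maketrans(";", ",")

PREDICTION_HEADER = ("query_id", "rank", "class_code", "score")


def _data_lines(path: str | os.PathLike) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_annotations(path: str | os.PathLike, dialect: str = "delimited") -> AnnotationTable:
    """Read a compound -> pathway-class table.

    Two dialects are accepted, matching the shapes KEGG exports appear in:

    - ``delimited``: one row per compound, second column packs the class
      codes separated by commas or semicolons (``C00106<TAB>4;6;8``);
    - ``pairs``: one row per (compound, class code) pair.

    Extra columns (e.g. compound names) are ignored.  Duplicate
    (compound, code) assignments collapse to a single indicator.
    """
    if dialect not in ANNOTATION_DIALECTS:
        raise ValueError(f"unknown annotation dialect {dialect!r}; expected one of {ANNOTATION_DIALECTS}")
    codes_of: dict[str, set[int]] = {}
    first_row = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected at least 2 tab-separated columns")
        cid, payload = fields[0].strip(), fields[1].strip()
        if not cid:
            raise ValueError(f"{path}: line {lineno}: empty compound id")
        if dialect == "delimited":
            tokens = [t.strip() for t in payload.translate(_CODE_SEPARATORS).split(",")]
        else:
            tokens = [payload]
        tokens = [t for t in tokens if t]
        if first_row:
            first_row = False
            if tokens and all(not _is_number(t) for t in tokens):
                continue  # header row
        if not tokens:
            raise ValueError(f"{path}: line {lineno}: compound {cid!r} has no class codes")
        codes: list[int] = []
        for tok in tokens:
            try:
                code = int(tok)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: class code {tok!r} is not an integer") from None
            if not 1 <= code <= N_CLASSES:
                raise ValueError(f"{path}: line {lineno}: class code {code} outside 1..{N_CLASSES}")
            codes.append(code)
        codes_of.setdefault(cid, set()).update(codes)
    return AnnotationTable({cid: sorted(codes) for cid, codes in codes_of.items()})


def read_interactions(path: str | os.PathLike, score_scale: str = "unit") -> InteractionNetwork:
    """Read a chemical-chemical interaction table into a network.

    Pairs listed in both directions, or repeatedly, merge into a single
    undirected edge carrying the maximum weight (warned).  Self-pairs are
    dropped with a warning; zero-score rows are dropped silently (absence
    of an edge already means score 0).
    """
    if score_scale not in SCORE_SCALES:
        raise ValueError(f"unknown score scale {score_scale!r}; expected one of {SCORE_SCALES}")
    net = InteractionNetwork()
    score_col = 2
    first_row = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: expected at least 3 tab-separated columns")
        if first_row:
            first_row = False
            if len(fields) > 3:
                logger.info("%s: %d extra columns ignored", path, len(fields) - 3)
            if not _is_number(fields[2].strip()):
                # header row: locate the score column by name
                lowered = [f.strip().lower() for f in fields]
                for name in ("score", "combined_score"):
                    if name in lowered:
                        score_col = lowered.index(name)
                        break
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: no 'score' or 'combined_score' column in header"
                    )
                continue
        a, b, token = fields[0].strip(), fields[1].strip(), fields[score_col].strip()
        if score_scale == "stitch999":
            try:
                raw = int(token)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: stitch999 score {token!r} is not an integer") from None
            if not 0 <= raw <= 999:
                raise ValueError(f"{path}: line {lineno}: stitch999 score {raw} outside 0..999")
            w = raw / 1000.0
        else:
            try:
                w = float(token)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: score {token!r} is not numeric") from None
            if not math.isfinite(w) or w < 0.0 or w > 1.0:
                raise ValueError(f"{path}: line {lineno}: unit-scale score {w} outside [0, 1]")
        if a == b:
            logger.warning("%s: line %d: self-pair %r dropped", path, lineno, a)
            continue
        if w == 0.0:
            continue
        if net.add_edge(a, b, w):
            logger.warning("%s: line %d: duplicate pair (%s, %s); keeping maximum weight", path, lineno, a, b)
    return net


def restrict_to_annotated(network: InteractionNetwork, annotations: AnnotationTable) -> InteractionNetwork:
    """Keep only the edges whose *both* endpoints carry pathway annotations.

    This is the benchmark assembly rule: interaction evidence is usable for
    training/evaluation only between compounds of known function.  The
    returned network's ``n_edges`` / ``n_compounds`` report what survived.
    """
    kept = InteractionNetwork()
    for a, b, w in network.edges():
        if a in annotations and b in annotations:
            kept.add_edge(a, b, w)
    return kept


def write_interactions(network: InteractionNetwork, path: str | os.PathLike) -> None:
    """Write a network as a sorted three-column interaction TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chemical_a\tchemical_b\tscore\n")
        for a, b, w in network.edges():
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def write_annotations(annotations: AnnotationTable, path: str | os.PathLike) -> None:
    """Write an annotation table in the delimited dialect, sorted by id."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound\tclass_codes\n")
        for cid in annotations.ids:
            fh.write(f"{cid}\t{','.join(map(str, annotations.classes_of(cid)))}\n")


def write_predictions(predictions: Iterable[RankedPrediction], path: str | os.PathLike) -> None:
    """Write ranked predictions, one row per (query, rank), sorted by query then rank.

    Scores are printed to 3 decimals, the precision at which interaction
    confidence scores are distributed.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_HEADER) + "\n")
        for pred in sorted(predictions, key=lambda p: p.query_id):
            for rank, (code, score) in enumerate(zip(pred.order, pred.scores), start=1):
                fh.write(f"{pred.query_id}\t{rank}\t{code}\t{score:.3f}\n")


def read_predictions(path: str | os.PathLike) -> list[RankedPrediction]:
    """Read back a prediction TSV written by :func:`write_predictions`."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _data_lines(path):
        if [f.strip().lower() for f in fields[:2]] == ["query_id", "rank"]:
            continue
        if len(fields) < 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 columns")
        qid, rank, code, score = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        rows.setdefault(qid, []).append((rank, code, score))
    preds = []
    for qid, entries in sorted(rows.items()):
        entries.sort()
        order = tuple(code for _, code, _ in entries)
        scores = tuple(score for _, _, score in entries)
        preds.append(RankedPrediction(qid, order, scores, no_evidence=not any(scores)))
    return preds
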