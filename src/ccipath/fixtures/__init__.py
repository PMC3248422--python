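"""Packaged worked-example fixtures.

Two small curated neighborhoods are shipped as plain TSV:

- the dihydrouracil (C00429) neighborhood — 32 annotated STITCH partners —
  whose class-score sums and ranking are known by hand;
- the neighborhoods of two un-annotated query compounds,
  N-acetylgalactosamine 4-sulfate (C16265) and cyclopropylamine (C14150),
  used to exercise independent prediction.
"""
from __future__ import annotations

from importlib import resources

from ..datamodel import AnnotationTable, InteractionNetwork
from ..io import read_annotations, read_interactions


def fixture_path(name: str):
    """Filesystem path of a packaged fixture (context-manager-free access)."""
    return resources.files(__package__) / name


def dihydrouracil_network() -> InteractionNetwork:
    """The 32-edge interaction neighborhood of dihydrouracil (C00429)."""
    return read_interactions(fixture_path("dihydrouracil_interactions.tsv"))


def dihydrouracil_annotations() -> AnnotationTable:
    """Pathway classes of dihydrouracil and its 32 partners (33 compounds)."""
    return read_annotations(fixture_path("dihydrouracil_annotations.tsv"))


def novel_query_network() -> InteractionNetwork:
    """Neighborhoods of the two un-annotated queries C16265 and C14150."""
    return read_interactions(fixture_path("novel_query_interactions.tsv"))


def novel_query_annotations() -> AnnotationTable:
    """Pathway classes of the 37 annotated partners of the two queries."""
    return read_annotations(fixture_path("novel_query_annotations.tsv"))
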