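"""ccipath: metabolic pathway-class prediction from chemical-chemical interactions.

Given a query compound and a network of interaction confidence scores, the
predictor sums the scores of the query's annotated neighbors per pathway
class and ranks the 11 top-level KEGG metabolism categories in descending
order of that evidence.  The package also ships the ranking-specific
evaluation framework (order accuracies, average label count, top-k
coverage, stratified cross-validation) and a synthetic benchmark generator.
"""
from __future__ import annotations

from .datamodel import (
    AnnotationTable,
    InteractionNetwork,
    RankedPrediction,
    ScoreVector,
)
from .evaluate import (
    CVReport,
    FoldAssignment,
    average_label_count,
    coverage,
    coverage_from_order_accuracies,
    cross_validate,
    make_folds,
    order_accuracy,
    order_cutoff_k,
    predict_independent,
    random_baseline,
    summarize_predictions,
)
from .io import (
    read_annotations,
    read_interactions,
    read_predictions,
    restrict_to_annotated,
    write_annotations,
    write_interactions,
    write_predictions,
)
from .predict import TieBreakPolicy, class_scores, neighbor_vector, predict_top, rank_classes
from .registry import CLASS_CODES, N_CLASSES, PATHWAY_CLASSES, class_name
from .simulate import (
    BENCHMARK_CLASS_COUNTS,
    BENCHMARK_MULTIPLICITY,
    SyntheticConfig,
    annotations_from_multiplicity,
    generate_annotations,
    generate_network,
    single_label_table,
)

__version__ = "0.1.0"

__all__ = [
    "AnnotationTable",
    "InteractionNetwork",
    "RankedPrediction",
    "ScoreVector",
    "TieBreakPolicy",
    "CVReport",
    "FoldAssignment",
    "SyntheticConfig",
    "PATHWAY_CLASSES",
    "CLASS_CODES",
    "N_CLASSES",
    "BENCHMARK_CLASS_COUNTS",
    "BENCHMARK_MULTIPLICITY",
    "class_name",
    "read_annotations",
    "read_interactions",
    "read_predictions",
    "restrict_to_annotated",
    "write_annotations",
    "write_interactions",
    "write_predictions",
    "neighbor_vector",
    "class_scores",
    "rank_classes",
    "predict_top",
    "average_label_count",
    "random_baseline",
    "order_cutoff_k",
    "order_accuracy",
    "coverage",
    "coverage_from_order_accuracies",
    "make_folds",
    "cross_validate",
    "summarize_predictions",
    "predict_independent",
    "generate_annotations",
    "generate_network",
    "annotations_from_multiplicity",
    "single_label_table",
    "__version__",
]
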