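"""The fixed registry of the 11 top-level KEGG metabolism categories.

Every label vector, score vector and ranking in this package is indexed
against this ordering; class *codes* are the 1-based integers printed in
KEGG pathway maps, while array *indices* are 0-based.
"""
from __future__ import annotations

PATHWAY_CLASSES: tuple[tuple[int, str], ...] = (
    (1, "Carbohydrate Metabolism"),
    (2, "Energy Metabolism"),
    (3, "Lipid Metabolism"),
    (4, "Nucleotide Metabolism"),
    (5, "Amino Acid Metabolism"),
    (6, "Metabolism of Other Amino Acids"),
    (7, "Glycan Biosynthesis and Metabolism"),
    (8, "Metabolism of Cofactors and Vitamins"),
    (9, "Metabolism of Terpenoids and Polyketides"),
    (10, "Biosynthesis of Other Secondary Metabolites"),
    (11, "Xenobiotics Biodegradation and Metabolism"),
)

N_CLASSES: int = len(PATHWAY_CLASSES)
CLASS_CODES: tuple[int, ...] = tuple(code for code, _ in PATHWAY_CLASSES)

_NAME_OF = dict(PATHWAY_CLASSES)


def class_name(code: int) -> str:
    """Human-readable name of a pathway class code (1-11)."""
    try:
        return _NAME_OF[code]
    except KeyError:
        raise ValueError(f"pathway class code must be in 1..{N_CLASSES}, got {code!r}") from None


def validate_code(code: int) -> int:
    """Return ``code`` if it is a valid class code, else raise ValueError."""
    if not isinstance(code, (int,)) or isinstance(code, bool) or not 1 <= code <= N_CLASSES:
        raise ValueError(f"pathway class code must be an integer in 1..{N_CLASSES}, got {code!r}")
    return code
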