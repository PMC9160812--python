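"""Flag genes encoding secreted or membrane-bound proteins.

Annotation is a two-column TSV (``gene``, semicolon-separated subcellular
``locations``); a gene is flagged when any of its locations falls in the
configured term set. A small synthetic fixture table covering the genes of
the reference model (and common lung epithelial markers) ships with the
package; supplying a full Human Protein Atlas subcellular-localization
export instead works with the same reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "GeneAnnotation",
    "DEFAULT_SECRETED_MEMBRANE_TERMS",
    "default_annotation_path",
    "load_annotation",
    "filter_secreted_membrane",
]

# Location terms counted as "secreted or membrane-bound" (case-insensitive).
DEFAULT_SECRETED_MEMBRANE_TERMS = frozenset({
    "secreted",
    "plasma membrane",
    "cell membrane",
    "membrane",
    "cell junctions",
})


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    locations: frozenset = field(default_factory=frozenset)
    secreted_or_membrane: bool = False


def default_annotation_path():
    """Path to the packaged synthetic annotation fixture."""
    return resources.files("scmalig.data") / "subcellular_fixture_synthetic.tsv"


def load_annotation(table_path=None, terms=DEFAULT_SECRETED_MEMBRANE_TERMS):
    """Read an annotation TSV into a ``gene -> GeneAnnotation`` mapping.

    Gene symbols are upper-cased; genes absent from the table are simply
    absent from the mapping (no default flag). Malformed rows raise with
    their line number.
    """
    if table_path is None:
        table_path = default_annotation_path()
    terms = {t.lower() for t in terms}
    mapping: dict[str, GeneAnnotation] = {}
    with open(table_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "gene":
                continue  # header
            if len(parts) != 2:
                raise ValueError(
                    f"{table_path}: malformed row at line {lineno}: {line!r}"
                )
            gene = parts[0].strip().upper()
            if not gene:
                raise ValueError(f"{table_path}: empty gene at line {lineno}")
            locs = frozenset(
                t.strip() for t in parts[1].split(";") if t.strip()
            )
            flag = any(t.lower() in terms for t in locs)
            mapping[gene] = GeneAnnotation(gene, locs, flag)
    return mapping


def filter_secreted_membrane(genes, annotation) -> list:
    """Subset of ``genes`` flagged secreted-or-membrane-bound.

    Genes missing from the annotation are excluded and reported in a
    warning. Output order follows input order; deterministic.
    """
    missing = [g for g in genes if str(g).upper() not in annotation]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) missing from annotation, excluded: "
            f"{missing[:10]}",
            stacklevel=2,
        )
    return [g for g in genes
            if str(g).upper() in annotation
            and annotation[str(g).upper()].secreted_or_membrane]
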