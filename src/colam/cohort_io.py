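"""Readers and writers for the pipeline's file formats.

Formats: TSV/CSV expression matrices (gene id in the first column, sample
ids in the header), TSV sample annotations (``sample_id`` and ``class``
columns required), GMT gene-set files, one-symbol-per-line gene lists, and
TSV screen tables.  Delimiters are sniffed (tab default, comma accepted).

Genes with any missing value are dropped with a logged count rather than
imputed: the downstream statistics are rank- and threshold-based and no
imputation rule would be neutral for them.  Symbols are canonicalized
upper-case for comparison with original casing preserved for display.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .models import (
    ColamError,
    DuplicateIdError,
    EmptyGeneSetError,
    ExpressionCohort,
    GeneSet,
    SampleMismatchError,
    canonical,
)

logger = logging.getLogger(__name__)

HUMAN = "human"
MOUSE = "mouse"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_matrix(
    path: str | Path, annotation_path: str | Path, cohort_id: str | None = None
) -> ExpressionCohort:
    """Read an expression matrix plus its sample-annotation table.

    The first matrix column is taken as the gene id regardless of its
    header label.  Genes containing missing values are dropped (logged);
    duplicate gene ids after canonicalization or a sample mismatch between
    the two files raise named errors.  Genes and samples are returned in
    canonical (lexicographic) order so reading is order-insensitive.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    matrix = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    n_missing = int(matrix.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d gene(s) with missing values", path.name, n_missing)
        matrix = matrix.dropna(axis=0)

    keys = matrix.index.map(canonical)
    if keys.duplicated().any():
        offenders = sorted(set(matrix.index[keys.duplicated(keep=False)]))
        raise DuplicateIdError(f"{path.name}: duplicate gene ids after canonicalization: {offenders}")

    ann = pd.read_csv(annotation_path, sep=_sniff_sep(annotation_path))
    if "sample_id" not in ann.columns or "class" not in ann.columns:
        raise ColamError(f"{annotation_path.name}: annotations need 'sample_id' and 'class' columns")
    ann = ann.set_index(ann["sample_id"].astype(str)).drop(columns=["sample_id"])

    mat_samples, ann_samples = set(matrix.columns), set(ann.index)
    if mat_samples != ann_samples:
        missing = sorted(mat_samples - ann_samples)
        extra = sorted(ann_samples - mat_samples)
        raise SampleMismatchError(
            f"{path.name} vs {annotation_path.name}: matrix samples without annotation "
            f"{missing}; annotated samples absent from matrix {extra}"
        )

    cohort = ExpressionCohort(cohort_id or path.stem, matrix, ann)
    return cohort.sorted_copy()


def write_expression_cohort(
    cohort: ExpressionCohort, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    """Write the matrix and annotations as TSV (gene id first column)."""
    matrix = cohort.matrix.copy()
    matrix.index.name = "gene"
    matrix.to_csv(matrix_path, sep="\t", float_format="%.10g")
    ann = cohort.annotations.copy()
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep="\t")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file, or a one-symbol-per-line list.

    GMT lines are ``name<TAB>description<TAB>symbol...``; a file without
    tabs is treated as a single plain list named after the file stem.
    Duplicate symbols within a set are collapsed with a warning; an empty
    set raises :class:`EmptyGeneSetError`.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyGeneSetError(f"{path.name}: no gene sets found")
    if any("\t" in ln for ln in lines):
        sets = []
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ColamError(f"{path.name}: malformed GMT line {ln[:60]!r}")
            name, _desc, *symbols = fields
            symbols = [s for s in symbols if s.strip()]
            if not symbols:
                raise EmptyGeneSetError(f"{path.name}: set {name!r} is empty")
            sets.append(GeneSet(name, symbols))
        return sets
    return [GeneSet(path.stem, lines)]


def read_gene_list(path: str | Path) -> GeneSet:
    """Read a one-symbol-per-line gene list as a single set."""
    sets = read_gene_sets(path)
    if len(sets) != 1:
        raise ColamError(f"{Path(path).name}: expected a plain list, found GMT content")
    return sets[0]


def write_gmt(sets: Sequence[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a screen TSV with at least (gene, relative_activity) columns."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"gene", "relative_activity"}
    if not required <= set(table.columns):
        raise ColamError(f"{path.name}: screen table needs columns {sorted(required)}")
    return table


def map_symbols_across_species(
    genes: Sequence[str],
    from_species: str,
    to_species: str,
    mapping_table: Mapping[str, str] | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Map gene symbols between human and mouse nomenclature.

    With an explicit ``mapping_table`` (keys matched case-insensitively)
    the table wins; symbols absent from it fall back to the naive case
    convention (human ALL-CAPS <-> mouse Title-case), which always
    produces a symbol.  Returns the mapped list plus a report with keys
    ``via_table``, ``via_convention`` and ``unmapped`` — nothing is
    silently dropped.
    """
    for sp in (from_species, to_species):
        if sp not in (HUMAN, MOUSE):
            raise ColamError(f"unknown species {sp!r}; expected {HUMAN!r} or {MOUSE!r}")
    table = {canonical(k): v for k, v in (mapping_table or {}).items()}

    def convention(symbol: str) -> str:
        return symbol.upper() if to_species == HUMAN else symbol.capitalize()

    mapped: list[str] = []
    report: dict[str, list[str]] = {"via_table": [], "via_convention": [], "unmapped": []}
    for g in genes:
        key = canonical(g)
        if key in table:
            mapped.append(table[key])
            report["via_table"].append(g)
        else:
            mapped.append(convention(g))
            report["via_convention"].append(g)
    return mapped, report
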