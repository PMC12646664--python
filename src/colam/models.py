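"""Core containers and exceptions for the ColAM signature workflow.

The pipeline revolves around a handful of shapes: an expression cohort
(genes x samples plus per-sample annotations), gene sets with optional
per-gene metadata, per-gene refinement statistics, per-sample composite
score tables, and per-candidate evidence records.  Gene symbols are
compared case-insensitively (human CCDC88A vs mouse Ccdc88a) while the
original casing is preserved for display.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# cluster labels of the parent macrophage-state signature
REACTIVE = "reactive"
TOLERANT = "tolerant"
CLUSTERS = (REACTIVE, TOLERANT)

# regulation directions for a gene in a case/control contrast
UP = "up_in_case"
DOWN = "down_in_case"
UNDETERMINED = "undetermined"

CONTROL = "control"
CASE = "case"


class ColamError(Exception):
    """Base class for all package errors."""


class DuplicateIdError(ColamError):
    """Duplicate gene or sample identifiers after canonicalization."""


class SampleMismatchError(ColamError):
    """Expression matrix and annotation table disagree on samples."""


class SingleClassError(ColamError):
    """An operation requiring two classes saw only one."""


class DegenerateValuesError(ColamError):
    """All values equal; a step threshold cannot be fit."""


class EmptyGeneSetError(ColamError):
    """A gene set on disk contained no symbols."""


class NoSignatureGenesError(ColamError):
    """None of a gene set's members are present in the cohort."""


class MissingControlPhaseError(ColamError):
    """Temporal profiling requires a designated control phase."""


class CandidateNotInUniverseError(ColamError):
    """The planted candidate must be drawn from the gene universe."""


class InvalidActivityError(ColamError):
    """Screen reporter activities must be non-negative."""


class ConfigError(ColamError):
    """Pipeline configuration failed validation."""


def canonical(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped, upper-cased."""
    return str(symbol).strip().upper()


def _check_unique(names: Iterable[str], what: str) -> None:
    seen: dict[str, str] = {}
    dupes: list[str] = []
    for name in names:
        key = canonical(name)
        if key in seen:
            dupes.append(name)
        else:
            seen[key] = name
    if dupes:
        raise DuplicateIdError(f"duplicate {what} after canonicalization: {sorted(set(dupes))}")


@dataclass
class ExpressionCohort:
    """A genes x samples expression matrix with per-sample annotations.

    Parameters
    ----------
    cohort_id:
        Free-form identifier (e.g. a GEO accession or a simulation tag).
    matrix:
        Numeric DataFrame, rows indexed by gene symbol, columns by sample id.
        Values are normalized expression on an (arbitrary) log scale.
    annotations:
        DataFrame indexed by sample id with at least a ``class`` column
        whose values are ``control`` / ``case``; optional columns include
        ``phase``, ``treatment`` and ``species``.
    """

    cohort_id: str
    matrix: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.matrix, pd.DataFrame):
            self.matrix = pd.DataFrame(self.matrix)
        _check_unique(self.matrix.index.astype(str), "gene ids")
        _check_unique(self.matrix.columns.astype(str), "sample ids")
        values = self.matrix.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise ColamError(f"cohort {self.cohort_id!r}: non-finite expression values")
        if "class" not in self.annotations.columns:
            raise ColamError(f"cohort {self.cohort_id!r}: annotations lack a 'class' column")
        mat_samples = set(map(str, self.matrix.columns))
        ann_samples = set(map(str, self.annotations.index))
        if mat_samples != ann_samples:
            missing = sorted(mat_samples - ann_samples)
            extra = sorted(ann_samples - mat_samples)
            raise SampleMismatchError(
                f"cohort {self.cohort_id!r}: samples without annotation {missing}; "
                f"annotated samples absent from matrix {extra}"
            )
        bad = set(self.annotations["class"].astype(str)) - {CONTROL, CASE}
        if bad:
            raise ColamError(f"cohort {self.cohort_id!r}: unknown class labels {sorted(bad)}")
        # align annotation rows to matrix column order
        self.annotations = self.annotations.loc[self.matrix.columns]
        self._gene_index = {canonical(g): g for g in self.matrix.index.astype(str)}

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def class_labels(self) -> np.ndarray:
        """Class label per sample, aligned with matrix columns."""
        return self.annotations["class"].to_numpy(dtype=object)

    def has_gene(self, symbol: str) -> bool:
        return canonical(symbol) in self._gene_index

    def expression(self, symbol: str) -> np.ndarray:
        """Expression vector for one gene (case-insensitive lookup)."""
        key = canonical(symbol)
        if key not in self._gene_index:
            raise KeyError(symbol)
        return self.matrix.loc[self._gene_index[key]].to_numpy(dtype=float)

    def canonical_genes(self) -> set[str]:
        return set(self._gene_index)

    def sorted_copy(self) -> "ExpressionCohort":
        """Cohort with genes and samples in canonical (lexicographic) order."""
        matrix = self.matrix.copy()
        matrix.index = matrix.index.astype(str)
        matrix.columns = matrix.columns.astype(str)
        matrix = matrix.sort_index(key=lambda idx: idx.map(canonical))
        matrix = matrix.reindex(columns=sorted(matrix.columns))
        ann = self.annotations.copy()
        ann.index = ann.index.astype(str)
        ann = ann.loc[matrix.columns]
        return ExpressionCohort(self.cohort_id, matrix, ann)

    def equals(self, other: "ExpressionCohort") -> bool:
        a, b = self.sorted_copy(), other.sorted_copy()

        def norm(m: pd.DataFrame) -> pd.DataFrame:
            m = m.astype(float)
            m.index = pd.Index(m.index.astype(str), name=None)
            m.columns = pd.Index(m.columns.astype(str), name=None)
            return m.round(10)

        ann_a, ann_b = (c.annotations.rename_axis(None) for c in (a, b))
        return (
            a.cohort_id == b.cohort_id
            and norm(a.matrix).equals(norm(b.matrix))
            and ann_a.equals(ann_b)
        )


@dataclass
class GeneSet:
    """A named list of gene symbols with optional per-gene metadata.

    Symbols are de-duplicated case-insensitively on construction (first
    occurrence wins); a warning is logged when duplicates are collapsed.
    """

    name: str
    genes: list[str]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique: list[str] = []
        dropped = 0
        for g in self.genes:
            key = canonical(g)
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
            unique.append(str(g))
        if dropped:
            logger.warning("gene set %r: collapsed %d duplicate symbol(s)", self.name, dropped)
        self.genes = unique

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return canonical(symbol) in self.canonical()

    def canonical(self) -> set[str]:
        return {canonical(g) for g in self.genes}


@dataclass
class ParentSignature:
    """A parent macrophage-state signature: genes tagged by cluster.

    ``clusters`` maps each gene symbol to ``reactive`` or ``tolerant``.
    The 338-gene macrophage reactivity/tolerance signature consumed by the
    refinement stage has this shape; the simulator emits the same shape
    with planted ground truth.
    """

    clusters: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.clusters.values() if c not in CLUSTERS}
        if bad:
            raise ColamError(f"unknown cluster labels {sorted(bad)}; expected {CLUSTERS}")
        _check_unique(self.clusters.keys(), "parent signature genes")

    @classmethod
    def from_gene_sets(cls, reactive: GeneSet, tolerant: GeneSet) -> "ParentSignature":
        clusters: dict[str, str] = {}
        for g in reactive.genes:
            clusters[g] = REACTIVE
        for g in tolerant.genes:
            clusters[g] = TOLERANT
        return cls(clusters)

    def genes(self) -> list[str]:
        return list(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class GeneStat:
    """Per-gene refinement record for one case/control contrast."""

    gene: str
    auc: float
    accuracy: float
    direction: str
    threshold: float
    fisher_p: float
    selected: bool
    cluster: str | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ColamSignature:
    """A refined signature: selected genes split by parent cluster.

    ``i_genes`` holds the reactive-cluster (inflammatory) members and
    ``ni_genes`` the tolerant-cluster (noninflammatory) members; ``stats``
    is the full per-gene audit table and ``unscored`` lists parent genes
    absent from the refinement cohort.
    """

    context: str
    i_genes: GeneSet
    ni_genes: GeneSet
    stats: pd.DataFrame
    unscored: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = self.i_genes.canonical() & self.ni_genes.canonical()
        if overlap:
            raise ColamError(f"signature sets overlap: {sorted(overlap)}")

    def all_genes(self) -> list[str]:
        return list(self.i_genes.genes) + list(self.ni_genes.genes)

    def set_of(self, symbol: str) -> str | None:
        if symbol in self.i_genes:
            return "iColAM"
        if symbol in self.ni_genes:
            return "niColAM"
        return None


@dataclass
class ScoreTable:
    """Per-sample composite scores for one or more gene sets.

    ``scores`` is indexed by sample id with one column per gene set; values
    are mean rank percentiles in [0, 1].  ``coverage`` maps each set name to
    the fraction of its genes found in the cohort.
    """

    cohort_id: str
    scores: pd.DataFrame
    coverage: dict[str, float]

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ColamError("composite scores outside [0, 1]")
        for name, cov in self.coverage.items():
            if not (0 < cov <= 1):
                raise ColamError(f"coverage for {name!r} outside (0, 1]: {cov}")


@dataclass(frozen=True)
class ClassificationResult:
    """Cohort-level classification of a composite score against class labels."""

    gene_set: str
    auc: float
    accuracy: float
    welch_p: float
    direction: str
    n_case: int
    n_control: int
    flags: tuple[str, ...] = ()


@dataclass
class CandidateEvidence:
    """Evidence layers for one candidate effector gene.

    ``meta`` is the per-target correlation meta-summary (median r, fraction
    of cohorts with r > 0, sign-consistency binomial p).  ``screen_effect``
    is reporter activity relative to the stimulated control (= 1.0).
    """

    gene: str
    signature_set: str | None = None
    interactome_hits: tuple[str, ...] = ()
    unique_to: str | None = None
    meta: pd.DataFrame | None = None
    screen_effect: float | None = None
    screen_flagged: bool = False

    def best_sign_p(self) -> float:
        """Smallest sign-consistency p across correlation targets (1 if none)."""
        if self.meta is None or self.meta.empty:
            return 1.0
        return float(self.meta["sign_p"].min())


def as_case_mask(labels: Sequence | np.ndarray) -> np.ndarray:
    """Boolean mask (True = case) from class labels or booleans."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    vals = np.asarray([str(v) for v in arr], dtype=object)
    bad = set(vals) - {CONTROL, CASE}
    if bad:
        raise ColamError(f"unknown class labels {sorted(bad)}; expected 'case'/'control'")
    return vals == CASE
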