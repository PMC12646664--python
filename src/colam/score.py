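"""Composite signature scores, cohort classification, temporal profiling.

A sample's composite score for a gene set is the mean rank percentile of
the set's member genes: each gene's expression is ranked across samples
(average ranks for ties) and mapped to [0, 1], and the per-gene
percentiles are averaged.  Rank percentiles make the score invariant to
any per-gene monotone normalization, which matters when signatures travel
across platforms and species.  The inflammatory (iColAM) and
noninflammatory (niColAM) scores are always reported separately, never
collapsed into a difference.

Cohort classification reuses the same pair-statistic AUC engine as
refinement plus a Welch two-sample t test on the raw scores.  Temporal
profiling assembles phase cohorts sharing a control arm into a single
matrix, scores it once (so phases are on a common rank scale), and calls
the trend for each set as the phase of maximum mean score, with seeded
bootstrap confidence intervals.
"""
from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    CASE,
    ClassificationResult,
    ColamError,
    ExpressionCohort,
    GeneSet,
    MissingControlPhaseError,
    NoSignatureGenesError,
    ScoreTable,
    SingleClassError,
    as_case_mask,
)
from .refine import gene_auc

logger = logging.getLogger(__name__)


def _rank_percentiles(matrix: np.ndarray) -> np.ndarray:
    """Row-wise rank percentiles across samples, in [0, 1]."""
    n = matrix.shape[1]
    if n == 1:
        return np.full_like(matrix, 0.5, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    return (ranks - 1.0) / (n - 1.0)


def composite_score(
    cohort: ExpressionCohort,
    gene_sets: Sequence[GeneSet] | GeneSet,
    weights: Mapping[str, float] | None = None,
) -> ScoreTable:
    """Per-sample composite scores for one or more gene sets.

    ``weights`` optionally maps gene symbols (canonical) to non-negative
    weights (e.g. per-gene classification accuracy) for a weighted mean;
    unweighted rank averaging is the default.  A warning is raised when
    fewer than half of a set's genes are present in the cohort.
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    scores: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    for gs in gene_sets:
        present = [g for g in gs.genes if cohort.has_gene(g)]
        if not present:
            raise NoSignatureGenesError(
                f"no gene of set {gs.name!r} present in cohort {cohort.cohort_id!r}"
            )
        cov = len(present) / len(gs)
        if cov < 0.5:
            warnings.warn(
                f"set {gs.name!r}: only {len(present)}/{len(gs)} genes found in "
                f"cohort {cohort.cohort_id!r}",
                stacklevel=2,
            )
        sub = np.vstack([cohort.expression(g) for g in present])
        pct = _rank_percentiles(sub)
        if weights is None:
            scores[gs.name] = pct.mean(axis=0)
        else:
            w = np.array([max(0.0, float(weights.get(g.upper(), weights.get(g, 0.0)))) for g in present])
            if w.sum() <= 0:
                raise ColamError(f"set {gs.name!r}: weights sum to zero")
            scores[gs.name] = (w[:, None] * pct).sum(axis=0) / w.sum()
        coverage[gs.name] = cov
    frame = pd.DataFrame(scores, index=cohort.matrix.columns)
    frame.index.name = "sample_id"
    return ScoreTable(cohort.cohort_id, frame, coverage)


def classify_cohort(
    score_table: ScoreTable, labels: Sequence | pd.Series
) -> list[ClassificationResult]:
    """Classify case vs control with each gene set's composite score.

    Reports the score ROC-AUC (case-high counted toward AUC > 0.5),
    classification accuracy = max(AUC, 1-AUC), a Welch two-sided p on the
    raw scores, and which class scores higher.  Degenerate (constant)
    scores yield AUC 0.5 and p 1 with a flag.  At n = 3 per class a
    warning is emitted but the computation proceeds, mirroring the
    smallest real designs.
    """
    if isinstance(labels, pd.Series):
        labels = labels.loc[score_table.scores.index].to_numpy()
    case = as_case_mask(labels)
    if case.shape[0] != score_table.scores.shape[0]:
        raise ValueError("labels and score table differ in length")
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("classification requires both classes")
    if min(n1, n0) < 3:
        warnings.warn(f"only {min(n1, n0)} samples in the smaller class", stacklevel=2)

    results = []
    for name in score_table.scores.columns:
        s = score_table.scores[name].to_numpy(dtype=float)
        flags: list[str] = []
        if np.ptp(s) == 0:
            auc, welch_p, direction = 0.5, 1.0, "none"
            flags.append("degenerate_scores")
        else:
            auc = gene_auc(s, case)
            with np.errstate(invalid="ignore"):
                welch_p = float(stats.ttest_ind(s[case], s[~case], equal_var=False).pvalue)
            if np.isnan(welch_p):
                welch_p = 1.0
                flags.append("welch_undefined")
            if auc > 0.5:
                direction = "case_high"
            elif auc < 0.5:
                direction = "control_high"
            else:
                direction = "none"
        results.append(
            ClassificationResult(
                gene_set=name,
                auc=auc,
                accuracy=max(auc, 1.0 - auc),
                welch_p=welch_p,
                direction=direction,
                n_case=n1,
                n_control=n0,
                flags=tuple(flags),
            )
        )
    return results


def _merge_phase_cohorts(phase_cohorts: Sequence[ExpressionCohort]) -> ExpressionCohort:
    """Assemble phase cohorts (each: shared control + one phase) into one
    cohort on the common genes, de-duplicating the shared control samples."""
    if len(phase_cohorts) < 1:
        raise ColamError("need at least one phase cohort")
    genes = set(map(str, phase_cohorts[0].matrix.index))
    for c in phase_cohorts[1:]:
        genes &= set(map(str, c.matrix.index))
    if not genes:
        raise ColamError("phase cohorts share no genes")
    gene_order = sorted(genes)
    blocks, ann_blocks, seen_samples = [], [], set()
    for c in phase_cohorts:
        if "phase" not in c.annotations.columns:
            raise MissingControlPhaseError(
                f"cohort {c.cohort_id!r} lacks a 'phase' annotation column"
            )
        keep = [s for s in c.matrix.columns.astype(str) if s not in seen_samples]
        seen_samples.update(keep)
        blocks.append(c.matrix.loc[gene_order, keep])
        ann_blocks.append(c.annotations.loc[keep])
    matrix = pd.concat(blocks, axis=1)
    ann = pd.concat(ann_blocks, axis=0)
    return ExpressionCohort("timecourse", matrix, ann)


def temporal_profile(
    phase_cohorts: Sequence[ExpressionCohort],
    gene_sets: Sequence[GeneSet] | GeneSet,
    control_phase: str = "control",
    n_boot: int = 1000,
    ci: float = 0.90,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-phase composite-score summary and a trend call per gene set.

    Returns a summary table (set, phase, n, mean score, bootstrap CI,
    Welch p vs the control phase) and, per set, the non-control phase of
    maximum mean score — the phase in which that macrophage population
    "emerges".  The control-phase mean is the reference baseline.
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    merged = _merge_phase_cohorts(phase_cohorts)
    phases = merged.annotations["phase"].astype(str)
    if control_phase not in set(phases):
        raise MissingControlPhaseError(f"no samples with phase {control_phase!r}")
    phase_order = [control_phase] + [
        p for p in dict.fromkeys(phases) if p != control_phase
    ]
    if len(phase_order) < 2:
        raise ColamError("need at least two phases (control plus one)")

    table = composite_score(merged, gene_sets)
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    trend: dict[str, str] = {}
    for gs in gene_sets:
        s = table.scores[gs.name]
        ctrl_scores = s[phases.values == control_phase].to_numpy()
        means: dict[str, float] = {}
        for phase in phase_order:
            vals = s[phases.values == phase].to_numpy()
            boot = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
            if phase == control_phase:
                welch_p = float("nan")
            else:
                with np.errstate(invalid="ignore"):
                    welch_p = float(stats.ttest_ind(vals, ctrl_scores, equal_var=False).pvalue)
                if np.isnan(welch_p):
                    welch_p = 1.0
            means[phase] = float(vals.mean())
            rows.append(
                {
                    "set": gs.name,
                    "phase": phase,
                    "n": int(vals.size),
                    "mean_score": means[phase],
                    "ci_low": float(np.quantile(boot, lo_q)),
                    "ci_high": float(np.quantile(boot, hi_q)),
                    "welch_p_vs_control": welch_p,
                    "is_control": phase == control_phase,
                }
            )
        non_control = {p: m for p, m in means.items() if p != control_phase}
        trend[gs.name] = max(non_control, key=lambda p: (non_control[p], p))
    return pd.DataFrame(rows), trend
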