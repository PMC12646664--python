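"""Signature refinement: per-gene classification statistics and gating.

Each parent-signature gene is treated as a single-gene monotone classifier
of case vs control.  Its ROC-AUC equals the Mann-Whitney pair statistic
(fraction of case/control pairs where the case sample is higher, ties
counting one half), computed here from average ranks; classification
accuracy is max(AUC, 1-AUC).  Expression is dichotomized at a step-fit
threshold (the split of the sorted vector minimizing the two-segment
squared error, in the Boolean-implication tradition) and a two-sided
Fisher exact test is run on the resulting 2x2 table.  A gene is selected
when accuracy >= auc_min (default 0.7) and Fisher p <= p_max (default
0.05); selected genes are partitioned into iColAM (reactive parent
cluster) and niColAM (tolerant parent cluster) sets.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    DOWN,
    REACTIVE,
    TOLERANT,
    UNDETERMINED,
    UP,
    ColamSignature,
    DegenerateValuesError,
    ExpressionCohort,
    GeneSet,
    GeneStat,
    NoSignatureGenesError,
    ParentSignature,
    SingleClassError,
    as_case_mask,
)

logger = logging.getLogger(__name__)

_AUC_TIE_TOL = 1e-12


def gene_auc(values: Sequence[float], labels: Sequence) -> float:
    """ROC-AUC of an expression vector against case/control labels.

    Equals the Mann-Whitney pair statistic: over all (case, control)
    pairs, the fraction won by the case sample plus half the ties, so
    values above 0.5 mean case-high expression.  Computed from average
    ranks, which handles ties exactly.
    """
    values = np.asarray(values, dtype=float)
    case = as_case_mask(labels)
    if values.shape != case.shape:
        raise ValueError("values and labels differ in length")
    n1 = int(case.sum())
    n0 = int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(values)
    return float((ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class StepFit:
    """Diagnostics of a two-segment step fit to a sorted vector."""

    threshold: float
    split_index: int  # size of the left (low) segment
    left_mean: float
    right_mean: float
    sse: float


def step_threshold(values: Sequence[float]) -> StepFit:
    """Fit a step function to a sorted expression vector.

    For every split of the ascending-sorted values into a low and a high
    segment, the squared error around the two segment means is computed;
    the threshold is the midpoint of the two means at the best split.
    Ties in the squared error are broken toward the more balanced split,
    then toward the smaller split index.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 values to fit a step, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateValuesError("all values equal; no step threshold exists")

    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total_sum, total_sq = csum[-1], csq[-1]
    ks = np.arange(1, n)  # left segment sizes
    left_sum = csum[:-1]
    left_sq = csq[:-1]
    right_sum = total_sum - left_sum
    right_sq = total_sq - left_sq
    sse = (left_sq - left_sum**2 / ks) + (right_sq - right_sum**2 / (n - ks))

    best = sse.min()
    # tolerance absorbs float-summation noise between algebraically equal splits
    tied = np.flatnonzero(sse <= best + 1e-9 * max(1.0, abs(best)))
    balance = np.abs(ks[tied] - n / 2)
    tied = tied[balance == balance.min()]
    k = int(ks[tied[0]])

    left_mean = float(csum[k - 1] / k)
    right_mean = float((total_sum - csum[k - 1]) / (n - k))
    return StepFit(
        threshold=(left_mean + right_mean) / 2,
        split_index=k,
        left_mean=left_mean,
        right_mean=right_mean,
        sse=float(sse[k - 1]),
    )


def dichotomized_fisher_p(
    values: Sequence[float], labels: Sequence, threshold: float
) -> float:
    """Two-sided Fisher exact p for (above / below-or-equal threshold) x class.

    When every sample falls on one side of the threshold the table has an
    empty margin and p is 1 (with a warning): the dichotomization carries
    no information.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    case = as_case_mask(labels)
    if case.all() or (~case).all():
        raise SingleClassError("both classes must be present")
    above = values > threshold
    table = np.array(
        [
            [int((above & case).sum()), int((above & ~case).sum())],
            [int((~above & case).sum()), int((~above & ~case).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0:
        warnings.warn("all samples on one side of the threshold; Fisher p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def gene_stat(
    values: Sequence[float],
    labels: Sequence,
    gene: str = "",
    cluster: str | None = None,
    auc_min: float = 0.7,
    p_max: float = 0.05,
    dichotomize: str = "step",
) -> GeneStat:
    """Full refinement record for one gene.

    ``dichotomize`` selects the Fisher threshold: ``step`` (step fit,
    default) or ``median``.  A gene whose AUC is exactly 0.5 has no
    regulation direction and is never selected.
    """
    values = np.asarray(values, dtype=float)
    auc = gene_auc(values, labels)
    accuracy = max(auc, 1.0 - auc)
    if abs(auc - 0.5) <= _AUC_TIE_TOL:
        direction = UNDETERMINED
    else:
        direction = UP if auc > 0.5 else DOWN

    flags: list[str] = []
    try:
        if dichotomize == "step":
            threshold = step_threshold(values).threshold
        elif dichotomize == "median":
            threshold = float(np.median(values))
        else:
            raise ValueError(f"unknown dichotomization {dichotomize!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fisher_p = dichotomized_fisher_p(values, labels, threshold)
    except DegenerateValuesError:
        threshold, fisher_p = float("nan"), 1.0
        flags.append("degenerate_expression")

    selected = accuracy >= auc_min and fisher_p <= p_max and direction != UNDETERMINED
    return GeneStat(
        gene=gene,
        auc=auc,
        accuracy=accuracy,
        direction=direction,
        threshold=threshold,
        fisher_p=fisher_p,
        selected=selected,
        cluster=cluster,
        flags=tuple(flags),
    )


# direction a cluster is expected to move in the case class: reactive
# (inflammatory) genes up, tolerant (noninflammatory) genes down
_EXPECTED_DIRECTION = {REACTIVE: UP, TOLERANT: DOWN}


def refine_signature(
    cohort: ExpressionCohort,
    parent: ParentSignature,
    auc_min: float = 0.7,
    p_max: float = 0.05,
    dichotomize: str = "step",
    fdr: bool = False,
    context: str | None = None,
) -> ColamSignature:
    """Refine a parent signature on a labeled cohort.

    Every parent gene present in the cohort gets a :class:`GeneStat`;
    selected genes are partitioned by parent cluster into the iColAM
    (reactive) and niColAM (tolerant) sets.  Parent genes absent from the
    cohort are reported in ``unscored``, never silently dropped.  When a
    gene's observed direction conflicts with its cluster's expected
    direction it keeps its cluster assignment and is flagged
    ``direction_conflict`` in the audit table.  With ``fdr=True`` the
    Fisher p values are Benjamini-Hochberg adjusted before gating (off by
    default: the gate is on raw p).
    """
    labels = cohort.class_labels
    case = as_case_mask(labels)
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("refinement requires both case and control samples")
    if min(n1, n0) < 3:
        warnings.warn(
            f"only {min(n1, n0)} samples in the smaller class; statistics will be coarse",
            stacklevel=2,
        )

    present: list[tuple[str, str]] = []
    unscored: list[str] = []
    for gene, cluster in parent.clusters.items():
        if cohort.has_gene(gene):
            present.append((gene, cluster))
        else:
            unscored.append(gene)
    if not present:
        raise NoSignatureGenesError(
            f"no parent signature gene found in cohort {cohort.cohort_id!r}"
        )
    if unscored:
        logger.info(
            "cohort %s: %d parent gene(s) absent and left unscored", cohort.cohort_id, len(unscored)
        )

    records = [
        gene_stat(
            cohort.expression(gene),
            labels,
            gene=gene,
            cluster=cluster,
            auc_min=auc_min,
            p_max=p_max,
            dichotomize=dichotomize,
        )
        for gene, cluster in present
    ]

    stats_df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "cluster": [r.cluster for r in records],
            "auc": [r.auc for r in records],
            "accuracy": [r.accuracy for r in records],
            "direction": [r.direction for r in records],
            "threshold": [r.threshold for r in records],
            "fisher_p": [r.fisher_p for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
    if fdr:
        stats_df["fisher_q"] = stats.false_discovery_control(stats_df["fisher_p"], method="bh")
        gate_p = stats_df["fisher_q"]
    else:
        gate_p = stats_df["fisher_p"]
    stats_df["selected"] = (
        (stats_df["accuracy"] >= auc_min)
        & (gate_p <= p_max)
        & (stats_df["direction"] != UNDETERMINED)
    )
    conflict = stats_df["selected"] & (
        stats_df["direction"] != stats_df["cluster"].map(_EXPECTED_DIRECTION)
    )
    stats_df.loc[conflict, "flags"] = (
        stats_df.loc[conflict, "flags"].str.cat(["direction_conflict"] * int(conflict.sum()), sep=";")
        .str.lstrip(";")
    )

    ctx = context or cohort.cohort_id
    sel = stats_df[stats_df["selected"]]
    i_genes = GeneSet(f"{ctx}_iColAM", sel.loc[sel["cluster"] == REACTIVE, "gene"].tolist())
    ni_genes = GeneSet(f"{ctx}_niColAM", sel.loc[sel["cluster"] == TOLERANT, "gene"].tolist())
    return ColamSignature(
        context=ctx, i_genes=i_genes, ni_genes=ni_genes, stats=stats_df, unscored=unscored
    )
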