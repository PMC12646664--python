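"""Candidate-effector prioritization within a refined signature.

Three evidence layers are applied in the order the screening logic uses
them — set overlap with interactome lists (is the gene an interactor, and
specific to exactly one list?), a functional screen (does depleting the
gene enhance reporter activity at least 75% over the stimulated
control?), and a cross-cohort correlation panel (does the gene track a
target sensor consistently across independent cohorts?).  The combined
ranking is lexicographic over these layers rather than a fused score,
because the layers act as sequential filters, not exchangeable weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    CandidateEvidence,
    ColamError,
    ColamSignature,
    ExpressionCohort,
    GeneSet,
    InvalidActivityError,
    canonical,
)

logger = logging.getLogger(__name__)


def _signature_genes(signature: ColamSignature | GeneSet | Sequence[str]) -> list[tuple[str, str | None]]:
    if isinstance(signature, ColamSignature):
        return [(g, "iColAM") for g in signature.i_genes.genes] + [
            (g, "niColAM") for g in signature.ni_genes.genes
        ]
    if isinstance(signature, GeneSet):
        return [(g, None) for g in signature.genes]
    return [(g, None) for g in signature]


def overlay_interactome(
    signature: ColamSignature | GeneSet | Sequence[str],
    lists: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Membership of every signature gene across named interactome lists.

    Returns one row per signature gene with a boolean column per list, the
    number of hits, and ``unique_to`` — the list name when the gene sits
    in exactly one list (the "list-specific interactor" of interest).
    Genes in several lists are reported but marked non-specific.  The
    overlay is pure set algebra: order-independent and idempotent.
    """
    if not lists:
        raise ColamError("need at least one interactome list")
    canon_lists = {name: {canonical(g) for g in genes} for name, genes in lists.items()}
    rows = []
    for gene, sig_set in _signature_genes(signature):
        key = canonical(gene)
        hits = sorted(name for name, members in canon_lists.items() if key in members)
        rows.append(
            {
                "gene": gene,
                "signature_set": sig_set,
                **{name: name in hits for name in lists},
                "n_hits": len(hits),
                "unique_to": hits[0] if len(hits) == 1 else None,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationPanel:
    """Per-cohort correlation records plus a per-target meta summary."""

    records: pd.DataFrame
    meta: pd.DataFrame
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)


def correlate_across_cohorts(
    cohorts: Sequence[ExpressionCohort],
    candidate: str,
    targets: Sequence[str],
    method: str = "pearson",
) -> CorrelationPanel:
    """Correlate a candidate with target genes across independent cohorts.

    Cohorts lacking the candidate or a target, or with fewer than 3
    samples, are skipped with a logged reason.  The meta summary per
    target gives the median r, the fraction of contributing cohorts with
    r > 0, and a two-sided binomial sign-consistency p (is the sign more
    consistent across cohorts than a fair coin?).  Pearson on normalized
    expression is the default; ``method='spearman'`` is rank-based.
    """
    if method not in ("pearson", "spearman"):
        raise ColamError(f"unknown correlation method {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rec_rows, skip_rows = [], []
    for cohort in cohorts:
        if cohort.n_samples < 3:
            skip_rows.append({"cohort": cohort.cohort_id, "reason": "fewer than 3 samples"})
            continue
        if not cohort.has_gene(candidate):
            skip_rows.append({"cohort": cohort.cohort_id, "reason": f"missing {candidate}"})
            continue
        x = cohort.expression(candidate)
        for target in targets:
            if not cohort.has_gene(target):
                skip_rows.append({"cohort": cohort.cohort_id, "reason": f"missing {target}"})
                continue
            y = cohort.expression(target)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skip_rows.append(
                    {"cohort": cohort.cohort_id, "reason": f"constant expression for {target}"}
                )
                continue
            res = corr(x, y)
            rec_rows.append(
                {
                    "cohort": cohort.cohort_id,
                    "target": target,
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": cohort.n_samples,
                }
            )
    for row in skip_rows:
        logger.info("correlation panel: skipped %s (%s)", row["cohort"], row["reason"])
    records = pd.DataFrame(rec_rows, columns=["cohort", "target", "r", "p", "n"])
    meta_rows = []
    for target in targets:
        sub = records[records["target"] == target]
        if sub.empty:
            meta_rows.append(
                {"target": target, "n_cohorts": 0, "median_r": float("nan"),
                 "frac_positive": float("nan"), "sign_p": 1.0}
            )
            continue
        k_pos = int((sub["r"] > 0).sum())
        n = len(sub)
        sign_p = float(stats.binomtest(k_pos, n, 0.5, alternative="two-sided").pvalue)
        meta_rows.append(
            {
                "target": target,
                "n_cohorts": n,
                "median_r": float(sub["r"].median()),
                "frac_positive": k_pos / n,
                "sign_p": sign_p,
            }
        )
    return CorrelationPanel(
        records=records,
        meta=pd.DataFrame(meta_rows),
        skipped=pd.DataFrame(skip_rows, columns=["cohort", "reason"]),
    )


@dataclass
class ScreenResult:
    """Signature genes scored against the perturbation screen."""

    table: pd.DataFrame  # gene, relative_activity, enhancement, flagged
    missing: list[str]


def screen_enhancement(
    screen_table: pd.DataFrame,
    signature: ColamSignature | GeneSet | Sequence[str],
    enhancement_threshold: float = 0.75,
) -> ScreenResult:
    """Enhancement of reporter activity per signature gene in the screen.

    Activities are relative to the stimulated control (= 1.0); enhancement
    = activity - 1.  A gene is flagged when enhancement >= threshold
    (inclusive: the 75% dashed line counts).  The table is ranked by
    enhancement descending; signature genes absent from the screen are
    returned in ``missing``.
    """
    if enhancement_threshold < 0:
        raise ColamError("enhancement_threshold must be >= 0")
    acts = screen_table["relative_activity"].to_numpy(dtype=float)
    if (acts < 0).any():
        bad = screen_table.loc[acts < 0, "gene"].tolist()
        raise InvalidActivityError(f"negative reporter activities for {bad}")
    by_gene = {canonical(g): a for g, a in zip(screen_table["gene"], acts)}
    rows, missing = [], []
    for gene, sig_set in _signature_genes(signature):
        key = canonical(gene)
        if key not in by_gene:
            missing.append(gene)
            continue
        activity = by_gene[key]
        enh = activity - 1.0
        rows.append(
            {
                "gene": gene,
                "signature_set": sig_set,
                "relative_activity": activity,
                "enhancement": enh,
                "flagged": enh >= enhancement_threshold,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "signature_set", "relative_activity", "enhancement", "flagged"])
    if not table.empty:
        table = table.sort_values(["enhancement", "gene"], ascending=[False, True]).reset_index(drop=True)
    if missing:
        logger.info("screen: %d signature gene(s) absent from the table", len(missing))
    return ScreenResult(table=table, missing=missing)


def build_candidate_evidence(
    signature: ColamSignature,
    overlay: pd.DataFrame,
    screen: ScreenResult | None = None,
    correlation_panels: Mapping[str, CorrelationPanel] | None = None,
) -> list[CandidateEvidence]:
    """Assemble one :class:`CandidateEvidence` per signature gene from the
    overlay table, screen result and per-gene correlation panels
    (``correlation_panels`` maps canonical gene symbol to its panel)."""
    screen_by_gene = {}
    if screen is not None:
        screen_by_gene = {
            canonical(r["gene"]): (float(r["relative_activity"]), bool(r["flagged"]))
            for _, r in screen.table.iterrows()
        }
    panels = {canonical(k): v for k, v in (correlation_panels or {}).items()}
    list_cols = [c for c in overlay.columns if c not in ("gene", "signature_set", "n_hits", "unique_to")]
    evidence = []
    for _, row in overlay.iterrows():
        key = canonical(row["gene"])
        hits = tuple(name for name in list_cols if row[name])
        effect, flagged = screen_by_gene.get(key, (None, False))
        panel = panels.get(key)
        evidence.append(
            CandidateEvidence(
                gene=row["gene"],
                signature_set=row["signature_set"],
                interactome_hits=hits,
                unique_to=row["unique_to"],
                meta=panel.meta if panel is not None else None,
                screen_effect=effect,
                screen_flagged=flagged,
            )
        )
    return evidence


def rank_candidates(
    evidence: Sequence[CandidateEvidence], sign_p_max: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank candidates lexicographically over the evidence layers.

    Order: (1) unique interactome hit first, (2) screen-flagged then raw
    enhancement descending, (3) smaller correlation sign-consistency p;
    remaining ties are broken alphabetically and flagged.  Only candidates
    passing at least one layer (any interactome hit, a screen flag, or a
    sign-consistency p <= ``sign_p_max``) enter the ranking; the full
    evidence table is returned alongside so users can re-rank.  With no
    passing candidate the ranking is empty and the reason is logged.
    """
    if not evidence:
        raise ColamError("need at least one candidate")
    rows = []
    for ev in evidence:
        sign_p = ev.best_sign_p()
        effect = ev.screen_effect if ev.screen_effect is not None else float("nan")
        rows.append(
            {
                "gene": ev.gene,
                "signature_set": ev.signature_set,
                "interactome_hits": ";".join(ev.interactome_hits),
                "unique_to": ev.unique_to,
                "screen_effect": effect,
                "enhancement": effect - 1.0 if ev.screen_effect is not None else float("nan"),
                "screen_flagged": ev.screen_flagged,
                "sign_p": sign_p,
                "passes_any": bool(
                    ev.interactome_hits or ev.screen_flagged or sign_p <= sign_p_max
                ),
            }
        )
    full = pd.DataFrame(rows)
    passing = full[full["passes_any"]].copy()
    if passing.empty:
        logger.info("no candidate passes any evidence layer; empty ranking")
        return passing.assign(rank=pd.Series(dtype=int), alpha_tiebreak=pd.Series(dtype=bool)), full

    enh = passing["enhancement"].fillna(float("-inf"))
    key = pd.DataFrame(
        {
            "not_unique": passing["unique_to"].isna(),
            "not_flagged": ~passing["screen_flagged"].astype(bool),
            "neg_enh": -enh,
            "sign_p": passing["sign_p"],
            "gene": passing["gene"].str.upper(),
        },
        index=passing.index,
    )
    order = key.sort_values(["not_unique", "not_flagged", "neg_enh", "sign_p", "gene"]).index
    ranked = passing.loc[order].reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    dup_key = key.loc[order, ["not_unique", "not_flagged", "neg_enh", "sign_p"]]
    ranked["alpha_tiebreak"] = dup_key.duplicated(keep=False).to_numpy()
    return ranked, full
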