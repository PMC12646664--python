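"""Synthetic expression cohorts with planted, known ground truth.

Every downstream stage (refinement, scoring, prioritization) is exercised
on data produced here, so the generators emit exactly the shapes the real
inputs take: two-class log-scale expression matrices with small group
sizes, multi-phase colitis-style time courses with a shared control arm,
interactor gene lists, and siRNA-screen reporter tables.

Expression is simulated directly on the log2 scale with Gaussian noise.
Downstream statistics are rank- or threshold-based, so the marginal
distribution is immaterial; a Gaussian keeps the planted effect size
interpretable as Cohen's d.  Seeds are mandatory: there is no hidden
global random state and identical designs reproduce bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    CASE,
    CONTROL,
    DOWN,
    REACTIVE,
    TOLERANT,
    UP,
    CandidateNotInUniverseError,
    ColamError,
    DuplicateIdError,
    ExpressionCohort,
    GeneSet,
    InvalidActivityError,
    ParentSignature,
    canonical,
)

_BASELINE_RANGE = (4.0, 12.0)  # log2 units; typical normalized array/RNA-seq range


@dataclass(frozen=True)
class PlantedDesign:
    """Design of a two-class cohort with planted directional genes.

    ``signature_genes`` is a sequence of ``(gene_id, cluster, direction)``
    triples with cluster in {reactive, tolerant} and direction in
    {up_in_case, down_in_case}.  Planted genes are shifted in cases by
    ``effect_size * noise_sd`` log2 units (Cohen's d = effect_size); when
    ``noise_sd`` is exactly 0 the shift is ``effect_size`` log2 units,
    giving perfect separation.
    """

    signature_genes: tuple[tuple[str, str, str], ...]
    n_background_genes: int = 300
    effect_size: float = 3.0
    n_case: int = 20
    n_control: int = 20
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ColamError("need at least one case and one control sample")
        if self.effect_size < 0:
            raise ColamError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ColamError("noise_sd must be >= 0")
        if self.n_background_genes < 0:
            raise ColamError("n_background_genes must be >= 0")
        for gene, cluster, direction in self.signature_genes:
            if cluster not in (REACTIVE, TOLERANT):
                raise ColamError(f"unknown cluster {cluster!r} for gene {gene!r}")
            if direction not in (UP, DOWN):
                raise ColamError(f"unknown direction {direction!r} for gene {gene!r}")

    @property
    def shift(self) -> float:
        return self.effect_size * (self.noise_sd if self.noise_sd > 0 else 1.0)


def default_signature_genes(
    n_reactive: int = 15, n_tolerant: int = 15, prefix: str = "SIG"
) -> tuple[tuple[str, str, str], ...]:
    """Convenience planted-gene roster: reactive genes up in cases
    (inflammation), tolerant genes down in cases."""
    genes = []
    for i in range(n_reactive):
        genes.append((f"{prefix}R{i:03d}", REACTIVE, UP))
    for i in range(n_tolerant):
        genes.append((f"{prefix}T{i:03d}", TOLERANT, DOWN))
    return tuple(genes)


def generate_case_control_cohort(
    design: PlantedDesign, cohort_id: str = "synthetic"
) -> tuple[ExpressionCohort, pd.DataFrame]:
    """Simulate a labeled two-class cohort from a planted design.

    Returns the cohort and a ground-truth table (gene, cluster, direction,
    shift) listing every planted gene, so tests never re-derive the truth.
    """
    rng = np.random.default_rng(design.seed)
    sig_ids = [g for g, _, _ in design.signature_genes]
    bg_ids = [f"BG{i:05d}" for i in range(design.n_background_genes)]
    if {canonical(g) for g in sig_ids} & {canonical(g) for g in bg_ids}:
        raise DuplicateIdError("signature gene ids collide with background ids")
    seen: set[str] = set()
    for g in sig_ids:
        key = canonical(g)
        if key in seen:
            raise DuplicateIdError(f"duplicate signature gene id {g!r}")
        seen.add(key)

    genes = bg_ids + sig_ids
    n_genes = len(genes)
    n_samples = design.n_case + design.n_control
    baselines = rng.uniform(*_BASELINE_RANGE, size=n_genes)
    matrix = baselines[:, None] + rng.normal(0.0, design.noise_sd, size=(n_genes, n_samples))

    case_cols = np.arange(design.n_case)  # cases first, then controls
    shift = design.shift
    for j, (gene, _cluster, direction) in enumerate(design.signature_genes):
        row = design.n_background_genes + j
        matrix[row, case_cols] += shift if direction == UP else -shift

    samples = [f"CASE{i + 1:03d}" for i in range(design.n_case)] + [
        f"CTRL{i + 1:03d}" for i in range(design.n_control)
    ]
    ann = pd.DataFrame(
        {"class": [CASE] * design.n_case + [CONTROL] * design.n_control},
        index=pd.Index(samples, name="sample_id"),
    )
    cohort = ExpressionCohort(
        cohort_id, pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=samples), ann
    )
    truth = pd.DataFrame(
        {
            "gene": sig_ids,
            "cluster": [c for _, c, _ in design.signature_genes],
            "direction": [d for _, _, d in design.signature_genes],
            "shift": [shift if d == UP else -shift for _, _, d in design.signature_genes],
        }
    )
    return cohort, truth


def parent_signature_for(
    design: PlantedDesign, include_background: bool = True
) -> ParentSignature:
    """Parent signature covering the design's planted genes and, optionally,
    its background genes (null members alternate clusters).

    Emulates feeding a broad parent signature into refinement where only a
    subset of members truly separates the classes.
    """
    clusters = {g: c for g, c, _ in design.signature_genes}
    if include_background:
        for i in range(design.n_background_genes):
            clusters[f"BG{i:05d}"] = REACTIVE if i % 2 == 0 else TOLERANT
    return ParentSignature(clusters)


@dataclass(frozen=True)
class TimecourseDesign:
    """Design of a multi-phase time course with a shared control arm.

    ``phase_shifts`` maps each planted gene-set name to one mean shift
    (log2 units) per phase, in phase order; the control phase shift must
    be 0.  Defaults mirror a chemically induced colitis time course:
    control, acute, chronic, recovery.
    """

    gene_sets: Mapping[str, tuple[str, ...]]
    phase_shifts: Mapping[str, tuple[float, ...]]
    phases: tuple[str, ...] = ("control", "acute", "chronic", "recovery")
    control_phase: str = "control"
    n_background_genes: int = 200
    n_per_phase: int = 6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phases) < 2:
            raise ColamError("need at least two phases")
        if self.control_phase not in self.phases:
            raise ColamError(f"control phase {self.control_phase!r} not among phases")
        if self.n_per_phase < 3:
            raise ColamError("need n_per_phase >= 3")
        if self.noise_sd < 0:
            raise ColamError("noise_sd must be >= 0")
        ctrl_idx = self.phases.index(self.control_phase)
        for name, shifts in self.phase_shifts.items():
            if name not in self.gene_sets:
                raise ColamError(f"shifts given for unknown gene set {name!r}")
            if len(shifts) != len(self.phases):
                raise ColamError(
                    f"set {name!r}: expected {len(self.phases)} shifts, got {len(shifts)}"
                )
            if shifts[ctrl_idx] != 0:
                raise ColamError(f"set {name!r}: control-phase shift must be 0")
        all_ids = [g for genes in self.gene_sets.values() for g in genes]
        if len({canonical(g) for g in all_ids}) != len(all_ids):
            raise DuplicateIdError("planted gene sets share gene ids")


def generate_timecourse_cohorts(design: TimecourseDesign) -> list[ExpressionCohort]:
    """Simulate one cohort per non-control phase, each carrying the same
    shared control samples (class=control) plus that phase's samples
    (class=case, annotated with the phase label)."""
    rng = np.random.default_rng(design.seed)
    planted: list[tuple[str, str]] = [
        (g, name) for name, genes in design.gene_sets.items() for g in genes
    ]
    bg_ids = [f"BG{i:05d}" for i in range(design.n_background_genes)]
    genes = bg_ids + [g for g, _ in planted]
    if len({canonical(g) for g in genes}) != len(genes):
        raise DuplicateIdError("planted gene ids collide with background ids")
    n_genes = len(genes)
    baselines = rng.uniform(*_BASELINE_RANGE, size=n_genes)

    def phase_matrix(phase: str) -> np.ndarray:
        mat = baselines[:, None] + rng.normal(
            0.0, design.noise_sd, size=(n_genes, design.n_per_phase)
        )
        k = design.phases.index(phase)
        for j, (_gene, set_name) in enumerate(planted):
            mat[design.n_background_genes + j, :] += design.phase_shifts[set_name][k]
        return mat

    ctrl_mat = phase_matrix(design.control_phase)
    ctrl_samples = [f"{design.control_phase.upper()}{i + 1:03d}" for i in range(design.n_per_phase)]

    cohorts = []
    for phase in design.phases:
        if phase == design.control_phase:
            continue
        mat = phase_matrix(phase)
        samples = [f"{phase.upper()}{i + 1:03d}" for i in range(design.n_per_phase)]
        full = np.concatenate([ctrl_mat, mat], axis=1)
        ann = pd.DataFrame(
            {
                "class": [CONTROL] * design.n_per_phase + [CASE] * design.n_per_phase,
                "phase": [design.control_phase] * design.n_per_phase + [phase] * design.n_per_phase,
            },
            index=pd.Index(ctrl_samples + samples, name="sample_id"),
        )
        cohorts.append(
            ExpressionCohort(
                f"phase_{phase}",
                pd.DataFrame(full, index=pd.Index(genes, name="gene"), columns=ctrl_samples + samples),
                ann,
            )
        )
    return cohorts


def generate_interactome_lists(
    universe: Sequence[str],
    planted_candidate: str,
    names: tuple[str, str] = ("NOD1_interactors", "NOD2_interactors"),
    size_a: int = 50,
    size_b: int = 60,
    n_shared: int = 10,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Two interactor gene lists with a planted unique candidate.

    The candidate appears in list B (``names[1]``) only, so an overlay with
    a signature containing it yields exactly one list-B-specific hit.
    """
    cand_key = canonical(planted_candidate)
    pool = [g for g in universe if canonical(g) != cand_key]
    if len(pool) == len(universe):
        raise CandidateNotInUniverseError(f"{planted_candidate!r} not in universe")
    n_unique_a = size_a - n_shared
    n_unique_b = size_b - n_shared - 1  # candidate occupies one list-B slot
    if n_unique_a < 0 or n_unique_b < 0 or n_shared < 0:
        raise ColamError("list sizes incompatible with requested overlap")
    needed = n_shared + n_unique_a + n_unique_b
    if needed > len(pool):
        raise ColamError(f"universe too small: need {needed}, have {len(pool)}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=needed, replace=False)
    shared = [pool[i] for i in picks[:n_shared]]
    unique_a = [pool[i] for i in picks[n_shared : n_shared + n_unique_a]]
    unique_b = [pool[i] for i in picks[n_shared + n_unique_a :]]
    return {
        names[0]: sorted(shared + unique_a),
        names[1]: sorted(shared + unique_b + [planted_candidate]),
    }


def generate_screen_table(
    genes: Sequence[str],
    enhancer_genes: Mapping[str, float] | Sequence[str] = (),
    enhancement: float = 0.8,
    control_activity: float = 1.0,
    noise_sd: float = 0.02,
    condition: str = "MDP",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene reporter activities relative to the stimulated control (=1.0).

    ``enhancer_genes`` may be a mapping gene -> enhancement fraction, or a
    plain sequence in which case every enhancer gets ``enhancement``.
    An enhancement of 0.8 yields relative activity 1.8 (80% above control).
    """
    if enhancement < 0:
        raise ColamError("enhancement must be >= 0")
    if control_activity < 0:
        raise InvalidActivityError("control activity must be >= 0")
    if not isinstance(enhancer_genes, Mapping):
        enhancer_genes = {g: enhancement for g in enhancer_genes}
    enhancer_keys = {canonical(g): e for g, e in enhancer_genes.items()}
    if any(e < 0 for e in enhancer_keys.values()):
        raise ColamError("per-gene enhancements must be >= 0")
    rng = np.random.default_rng(seed)
    activities = []
    for g in genes:
        e = enhancer_keys.get(canonical(g), 0.0)
        activities.append(control_activity * (1.0 + e) + rng.normal(0.0, noise_sd))
    activities = np.asarray(activities)
    if (activities < 0).any():
        raise InvalidActivityError("simulated activity fell below zero; reduce noise_sd")
    return pd.DataFrame(
        {"gene": list(genes), "relative_activity": activities, "condition": condition}
    )


def generate_correlation_cohorts(
    candidate: str,
    target_r: Mapping[str, float],
    n_cohorts: int = 21,
    n_samples: int = 30,
    n_background_genes: int = 20,
    seed: int = 0,
) -> list[ExpressionCohort]:
    """Independent cohorts in which the candidate has a planted Pearson
    correlation with each target gene (e.g. r=0.6 with NOD2, r=0 with NOD1).

    Emulates a multi-cohort correlation panel: each cohort has its own
    noise realisation, with samples split evenly into case/control purely
    to satisfy the annotation contract (correlations ignore class).
    """
    for t, r in target_r.items():
        if not -1 <= r <= 1:
            raise ColamError(f"target {t!r}: correlation {r} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    cohorts = []
    for c in range(n_cohorts):
        z_cand = rng.standard_normal(n_samples)
        rows = {candidate: 8.0 + z_cand}
        for target, r in target_r.items():
            noise = rng.standard_normal(n_samples)
            rows[target] = 8.0 + r * z_cand + np.sqrt(max(0.0, 1 - r * r)) * noise
        for i in range(n_background_genes):
            rows[f"BG{i:05d}"] = 8.0 + rng.standard_normal(n_samples)
        samples = [f"S{i + 1:03d}" for i in range(n_samples)]
        half = n_samples // 2
        ann = pd.DataFrame(
            {"class": [CASE] * half + [CONTROL] * (n_samples - half)},
            index=pd.Index(samples, name="sample_id"),
        )
        matrix = pd.DataFrame(rows, index=samples).T
        matrix.index.name = "gene"
        cohorts.append(ExpressionCohort(f"corr_cohort_{c + 1:02d}", matrix, ann))
    return cohorts


@dataclass
class PrioritizationWorld:
    """A complete synthetic world for the end-to-end prioritization run."""

    cohort: ExpressionCohort
    truth: pd.DataFrame
    parent: ParentSignature
    interactome: dict[str, list[str]]
    screen: pd.DataFrame
    correlation_cohorts: list[ExpressionCohort]
    candidate: str
    targets: tuple[str, ...]


def generate_prioritization_world(
    seed: int,
    candidate: str = "CCDC88A",
    targets: tuple[str, str] = ("NOD2", "NOD1"),
    candidate_r: float = 0.6,
    effect_size: float = 3.0,
    n_case: int = 20,
    n_control: int = 20,
    n_background_genes: int = 300,
    n_corr_cohorts: int = 21,
    screen_enhancement: float = 0.9,
    decoy_enhancement: float = 0.5,
) -> PrioritizationWorld:
    """Assemble cohort + interactome + screen + correlation panel with one
    planted candidate that is (a) a unique second-list interactor, (b) a
    screen enhancer above the 75% line, and (c) consistently correlated
    with the first target across cohorts."""
    rng = np.random.default_rng(seed)
    sig = list(default_signature_genes(15, 14))
    sig.append((candidate, TOLERANT, UP))  # the planted candidate sits in the tolerant set
    design = PlantedDesign(
        signature_genes=tuple(sig),
        n_background_genes=n_background_genes,
        effect_size=effect_size,
        n_case=n_case,
        n_control=n_control,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cohort, truth = generate_case_control_cohort(design, cohort_id=f"world_{seed}")
    parent = parent_signature_for(design, include_background=True)
    # interactome universe: candidate plus genes outside the planted signature
    universe = [candidate] + [f"IX{i:04d}" for i in range(400)]
    interactome = generate_interactome_lists(
        universe, candidate, seed=int(rng.integers(0, 2**31 - 1))
    )
    # a decoy signature gene present in BOTH lists (non-specific interactor)
    decoy = sig[0][0]
    for name in interactome:
        interactome[name] = sorted(interactome[name] + [decoy])
    screen = generate_screen_table(
        [g for g, _, _ in sig],
        enhancer_genes={candidate: screen_enhancement, decoy: decoy_enhancement},
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    corr = generate_correlation_cohorts(
        candidate,
        {targets[0]: candidate_r, targets[1]: 0.0},
        n_cohorts=n_corr_cohorts,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return PrioritizationWorld(
        cohort=cohort,
        truth=truth,
        parent=parent,
        interactome=interactome,
        screen=screen,
        correlation_cohorts=corr,
        candidate=candidate,
        targets=targets,
    )
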