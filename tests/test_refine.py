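"""Refinement statistics against independent brute-force oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colam.models import (
    DOWN,
    UNDETERMINED,
    UP,
    DegenerateValuesError,
    ParentSignature,
    SingleClassError,
)
from colam.refine import (
    dichotomized_fisher_p,
    gene_auc,
    gene_stat,
    refine_signature,
    step_threshold,
)


def auc_pair_oracle(values, case_mask):
    """Brute-force Mann-Whitney pair statistic: wins + half ties over all
    (case, control) pairs, case-high counted toward AUC > 0.5."""
    cases = [v for v, c in zip(values, case_mask) if c]
    controls = [v for v, c in zip(values, case_mask) if not c]
    score = 0.0
    for a in cases:
        for b in controls:
            if a > b:
                score += 1.0
            elif a == b:
                score += 0.5
    return score / (len(cases) * len(controls))


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (math.comb only)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    observed = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= observed * (1 + 1e-9))


def step_oracle(values):
    """Exhaustive split search: per-split means and SSE, naive loops."""
    x = sorted(values)
    n = len(x)
    best = None
    for k in range(1, n):
        left, right = x[:k], x[k:]
        ml = sum(left) / k
        mr = sum(right) / (n - k)
        sse = sum((v - ml) ** 2 for v in left) + sum((v - mr) ** 2 for v in right)
        key = (sse, abs(k - n / 2), k)
        if best is None or (key[0] < best[0] - 1e-9 * max(1.0, best[0])) or (
            abs(key[0] - best[0]) <= 1e-9 * max(1.0, best[0]) and key[1:] < best[1:]
        ):
            best = (sse, abs(k - n / 2), k, (ml + mr) / 2)
    return best[3], best[2]


class TestGeneAuc:
    def test_perfect_separation(self):
        assert gene_auc([4, 3, 2, 1], ["case", "case", "control", "control"]) == 1.0

    def test_half_with_ties(self):
        # pairs: (1,1) tie, (1,2) loss, (2,1) win, (2,2) tie -> (1 + 2*0.5)/4
        assert gene_auc([1, 1, 2, 2], ["case", "control", "case", "control"]) == 0.5

    def test_label_flip_symmetry(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            values = rng.integers(0, 5, size=n).astype(float)
            case = rng.integers(0, 2, size=n).astype(bool)
            if case.all() or not case.any():
                continue
            assert gene_auc(values, case) + gene_auc(values, ~case) == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 13))
            values = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            case = rng.integers(0, 2, size=n).astype(bool)
            if case.all() or not case.any():
                continue
            assert gene_auc(values, case) == auc_pair_oracle(values, case)

    def test_matches_sklearn_cross_check(self, rng):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        for _ in range(50):
            n = int(rng.integers(4, 20))
            values = rng.normal(size=n)
            case = rng.integers(0, 2, size=n).astype(bool)
            if case.all() or not case.any():
                continue
            assert gene_auc(values, case) == pytest.approx(roc_auc_score(case, values))

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            gene_auc([1, 2, 3], ["case", "case", "case"])


class TestStepThreshold:
    def test_balanced_step(self):
        fit = step_threshold([1, 1, 1, 5, 5, 5])
        assert fit.split_index == 3
        assert fit.threshold == 3.0

    def test_outlier_step(self):
        fit = step_threshold([0, 0, 0, 0, 10])
        assert fit.split_index == 4
        assert fit.threshold == 5.0

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateValuesError):
            step_threshold([2, 2, 2, 2])

    def test_too_short(self):
        with pytest.raises(ValueError):
            step_threshold([1, 2, 3])

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 21))
            values = rng.uniform(0, 10, size=n)
            fit = step_threshold(values)
            thr, k = step_oracle(values)
            assert fit.threshold == pytest.approx(thr, abs=1e-9)
            assert fit.split_index == k


class TestFisher:
    def test_diagonal_table(self):
        # table [[5,0],[0,5]]: p = 2/C(10,5) * ... = 0.00793...
        values = [1.0] * 5 + [0.0] * 5
        labels = ["case"] * 5 + ["control"] * 5
        p = dichotomized_fisher_p(values, labels, 0.5)
        assert p == pytest.approx(fisher_oracle(5, 0, 0, 5), abs=1e-10)
        assert p == pytest.approx(0.00794, abs=5e-6)

    def test_independent_table(self):
        values = [1, 1, 1, 0, 0, 0] * 2
        labels = ["case"] * 6 + ["control"] * 6
        assert dichotomized_fisher_p(values, labels, 0.5) == 1.0

    def test_class_transposition_symmetry(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 14))
            values = rng.integers(0, 2, size=n).astype(float)
            case = rng.integers(0, 2, size=n).astype(bool)
            if case.all() or not case.any():
                continue
            p1 = dichotomized_fisher_p(values, case, 0.5)
            p2 = dichotomized_fisher_p(values, ~case, 0.5)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            p = dichotomized_fisher_p([1, 1, 1, 1], ["case", "case", "control", "control"], 5.0)
        assert p == 1.0


class TestGeneStat:
    def test_directions(self):
        labels = ["case"] * 3 + ["control"] * 3
        up = gene_stat([5, 6, 7, 1, 2, 3], labels)
        dn = gene_stat([1, 2, 3, 5, 6, 7], labels)
        assert up.direction == UP and dn.direction == DOWN
        assert up.accuracy == dn.accuracy == 1.0

    def test_tied_auc_undetermined_never_selected(self):
        stat = gene_stat([1, 2, 2, 1], ["case", "control", "case", "control"])
        assert stat.direction == UNDETERMINED
        assert not stat.selected

    def test_degenerate_expression_flagged(self):
        stat = gene_stat([3, 3, 3, 3, 3, 3], ["case"] * 3 + ["control"] * 3)
        assert "degenerate_expression" in stat.flags
        assert stat.fisher_p == 1.0 and not stat.selected

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=6, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gate_monotonicity(self, values, seed):
        """Loosening the gate (lower auc_min, higher p_max) never deselects."""
        lab_rng = np.random.default_rng(seed)
        case = lab_rng.integers(0, 2, size=len(values)).astype(bool)
        if case.all() or not case.any() or np.ptp(values) == 0:
            return
        strict = gene_stat(values, case, auc_min=0.8, p_max=0.01)
        loose = gene_stat(values, case, auc_min=0.6, p_max=0.2)
        assert not strict.selected or loose.selected


class TestRefineSignature:
    def test_planted_recovery(self, planted_world):
        design, cohort, truth, parent = planted_world
        sig = refine_signature(cohort, parent)
        selected = set(sig.i_genes.genes) | set(sig.ni_genes.genes)
        planted = set(truth["gene"])
        assert len(planted & selected) >= 29
        nulls_selected = selected - planted
        assert len(nulls_selected) <= 0.05 * design.n_background_genes
        # reactive planted genes land in the inflammatory set, tolerant in the other
        assert set(sig.i_genes.genes) & planted <= set(truth.loc[truth.cluster == "reactive", "gene"])

    def test_absent_parent_gene_reported_unscored(self, tiny_cohort):
        parent = ParentSignature({"GENEUP": "reactive", "GENEDN": "tolerant", "GHOST": "reactive"})
        sig = refine_signature(tiny_cohort, parent)
        assert sig.unscored == ["GHOST"]
        assert "GHOST" not in sig.stats["gene"].tolist()

    def test_no_parent_gene_in_cohort(self, tiny_cohort):
        from colam.models import NoSignatureGenesError

        with pytest.raises(NoSignatureGenesError):
            refine_signature(tiny_cohort, ParentSignature({"GHOST": "reactive"}))

    def test_direction_conflict_keeps_cluster_and_flags(self, planted_world):
        # tolerant gene planted UP in cases conflicts with its cluster expectation
        from colam import PlantedDesign, generate_case_control_cohort
        from colam.simulate import parent_signature_for

        design = PlantedDesign(
            signature_genes=(("ODDONE", "tolerant", "up_in_case"),),
            n_background_genes=20,
            effect_size=4.0,
            seed=5,
        )
        cohort, _ = generate_case_control_cohort(design)
        sig = refine_signature(cohort, parent_signature_for(design, include_background=False))
        assert "ODDONE" in sig.ni_genes.genes
        row = sig.stats.set_index("gene").loc["ODDONE"]
        assert "direction_conflict" in row["flags"]

    def test_fdr_gate_is_stricter(self, planted_world):
        _, cohort, _, parent = planted_world
        raw = refine_signature(cohort, parent, fdr=False)
        adj = refine_signature(cohort, parent, fdr=True)
        raw_sel = set(raw.stats.loc[raw.stats.selected, "gene"])
        adj_sel = set(adj.stats.loc[adj.stats.selected, "gene"])
        assert adj_sel <= raw_sel
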