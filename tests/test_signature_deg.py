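import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pyrosynergy.io_formats import ExpressionMatrix, GeneSet
from pyrosynergy.signature_deg import (
    availability_filter,
    bh_adjust,
    coexpression,
    contrast_overlap,
    signature_screen,
)
from pyrosynergy.signature_deg import test_gene as two_group_test
from pyrosynergy.synthetic_data import SyntheticConfig, gen_cohort

import pandas as pd


def _exact_ranksum_oracle(x1, x2):
    """Brute-force two-sided exact rank-sum p over all group assignments."""
    pooled = np.concatenate([x1, x2])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    n2 = len(x2)
    w_obs = ranks[len(x1):].sum()
    le = ge = total = 0
    for idx in itertools.combinations(range(n), n2):
        w = ranks[list(idx)].sum()
        total += 1
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    return min(1.0, 2 * min(le, ge) / total)


class TestTestGene:
    def test_degenerate_identical_constants(self):
        log2fc, p = two_group_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert log2fc == 0.0
        assert p == 1.0

    def test_separated_groups_enumeration(self):
        x1, x2 = [1.0, 1.0, 2.0, 2.0], [4.0, 5.0, 6.0, 7.0]
        log2fc, p = two_group_test(x1, x2)
        assert log2fc == pytest.approx(4.0)
        assert p == pytest.approx(2 / 70)
        assert p == pytest.approx(_exact_ranksum_oracle(x1, x2))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_mannwhitney(self, seed):
        """Tie-free small samples: exact p equals the U-test reference."""
        r = np.random.default_rng(seed)
        x1 = r.normal(size=6)
        x2 = r.normal(loc=0.8, size=7)
        _, p = two_group_test(x1, x2)
        ref = stats.mannwhitneyu(x2, x1, alternative="two-sided",
                                 method="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_approx_branch_tie_corrected(self):
        r = np.random.default_rng(1)
        x1 = np.round(r.normal(size=15), 1)  # induce ties
        x2 = np.round(r.normal(loc=0.5, size=16), 1)
        _, p = two_group_test(x1, x2)
        ref = stats.mannwhitneyu(x2, x1, alternative="two-sided",
                                 method="asymptotic", use_continuity=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_missing_values_dropped_and_floor_enforced(self):
        log2fc, _ = two_group_test([1.0, np.nan, 2.0], [3.0, 4.0])
        assert log2fc == pytest.approx(2.0)
        with pytest.raises(ValueError, match="non-missing"):
            two_group_test([1.0, np.nan], [3.0, 4.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_label_swap_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        x1 = r.normal(size=8)
        x2 = r.normal(size=9)
        fc_a, p_a = two_group_test(x1, x2)
        fc_b, p_b = two_group_test(x2, x1)
        assert fc_a == pytest.approx(-fc_b)
        assert p_a == pytest.approx(p_b)


class TestBhAdjust:
    def _oracle(self, p):
        """Step-up recursion: q_(i) = min(q_(i+1), m*p_(i)/i)."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            prev = min(prev, m * p[order[rank - 1]] / rank)
            q_sorted[rank - 1] = prev
        out = np.empty(m)
        out[order] = q_sorted
        return out

    def test_hand_enumerated_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p", [[0.2], [1.0, 1.0, 1.0],
                                   [0.5, 0.001, 0.04, 0.04, 0.9]])
    def test_matches_step_up_recursion(self, p):
        assert bh_adjust(p) == pytest.approx(self._oracle(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_recursion_equivalence_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(self._oracle(p))
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSignatureScreen:
    def test_planted_de_recovery(self):
        cfg = SyntheticConfig(seed=17)
        expr, _, truth = gen_cohort(cfg)
        gs = GeneSet("SIG", genes=list(expr.data.index))
        res, unmeasured = signature_screen(expr, gs,
                                           class_order=["normal", "tumor"])
        assert unmeasured == []
        called = {r.gene: r.direction for r in res if r.direction != "ns"}
        planted = truth.de_directions
        recovered = sum(called.get(g) == d for g, d in planted.items())
        assert recovered >= 27
        assert len(set(called) - set(planted)) <= 2

    def test_alpha_zero_flags_nothing(self, toy_expression):
        gs = GeneSet("S", genes=["AIM2", "BCL2", "GBP5"])
        res, _ = signature_screen(toy_expression, gs, alpha=0.0)
        assert all(r.direction == "ns" for r in res)

    def test_absent_gene_listed_unmeasured(self, toy_expression):
        gs = GeneSet("S", genes=["AIM2", "TNF"])
        res, unmeasured = signature_screen(toy_expression, gs)
        assert [r.gene for r in res] == ["AIM2"]
        assert unmeasured == ["TNF"]

    def test_direction_respects_both_thresholds(self):
        # strong shift on G1 only; G2 shifted but below fc_min
        data = pd.DataFrame(
            [[0.0, 0.1, 0.2, 2.0, 2.1, 2.2],
             [0.0, 0.1, 0.2, 0.5, 0.6, 0.7]],
            index=["G1", "G2"],
            columns=[f"s{i}" for i in range(6)],
        )
        classes = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        expr = ExpressionMatrix(data, classes)
        res, _ = signature_screen(expr, GeneSet("S", genes=["G1", "G2"]),
                                  alpha=0.15, fc_min=1.0,
                                  class_order=["a", "b"])
        by_gene = {r.gene: r for r in res}
        assert by_gene["G1"].direction == "up"
        assert by_gene["G2"].direction == "ns"

    def test_type_i_calibration_on_null_cohort(self):
        cfg = SyntheticConfig(seed=29, n_tumor=40, n_normal=40, n_genes=400,
                              de_log2fc=0.0, n_risk_genes=2)
        expr, _, _ = gen_cohort(cfg)
        gs = GeneSet("ALL", genes=list(expr.data.index))
        res, _ = signature_screen(expr, gs, class_order=["normal", "tumor"])
        rate = np.mean([r.p < 0.05 for r in res])
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) <= 2 * se


class TestAvailabilityFilter:
    def _panel(self, genes):
        data = pd.DataFrame(np.zeros((len(genes), 3)), index=genes,
                            columns=["c1", "c2", "c3"])
        return ExpressionMatrix(data, {c: "cell_line" for c in data.columns})

    def test_printed_28_gene_example(self):
        from pyrosynergy.gene_lists import (
            BLBC_PYROPTOSIS_REGULATORS,
            NCI60_UNMEASURED,
        )

        panel = self._panel(
            [g for g in BLBC_PYROPTOSIS_REGULATORS if g not in NCI60_UNMEASURED])
        kept, dropped = availability_filter(BLBC_PYROPTOSIS_REGULATORS, panel)
        assert len(kept) == 20
        assert sorted(dropped) == sorted(NCI60_UNMEASURED)

    def test_partition_invariant(self):
        panel = self._panel(["A1", "B1"])
        kept, dropped = availability_filter(["A1", "B1", "C1"], panel)
        assert kept + dropped != []
        assert set(kept) | set(dropped) == {"A1", "B1", "C1"}
        assert set(kept).isdisjoint(dropped)

    def test_empty_input(self):
        panel = self._panel(["A1"])
        assert availability_filter([], panel) == ([], [])


class TestContrastOverlap:
    def test_two_set_regions(self):
        _, regions = contrast_overlap({"one": ["A", "B"], "two": ["B", "C"]})
        assert regions[("one",)] == 1
        assert regions[("two",)] == 1
        assert regions[("one", "two")] == 1

    def test_identical_sets_all_shared(self):
        _, regions = contrast_overlap({"x": ["A", "B"], "y": ["A", "B"]})
        assert regions == {("x", "y"): 2}

    def test_three_random_sets_match_power_set_enumeration(self, rng):
        universe = [f"G{i}" for i in range(40)]
        sets = {k: set(rng.choice(universe, size=15, replace=False))
                for k in ("s1", "s2", "s3")}
        table, regions = contrast_overlap(sets)
        # brute force every region over the power set of set names
        expected = {}
        for g in set().union(*sets.values()):
            key = tuple(sorted(k for k in sets if g in sets[k]))
            expected[key] = expected.get(key, 0) + 1
        assert regions == expected
        assert int(table.to_numpy().sum()) == sum(len(s) for s in sets.values())


class TestCoexpression:
    def _expr(self, arr, genes):
        data = pd.DataFrame(arr, index=genes,
                            columns=[f"s{i}" for i in range(arr.shape[1])])
        return ExpressionMatrix(data, {c: "x" for c in data.columns})

    def test_duplicate_gene_perfectly_correlated(self, rng):
        v = rng.normal(size=10)
        expr = self._expr(np.vstack([v, v, rng.normal(size=10)]),
                          ["A1", "A2", "B1"])
        cm = coexpression(expr, GeneSet("S", genes=["A1", "A2", "B1"]))
        assert cm.r_matrix[0, 1] == pytest.approx(1.0)

    def test_negation_anticorrelated(self, rng):
        v = rng.normal(size=10)
        expr = self._expr(np.vstack([v, -v]), ["A1", "B1"])
        cm = coexpression(expr, GeneSet("S", genes=["A1", "B1"]))
        assert cm.r_matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        arr = rng.normal(size=(4, 10))
        genes = ["A1", "B1", "C1", "D1"]
        cm = coexpression(self._expr(arr, genes), GeneSet("S", genes=genes))
        for i in range(4):
            for j in range(4):
                xi, xj = arr[i] - arr[i].mean(), arr[j] - arr[j].mean()
                ref = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cm.r_matrix[i, j] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_gene_goes_missing(self, rng):
        arr = np.vstack([np.full(10, 3.0), rng.normal(size=10),
                         rng.normal(size=10)])
        genes = ["FLAT", "B1", "C1"]
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = coexpression(self._expr(arr, genes), GeneSet("S", genes=genes))
        assert np.isnan(cm.r_matrix[0, 1])
        assert not np.isnan(cm.r_matrix[1, 2])
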