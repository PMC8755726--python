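"""Unit and property tests for the statistical primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_stepup, fisher_enumeration, hypergeom_tail, mann_whitney_enumeration
from xenosig.stats_core import (
    Contingency2x2,
    bh_adjust,
    fisher_exact_2x2,
    hypergeometric_enrichment,
    mann_whitney_exact,
    tumor_volume,
    unpaired_t_test,
    zscore,
)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, expected_u, expected_p",
        [
            # complete separation, sizes 5 and 4: p = 2/126
            ([1, 2, 3, 4, 5], [6, 7, 8, 9], 0, 0.0159),
            # complete separation, sizes 4 and 4: p = 2/70
            ([1, 2, 3, 4], [5, 6, 7, 8], 0, 0.0286),
            # one rank inversion (U = 1), sizes 5 and 4: p = 4/126
            ([1, 2, 3, 4, 6], [5, 7, 8, 9], 1, 0.0317),
        ],
    )
    def test_small_sample_exact_values(self, x, y, expected_u, expected_p):
        u, p = mann_whitney_exact(x, y)
        assert u == expected_u
        assert p == pytest.approx(expected_p, abs=5e-5)

    def test_identical_samples_approximation_path(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney_exact(x, x)  # ties force the normal approximation
        assert p > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_exact_matches_enumeration_all_small_sizes(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
                x, y = vals[:n1], vals[n1:]
                u_impl, p_impl = mann_whitney_exact(x, y)
                u_ref, p_ref = mann_whitney_enumeration(x, y)
                assert u_impl == u_ref
                assert p_impl == pytest.approx(p_ref, abs=1e-12)

    def test_null_type_one_error_calibrated(self, rng):
        alpha, n_rej, reps = 0.05, 0, 2000
        for _ in range(reps):
            x, y = rng.standard_normal(6), rng.standard_normal(6)
            if mann_whitney_exact(x, y)[1] < alpha:
                n_rej += 1
        assert 0.03 <= n_rej / reps <= 0.07


class TestFisher:
    def test_macrometastasis_table(self):
        # 5/8 vs 1/10 mice with macrometastases
        p = fisher_exact_2x2(Contingency2x2(5, 3, 1, 9))
        assert p == pytest.approx(0.043, abs=5e-4)

    def test_degenerate_column_gives_one(self):
        assert fisher_exact_2x2(Contingency2x2(4, 0, 7, 0)) == 1.0

    def test_matches_margin_preserving_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 7, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact_2x2(Contingency2x2(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-10)


class TestBH:
    def test_single_test_unchanged(self):
        assert bh_adjust([0.05]).adjusted == (0.05,)

    def test_stepup_with_cumulative_min(self):
        res = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert res.adjusted == pytest.approx((0.04, 0.04, 0.04, 0.04))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_hand_stepup_and_dominates_raw(self, pvals):
        res = bh_adjust(pvals)
        adj = np.asarray(res.adjusted)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        assert adj == pytest.approx(bh_stepup(pvals), abs=1e-12)

    def test_fdr_control_with_planted_signal(self, rng):
        # 10% true effects among 2000 genes; empirical FDR <= 1.5 x nominal
        n_genes, n_true, reps = 2000, 200, 40
        fdrs = []
        for _ in range(reps):
            p = rng.random(n_genes)
            p[:n_true] = rng.beta(0.05, 8, size=n_true)  # strong true effects
            rej = np.asarray(bh_adjust(p).adjusted) < 0.05
            if rej.sum():
                fdrs.append(rej[n_true:].sum() / rej.sum())
        assert np.mean(fdrs) <= 1.5 * 0.05


class TestEnrichment:
    def test_selected_equals_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(20)]
        sets = {"S": uni[:5]}
        res = hypergeometric_enrichment(uni, sets, uni)
        assert len(res) == 1
        assert res[0].p == pytest.approx(1.0)

    def test_full_overlap_matches_tail_sum(self):
        uni = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(uni[:5], {"S": uni[:5]}, uni)
        assert res[0].p == pytest.approx(hypergeom_tail(5, 20, 5, 5), rel=1e-12)

    def test_disjoint_set_excluded(self):
        uni = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(uni[:5], {"S": uni[10:15]}, uni)
        assert res == []

    def test_selected_outside_universe_dropped(self):
        uni = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(
            uni[:3] + ["absent"], {"S": uni[:5]}, uni, p_cutoff=0.5, adj_cutoff=0.5
        )
        assert res[0].n == 3


class TestTTest:
    def test_identical_samples(self):
        assert unpaired_t_test([1, 2, 3], [1, 2, 3])[1] == pytest.approx(1.0)

    def test_clear_shift_significant(self, rng):
        x = np.zeros(3) + rng.normal(0, 1e-3, 3)
        y = np.ones(3) + rng.normal(0, 1e-3, 3)
        assert unpaired_t_test(x, y)[1] < 0.01

    def test_swap_symmetry(self, rng):
        x, y = rng.standard_normal(5), rng.standard_normal(7)
        t1, p1 = unpaired_t_test(x, y)
        t2, p2 = unpaired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_degenerate_cases(self):
        assert unpaired_t_test([1.0, 1.0], [1.0, 1.0])[1] == 1.0
        assert unpaired_t_test([1.0, 1.0], [2.0, 2.0])[1] == 0.0

    def test_null_type_one_error_calibrated(self, rng):
        reps = 2000
        x = rng.standard_normal((reps, 4))
        y = rng.standard_normal((reps, 4))
        n_rej = sum(unpaired_t_test(x[i], y[i])[1] < 0.05 for i in range(reps))
        assert 0.03 <= n_rej / reps <= 0.07


class TestTumorVolume:
    def test_subcutaneous_formula(self):
        assert tumor_volume("subcutaneous", (2, 1)) == pytest.approx(1.0)

    def test_orthotopic_formula(self):
        assert tumor_volume("orthotopic", (1, 1, 1)) == pytest.approx(4 * math.pi / 18)

    def test_cubic_homogeneity(self):
        v1 = tumor_volume("orthotopic", (1.5, 2.0, 2.5))
        v2 = tumor_volume("orthotopic", (3.0, 4.0, 5.0))
        assert v2 == pytest.approx(8 * v1)

    @pytest.mark.parametrize(
        "kind, dims", [("orthotopic", (1, 2)), ("subcutaneous", (1, 2, 3)), ("spherical", (1, 1))]
    )
    def test_wrong_arity_or_kind_rejected(self, kind, dims):
        with pytest.raises(ValueError):
            tumor_volume(kind, dims)


class TestZscore:
    def test_hand_computed_example(self):
        assert zscore([1, 2, 3]) == pytest.approx([-1.224745, 0, 1.224745], abs=1e-5)

    def test_idempotent_on_standardized_input(self, rng):
        v = zscore(rng.standard_normal(30))
        assert zscore(v) == pytest.approx(v, abs=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, a, b):
        v = np.array([0.3, -1.2, 2.5, 0.0, 1.1])
        assert zscore(a * v + b) == pytest.approx(zscore(v), abs=1e-8)

    def test_constant_vector_maps_to_zeros(self):
        assert np.all(zscore([5.0, 5.0, 5.0]) == 0)
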