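"""Quartile grouping, the global-test statistic and its tail probabilities."""

import numpy as np
import pytest

import mirdrug as md
from mirdrug.pathway import _permutation_moments

from conftest import (
    global_test_q_oracle,
    permutation_p_enumeration,
)


class TestQuartileGroups:
    def test_36_samples_quarter_gives_9_per_group(self, rng):
        ids = [f"s{i}" for i in range(36)]
        g = md.quartile_groups(rng.normal(size=36), ids, fraction=0.25)
        assert g.group_size == 9
        assert len(g.top_ids) == len(g.bottom_ids) == 9
        assert not set(g.top_ids) & set(g.bottom_ids)

    def test_floor_arithmetic_at_n8(self, rng):
        g = md.quartile_groups(rng.normal(size=8), [f"s{i}" for i in range(8)])
        assert g.group_size == 2

    def test_sorted_input_takes_ends(self):
        ids = [f"s{i:02d}" for i in range(12)]
        g = md.quartile_groups(np.arange(12.0), ids, fraction=0.25)
        assert g.bottom_ids == tuple(ids[:3])
        assert g.top_ids == tuple(ids[-3:])

    def test_ties_break_deterministically_by_sample_id(self):
        ids = ["b", "a", "d", "c", "f", "e", "h", "g"]
        g1 = md.quartile_groups(np.zeros(8), ids, fraction=0.25)
        g2 = md.quartile_groups(np.zeros(8), ids, fraction=0.25)
        assert g1 == g2
        assert g1.bottom_ids == ("a", "b")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            md.quartile_groups(np.arange(6.0), [f"s{i}" for i in range(6)])


BINARY_Y = np.array([0.0, 0, 0, 1, 1, 1])


class TestGlobalTestQ:
    def test_constant_genes_give_zero(self):
        X = np.ones((4, 6)) * 3.0
        assert md.global_test_q(X, BINARY_Y) == 0.0

    def test_single_gene_equal_to_centered_labels(self):
        # x = y_c: Q = (y_c.y_c)^2 / (1 * s^2) = n * (y_c.y_c)
        y_c = BINARY_Y - BINARY_Y.mean()
        q = md.global_test_q(y_c[None, :], BINARY_Y)
        assert q == pytest.approx(len(BINARY_Y) * (y_c @ y_c))

    def test_matches_dense_quadratic_form_oracle(self, rng):
        for _ in range(10):
            X = rng.normal(size=(7, 10))
            y = np.array([0.0] * 5 + [1.0] * 5)
            assert md.global_test_q(X, y) == pytest.approx(
                global_test_q_oracle(X, y), rel=1e-10
            )

    def test_invariances(self, rng):
        X = rng.normal(size=(5, 8))
        y = np.array([0.0] * 4 + [1.0] * 4)
        q = md.global_test_q(X, y)
        assert md.global_test_q(X, 1 - y) == pytest.approx(q)  # label swap
        assert md.global_test_q(X[::-1], y) == pytest.approx(q)  # gene order
        assert md.global_test_q(X + 7.0, y + 3.0) == pytest.approx(q)  # shifts

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            md.global_test_q(rng.normal(size=(3, 6)), np.ones(6))


class TestPermutationP:
    def test_add_one_floor(self, rng):
        X = rng.normal(size=(4, 10))
        y = np.array([0.0] * 5 + [1.0] * 5)
        p = md.permutation_p(X, y, n_perm=200, seed=1)
        assert p >= 1 / 201

    def test_observed_minimum_gives_p_one(self):
        # labels exactly orthogonal to the only gene pattern: Q_obs = 0, the
        # distribution's minimum, so every permutation lands in the tail
        X = np.vstack([np.array([1.0, -1, 1, -1, 1, -1])] * 3)
        y = np.array([0.0, 0, 1, 1, 0, 0])  # x . y_c = 0
        assert md.permutation_p(X, y, n_perm=400, seed=2) == 1.0

    def test_converges_to_enumeration_at_n6(self, rng):
        X = rng.normal(size=(5, 6))
        y = BINARY_Y
        exact = permutation_p_enumeration(X, y)
        mc = md.permutation_p(X, y, n_perm=4000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(mc - exact) <= 4 * se + 1e-3

    def test_reproducible_for_fixed_seed(self, rng):
        X = rng.normal(size=(4, 12))
        y = np.array([0.0] * 6 + [1.0] * 6)
        assert md.permutation_p(X, y, 300, seed=9) == md.permutation_p(X, y, 300, seed=9)


class TestApproxP:
    def test_enumeration_route_matches_oracle(self, rng):
        X = rng.normal(size=(5, 6))
        p = md.approx_p(X, BINARY_Y)
        assert p == pytest.approx(permutation_p_enumeration(X, BINARY_Y))

    def test_three_vs_three_toy_within_tolerance_of_enumeration(self, rng):
        for _ in range(5):
            X = rng.normal(size=(4, 6))
            assert abs(
                md.approx_p(X, BINARY_Y) - permutation_p_enumeration(X, BINARY_Y)
            ) <= 0.05

    def test_moment_route_matches_enumeration_moments(self, rng):
        X = rng.normal(size=(6, 10))
        y = np.array([0.0] * 6 + [1.0] * 4)
        X_c = X - X.mean(axis=1, keepdims=True)
        A = X_c.T @ X_c
        from itertools import combinations

        vals = []
        for idx in combinations(range(10), 4):
            z = np.zeros(10)
            z[list(idx)] = 1.0
            vals.append(z @ A @ z)
        vals = np.asarray(vals)
        mean, var = _permutation_moments(A, 10, 4)
        assert mean == pytest.approx(vals.mean(), rel=1e-10)
        assert var == pytest.approx(vals.var(), rel=1e-10)

    def test_moment_route_close_to_enumeration_p(self, rng):
        """Force the chi-square route at a size where enumeration is still exact."""
        for _ in range(5):
            X = rng.normal(size=(8, 12))
            y = np.array([0.0] * 6 + [1.0] * 6)
            p_chi = md.approx_p(X, y, max_enum=1)
            p_ex = permutation_p_enumeration(X, y)
            assert abs(p_chi - p_ex) <= 0.05

    def test_null_p_is_approximately_uniform(self):
        rng = np.random.default_rng(1234)
        n, g, m = 18, 9, 15
        y = np.array([0.0] * g + [1.0] * g)
        ps = []
        for _ in range(300):
            X = rng.normal(size=(m, n))
            ps.append(md.approx_p(X, y))
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - np.arange(1, 301) / 301))
        assert ks < 0.1

    def test_strong_signal_detected(self, rng):
        y = np.array([0.0] * 9 + [1.0] * 9)
        X = np.vstack([y + rng.normal(0, 0.3, size=18) for _ in range(50)])
        assert md.approx_p(X, y) < 0.001

    def test_zero_variance_returns_one(self):
        X = np.ones((3, 8))
        y = np.array([0.0] * 4 + [1.0] * 4)
        assert md.approx_p(X, y, max_enum=1) == 1.0


class TestPathwayScreen:
    def test_planted_set_significant_null_sets_not(self, small_panel):
        panel = small_panel
        res = md.pathway_screen(
            panel.mrna, panel.gene_sets, panel.mirna, ["miR-0001"],
            n_perm=500, seed=7,
        )
        by_name = {r.set_name: r for r in res}
        assert by_name["SET_planted_1"].significant
        assert not any(r.significant for n, r in by_name.items() if "null" in n)

    def test_bh_pool_is_per_mirna(self, small_panel):
        panel = small_panel
        solo = md.pathway_screen(
            panel.mrna, panel.gene_sets, panel.mirna, ["miR-0001"],
            n_perm=200, seed=7,
        )
        joint = md.pathway_screen(
            panel.mrna, panel.gene_sets, panel.mirna, ["miR-0001", "miR-0005"],
            n_perm=200, seed=7,
        )
        solo_bh = {r.set_name: r.p_bh for r in solo}
        joint_bh = {r.set_name: r.p_bh for r in joint if r.mirna_id == "miR-0001"}
        assert solo_bh == pytest.approx(joint_bh)

    def test_dual_criterion_enforced(self, small_panel):
        panel = small_panel
        res = md.pathway_screen(
            panel.mrna, panel.gene_sets, panel.mirna, ["miR-0001"],
            n_perm=500, seed=7,
        )
        for r in res:
            assert r.significant == (r.p_bh < 0.1 and r.p_perm < 0.05)
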