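"""The three branch analyses and the panel-wide association driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mirdrug as md
from mirdrug.association import Direction, _vectorised_spearman
from mirdrug.profile_classifier import Branch

from conftest import mannwhitney_enumeration_p


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = md.spearman_assoc([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_perfect_antitone(self):
        rho, _ = md.spearman_assoc([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_rank_pearson_formula_oracle(self):
        # ranks of y = [2,1,4,3] against x ranks [1,2,3,4]: rho = 0.6 by the
        # Pearson-of-ranks formula; p from t = rho sqrt((n-2)/(1-rho^2))
        rho, p = md.spearman_assoc([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        assert p == pytest.approx(2 * stats.t.sf(t, df=2))

    def test_matches_scipy_with_ties(self, rng):
        x = rng.normal(size=30)
        y = np.round(rng.normal(size=30), 1)  # ties likely
        rho, p = md.spearman_assoc(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            md.spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pairwise_missing_removal(self):
        rho, _ = md.spearman_assoc(
            [1, 2, 3, 4, np.nan], [2, 4, 6, 8, 0.0]
        )
        assert rho == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(-100, 100), min_size=5, max_size=15, unique=True))
    def test_invariance_under_strictly_increasing_transform(self, xs):
        """Rank statistics cannot see monotone rescaling (raw vs log10 alike)."""
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.normal(size=len(xs))
        x = np.array(xs, dtype=float)
        rho1, p1 = md.spearman_assoc(x, y)
        rho2, p2 = md.spearman_assoc(np.exp(x / 50), y)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_sign_flip_under_neglog10(self, rng):
        """rho(x, -log10 y) = -rho(x, y) for positive y."""
        x = rng.normal(size=20)
        y = 10.0 ** rng.uniform(-8, -5, size=20)
        rho_raw, _ = md.spearman_assoc(x, y)
        rho_neg, _ = md.spearman_assoc(x, -np.log10(y))
        assert rho_neg == pytest.approx(-rho_raw)

    def test_vectorised_path_matches_scalar(self, rng):
        X = rng.normal(size=(10, 25))
        y = rng.normal(size=25)
        rho_v, p_v = _vectorised_spearman(X, y)
        for i in range(10):
            rho_s, p_s = md.spearman_assoc(X[i], y)
            assert rho_v[i] == pytest.approx(rho_s)
            assert p_v[i] == pytest.approx(p_s, rel=1e-9)


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, direction = md.mann_whitney_assoc(
            np.array([1, 2, 3, 4, 5, 6.0]),
            np.array([False, False, False, True, True, True]),
        )
        assert u == 9.0  # n1 * n2
        assert p == pytest.approx(0.1)  # 2 * 2/20 from full enumeration
        assert direction is Direction.RESISTANCE

    def test_interleaved_groups_not_significant(self):
        u, p, _ = md.mann_whitney_assoc(
            np.array([1, 2, 3, 4, 5, 6.0]),
            np.array([False, True, False, True, False, True]),
        )
        assert p > 0.5

    def test_identical_groups_give_central_u(self):
        u, _, direction = md.mann_whitney_assoc(
            np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),
            np.array([True, True, True, False, False, False]),
        )
        assert u == 4.5  # n1 n2 / 2
        assert direction is Direction.SENSITIVITY  # tie resolves to sensitivity

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            md.mann_whitney_assoc(np.array([1.0, 2.0]), np.array([True, True]))

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_p_equals_enumeration(self, n1, n2, rng):
        """Small tie-free samples: the exact method is the full enumeration."""
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            labels = np.array([True] * n1 + [False] * n2)
            u, p, _ = md.mann_whitney_assoc(vals, labels)
            u_ref, p_ref = mannwhitney_enumeration_p(vals[:n1], vals[n1:])
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_uses_corrected_normal_approximation(self, rng):
        vals = np.round(rng.normal(size=40), 1)
        labels = rng.random(40) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        u, p, _ = md.mann_whitney_assoc(vals, labels)
        ref = stats.mannwhitneyu(vals[labels], vals[~labels],
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        assert (u, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))


def make_two_step_profile(mirna, latent, censor_fraction=0.3):
    """Profile on the 2-step branch from a latent -log10 IC50 vector."""
    ic50 = 10.0 ** (-np.asarray(latent, dtype=float))
    max_conc = float(np.quantile(ic50, 1 - censor_fraction))
    ic50 = np.minimum(ic50, max_conc)
    ids = tuple(f"s{i}" for i in range(len(ic50)))
    return md.DrugResponseProfile("d", ids, ic50, max_conc)


class TestTwoStep:
    def test_planted_effect_screens_and_confirms(self, rng):
        n = 36
        x = rng.normal(0, 1, size=n)
        latent = 6 + 1.2 * x + rng.normal(0, 0.2, size=n)
        p = make_two_step_profile(x, latent)
        assert md.classify_profile(p).branch is Branch.TWO_STEP
        out = md.two_step_assoc(p, x)
        assert out.screened
        assert out.final_p is not None and out.final_p < 0.05
        assert out.step1[0] > 0

    def test_null_rarely_screens(self):
        n = 36
        hits = 0
        reps = 200
        rng = np.random.default_rng(5)
        for _ in range(reps):
            x = rng.normal(size=n)
            latent = 6 + rng.normal(0, 0.4, size=n)
            p = make_two_step_profile(x, latent)
            out = md.two_step_assoc(p, x)
            hits += out.screened
        assert hits / reps <= 0.10  # screened in <= 10% of null replicates

    def test_constant_variable_values_not_screenable(self):
        ic50 = np.array([1e-6] * 12 + [1e-5] * 24)
        p = md.DrugResponseProfile("d", tuple(f"s{i}" for i in range(36)), ic50, 1e-5)
        out = md.two_step_assoc(p, np.arange(36.0))
        assert not out.screened
        assert "not screenable" in out.note

    def test_branch_mismatch_rejected(self, rng):
        x = rng.normal(size=36)
        latent = 6 + rng.normal(0, 0.3, size=36)
        p = make_two_step_profile(x, latent, censor_fraction=0.0)
        with pytest.raises(ValueError, match="not on the 2-step branch"):
            md.two_step_assoc(p, x)


class TestAssociateAll:
    def test_planted_pair_has_smallest_p(self, rng):
        n = 30
        ids = tuple(f"s{i}" for i in range(n))
        X = rng.normal(2, 0.4, size=(51, n))
        latent = 6 + 1.0 * (X[0] - 2) + rng.normal(0, 0.25, size=n)
        ic50 = 10.0 ** (-latent)
        drug = md.DrugResponseProfile("drug", ids, ic50, float(ic50.max() * 1.2))
        mirna = md.ExpressionMatrix(
            tuple(f"m{i}" for i in range(51)), ids, X, md.Scale.LOG10
        )
        res = md.associate_all(mirna, [drug])
        best = min(res, key=lambda r: r.p_value)
        assert best.mirna == "m0"
        assert best.direction is Direction.SENSITIVITY

    def test_direction_follows_rho_sign(self, rng):
        n = 24
        ids = tuple(f"s{i}" for i in range(n))
        x = rng.normal(0, 1, size=n)
        latent = 6 + 1.5 * x  # higher miRNA -> higher -log10 IC50 -> sensitivity
        ic50 = 10.0 ** (-latent)
        drug = md.DrugResponseProfile("drug", ids, ic50, float(ic50.max() * 1.2))
        mirna = md.ExpressionMatrix(
            ("up", "down"), ids, np.vstack([x, -x]), md.Scale.LOG10
        )
        res = {r.mirna: r for r in md.associate_all(mirna, [drug])}
        assert res["up"].direction is Direction.SENSITIVITY
        assert res["down"].direction is Direction.RESISTANCE

    def test_raw_scale_matrix_rejected(self, rng):
        ids = ("a", "b", "c", "d")
        mirna = md.ExpressionMatrix(("m",), ids, np.ones((1, 4)) * 2, md.Scale.RAW)
        drug = md.DrugResponseProfile("d", ids, np.full(4, 1e-6), 1e-5)
        with pytest.raises(ValueError, match="log10"):
            md.associate_all(mirna, [drug])

    def test_disjoint_samples_rejected(self, rng):
        mirna = md.ExpressionMatrix(
            ("m",), ("a", "b"), rng.normal(size=(1, 2)), md.Scale.LOG10
        )
        drug = md.DrugResponseProfile("d", ("x", "y"), np.full(2, 1e-6), 1e-5)
        with pytest.raises(ValueError, match="shares"):
            md.associate_all(mirna, [drug])

    def test_output_covers_every_branch(self, small_panel):
        res = md.associate_all(small_panel.mirna, small_panel.drugs)
        branches = {r.branch.branch for r in res}
        assert branches == {Branch.SPEARMAN, Branch.TWO_STEP, Branch.MANN_WHITNEY}
        # every non-degenerate pair appears at most once
        keys = [(r.mirna, r.drug) for r in res]
        assert len(keys) == len(set(keys))
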