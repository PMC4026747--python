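import numpy as np
import pytest
from scipy import stats

from rvassoc.data import GenotypeMatrix
from rvassoc import scoretests as st


def direct_components(X, y):
    """Element-by-element summation oracle for U, V and sigma0^2."""
    n, k = X.shape
    ybar = sum(y) / n
    xbar = X.sum(axis=0) / n
    U = np.zeros(k)
    V = np.zeros((k, k))
    s0 = sum((yi - ybar) ** 2 for yi in y) / (n - 1)
    for i in range(n):
        U += (y[i] - ybar) * X[i]
        V += s0 * np.outer(X[i] - xbar, X[i] - xbar)
    return U, V, s0


class TestScoreComponents:
    def test_constant_trait_kills_score(self, rng):
        X = rng.integers(0, 3, (10, 3)).astype(float)
        sc = st.compute_score_components(X, np.full(10, 2.5))
        assert np.allclose(sc.U, 0)
        assert np.allclose(sc.V, 0)
        assert sc.degenerate

    def test_hand_example_n2(self):
        sc = st.compute_score_components(np.array([[0.0], [1.0]]),
                                         np.array([0.0, 1.0]))
        assert sc.U[0] == pytest.approx(0.5)
        assert sc.sigma0_sq == pytest.approx(0.5)
        assert sc.V[0, 0] == pytest.approx(0.25)

    def test_matches_direct_summation(self, rng):
        X = rng.integers(0, 3, (10, 3)).astype(float)
        y = rng.normal(size=10)
        sc = st.compute_score_components(X, y)
        U, V, s0 = direct_components(X, y)
        assert np.allclose(sc.U, U, atol=1e-10)
        assert np.allclose(sc.V, V, atol=1e-10)
        assert sc.sigma0_sq == pytest.approx(s0, abs=1e-12)


class TestScoreTest:
    def test_zero_score(self, rng):
        X = rng.integers(0, 3, (10, 2)).astype(float)
        sc = st.compute_score_components(X, np.full(10, 1.0))
        res = st.score_test(sc)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_example(self):
        sc = st.compute_score_components(np.array([[0.0], [1.0]]),
                                         np.array([0.0, 1.0]))
        res = st.score_test(sc)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(1.0, 1))


class TestReductions:
    """Single-variant and degenerate cases collapse to the score test."""

    def test_ssu_k1_equals_score(self, small_dataset):
        geno, y = small_dataset
        X1 = geno.dosages[:, :1]
        sc = st.compute_score_components(X1, y)
        assert st.ssu_test(sc).p_value == pytest.approx(
            st.score_test(sc).p_value, abs=1e-6)

    def test_ssuw_diagonal_equals_score(self, rng):
        # Walsh-pattern dosages: centered columns orthogonal -> V diagonal
        h = np.array([[1, 1, 1], [1, -1, 1], [1, 1, -1], [1, -1, -1],
                      [-1, 1, 1], [-1, -1, 1], [-1, 1, -1], [-1, -1, -1]])
        X = (1.0 + h[:, [0, 1, 2]] * np.array([1, 1, 1]))  # entries in {0, 2}
        Xc = X - X.mean(0)
        V = Xc.T @ Xc
        assert np.allclose(V - np.diag(np.diag(V)), 0)
        y = rng.normal(size=8)
        sc = st.compute_score_components(X, y)
        assert st.ssuw_test(sc).statistic == pytest.approx(
            st.score_test(sc).statistic, rel=1e-8)
        assert st.ssuw_test(sc).p_value == pytest.approx(
            st.score_test(sc).p_value, abs=1e-6)

    def test_uminp_k1_equals_score(self, small_dataset):
        geno, y = small_dataset
        X1 = geno.dosages[:, :1]
        sc = st.compute_score_components(X1, y)
        assert st.uminp_test(sc).p_value == pytest.approx(
            st.score_test(sc).p_value, abs=1e-6)

    def test_uminp_duplicate_columns_collapse(self, rng):
        a = rng.integers(0, 3, 50).astype(float)
        y = rng.normal(size=50) + 0.4 * a
        sc2 = st.compute_score_components(np.column_stack([a, a]), y)
        sc1 = st.compute_score_components(a[:, None], y)
        assert st.uminp_test(sc2).p_value == pytest.approx(
            st.uminp_test(sc1).p_value, abs=1e-4)


class TestFTest:
    def test_orthogonal_trait(self):
        X = np.array([[0.0, 1], [1, 0], [0, 1], [1, 0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to centered X
        res = st.f_test(X, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_fit_flagged(self, rng):
        X = rng.integers(0, 3, (20, 2)).astype(float)
        y = 1.0 + 2.0 * X[:, 0] - X[:, 1]
        res = st.f_test(X, y)
        assert res.p_value == 0.0
        assert res.degenerate

    def test_matches_rss_ratio_oracle(self, rng):
        X = rng.integers(0, 3, (20, 3)).astype(float)
        y = rng.normal(size=20) + X[:, 1]
        Xc = X - X.mean(0)
        yc = y - y.mean()
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        rss1 = np.sum((yc - Xc @ beta) ** 2)
        rss0 = np.sum(yc**2)
        F = ((rss0 - rss1) / 3) / (rss1 / (20 - 3 - 1))
        res = st.f_test(X, y)
        assert res.statistic == pytest.approx(F, abs=1e-10)
        assert res.p_value == pytest.approx(stats.f.sf(F, 3, 16), abs=1e-12)

    def test_matches_statsmodels(self, small_dataset):
        sm = pytest.importorskip("statsmodels.api")
        geno, y = small_dataset
        fit = sm.OLS(y, sm.add_constant(geno.dosages)).fit()
        res = st.f_test(geno, y)
        assert res.statistic == pytest.approx(fit.fvalue, rel=1e-8)
        assert res.p_value == pytest.approx(fit.f_pvalue, rel=1e-6)


class TestSumTest:
    def test_k1_equals_marginal_regression(self, rng):
        x = rng.integers(0, 3, 40).astype(float)
        y = rng.normal(size=40) + 0.5 * x
        res = st.sum_test(x[:, None], y)
        lr = stats.linregress(x, y)
        assert res.p_value == pytest.approx(lr.pvalue, rel=1e-9)

    def test_opposite_effects_cancel(self, rng):
        a = rng.integers(0, 2, 200).astype(float)
        b = 1.0 - a  # perfectly anticorrelated carriers
        X = np.column_stack([a, b])
        y = 2.0 * a - 2.0 * b + rng.normal(0, 0.1, 200)
        # row sum is constant -> the burden covariate carries no signal
        res = st.sum_test(X, y)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_column_order_invariance(self, small_dataset):
        geno, y = small_dataset
        p1 = st.sum_test(geno.dosages, y).p_value
        p2 = st.sum_test(geno.dosages[:, ::-1], y).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestAsum:
    def test_flip_rule(self, rng):
        # strong negative marginal effect on column 0 -> flipped
        X = rng.integers(0, 3, (100, 2)).astype(float)
        y = -1.0 * X[:, 0] + 0.8 * X[:, 1] + rng.normal(0, 1.0, 100)
        coding = st.asum_coding(X, y, alpha0=0.1)
        assert coding.flip_mask[0]
        assert not coding.flip_mask[1]
        assert coding.marginal_beta[0] < 0
        assert coding.marginal_p[0] <= 0.1

    def test_no_flip_when_all_positive(self, rng):
        X = rng.integers(0, 3, (80, 3)).astype(float)
        y = 0.7 * X.sum(axis=1) + rng.normal(0, 1.0, 80)
        coding = st.asum_coding(X, y)
        assert not coding.flip_mask.any()
        # observed statistic equals the burden LRT on the original coding
        res = st.asum_test(X, y, B=5, seed=1)
        s = X.sum(axis=1)
        lr = stats.linregress(s, y)
        rss1 = np.sum((y - lr.intercept - lr.slope * s) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        assert res.statistic == pytest.approx(80 * np.log(rss0 / rss1), rel=1e-8)

    def test_beats_sum_with_mixed_signs(self):
        # Case-2-style mixed signs: aSum recovers power the Sum test loses
        from rvassoc.simulate import simulate_replicate
        hits_sum = hits_asum = 0
        for r in range(50):
            geno, y, _ = simulate_replicate("rv_only", 2, 0, 400, seed=5, replicate=r)
            hits_sum += st.sum_test(geno, y).p_value < 0.05
            hits_asum += st.asum_test(geno, y, B=100, seed=r).p_value < 0.05
        assert hits_asum > hits_sum


class TestMixtureChisq:
    def test_single_weight_quantile(self):
        assert st.mixture_chisq_pvalue([1.0], stats.chi2.isf(0.05, 1)) == \
            pytest.approx(0.05, abs=1e-6)

    def test_t_zero_gives_one(self):
        assert st.mixture_chisq_pvalue([0.5, 2.0], 0.0) == 1.0

    def test_scaling_identity(self):
        for t in (0.5, 2.0, 7.0):
            assert st.mixture_chisq_pvalue([2.0, 2.0], t) == \
                pytest.approx(stats.chi2.sf(t / 2.0, 2), abs=1e-8)

    def test_monotone_in_t(self):
        w = [3.0, 1.0, 0.2]
        ps = [st.mixture_chisq_pvalue(w, t) for t in np.linspace(0.1, 30, 40)]
        assert np.all(np.diff(ps) <= 1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            st.mixture_chisq_pvalue([1.0, -0.5], 1.0)

    def test_matches_monte_carlo(self, rng):
        w = np.array([4.0, 1.5, 0.3])
        sims = (rng.chisquare(1, (200000, 3)) * w).sum(axis=1)
        for t in (2.0, 8.0, 20.0):
            mc = float(np.mean(sims >= t))
            assert st.mixture_chisq_pvalue(w, t) == pytest.approx(mc, abs=0.01)


class TestInvariances:
    def test_coding_flip_leaves_statistics_unchanged(self, small_dataset):
        geno, y = small_dataset
        X = geno.dosages
        sc = st.compute_score_components(X, y)
        sc_f = st.compute_score_components(2.0 - X, y)
        assert np.allclose(sc_f.U, -sc.U)
        for test in (st.score_test, st.ssu_test, st.ssuw_test, st.uminp_test):
            a, b = test(sc), test(sc_f)
            assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-5)

    def test_all_pvalues_in_unit_interval(self, null_dataset):
        geno, y = null_dataset
        sc = st.compute_score_components(geno, y)
        for res in (st.score_test(sc), st.ssu_test(sc), st.ssuw_test(sc),
                    st.uminp_test(sc), st.f_test(geno, y),
                    st.sum_test(geno, y), st.asum_test(geno, y, B=20, seed=0)):
            assert 0.0 <= res.p_value <= 1.0


def test_null_pvalues_uniform():
    """Every test's p-value is uniform under the permuted-trait null.

    500 null replicates at n = 400, k = 6; Kolmogorov-Smirnov against
    Uniform(0, 1) at alpha = 0.01 per test.
    """
    R = 500
    ps = {k: [] for k in ("f", "score", "ssu", "ssuw", "uminp", "sum", "asum")}
    for r in range(R):
        geno, y, _ = simulate_replicate_null(r)
        sc = st.compute_score_components(geno, y)
        ps["f"].append(st.f_test(geno, y).p_value)
        ps["score"].append(st.score_test(sc).p_value)
        ps["ssu"].append(st.ssu_test(sc).p_value)
        ps["ssuw"].append(st.ssuw_test(sc).p_value)
        ps["uminp"].append(st.uminp_test(sc).p_value)
        ps["sum"].append(st.sum_test(geno, y).p_value)
        ps["asum"].append(st.asum_test(geno, y, B=100, seed=3000 + r).p_value)
    for name, vals in ps.items():
        assert stats.kstest(vals, "uniform").pvalue > 0.01, name


def simulate_replicate_null(r):
    from rvassoc.simulate import simulate_replicate
    return simulate_replicate("rv_only", 0, 0, 400, 515, r)


def test_asymptotic_p_matches_permutation_null(rng):
    """Permutation and mixture/asymptotic p-values agree on simulated data."""
    from rvassoc.simulate import simulate_replicate
    geno, y, _ = simulate_replicate("rv_only", 0, 0, 400, seed=9, replicate=0)
    X = geno.dosages
    Xc = X - X.mean(0)
    B = 3000
    perms = np.stack([rng.permutation(y) for _ in range(B)])
    Yc = perms - perms.mean(axis=1, keepdims=True)
    U = Yc @ Xc
    sc = st.compute_score_components(X, y)
    U0 = sc.U
    # SSU
    p_perm = np.mean(U0 @ U0 < np.einsum("bk,bk->b", U, U))
    assert st.ssu_test(sc).p_value == pytest.approx(p_perm, abs=0.03)
    # SSUw (diag V is permutation-invariant)
    d = np.einsum("nk,nk->k", Xc, Xc)
    keep = d > 0
    t_obs = np.sum(U0[keep] ** 2 / d[keep])
    t_null = (U[:, keep] ** 2 / d[keep]).sum(axis=1)
    assert st.ssuw_test(sc).p_value == pytest.approx(
        np.mean(t_obs < t_null), abs=0.03)
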