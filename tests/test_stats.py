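from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alps_glymph import stats as st

# ---------------------------------------------------------------------------
# independent oracles


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = sps.hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """From-scratch Newton-Raphson maximum-likelihood logistic fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# normality


class TestKSNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            st.ks_normality([1.0, 2.0, 3.0, 4.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.ks_normality([2.0] * 10)

    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(0)
        res = st.ks_normality(rng.normal(10, 2, size=200), seed=1)
        assert res.p > 0.05

    def test_exponential_sample_rejected_with_power(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            st.ks_normality(rng.exponential(size=200), n_monte_carlo=400, seed=s).p < 0.05
            for s in range(30)
        )
        assert rejections > 27  # > 90% power

    def test_type_i_error_calibrated(self):
        """Monte-Carlo null keeps the size near the nominal 5%."""
        rng = np.random.default_rng(2)
        n, n_sims = 50, 400
        null = st.simulate_lilliefors_null(n, 4000, np.random.default_rng(3))
        crit = np.quantile(null, 0.95)
        stats = [st.lilliefors_statistic(rng.normal(size=n)) for _ in range(n_sims)]
        rate = np.mean(np.asarray(stats) > crit)
        assert 0.03 < rate < 0.08

    def test_seed_recorded_and_deterministic(self):
        x = np.random.default_rng(4).normal(size=60)
        r1 = st.ks_normality(x, seed=9)
        r2 = st.ks_normality(x, seed=9)
        assert r1.p == r2.p
        assert "seed=9" in r1.method


# ---------------------------------------------------------------------------
# t-test


class TestTTest:
    def test_published_summary_moments(self):
        """Pooled t on n=46: 1.34+/-0.24 vs n=97: 1.46+/-0.22."""
        res = st.ttest_two_sample(st.SummaryGroup(46, 1.34, 0.24),
                                  st.SummaryGroup(97, 1.46, 0.22))
        assert 0.003 <= res.p <= 0.005
        assert res.df == 141

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = st.ttest_two_sample(x, x)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_summary_equals_raw(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        raw = st.ttest_two_sample(a, b)
        summ = st.ttest_two_sample(st.SummaryGroup.from_sample(a),
                                   st.SummaryGroup.from_sample(b))
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)

    def test_matches_permutation_oracle(self):
        a = np.array([2.1, 3.4, 1.8, 4.0, 2.9])
        b = np.array([4.5, 5.1, 3.9, 5.8, 4.2])
        t_obs = abs(st.ttest_two_sample(a, b).statistic)
        pooled = np.concatenate([a, b])
        count = total = 0
        for idx in combinations(range(10), 5):
            sel = np.zeros(10, dtype=bool)
            sel[list(idx)] = True
            t_perm = abs(st.ttest_two_sample(pooled[sel], pooled[~sel]).statistic)
            count += t_perm >= t_obs - 1e-12
            total += 1
        p_perm = count / total
        assert st.ttest_two_sample(a, b).p == pytest.approx(p_perm, abs=0.05)

    def test_welch_differs_under_unequal_variance(self):
        a = np.array([1.0, 2.0, 3.0, 2.0, 1.5])
        b = np.array([10.0, -5.0, 12.0, -8.0, 9.0, 0.0, 4.0])
        pooled = st.ttest_two_sample(a, b, pooled=True)
        welch = st.ttest_two_sample(a, b, pooled=False)
        assert welch.df < pooled.df
        assert welch.method == "welch_t"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.ttest_two_sample([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_type_i_error_calibration(self):
        """Size of the nominal 5% pooled test at the study's group sizes."""
        rng = np.random.default_rng(6)
        n_sims, n1, n2 = 4000, 46, 97
        a = rng.normal(size=(n_sims, n1))
        b = rng.normal(size=(n_sims, n2))
        rejected = sum(
            st.ttest_two_sample(a[i], b[i]).p < 0.05 for i in range(n_sims)
        )
        assert 0.04 <= rejected / n_sims <= 0.06


# ---------------------------------------------------------------------------
# correlation


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = st.correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(-2, 2, 30)
        y = x**3
        assert st.correlation(x, y, "spearman").r == pytest.approx(1.0)
        assert st.correlation(x, y, "pearson").r < 1.0

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = st.correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert res.r == pytest.approx(direct, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            st.correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            st.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            st.correlation([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# categorical


class TestCategorical2x2:
    def test_pearson_hand_formula(self):
        a, b, c, d = 22, 75, 5, 50
        res = st.categorical_2x2(a, b, c, d, method="pearson")
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(hand, rel=1e-12)
        assert res.statistic == pytest.approx(4.44, abs=0.01)

    def test_identical_proportions(self):
        res = st.categorical_2x2(10, 20, 20, 40, method="pearson")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        res = st.categorical_2x2(2, 3, 4, 1, method="fisher")
        assert res.p == pytest.approx(fisher_p_enumeration(2, 3, 4, 1), abs=1e-12)

    def test_fisher_matches_enumeration_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = st.categorical_2x2(int(a), int(b), int(c), int(d), method="fisher")
            assert res.p == pytest.approx(
                fisher_p_enumeration(int(a), int(b), int(c), int(d)), abs=1e-9
            )

    def test_auto_picks_fisher_for_sparse_tables(self):
        assert st.categorical_2x2(1, 2, 3, 1).method == "fisher_exact"
        assert st.categorical_2x2(30, 40, 35, 45).method == "chi2_pearson"

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            st.categorical_2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            st.categorical_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            st.categorical_2x2(1.5, 2, 3, 4)


# ---------------------------------------------------------------------------
# regression


class TestLogistic:
    def test_null_recovery(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x1": rng.normal(size=10000), "x2": rng.normal(size=10000)})
        y = rng.integers(0, 2, size=10000)
        fit = st.logistic_fit(X, y)
        assert np.all(np.abs(fit.params[["x1", "x2"]]) < 0.05)
        assert np.allclose(fit.or_ci.loc[["x1", "x2"], "OR"], 1.0, atol=0.05)

    def test_per_01_or_parameter_recovery(self):
        beta1 = np.log(1.686) / 0.1
        rng = np.random.default_rng(10)
        alps = rng.normal(1.34, 0.24, size=5000)
        p = 1 / (1 + np.exp(-(-6.0 + beta1 * alps)))
        y = (rng.random(5000) < p).astype(int)
        fit = st.logistic_fit(pd.DataFrame({"alps": alps}), y, rescale={"alps": 0.1})
        or01 = fit.rescaled_or["alps"][0]
        assert 1.55 <= or01 <= 1.85

    def test_per_unit_rescaling_identity(self):
        """OR per 0.1 equals the OR of the predictor rescaled by 10."""
        rng = np.random.default_rng(11)
        x = rng.normal(1.3, 0.3, size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(x - 1.3) * 3))).astype(int)
        f1 = st.logistic_fit(pd.DataFrame({"x": x}), y, rescale={"x": 0.1})
        f2 = st.logistic_fit(pd.DataFrame({"x": x * 10}), y)
        assert f1.rescaled_or["x"][0] == pytest.approx(f2.or_ci.loc["x", "OR"], rel=1e-6)

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(50), rng.normal(size=50), rng.normal(size=50)])
        y = (rng.random(50) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])))).astype(int)
        fit = st.logistic_fit(pd.DataFrame(X[:, 1:], columns=["a", "b"]), y)
        oracle = newton_logistic(X, y)
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-8)

    def test_perfect_separation_reported(self):
        x = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])
        y = (x > 0).astype(int)
        with pytest.raises(ValueError, match="separation|failed"):
            st.logistic_fit(pd.DataFrame({"x": x}), y)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = rng.integers(0, 2, size=50)
        with pytest.raises(ValueError, match="singular"):
            st.logistic_fit(X, y)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            st.logistic_fit(pd.DataFrame({"x": np.arange(10.0)}), np.arange(10))


class TestLinear:
    def test_exact_linear_data(self):
        x = np.arange(20.0)
        y = 3.0 + 2.0 * x
        fit = st.linear_fit(pd.DataFrame({"x": x}), y)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_orthogonal_predictors_equal_simple_slopes(self):
        rng = np.random.default_rng(14)
        x1 = np.tile([-1.0, 1.0], 50)
        x2 = np.repeat([-1.0, 1.0], 50)
        y = 0.5 * x1 - 1.2 * x2 + rng.normal(size=100)
        multi = st.linear_fit(pd.DataFrame({"x1": x1, "x2": x2}), y)
        s1 = st.linear_fit(pd.DataFrame({"x1": x1}), y)
        s2 = st.linear_fit(pd.DataFrame({"x2": x2}), y)
        assert multi.params["x1"] == pytest.approx(s1.params["x1"], rel=1e-10)
        assert multi.params["x2"] == pytest.approx(s2.params["x2"], rel=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        fit = st.linear_fit(pd.DataFrame(X, columns=list("abcd")), y)
        Xi = np.column_stack([np.ones(100), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_rank_deficiency_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            st.linear_fit(pd.DataFrame({"a": x, "b": 3 * x}), x)


class TestCovariateScreen:
    def test_threshold_one_selects_all(self):
        rng = np.random.default_rng(16)
        cand = pd.DataFrame({"u": rng.normal(size=60), "v": rng.normal(size=60)})
        y = rng.integers(0, 2, size=60)
        assert set(st.covariate_screen(cand, y, threshold=1.0)) == {"u", "v"}

    def test_empty_candidates_keep_always_include(self):
        df = pd.DataFrame({"age": np.arange(30.0), "sex": np.tile([0, 1], 15)})
        y = np.tile([0, 1], 15)
        sel = st.covariate_screen(df, y, threshold=0.0001)
        assert sel == ["age", "sex"]

    def test_null_selection_rate_near_threshold(self):
        rng = np.random.default_rng(17)
        n, k, sims = 400, 4, 250
        picked = 0
        for _ in range(sims):
            cand = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"c{i}" for i in range(k)])
            y = rng.integers(0, 2, size=n)
            picked += len(st.covariate_screen(cand, y, threshold=0.1, always_include=()))
        rate = picked / (sims * k)
        assert 0.06 < rate < 0.15
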