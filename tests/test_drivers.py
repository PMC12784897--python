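import numpy as np
import pandas as pd
import pytest

from fishdiv import drivers
from fishdiv.tables import EnvironmentTable


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH by the explicit min-over-tail definition."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        tail = [pvals[order[k]] * m / (k + 1) for k in range(rank_pos, m)]
        adj[idx] = min(1.0, min(tail))
    return adj


class TestHeterogeneity:
    def test_two_site_hand_value(self):
        env = EnvironmentTable(pd.DataFrame({"v": [0.0, 2.0]},
                                            index=["a", "b"]))
        res = drivers.env_heterogeneity(env)
        assert np.allclose(res.per_site, np.sqrt(0.5), atol=1e-12)
        assert res.overall == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_identical_sites_all_zero(self):
        env = EnvironmentTable(pd.DataFrame(
            {"v": [1.0, 1.0, 1.0], "w": [2.0, 2.0, 2.0]},
            index=list("abc")))
        with pytest.warns(UserWarning, match="constant"):
            res = drivers.env_heterogeneity(env)
        assert np.allclose(res.per_site, 0.0) and res.overall == 0.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"),
                            columns=list("wxyz"))
        base = drivers.env_heterogeneity(EnvironmentTable(vals))
        scaled = vals.copy()
        scaled["x"] = scaled["x"] * 37.0 - 4.0
        res = drivers.env_heterogeneity(EnvironmentTable(scaled))
        assert np.allclose(res.per_site, base.per_site, atol=1e-10)

    def test_permutation_invariance_of_overall(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"),
                            columns=list("wxyz"))
        base = drivers.env_heterogeneity(EnvironmentTable(vals)).overall
        shuffled = vals.sample(frac=1, axis=0, random_state=2) \
                       .sample(frac=1, axis=1, random_state=3)
        res = drivers.env_heterogeneity(EnvironmentTable(shuffled)).overall
        assert res == pytest.approx(base, abs=1e-12)


class TestEnvDistance:
    def test_two_site_hand_value(self):
        env = EnvironmentTable(pd.DataFrame({"v": [0.0, 2.0]},
                                            index=["a", "b"]))
        m = drivers.env_distance_matrix(env)
        assert m.iloc[0, 1] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(size=(7, 5)), index=list("abcdefg"))
        m = drivers.env_distance_matrix(EnvironmentTable(vals)).to_numpy()
        n = m.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9


class TestSpearmanScreen:
    def _tables(self):
        sites = list("abcdefghi")
        x = np.arange(9.0)
        alpha = pd.DataFrame({"S": x, "pielou": np.r_[x[::-1][:5], 9, 1, 4, 2]},
                             index=sites)
        drv = pd.DataFrame({"dam": x, "noise": [3, 1, 4, 1, 5, 9, 2, 6, 5.5]},
                           index=sites)
        return alpha, drv

    def test_monotone_pair_rho_one(self):
        alpha, drv = self._tables()
        res = drivers.spearman_bh_screen(alpha, drv)
        row = res[(res["index"] == "S") & (res.driver == "dam")].iloc[0]
        assert row.rho == pytest.approx(1.0)

    def test_adjusted_never_below_raw(self):
        alpha, drv = self._tables()
        res = drivers.spearman_bh_screen(alpha, drv)
        ok = res.dropna()
        assert (ok.p_adj >= ok.p - 1e-12).all()

    def test_bh_worked_case(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04, atol=1e-12)

    def test_bh_matches_brute_force(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            lib = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(lib, brute_force_bh(p), atol=1e-12)


class TestDistanceDecay:
    def test_exact_linear_recovery(self):
        x = np.linspace(0, 5, 10)
        y = 0.1 + 0.07 * x
        fit = drivers.distance_decay(y, x)
        assert fit.slope == pytest.approx(0.07, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_regression(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            fit = drivers.distance_decay(y, x)
            sxy = np.cov(x, y, ddof=1)[0, 1]
            slope = sxy / np.var(x, ddof=1)
            r2 = sxy ** 2 / (np.var(x, ddof=1) * np.var(y, ddof=1))
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_predictor_refused(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = drivers.distance_decay(np.arange(5.0), np.ones(5))
        assert np.isnan(fit.slope)

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            drivers.distance_decay([0.1, 0.2], [1.0, 2.0])

    def test_mantel_p_uniformish_under_null(self):
        rng = np.random.default_rng(6)
        sites = list("abcdefghi")
        rows = [{"site_i": sites[i], "site_j": sites[j]}
                for i in range(9) for j in range(i + 1, 9)]
        idx = pd.DataFrame(rows)
        ps = []
        for rep in range(30):
            y = rng.uniform(size=36)
            x = rng.uniform(size=36)
            fit = drivers.distance_decay(y, x, n_mantel=199, seed=rep,
                                         pair_index=idx)
            ps.append(fit.mantel_p)
        assert 0.2 < np.mean(ps) < 0.8        # no systematic anti-conservatism


class TestHierarchicalPartition:
    def test_orthogonal_single_driver(self):
        x1 = np.tile([1.0, -1.0], 32)
        x2 = np.repeat([1.0, -1.0], 32)
        y = 3.0 * x1
        hp = drivers.hierarchical_partition(y, x1, x2)
        assert hp.contributions["environment"] == pytest.approx(1.0, abs=1e-10)
        assert hp.contributions["spatial"] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_additive_drivers_recover_marginals(self):
        x1 = np.tile([1.0, -1.0], 32)
        x2 = np.repeat([1.0, -1.0], 32)
        y = x1 + 2.0 * x2
        hp = drivers.hierarchical_partition(y, x1, x2)
        r2_1 = 1.0 / 5.0
        r2_2 = 4.0 / 5.0
        assert hp.contributions["environment"] == pytest.approx(r2_1, abs=1e-10)
        assert hp.contributions["spatial"] == pytest.approx(r2_2, abs=1e-10)

    def test_contributions_sum_to_full_r2(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            n = int(rng.integers(8, 40))
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            y = rng.normal(size=n)
            hp = drivers.hierarchical_partition(y, x1, x2)
            assert sum(hp.contributions.values()) == pytest.approx(
                hp.full_r2, abs=1e-10)
            assert hp.residual == pytest.approx(1 - hp.full_r2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            drivers.hierarchical_partition(np.arange(5.0), np.arange(5.0),
                                           np.ones(5))


class TestSmoothTrend:
    def test_perfect_line_fully_explained(self):
        x = np.linspace(0, 30, 9)
        fit = drivers.smooth_trend(x, 1.0 + 0.4 * x, normality_check=False)
        assert fit.deviance_explained == pytest.approx(1.0, abs=1e-6)

    def test_constant_response(self):
        x = np.linspace(0, 30, 9)
        fit = drivers.smooth_trend(x, np.full(9, 2.0), normality_check=False)
        assert fit.deviance_explained == 0.0

    def test_quadratic_signal_recovered(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 30, 9)
        good = 0
        for _ in range(100):
            y = (x - 15.0) ** 2 / 50.0 + rng.normal(0, 0.3, 9)
            fit = drivers.smooth_trend(x, y, normality_check=False)
            good += fit.deviance_explained > 0.8
        assert good >= 90

    def test_few_points_linear_fallback(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="linear"):
            fit = drivers.smooth_trend(x, 2 * x + 1, normality_check=False)
        assert fit.linear_fallback and fit.adj_r2 == pytest.approx(1.0)

    def test_nonnormal_response_logged(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 30, 20)
        y = np.exp(rng.normal(size=20) * 2)    # heavily right-skewed
        fit = drivers.smooth_trend(x, y)
        assert fit.log_transformed
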