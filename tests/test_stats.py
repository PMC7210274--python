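"""Inference layer: correlations, Cook's d, JZS Bayes factors, GG rmANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stopmark import stats as S

from oracles import cooks_d_leave_one_out, jzs_bf10_g_integral


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert S.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert S.pearson_r(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # cov = 0.75 on ssd-normalized vectors -> r = 0.6
        assert S.pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            S.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCooksD:
    def test_matches_leave_one_out_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(6, 21))
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            assert np.allclose(
                S.cooks_distances(x, y), cooks_d_leave_one_out(x, y), rtol=1e-8
            )

    def test_collinear_data_nothing_removed(self):
        x = np.linspace(0, 1, 12)
        kept, removed = S.remove_bivariate_outliers(x, 3 * x - 1 + 1e-6 * np.sin(x))
        assert removed.size == 0

    def test_high_leverage_off_line_point_removed(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 17)
        y = 2 * x + rng.normal(0, 0.05, 17)
        x = np.append(x, 3.0)
        y = np.append(y, -4.0)  # far off the line at high leverage
        d = S.cooks_distances(x, y)
        assert d[17] > 1.0
        kept, removed = S.remove_bivariate_outliers(x, y)
        assert list(removed) == [17]
        assert kept.size == 17

    def test_single_pass_not_iterated(self):
        """Points whose d rises above 1 only after another removal stay in."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 10.0, 10.2])
        y = np.array([0.0, 1.1, 1.9, 3.2, 3.9, -6.0, -5.0])
        d = S.cooks_distances(x, y)
        kept, removed = S.remove_bivariate_outliers(x, y)
        assert set(removed) == set(np.flatnonzero(d > 1))


class TestJZS:
    def test_null_evidence_at_t_zero(self):
        for n in (5, 18, 50):
            assert S.bf10_from_t(0.0, n) < 1.0

    @pytest.mark.parametrize("t,n", [(0.0, 18), (1.0, 18), (2.5, 18), (5.0, 18),
                                     (3.0, 9), (1.5, 80), (4.2, 30)])
    def test_matches_quadrature_oracle_to_4_sig_figs(self, t, n):
        ours = S.bf10_from_t(t, n)
        oracle = jzs_bf10_g_integral(t, n)
        assert ours == pytest.approx(oracle, rel=5e-5)

    def test_monotone_in_abs_t(self):
        grid = [S.bf10_from_t(t, 18) for t in np.arange(0.0, 6.5, 0.5)]
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_consistency_as_n_grows(self):
        """With a fixed true nonzero mean, evidence accumulates without
        bound as the sample grows."""
        rng = np.random.default_rng(42)
        pop = rng.normal(0.5, 1.0, 320)
        bfs = [S.jzs_bf_one_sample(pop[:n]).bf10 for n in (20, 80, 320)]
        assert bfs[0] < bfs[1] < bfs[2]
        assert bfs[2] > 1e6

    def test_paired_antisymmetry(self, rng):
        x = rng.normal(0.3, 1.0, 15)
        y = rng.normal(0.0, 1.0, 15)
        a = S.jzs_bf_paired(x, y)
        b = S.jzs_bf_paired(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.bf10 == pytest.approx(b.bf10, rel=1e-9)

    def test_identical_pairs_favor_null_loudly(self):
        with pytest.raises(ValueError):
            S.jzs_bf_paired(np.arange(5.0), np.arange(5.0))  # zero-variance diffs

    def test_race_model_simulation_direction(self):
        """goRT vs USRT across a simulated cohort: the paired test must
        find overwhelming evidence for the positive difference."""
        from stopmark.behavior import BehavioralDataset, race_model_paired_test
        from stopmark.task import RaceModelParams, simulate_session

        go_means, usrt_means = [], []
        for s in range(18):
            ds = BehavioralDataset(list(simulate_session(RaceModelParams(seed=s))))
            go_means.append(ds.go_rts().mean())
            usrt_means.append(ds.usrts().mean())
        res = race_model_paired_test(go_means, usrt_means)
        assert res.t > 0 and res.bf10 > 1e3


class TestPooling:
    def test_tanh_atanh_identity(self):
        r = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(np.tanh(np.arctanh(r)), r)

    def test_equal_cells_pool_to_common_value(self):
        pooled = S.pool_correlations([(0.42, 18)] * 9, ci_method="t")
        assert pooled.m_r == pytest.approx(0.42)

    def test_order_invariance_and_equal_n_reduction(self):
        cells = [(0.1, 18), (0.5, 18), (0.3, 18), (-0.2, 18), (0.4, 18),
                 (0.0, 18), (0.25, 18), (0.35, 18), (0.15, 18)]
        a = S.pool_correlations(cells, ci_method="t")
        b = S.pool_correlations(cells[::-1], ci_method="t")
        assert a.m_r == pytest.approx(b.m_r)
        simple = np.tanh(np.mean(np.arctanh([c[0] for c in cells])))
        assert a.m_r == pytest.approx(simple)

    def test_published_grid_rows(self):
        """Weighted z-pooling reproduces the reference pooled values from
        the printed two-decimal cells."""
        ssrt_premg = [(0.39, 18), (0.82, 17), (0.57, 18), (0.71, 18), (0.63, 17),
                      (0.78, 17), (0.67, 17), (0.78, 18), (0.71, 18)]
        gort_ssrt = [(-0.38, 18), (-0.62, 18), (-0.30, 18), (-0.03, 18), (-0.40, 18),
                     (-0.32, 18), (-0.38, 18), (-0.22, 18), (-0.17, 18)]
        assert S.pool_correlations(ssrt_premg).m_r == pytest.approx(0.69, abs=0.005)
        assert S.pool_correlations(gort_ssrt).m_r == pytest.approx(-0.32, abs=0.005)

    def test_posterior_interval_brackets_t_interval(self):
        cells = [(0.39, 18), (0.82, 17), (0.57, 18), (0.71, 18), (0.63, 17),
                 (0.78, 17), (0.67, 17), (0.78, 18), (0.71, 18)]
        post = S.pool_correlations(cells, ci_method="posterior")
        freq = S.pool_correlations(cells, ci_method="t")
        assert post.ci95[0] < post.m_r < post.ci95[1]
        # the two constructions agree to correlation-scale precision
        assert post.ci95[0] == pytest.approx(freq.ci95[0], abs=0.05)
        assert post.ci95[1] == pytest.approx(freq.ci95[1], abs=0.05)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            S.pool_correlations([(1.0, 18)] * 9)


def _long_table(y, subjects, times=("pre", "peri", "post"), conds=("IFG", "VC", "SHAM")):
    rows = []
    for p in range(subjects):
        for ti, tm in enumerate(times):
            for ci, c in enumerate(conds):
                rows.append(
                    dict(participant=p, time=tm, condition=c, value=y[p, ti, ci])
                )
    return pd.DataFrame(rows)


class TestRmAnovaGG:
    def test_corrected_df_arithmetic(self):
        assert S.gg_corrected_df(0.609, 4, 68) == pytest.approx((2.436, 41.412))

    def test_epsilon_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(18, 3)) @ rng.normal(size=(3, 3))
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["participant"] = range(18)
        long = df.melt(id_vars="participant", var_name="w", value_name="value")
        theirs = pg.epsilon(long, dv="value", within="w", subject="participant",
                            correction="gg")
        assert S.gg_epsilon(x) == pytest.approx(float(theirs), rel=1e-9)

    def test_compound_symmetry_epsilon_near_one(self, rng):
        subj = rng.normal(0, 10, size=(24, 1))
        y = subj + rng.normal(0, 3, size=(24, 9))
        eps = S.gg_epsilon(y.reshape(24, 9))
        assert eps > 0.7  # spherical covariance: epsilon approaches 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_epsilon_bounds_random_covariance(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        x = rng.normal(size=(k + 5, k)) @ rng.normal(size=(k, k))
        eps = S.gg_epsilon(x)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_two_way_table_structure(self, rng):
        y = rng.normal(500, 40, size=(18, 3, 3))
        res = S.rm_anova_gg(_long_table(y, 18))
        assert set(res) == {"time", "condition", "time x condition"}
        inter = res["time x condition"]
        assert inter.df == (4.0, 68.0)
        assert 0.25 <= inter.epsilon <= 1.0
        assert inter.df_gg == pytest.approx(
            (inter.epsilon * 4.0, inter.epsilon * 68.0)
        )
        assert 0.0 <= inter.p_gg <= 1.0

    def test_detects_injected_condition_effect(self, rng):
        y = rng.normal(500, 10, size=(18, 3, 3))
        y[:, :, 0] += 40.0  # one condition slower
        res = S.rm_anova_gg(_long_table(y, 18))
        assert res["condition"].p_gg < 0.001
        assert res["time"].p_gg > 0.001

    def test_missing_cells_rejected(self, rng):
        y = rng.normal(size=(6, 3, 3))
        df = _long_table(y, 6).iloc[:-1]
        with pytest.raises(ValueError):
            S.rm_anova_gg(df)

    def test_null_type_i_rate_with_gg_correction(self):
        """Under a spherical null the GG-corrected interaction test should
        reject at close to the nominal 5% rate."""
        rejections = 0
        reps = 120
        for s in range(reps):
            rng = np.random.default_rng(10_000 + s)
            y = rng.normal(0, 1, size=(12, 3, 3))
            res = S.rm_anova_gg(_long_table(y, 12))
            rejections += res["time x condition"].p_gg < 0.05
        rate = rejections / reps
        assert 0.005 <= rate <= 0.11  # 3 MC sigmas around 0.05
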