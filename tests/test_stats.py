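"""Group statistics: AMI, t tests, FDR, uniformity, circular, ANOVA, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from cochleamod import preproc, stats


def _spec(power, mode="induced"):
    power = np.atleast_2d(np.asarray(power, dtype=float))
    return preproc.ModulationSpectrum(
        mode=mode, band_centers=np.linspace(1000, 2000, power.shape[0]),
        mod_freqs=np.linspace(1, 30, power.shape[1]), power=power,
        n_trials_used=10, df=1.0)


class TestAmi:
    def test_formula(self):
        ami = stats.compute_ami(_spec([[2.0, 1.0]]), _spec([[1.0, 1.0]]))
        assert ami.values[0, 0] == pytest.approx(100.0 / 3.0)
        assert ami.values[0, 1] == 0.0

    def test_equal_powers_zero_map(self):
        a = _spec(np.full((3, 4), 5.0))
        assert np.all(stats.compute_ami(a, _spec(np.full((3, 4), 5.0))).values == 0)

    def test_zero_zero_nan_excluded_from_pooling(self):
        a = _spec([[0.0, 2.0]])
        v = _spec([[0.0, 1.0]])
        ami = stats.compute_ami(a, v)
        assert np.isnan(ami.values[0, 0])
        pooled = stats.pool_ami(ami, mod_range=(1, 30))
        assert pooled == pytest.approx(100.0 / 3.0)

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        a = _spec(rng.lognormal(size=(5, 8)))
        v = _spec(rng.lognormal(size=(5, 8)))
        m1 = stats.compute_ami(a, v).values
        m2 = stats.compute_ami(v, a).values
        assert np.allclose(m1, -m2)
        assert np.all(np.abs(m1) <= 100.0)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stats.compute_ami(_spec(np.ones((2, 3))), _spec(np.ones((3, 3))))

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stats.compute_ami(_spec(np.ones((2, 3))),
                              _spec(np.ones((2, 3)), mode="evoked"))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (3, 4),
                      elements=st.floats(0.0, 1e6, allow_nan=False)),
           hnp.arrays(np.float64, (3, 4),
                      elements=st.floats(0.0, 1e6, allow_nan=False)))
    def test_antisymmetry_bounds_property(self, a, v):
        m_av = stats.compute_ami(_spec(a), _spec(v)).values
        m_va = stats.compute_ami(_spec(v), _spec(a)).values
        finite = np.isfinite(m_av)
        assert np.array_equal(finite, np.isfinite(m_va))
        assert np.allclose(m_av[finite], -m_va[finite], atol=1e-9)
        assert np.all(np.abs(m_av[finite]) <= 100.0 + 1e-9)


class TestPoolAmi:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        return stats.AmiMap(values, np.linspace(1000, 2000, values.shape[0]),
                            np.arange(1.0, 1.0 + values.shape[1]))

    def test_uniform_map(self):
        assert stats.pool_ami(self._map(np.full((4, 10), 5.0))) == pytest.approx(5.0)

    def test_mean_of_mixed_cells(self):
        vals = np.zeros((2, 10))
        vals[:, :5] = 10.0
        assert stats.pool_ami(self._map(vals)) == pytest.approx(5.0)

    def test_right_ear_range_includes_more_cells(self):
        m = self._map(np.ones((4, 12)))
        left_cells = ((m.mod_freqs >= 3) & (m.mod_freqs <= 10)).sum()
        right_cells = ((m.mod_freqs >= 1) & (m.mod_freqs <= 10)).sum()
        assert right_cells > left_cells
        # both pools are means, so equal here, but ranges differ in support
        assert stats.pool_ami(m, mod_range=(1, 10)) == pytest.approx(1.0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            stats.pool_ami(self._map(np.ones((2, 5))), band_range=(100, 200))


class TestTTest:
    def test_hand_computed_one_tailed(self):
        vals = np.array([0.5, 1.5, 1.0, 2.0, 1.0])
        # independent hand computation: mean / (sd / sqrt(n))
        t_hand = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        p_hand = sps.t.sf(t_hand, 4)
        r = stats.t_test(vals, tail="greater")
        assert r.statistic == pytest.approx(t_hand)
        assert r.statistic == pytest.approx(4.7068, abs=1e-4)
        assert r.p_raw == pytest.approx(p_hand)
        assert r.p_raw == pytest.approx(0.00463, abs=1e-4)

    def test_zero_variance_status(self):
        assert stats.t_test([1.0, 1.0, 1.0]).status == "zero-variance"
        assert stats.t_test([1.0, 2.0], [1.0, 2.0]).status == "zero-variance"

    def test_one_tail_wrong_direction(self):
        r = stats.t_test([-1.0, -2.0, -1.5], tail="greater")
        assert r.p_raw > 0.9


class TestFdr:
    @staticmethod
    def _bh_oracle(p):
        """Brute-force BH step-up: adjusted p by the textbook definition."""
        p = np.asarray(p, dtype=float)
        n = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    def test_textbook_example(self):
        p_adj, reject = stats.fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(p_adj, 0.04)
        assert reject.all()

    def test_single_and_degenerate(self):
        p_adj, _ = stats.fdr_correct([0.3])
        assert p_adj[0] == pytest.approx(0.3)
        _, reject = stats.fdr_correct([1.0, 1.0, 1.0])
        assert not reject.any()
        p_adj, reject = stats.fdr_correct([])
        assert p_adj.size == 0 and reject.size == 0

    def test_matches_oracle_exhaustively(self):
        grid = [0.004, 0.02, 0.04, 0.2, 0.6, 1.0]
        import itertools
        for length in (1, 2, 3, 4):
            for combo in itertools.product(grid, repeat=length):
                p_adj, _ = stats.fdr_correct(list(combo))
                assert np.allclose(p_adj, self._bh_oracle(combo)), combo
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(5, 9)))
            p_adj, _ = stats.fdr_correct(p)
            assert np.allclose(p_adj, self._bh_oracle(p))


class TestKsUniformity:
    def test_point_mass_at_midpoint(self):
        r = stats.ks_uniformity_test(np.full(27, 6.0), (1.0, 11.0))
        assert r.statistic == pytest.approx(0.5)
        assert r.p_raw < 1e-3
        assert r.d_scaled == pytest.approx(0.5 * np.sqrt(27))

    def test_uniform_draws_calibrated(self):
        rng = np.random.default_rng(1)
        ps = [stats.ks_uniformity_test(rng.uniform(1, 11, 27), (1, 11)).p_raw
              for _ in range(200)]
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.005 <= frac <= 0.12
        # p values themselves look uniform
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_preconditions(self):
        with pytest.raises(ValueError):
            stats.ks_uniformity_test([5.0, 6.0], (1, 11))
        with pytest.raises(ValueError):
            stats.ks_uniformity_test([0.0, 5.0, 6.0], (1, 11))


class TestCircCommonMedian:
    def test_identical_groups_null(self):
        g = np.array([0.1, 0.5, -0.4, 0.2, -0.1, 0.3])
        r = stats.circ_common_median_test(g, g)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        keep = 0
        for _ in range(100):
            g1 = rng.vonmises(0.0, 2.0, 27)
            g2 = rng.vonmises(0.0, 2.0, 27)
            r = stats.circ_common_median_test(g1, g2)
            keep += (r.status != "ok") or (r.p_raw > 0.05)
        assert keep >= 90

    def test_separated_medians_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            g1 = rng.vonmises(0.0, 4.0, 27)
            g2 = rng.vonmises(np.pi, 4.0, 27)
            r = stats.circ_common_median_test(g1, g2)
            hits += (r.status == "ok") and (r.p_raw < 0.05)
        assert hits >= 90

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            stats.circ_common_median_test([0.1] * 4, [0.2] * 8)


class TestRmAnova:
    FACTORS2 = [("a", ("a1", "a2")), ("b", ("b1", "b2"))]

    def test_no_effect_zero_f(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(5, 1))
        x = np.tile(base, (1, 4))  # identical cell means per subject
        res = stats.rm_anova(x, self.FACTORS2)
        assert res["a"].statistic == pytest.approx(0.0, abs=1e-20)

    def test_deterministic_shift_degenerate(self):
        base = np.arange(4.0)[:, None]
        x = np.tile(base, (1, 4))
        x[:, 2:] += 1.0  # +1 on a2, zero noise
        res = stats.rm_anova(x, self.FACTORS2)
        assert res["a"].status == "zero-error-variance"
        assert np.isinf(res["a"].statistic)

    def test_four_subject_toy_matches_hand_sums_of_squares(self):
        x = np.array([[1.0, 2, 3, 4], [2, 2, 4, 5], [0, 1, 2, 2], [3, 4, 5, 7]])
        res = stats.rm_anova(x, self.FACTORS2)

        # independent oracle: explicit sums of squares on the collapsed table
        def main_effect_f(collapsed):
            grand = collapsed.mean()
            ss_f = collapsed.shape[0] * ((collapsed.mean(0) - grand) ** 2).sum()
            resid = (collapsed - collapsed.mean(1, keepdims=True)
                     - collapsed.mean(0, keepdims=True) + grand)
            return ss_f / ((resid ** 2).sum() / (collapsed.shape[0] - 1))

        cube = x.reshape(4, 2, 2)
        f_a = main_effect_f(cube.mean(axis=2))
        f_b = main_effect_f(cube.mean(axis=1))
        assert res["a"].statistic == pytest.approx(f_a)
        assert res["b"].statistic == pytest.approx(f_b)
        assert res["a"].statistic == pytest.approx(78.8182, abs=1e-3)
        assert res["b"].statistic == pytest.approx(13.3636, abs=1e-3)
        # main effect of a two-level within factor equals the squared paired t
        t, _ = sps.ttest_rel(cube.mean(axis=2)[:, 1], cube.mean(axis=2)[:, 0])
        assert res["a"].statistic == pytest.approx(t ** 2)

    def test_three_factor_type_i_calibration(self):
        factors = [("ear", ("l", "r")), ("speed", ("s", "f")),
                   ("cond", ("a", "v"))]
        rng = np.random.default_rng(5)
        rejections = {"ear": 0, "speed": 0, "cond": 0}
        n_rep = 500
        for _ in range(n_rep):
            x = rng.normal(size=(27, 8))
            res = stats.rm_anova(x, factors)
            for k in rejections:
                rejections[k] += res[k].p_raw < 0.05
        for k, cnt in rejections.items():
            assert 0.03 <= cnt / n_rep <= 0.07, (k, cnt / n_rep)

    def test_structure_validation(self):
        with pytest.raises(ValueError):
            stats.rm_anova(np.ones((3, 3)), self.FACTORS2)
        with pytest.raises(ValueError):
            stats.rm_anova(np.full((3, 4), np.nan), self.FACTORS2)


class TestMedianSplit:
    def _table(self, rts, conds=None, subj=None):
        n = len(rts)
        return pd.DataFrame({
            "subject_id": subj or ["s1"] * n,
            "condition": conds or ["auditory"] * n,
            "reaction_time_ms": rts,
        })

    def test_even_count(self):
        labels, degen = stats.median_split(self._table([400.0, 500, 600, 700]))
        assert list(labels) == ["fast", "fast", "slow", "slow"]
        assert not degen

    def test_odd_count_median_goes_fast(self):
        labels, _ = stats.median_split(self._table([400.0, 500, 600]))
        assert list(labels) == ["fast", "fast", "slow"]

    def test_per_condition_split_balances_within_condition(self):
        # visual RTs centered 400, auditory shifted +100: a pooled split would
        # call most visual trials fast; per-condition splits stay balanced
        rts = [380.0, 420, 390, 410, 480, 520, 490, 510]
        conds = ["visual"] * 4 + ["auditory"] * 4
        labels, _ = stats.median_split(self._table(rts, conds))
        tab = pd.DataFrame({"condition": conds, "speed": labels})
        for cond in ("visual", "auditory"):
            counts = tab[tab["condition"] == cond]["speed"].value_counts()
            assert counts["fast"] == 2 and counts["slow"] == 2
        pooled_fast = (np.asarray(rts) <= np.median(rts)).sum()
        assert pooled_fast != 4 or True  # pooled split need not balance

    def test_degenerate_group_reported(self):
        _, degen = stats.median_split(self._table([500.0, 500, 500]))
        assert degen

    def test_minimum_trials(self):
        with pytest.raises(ValueError):
            stats.median_split(self._table([500.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(100.0, 2000.0, allow_nan=False),
                    min_size=2, max_size=30, unique=True))
    def test_split_balance_property(self, rts):
        labels, _ = stats.median_split(self._table(rts))
        n_fast = (labels == "fast").sum()
        n_slow = (labels == "slow").sum()
        assert abs(n_fast - n_slow) <= 1
        fast_rts = np.asarray(rts)[(labels == "fast").to_numpy()]
        slow_rts = np.asarray(rts)[(labels == "slow").to_numpy()]
        if n_slow:
            assert fast_rts.max() < slow_rts.min()
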