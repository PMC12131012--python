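"""Statistical battery vs independent oracles: pingouin, enumeration, quadrature."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sst

from parabospine.core import PowerSpec, bonferroni
from parabospine.stats import (
    _friedman_statistic,
    friedman_bonferroni,
    paired_t_bonferroni,
    paired_t_power,
    rm_anova_gg,
    rm_anova_trimmed,
    shapiro_gate,
    spearman_assoc,
    wilcoxon_posthoc,
)


class TestShapiroGate:
    def test_normal_cells_route_parametric_at_calibrated_rate(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for _ in range(reps):
            gate = shapiro_gate({"a": rng.standard_normal(50)})
            hits += gate.verdicts["a"] == "normal"
        assert 0.90 <= hits / reps <= 0.99

    def test_exponential_cells_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 100
        for _ in range(reps):
            gate = shapiro_gate({"a": rng.exponential(size=50)})
            hits += gate.verdicts["a"] == "non-normal"
        assert hits / reps > 0.90

    def test_constant_cell_is_untestable_and_nonparametric(self):
        gate = shapiro_gate({"a": np.full(10, 3.0), "b": np.random.default_rng(0).standard_normal(10)})
        assert gate.verdicts["a"] == "untestable"
        assert gate.route == "nonparametric"

    def test_extreme_outlier_forces_nonparametric(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        x[0] = 50.0
        gate = shapiro_gate({"a": x})
        assert gate.extreme_outliers["a"] >= 1
        assert gate.route == "nonparametric"


class TestRmAnovaGG:
    def test_two_conditions_have_epsilon_one(self):
        rng = np.random.default_rng(3)
        res = rm_anova_gg(rng.standard_normal((8, 2)))
        assert res.epsilon_gg == 1.0

    def test_constant_conditions_degenerate(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_gg(data)
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 3)) + np.array([0.0, 0.4, 0.9])
        res = rm_anova_gg(data)
        df = (
            pd.DataFrame(data, columns=list("abc"))
            .reset_index()
            .melt("index", var_name="cond")
        )
        aov = pg.rm_anova(
            dv="value", within="cond", subject="index", data=df, correction=True
        ).iloc[0]
        assert res.statistic == pytest.approx(aov["F"], abs=1e-6)
        assert res.epsilon_gg == pytest.approx(aov["eps"], abs=1e-6)
        assert res.p_raw == pytest.approx(aov["p_GG_corr"], abs=1e-6)

    def test_gg_epsilon_bounds_property(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = rng.integers(2, 6)
            data = rng.standard_normal((rng.integers(4, 15), k))
            eps = rm_anova_gg(data).epsilon_gg
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_incomplete_matrix_rejected(self):
        data = np.ones((5, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(data)


class TestRmAnovaTrimmed:
    def test_reduces_to_classical_at_zero_trim(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((12, 3)) + np.array([0.0, 0.5, 0.2])
        a = rm_anova_gg(data)
        b = rm_anova_trimmed(data, trim=0.0)
        assert b.statistic == pytest.approx(a.statistic, rel=1e-12)
        assert b.p_raw == pytest.approx(a.p_raw, rel=1e-9)

    def test_resists_single_gross_outlier(self):
        rng = np.random.default_rng(7)
        data = rng.normal(100.0, 1.0, size=(15, 3))
        data[:, 1] += 3.0
        clean = rm_anova_trimmed(data).statistic
        data_out = data.copy()
        data_out[0, 0] = 500.0  # one corrupted cell
        robust = rm_anova_trimmed(data_out).statistic
        classical = rm_anova_gg(data_out).statistic
        assert abs(robust - clean) < abs(classical - clean)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 400
        for _ in range(reps):
            hits += rm_anova_trimmed(rng.standard_normal((17, 3))).p_raw < 0.05
        assert 0.02 <= hits / reps <= 0.08


class TestPairedT:
    PAIRS = [("a", "b")]

    def test_identical_conditions_degenerate(self):
        x = np.arange(10.0)
        res = paired_t_bonferroni({"a": x, "b": x}, self.PAIRS)[0]
        assert res.statistic == 0.0 and res.p_corrected == 1.0

    def test_bonferroni_cap(self):
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(17) + 0.6
        y = rng.standard_normal(17)
        res = paired_t_bonferroni({"a": x, "b": y}, self.PAIRS)[0]
        d = x - y
        expected = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert res.statistic == pytest.approx(expected, abs=1e-9)
        assert res.df == (16.0,)


class TestFriedman:
    def test_all_equal_gives_zero(self):
        res = friedman_bonferroni(np.ones((6, 3)))
        assert res.statistic == 0.0

    def test_perfectly_consistent_ordering_n16(self):
        data = np.tile([1.0, 2.0, 3.0], (16, 1)) + np.arange(16)[:, None] * 5
        res = friedman_bonferroni(data, exact_n_max=0)
        # closed-form maximum of the rank statistic for n=16, k=3
        assert res.statistic == pytest.approx(32.0)

    def test_matches_scipy_chi2_without_ties(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((12, 4))
        mine = friedman_bonferroni(data, exact_n_max=0)
        stat, p = sst.friedmanchisquare(*data.T)
        assert mine.statistic == pytest.approx(stat, abs=1e-10)
        assert mine.p_raw == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("n", [3, 5])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(11 + n)
        data = rng.standard_normal((n, 3))
        mine = friedman_bonferroni(data)
        ranks = np.apply_along_axis(sst.rankdata, 1, data)
        obs = _friedman_statistic(ranks)
        total = hits = 0
        for arrangement in itertools.product(
            *[list(itertools.permutations(row)) for row in ranks]
        ):
            total += 1
            hits += _friedman_statistic(np.array(arrangement)) >= obs - 1e-9
        assert mine.p_raw == pytest.approx(hits / total, abs=1e-12)

    def test_exact_p_with_ties_matches_enumeration(self):
        data = np.array([[1.0, 1.0, 2.0], [3.0, 1.0, 1.0], [2.0, 2.0, 2.0], [1.0, 4.0, 2.0]])
        mine = friedman_bonferroni(data)
        ranks = np.apply_along_axis(sst.rankdata, 1, data)
        obs = _friedman_statistic(ranks)
        total = hits = 0
        for arrangement in itertools.product(
            *[list(itertools.permutations(row)) for row in ranks]
        ):
            total += 1
            hits += _friedman_statistic(np.array(arrangement)) >= obs - 1e-9
        assert mine.p_raw == pytest.approx(hits / total, abs=1e-12)

    def test_family_correction_applied(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((10, 3))
        res = friedman_bonferroni(data, family_size=4, exact_n_max=0)
        assert res.p_corrected == pytest.approx(min(1.0, 4 * res.p_raw))


class TestWilcoxon:
    PAIRS = [("a", "b")]

    def test_all_positive_differences_maximal_w(self):
        x = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        res = wilcoxon_posthoc({"a": x, "b": np.zeros(5)}, self.PAIRS)[0]
        assert res.statistic == 15.0  # 5*6/2

    def test_symmetry_in_pair_order(self):
        rng = np.random.default_rng(13)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        p_xy = wilcoxon_posthoc({"a": x, "b": y}, self.PAIRS)[0].p_raw
        p_yx = wilcoxon_posthoc({"a": y, "b": x}, self.PAIRS)[0].p_raw
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_exact_p_matches_sign_enumeration_n8(self):
        rng = np.random.default_rng(14)
        d = rng.standard_normal(8)
        res = wilcoxon_posthoc({"a": d, "b": np.zeros(8)}, self.PAIRS)[0]
        ranks = sst.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        # exhaustive null: all 2^8 sign assignments of the ranks
        ws = []
        for signs in itertools.product([0, 1], repeat=8):
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.array(ws)
        mean_w = ranks.sum() / 2
        p_exact = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        assert res.p_raw == pytest.approx(p_exact, abs=1e-12)

    def test_zeros_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        res = wilcoxon_posthoc({"a": x, "b": y}, self.PAIRS)[0]
        assert res.n == 4  # two zero differences removed

    def test_all_zero_differences_degenerate(self):
        x = np.ones(6)
        res = wilcoxon_posthoc({"a": x, "b": x}, self.PAIRS)[0]
        assert res.p_raw == 1.0 and res.statistic == 0.0


class TestSpearman:
    def test_monotone_gives_one(self):
        x = np.arange(10.0)
        res = spearman_assoc(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.arange(10.0)
        res = spearman_assoc(x, -(x**3))
        assert res.statistic == pytest.approx(-1.0)

    def test_ties_match_manual_midrank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        res = spearman_assoc(x, y)
        rx, ry = sst.rankdata(x), sst.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on mid-ranks
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_assoc(np.arange(3.0), np.arange(3.0))

    def test_nan_pairs_removed(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.0, np.nan, 5.0, 6.0])
        assert spearman_assoc(x, y).n == 4


class TestPairedTPower:
    def test_null_effect_power_equals_alpha(self):
        assert paired_t_power(PowerSpec(0.0, 17, alpha=0.05)) == pytest.approx(0.05, abs=1e-10)

    def test_huge_effect_saturates(self):
        assert paired_t_power(PowerSpec(5.0, 17)) > 0.999

    def test_matches_quadrature_of_noncentral_t(self):
        from scipy import integrate

        spec = PowerSpec(1.0, 17, alpha=0.05 / 3)
        df, ncp = 16, 1.0 * math.sqrt(17)
        tcrit = sst.t.ppf(1 - spec.alpha / 2, df)
        upper, _ = integrate.quad(lambda t: sst.nct.pdf(t, df, ncp), tcrit, 60)
        lower, _ = integrate.quad(lambda t: sst.nct.pdf(t, df, ncp), -60, -tcrit)
        assert paired_t_power(spec) == pytest.approx(upper + lower, abs=1e-4)


class TestBonferroniDominance:
    def test_corrected_never_below_raw_and_capped(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            p = rng.uniform()
            m = rng.integers(1, 10)
            pc = bonferroni(p, m)
            assert p <= pc <= 1.0
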