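"""Percent change, Spearman correlation, response tables and the cohort
simulator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrpqct.longitudinal import (
    EffectSpec,
    percent_change,
    response_tables,
    significance_stars,
    simulate_cohort,
    spearman,
)


def make_table(rows):
    return pd.DataFrame(rows)


class TestPercentChange:
    def table(self):
        return make_table(
            [
                {"subject_id": "a", "group": "ALN", "visit": 0, "x": 2.0},
                {"subject_id": "a", "group": "ALN", "visit": 24, "x": 2.1},
                {"subject_id": "b", "group": "ALN", "visit": 0, "x": 5.0},
                {"subject_id": "b", "group": "ALN", "visit": 24, "x": 5.0},
            ]
        )

    def test_values(self):
        pc = percent_change(self.table(), "x", 24)
        assert pc["a"] == pytest.approx(5.0)
        assert pc["b"] == pytest.approx(0.0)

    def test_absolute_mode_for_biomarkers(self):
        pc = percent_change(self.table(), "x", 24, absolute=True)
        assert pc["a"] == pytest.approx(0.1)

    def test_zero_baseline_is_missing(self):
        t = self.table()
        t.loc[t["subject_id"] == "a", "x"] = [0.0, 1.0]
        pc = percent_change(t, "x", 24)
        assert np.isnan(pc["a"])

    @given(scale=st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        t = self.table()
        t2 = t.copy()
        t2["x"] = t2["x"] * scale
        pd.testing.assert_series_equal(
            percent_change(t, "x", 24), percent_change(t2, "x", 24)
        )


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_rank_formula(self):
        """Six-point example vs the direct d^2 rank formula (no ties)."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        from scipy.stats import rankdata

        d = rankdata(x) - rankdata(y)
        rho_formula = 1 - 6 * (d**2).sum() / (6 * (36 - 1))
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(rho_formula, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        """Independent oracle: scipy's implementation on tied data."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 30).astype(float)
        y = x + rng.integers(0, 3, 30)
        rho, p = spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_flagged(self):
        rho, p = spearman(np.ones(6), np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, p = spearman(x, y, method="exact")
        # oracle: scipy exact permutation test
        from scipy.stats import PermutationMethod, spearmanr

        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert 0 < p <= 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestStars:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00005, "****")],
    )
    def test_notation(self, p, stars):
        assert significance_stars(p) == stars


class TestResponseTables:
    def test_planted_monotone_dependence_gives_unit_rho(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(12):
            tb_n0, k0 = 2.0 + rng.normal(0, 0.1), 10.0 + rng.normal(0, 1)
            d = rng.normal(0, 5)
            rows.append({"subject_id": f"s{i}", "group": "ALN", "visit": 0,
                         "tb_n": tb_n0, "k": k0, "bsap": 20.0, "untx": 30.0})
            rows.append({
                "subject_id": f"s{i}", "group": "ALN", "visit": 24,
                "tb_n": tb_n0 * (1 + d / 100),
                "k": k0 * (1 + (2 * d + 5) / 100),  # monotone in d
                "bsap": 20.0 + rng.normal(), "untx": 30.0 + rng.normal(),
            })
        tables = response_tables(
            make_table(rows), index_vars=["tb_n"],
            response_vars=("d_bsap", "d_untx", "pct_k"),
        )
        tab = tables[("ALN", "change-vs-response")]
        assert tab.rho.loc["chg_tb_n", "pct_k"] == pytest.approx(1.0)

    def test_shuffled_subjects_break_association(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            x0 = 10 + rng.normal()
            d = rng.normal(0, 5)
            rows.append({"subject_id": f"s{i}", "group": "PBO", "visit": 0,
                         "x": x0, "y": 5.0})
            rows.append({"subject_id": f"s{i}", "group": "PBO", "visit": 24,
                         "x": x0 * (1 + d / 100), "y": 5.0 * (1 + d / 100)})
        t = make_table(rows)
        tables = response_tables(t, ["x"], response_vars=("pct_y",))
        rho_paired = tables[("PBO", "change-vs-response")].rho.iloc[0, 0]
        # shuffle follow-up subject ids
        mask = t["visit"] == 24
        shuffled = t.loc[mask, "subject_id"].sample(frac=1, random_state=3).values
        t.loc[mask, "subject_id"] = shuffled
        tables2 = response_tables(t, ["x"], response_vars=("pct_y",))
        rho_broken = tables2[("PBO", "change-vs-response")].rho.iloc[0, 0]
        assert rho_paired == pytest.approx(1.0)
        assert abs(rho_broken) < 0.5

    def test_null_type_I_rate_near_nominal(self):
        """Independent change columns, n=20: the p<.05 flag fires in about
        5% of replicates (binomial band [0.03, 0.07] at 1000 reps)."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            _, p = spearman(x, y)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestSimulateCohort:
    def test_zero_effect_zero_noise_gives_zero_change(self):
        spec = EffectSpec(baseline_mean={"ct_th": 1.0}, baseline_sd={"ct_th": 0.1})
        t = simulate_cohort(spec, n_per_group=5, seed=1)
        pc = percent_change(t, "ct_th", 24)
        assert np.allclose(pc.dropna(), 0.0)

    def test_planted_group_effect_recovered(self):
        spec = EffectSpec(
            baseline_mean={"ct_th": 1.0},
            baseline_sd={"ct_th": 0.1},
            change_mean_pct={"ct_th": {"ALN": 3.5, "PBO": 0.0}},
            change_sd_pct={"ct_th": 1.0},
        )
        means = []
        for seed in range(50):
            t = simulate_cohort(spec, n_per_group=20, seed=seed)
            aln = t[t["group"] == "ALN"]
            means.append(percent_change(aln, "ct_th", 24).mean())
        grand = np.mean(means)
        se = 1.0 / np.sqrt(20 * 50)
        assert abs(grand - 3.5) < 4 * se

    def test_planted_change_correlation_recovered(self):
        spec = EffectSpec(
            baseline_mean={"tb_n": 2.0, "k": 10.0},
            baseline_sd={"tb_n": 0.2, "k": 1.0},
            change_mean_pct={"tb_n": {"ALN": -1.0}, "k": {"ALN": -2.0}},
            change_sd_pct={"tb_n": 2.0, "k": 3.0},
            change_corr={("tb_n", "k"): 0.8},
        )
        rs = []
        for seed in range(100):
            t = simulate_cohort(spec, n_per_group=20, seed=seed)
            aln = t[t["group"] == "ALN"]
            d1 = percent_change(aln, "tb_n", 24)
            d2 = percent_change(aln, "k", 24)
            rs.append(np.corrcoef(d1, d2)[0, 1])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.03)

    def test_invalid_correlation_spec_errors(self):
        spec = EffectSpec(
            baseline_mean={"a": 1, "b": 1, "c": 1},
            change_corr={("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): -0.9},
        )
        with pytest.raises(ValueError, match="not jointly consistent"):
            simulate_cohort(spec, 5, seed=0)
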