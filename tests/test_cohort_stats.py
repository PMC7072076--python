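"""Cohort statistics: GEE, rank tests, bands, ANOVA, exact tests.

The exact tests are checked against independent brute-force oracles:
Mann-Whitney against enumeration of all group assignments, the 2xk exact
test against a direct sum over all margin-preserving tables using exact
binomial coefficients.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phagoflow import cohort_stats as cs
from phagoflow.synthetic_data import simulate_longitudinal_metric


from oracles import exact_2xk_oracle, mw_enumeration_oracle


# ---------------------------------------------------------------------------
# GEE
# ---------------------------------------------------------------------------

class TestGee:
    def _constant_cohort(self, value_by_group):
        rows = []
        for g, v in value_by_group.items():
            for i in range(4):
                for d in (0, 3, 6):
                    rows.append({"patient_id": f"{g}{i}", "group": g, "day": d,
                                 "metric": "m", "value": v})
        return pd.DataFrame(rows)

    def test_null_identity_beta_is_zero(self):
        df = self._constant_cohort({"infection": 1.0, "no_infection": 1.0})
        res = cs.fit_gee(df, "m")
        assert abs(res.beta) < 1e-8

    def test_single_timepoint_degenerates_to_mean_difference(self):
        df = self._constant_cohort({"infection": 2.0, "no_infection": 1.0})
        df = df[df["day"] == 0]
        res = cs.fit_gee(df, "m")
        assert res.degenerate
        assert res.beta == pytest.approx(1.0)

    def test_simulated_recovery_short(self):
        betas = [cs.fit_gee(simulate_longitudinal_metric(8, 0.5, seed=100 + r), "metric").beta
                 for r in range(25)]
        assert np.mean(betas) == pytest.approx(0.5, abs=0.1)

    def test_requires_two_patients_per_group(self):
        df = self._constant_cohort({"infection": 1.0, "no_infection": 2.0})
        df = df[df["patient_id"] != "infection1"]
        df = df[~df["patient_id"].isin(["infection2", "infection3"])]
        with pytest.raises(cs.CohortStatsError, match="2 patients"):
            cs.fit_gee(df, "m")

    def test_robust_se_positive_on_noisy_data(self):
        res = cs.fit_gee(simulate_longitudinal_metric(8, 0.5, seed=3), "metric")
        assert res.se > 0 and 0 <= res.p_value <= 1
        assert res.working_correlation == "exchangeable"


class TestMannWhitney:
    def test_fully_separated_3v3(self):
        u, p = cs.mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_near_one(self):
        _, p = cs.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_all_4v5_rank_configurations_match_oracle(self):
        ranks = list(range(1, 10))
        for idx in itertools.combinations(range(9), 4):
            x = [ranks[i] for i in idx]
            y = [ranks[i] for i in range(9) if i not in idx]
            u, p = cs.mann_whitney_u(x, y)
            u_o, p_o = mw_enumeration_oracle(x, y)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_per_timepoint_flags_missing_group(self):
        df = pd.DataFrame({"patient_id": ["a", "b"], "group": ["infection"] * 2,
                           "day": [0, 0], "metric": ["m"] * 2, "value": [1.0, 2.0]})
        out = cs.per_timepoint_test(df, "m", 0)
        assert out["missing"]

    def test_per_timepoint_runs_both_groups(self):
        df = simulate_longitudinal_metric(6, 1.0, seed=9)
        out = cs.per_timepoint_test(df, "metric", 0)
        assert not out["missing"] and 0 <= out["p"] <= 1


class TestReferenceBand:
    def test_constant_controls_give_degenerate_band(self):
        band = cs.reference_band([5.0] * 8, "m")
        assert band.lower == band.upper == 5.0

    def test_band_matches_hand_computation(self):
        from scipy import stats as sps
        v = np.array([1.2, 0.9, 1.1, 1.4, 0.8, 1.0, 1.3, 1.05, 0.95, 1.15])
        band = cs.reference_band(v, "m")
        half = sps.t.ppf(0.975, 9) * v.std(ddof=1) / math.sqrt(10)
        assert band.lower == pytest.approx(v.mean() - half, abs=1e-10)
        assert band.upper == pytest.approx(v.mean() + half, abs=1e-10)
        assert band.n_controls == 10

    def test_classification_above_below_within(self):
        band = cs.reference_band([1.0, 1.1, 0.9, 1.0], "m")
        assert band.classify(band.upper + 1) == "above"
        assert band.classify(band.lower - 1) == "below"
        assert band.classify(band.midpoint) == "within"

    def test_single_control_is_error(self):
        with pytest.raises(cs.CohortStatsError):
            cs.reference_band([1.0], "m")


class TestSubsetAnova:
    @staticmethod
    def anova_loop_oracle(groups):
        all_v = [v for g in groups for v in g]
        grand = sum(all_v) / len(all_v)
        ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ss_w = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        df_b = len(groups) - 1
        df_w = len(all_v) - len(groups)
        return (ss_b / df_b) / (ss_w / df_w)

    def test_textbook_arrays_match_loop_oracle(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [3.0, 4, 5]]
        out = cs.subset_anova(groups)
        assert out["F"] == pytest.approx(self.anova_loop_oracle(groups), rel=1e-12)
        assert 0 <= out["p"] <= 1

    def test_identical_groups_tukey_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        out = cs.subset_anova([g, g, g])
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0, abs=1e-9) for p in out["tukey"].values())

    def test_zero_within_variance_distinct_means_degenerate(self):
        out = cs.subset_anova([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert out["degenerate"] and out["p"] == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(cs.CohortStatsError):
            cs.subset_anova([[1.0], [2.0, 3.0], [4.0, 5.0]])


class TestExactContingency:
    def test_proportional_table_is_independent(self):
        assert cs.fisher_freeman_halton([[2, 3], [2, 3]]) == pytest.approx(1.0)

    def test_2x2_enumeration_example(self):
        assert cs.fisher_freeman_halton([[2, 1], [1, 2]]) == pytest.approx(1.0)

    def test_all_small_2x2_tables_match_oracle(self):
        for cells in itertools.product(range(4), repeat=4):
            t = np.array(cells).reshape(2, 2)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert cs.fisher_freeman_halton(t) == pytest.approx(
                exact_2xk_oracle(t), rel=1e-9), t

    def test_small_2x3_tables_match_oracle(self):
        for cells in itertools.product(range(3), repeat=6):
            t = np.array(cells).reshape(2, 3)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert cs.fisher_freeman_halton(t) == pytest.approx(
                exact_2xk_oracle(t), rel=1e-9), t

    def test_2x4_against_r_fisher_test(self):
        # frozen oracle: R 4.3 fisher.test on the same table gives 0.2747253
        assert cs.fisher_freeman_halton([[7, 1, 1, 0], [4, 0, 0, 2]]) == pytest.approx(
            0.2747253, abs=1e-6)

    def test_empty_margin_is_error(self):
        with pytest.raises(cs.CohortStatsError, match="margin"):
            cs.fisher_freeman_halton([[0, 0], [1, 2]])

    def test_baseline_dispatch(self):
        out = cs.baseline_tests(table=[[5, 4], [5, 1]])
        assert out["test"] == "fisher_exact"
        out = cs.baseline_tests(x=[1.0, 2.0, 3.0], y=[4.0, 5.0, 6.0])
        assert out["test"] == "mann_whitney"


class TestCorrelationsAndScreens:
    def test_spearman_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert cs.spearman(x, [2, 4, 9, 16, 25])["rho"] == pytest.approx(1.0)
        assert cs.spearman(x, [10, 8, 3, 2, 1])["rho"] == pytest.approx(-1.0)

    def test_spearman_constant_undefined(self):
        assert cs.spearman([1, 1, 1], [1, 2, 3])["undefined"]

    def test_friedman_identical_within_subject(self):
        v = [1.0, 4.0, 2.0, 5.0, 3.0]
        out = cs.friedman(v, v, v)
        assert out["statistic"] == 0.0 and out["p"] == 1.0

    def test_friedman_detects_shifted_condition(self, rng):
        base = rng.normal(0, 1, 12)
        out = cs.friedman(base, base + 0.1 * rng.normal(size=12), base + 3.0)
        assert out["p"] < 0.01

    def test_shapiro_deterministic_and_discriminates(self, rng):
        normal = rng.normal(0, 1, 50)
        uniform = rng.uniform(0, 1, 50) ** 3  # heavily skewed
        a, b = cs.shapiro_wilk(normal), cs.shapiro_wilk(normal)
        assert a == b
        assert cs.shapiro_wilk(uniform)["p"] < 0.05 < a["p"]


class TestCohortTableValidation:
    def test_valid_table_passes(self):
        df = simulate_longitudinal_metric(3, 0.5, seed=0)
        cs.validate_cohort_table(df)

    def test_duplicate_rows_rejected(self):
        df = simulate_longitudinal_metric(3, 0.5, seed=0)
        with pytest.raises(ValueError, match="duplicate"):
            cs.validate_cohort_table(pd.concat([df, df.iloc[:1]]))

    def test_unknown_day_rejected(self):
        df = simulate_longitudinal_metric(3, 0.5, seed=0)
        df.loc[0, "day"] = 7
        with pytest.raises(ValueError, match="design set"):
            cs.validate_cohort_table(df)


@given(st.lists(st.integers(0, 5), min_size=4, max_size=4))
def test_fisher_p_always_in_unit_interval(cells):
    t = np.array(cells).reshape(2, 2)
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        return
    p = cs.fisher_freeman_halton(t)
    assert 0.0 <= p <= 1.0
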