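"""Phagocytosis percentage, acidification ratio and kinetics ordering."""

import numpy as np
import pytest
from scipy import stats

from phagoflow.fcs_io import ROLES, EventTable, SampleMeta
from phagoflow.function_metrics import (
    MetricsError,
    acidification_metrics,
    kinetics_curve,
    pf520_positive_threshold,
    phagocytosis_fraction,
    subset_acid_ratios,
)
from phagoflow.gating import GateConfig
from phagoflow.synthetic_data import SynthConfig, simulate_sample

CFG = GateConfig()


def _table(pf520, phrodo, meta=None):
    n = len(pf520)
    mat = np.zeros((n, 6))
    mat[:, 0:2] = 500.0
    mat[:, 2] = 50_000.0
    mat[:, 3] = 20_000.0
    mat[:, 4] = phrodo
    mat[:, 5] = pf520
    return EventTable(mat, ROLES, meta or SampleMeta())


def _tf(x):
    return np.arcsinh(np.asarray(x, float) / 150.0)


class TestThreshold:
    def test_constant_reference_gives_its_value(self):
        ref = _table(np.full(200, 300.0), np.zeros(200))
        cut = pf520_positive_threshold(_table([1.0], [1.0]), np.array([True]), CFG,
                                       negative_reference=ref,
                                       reference_flags=np.ones(200, bool))
        assert cut == pytest.approx(float(_tf(300.0)))

    def test_lognormal_reference_cut_is_exact_percentile(self, rng):
        vals = rng.lognormal(np.log(120.0), 0.5, 5000)
        ref = _table(vals, np.zeros(5000))
        cut = pf520_positive_threshold(_table([1.0], [1.0]), np.array([True]), CFG,
                                       negative_reference=ref,
                                       reference_flags=np.ones(5000, bool))
        assert cut == pytest.approx(float(np.percentile(_tf(vals), 99.5)))

    def test_empty_reference_falls_back_with_warning(self, rng):
        vals = np.concatenate([rng.lognormal(np.log(100), 0.4, 3000),
                               rng.lognormal(np.log(30_000), 0.4, 3000)])
        tab = _table(vals, vals)
        empty_ref = _table(np.empty(0), np.empty(0))
        with pytest.warns(UserWarning, match="reference"):
            cut = pf520_positive_threshold(tab, np.ones(6000, bool), CFG,
                                           negative_reference=empty_ref,
                                           reference_flags=np.empty(0, bool))
        assert float(_tf(100)) < cut < float(_tf(30_000))

    def test_no_reference_valley_between_modes(self, rng):
        neg = rng.lognormal(np.log(100), 0.4, 4000)
        pos = rng.lognormal(np.log(30_000), 0.4, 6000)
        tab = _table(np.concatenate([neg, pos]), np.ones(10_000))
        cut = pf520_positive_threshold(tab, np.ones(10_000, bool), CFG)
        # generator boundary: geometric midpoint of the two modes, transformed
        boundary = float(_tf(np.sqrt(100 * 30_000)))
        assert cut == pytest.approx(boundary, abs=1.0)


class TestPhagocytosisFraction:
    def test_all_below_cut_is_zero(self):
        tab = _table(np.full(100, 10.0), np.zeros(100))
        assert phagocytosis_fraction(tab, np.ones(100, bool), float(_tf(1000.0))) == 0.0

    def test_half_above_cut_is_fifty(self):
        pf = np.r_[np.full(50, 10.0), np.full(50, 10_000.0)]
        tab = _table(pf, np.zeros(100))
        assert phagocytosis_fraction(tab, np.ones(100, bool), float(_tf(1000.0))) == 50.0

    def test_zero_neutrophils_undefined(self):
        tab = _table(np.full(10, 5.0), np.zeros(10))
        assert phagocytosis_fraction(tab, np.zeros(10, bool), 1.0) is None

    def test_poisson_zero_class_analytic(self):
        # lambda = 1.2 exactly at 60 min / 37 C: expect 1 - exp(-1.2) positive
        config = SynthConfig(seed=11, events_per_sample=17_000,
                             lambda_max=1.2, tau_uptake_min=1e-9)
        table, truth = simulate_sample(config, SampleMeta("p", "healthy", 0, 60, 37.0))
        flags = truth["is_neutrophil"].to_numpy()
        n = int(flags.sum())
        assert n >= 9000
        cut = pf520_positive_threshold(table, flags, CFG)
        frac = phagocytosis_fraction(table, flags, cut) / 100.0
        p0 = 1.0 - np.exp(-1.2)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p0) / n
        assert lo <= frac <= hi

    def test_invariant_under_monotone_transform_of_channel_and_cut(self, rng):
        pf = rng.lognormal(np.log(500), 1.0, 2000)
        tab = _table(pf, np.ones(2000))
        cut = float(_tf(400.0))
        base = phagocytosis_fraction(tab, np.ones(2000, bool), cut)
        scaled = _table(3.0 * pf, np.ones(2000))
        scaled_cut = float(np.arcsinh(3.0 * np.sinh(cut)))
        assert phagocytosis_fraction(scaled, np.ones(2000, bool), scaled_cut) == base


class TestAcidificationRatio:
    def test_proportional_channels_give_exact_ratio(self):
        pf = np.linspace(1000, 9000, 60)
        tab = _table(pf, 2.0 * pf)
        m = acidification_metrics(tab, np.ones(60, bool), float(_tf(500.0)))
        assert m.mean_acid_ratio == 2.0
        assert m.n_pf520_positive == 60

    def test_mean_ratio_matches_loop_oracle(self, rng):
        pf = rng.uniform(1000, 50_000, 50)
        ph = rng.uniform(500, 80_000, 50)
        tab = _table(pf, ph)
        m = acidification_metrics(tab, np.ones(50, bool), float(_tf(500.0)))
        oracle = sum(ph[i] / pf[i] for i in range(50)) / 50
        assert m.mean_acid_ratio == pytest.approx(oracle, rel=1e-12)
        assert m.mfi_pf520 == pytest.approx(pf.mean(), rel=1e-12)
        assert m.mfi_phrodo == pytest.approx(ph.mean(), rel=1e-12)

    def test_zero_positive_cells_flagged_undefined(self):
        tab = _table(np.full(40, 10.0), np.full(40, 10.0))
        m = acidification_metrics(tab, np.ones(40, bool), float(_tf(1000.0)))
        assert m.undefined and m.mean_acid_ratio is None and m.mfi_pf520 is None
        assert m.phagocytosis_pct == 0.0

    def test_ratio_invariant_under_common_rescaling(self, rng):
        pf = rng.lognormal(np.log(10_000), 0.4, 500)
        ph = rng.lognormal(np.log(15_000), 0.4, 500)
        cut = float(_tf(500.0))
        m1 = acidification_metrics(_table(pf, ph), np.ones(500, bool), cut)
        c = 4.7
        m2 = acidification_metrics(_table(c * pf, c * ph), np.ones(500, bool),
                                   float(np.arcsinh(c * np.sinh(cut))))
        assert m2.mean_acid_ratio == pytest.approx(m1.mean_acid_ratio, rel=1e-12)

    def test_median_statistic_option(self, rng):
        pf = rng.uniform(1000, 9000, 31)
        tab = _table(pf, 2.0 * pf)
        m = acidification_metrics(tab, np.ones(31, bool), float(_tf(500.0)),
                                  statistic="median")
        assert m.mfi_pf520 == pytest.approx(np.median(pf))


class TestSubsetRatios:
    def test_per_subset_ratio_matches_groupwise_oracle(self, gated_sample):
        table, truth, res = gated_sample
        cut = pf520_positive_threshold(table, res.neutrophil, CFG)
        out = subset_acid_ratios(table, res, cut, CFG)
        pf_t = _tf(table.channel("PF520"))
        for name, val in out.items():
            sel = (res.subset == name) & (pf_t > cut)
            if val is None:
                assert not sel.any()
            else:
                oracle = (table.channel("PHRODO")[sel] / table.channel("PF520")[sel]).mean()
                assert val == pytest.approx(oracle, rel=1e-12)

    def test_empty_subset_is_none(self):
        tab = _table(np.full(10, 1e4), np.full(10, 1e4))
        from phagoflow.gating import GatingResult
        res = GatingResult(population=np.full(10, "granulocyte", object),
                           neutrophil=np.ones(10, bool),
                           subset=np.full(10, "CD16bright_CD62Lbright", object))
        out = subset_acid_ratios(tab, res, float(_tf(500.0)))
        assert out["CD16dim_CD62Lbright"] is None
        assert out["CD16bright_CD62Lbright"] is not None


class TestKinetics:
    def _metrics_at(self, t):
        tab = _table(np.full(10, 1e4), np.full(10, 1e4),
                     SampleMeta("p", "healthy", 0, t, 37.0))
        return acidification_metrics(tab, np.ones(10, bool), 1.0)

    def test_shuffled_input_is_ordered(self):
        series = kinetics_curve([self._metrics_at(t) for t in (40, 10, 60, 20)])
        assert [m.incubation_min for m in series.points] == [10, 20, 40, 60]
        assert series.missing_timepoints == ()

    def test_single_point_flags_three_missing(self):
        series = kinetics_curve([self._metrics_at(20)])
        assert len(series.points) == 1
        assert series.missing_timepoints == (10, 40, 60)

    def test_duplicate_timepoint_is_error(self):
        with pytest.raises(MetricsError, match="duplicate"):
            kinetics_curve([self._metrics_at(10), self._metrics_at(10)])

    def test_mean_phagocytosis_curve_monotone_in_time(self):
        # uptake rate increases with incubation time; the mean curve over
        # seeds must be non-decreasing across 10/20/40/60 min
        means = {t: [] for t in (10, 20, 40, 60)}
        for seed in range(20):
            config = SynthConfig(seed=seed, events_per_sample=1500)
            for t in means:
                table, truth = simulate_sample(
                    config, SampleMeta("p", "healthy", 0, t, 37.0))
                flags = truth["is_neutrophil"].to_numpy()
                cut = pf520_positive_threshold(table, flags, CFG)
                means[t].append(phagocytosis_fraction(table, flags, cut))
        curve = [np.mean(means[t]) for t in (10, 20, 40, 60)]
        assert all(a < b for a, b in zip(curve, curve[1:]))
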