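import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evocea.cea import (
    CeaError,
    Distribution,
    PsaSample,
    ceac,
    icer,
    one_way_dsa,
    run_psa,
    summarize_psa,
)
from evocea.markov import StrategyResult


def sr(cost, eff, name=""):
    return StrategyResult(cost=cost, effectiveness=eff, name=name)


class TestIcer:
    def test_published_pair_arithmetic(self):
        """ICER of the two published global cost/effect pairs: the exact
        ratio of the printed values is 189619.41 / 0.19."""
        res = icer(sr(46522.44, 0.54), sr(236141.85, 0.73))
        assert res.delta_cost == pytest.approx(189619.41, abs=1e-9)
        assert res.delta_eff == pytest.approx(0.19, abs=1e-12)
        assert res.icer == pytest.approx(189619.41 / 0.19, rel=1e-12)
        assert res.icer == pytest.approx(997996.89, abs=0.01)
        assert res.dominance == "none"

    def test_dominance_cheaper_and_better(self):
        assert icer(sr(100, 0.5), sr(50, 0.6)).dominance == "b_dominates"
        assert icer(sr(50, 0.6), sr(100, 0.5)).dominance == "a_dominates"

    def test_identical_results_undefined_icer(self):
        res = icer(sr(100, 0.5), sr(100, 0.5))
        assert res.delta_cost == 0.0
        assert res.icer is None

    def test_nonfinite_rejected(self):
        with pytest.raises(CeaError):
            icer(sr(float("nan"), 0.5), sr(1.0, 0.6))

    def test_identity_against_independent_recomputation(self):
        res = icer(sr(123.4, 0.41), sr(987.6, 0.62))
        assert res.icer == pytest.approx((987.6 - 123.4) / (0.62 - 0.41), rel=1e-12)


def linear_model(params):
    """Tiny analytic CEA model for DSA tests: cost_b depends on 'price',
    effects fixed; 'inert' has no influence on the ICER."""
    a = sr(100.0, 0.5)
    b = sr(100.0 + params["price"], 0.5 + params["gain"])
    return icer(a, b)


class TestDsa:
    BASE = {"price": 1000.0, "gain": 0.1, "inert": 5.0}

    def test_insensitive_parameter_has_flat_range(self):
        res = one_way_dsa(self.BASE, linear_model)
        entry = {e.parameter: e for e in res.entries}["inert"]
        assert entry.icer_low == entry.icer_high == res.base_icer

    def test_zero_fraction_collapses_to_base(self):
        res = one_way_dsa(self.BASE, linear_model, fraction=0.0)
        for e in res.entries:
            assert e.icer_low == e.icer_high == res.base_icer

    def test_overall_range_brackets_base(self):
        res = one_way_dsa(self.BASE, linear_model)
        assert res.icer_min <= res.base_icer <= res.icer_max

    def test_tornado_ordered_by_width(self):
        res = one_way_dsa(self.BASE, linear_model)
        widths = [e.width for e in res.entries]
        assert widths == sorted(widths, reverse=True)

    def test_probability_bound_clamps_with_warning(self):
        base = {"price": 1000.0, "gain": 0.9, "inert": 5.0}
        with pytest.warns(UserWarning, match="clamped"):
            res = one_way_dsa(base, linear_model, bounds={"gain": (0.0, 1.0)})
        entry = {e.parameter: e for e in res.entries}["gain"]
        assert entry.high_value == 1.0


def two_point_model(params):
    a = sr(params["cost_a"], params["eff_a"])
    b = sr(params["cost_b"], params["eff_b"])
    return a, b


class TestPsa:
    BASE = {"cost_a": 100.0, "eff_a": 0.5, "cost_b": 300.0, "eff_b": 0.7}

    def test_zero_variance_reproduces_base_case(self):
        dists = {k: Distribution("fixed", v) for k, v in self.BASE.items()}
        samples = run_psa(two_point_model, self.BASE, dists, n_draws=50, seed=0)
        assert all(s.cost_a == 100.0 and s.eff_b == 0.7 for s in samples)

    def test_seed_determinism(self):
        dists = {k: Distribution("gamma", v, 0.1 * v) for k, v in self.BASE.items()}
        s1 = run_psa(two_point_model, self.BASE, dists, n_draws=100, seed=7)
        s2 = run_psa(two_point_model, self.BASE, dists, n_draws=100, seed=7)
        assert s1 == s2
        s3 = run_psa(two_point_model, self.BASE, dists, n_draws=100, seed=8)
        assert s1 != s3

    def test_unknown_distribution_parameter_rejected(self):
        with pytest.raises(CeaError):
            run_psa(two_point_model, self.BASE, {"nope": Distribution("fixed", 1.0)})

    def test_unknown_distribution_kind_rejected(self):
        with pytest.raises(CeaError):
            Distribution("lognormal-ish", 1.0, 0.1)

    def test_gamma_and_beta_match_target_moments(self):
        rng = np.random.default_rng(0)
        g = Distribution("gamma", 200.0, 20.0).sample(rng, 200_000)
        assert g.mean() == pytest.approx(200.0, rel=0.01)
        assert g.std() == pytest.approx(20.0, rel=0.02)
        b = Distribution("beta", 0.35, 0.05).sample(rng, 200_000)
        assert b.mean() == pytest.approx(0.35, rel=0.01)
        assert b.std() == pytest.approx(0.05, rel=0.02)

    def test_scale_multiplies_draws(self):
        rng = np.random.default_rng(0)
        x = Distribution("beta", 0.35, 0.02, scale=100.0).sample(rng, 50_000)
        assert x.mean() == pytest.approx(35.0, rel=0.02)


class TestSummarize:
    def test_constant_samples_collapse(self):
        samples = [PsaSample(i, {}, 10.0, 0.5, 20.0, 0.7) for i in range(30)]
        summ = summarize_psa(samples)
        for m in ("mean", "median", "p2.5", "p97.5"):
            assert summ.value("cost", m, "a") == 10.0
        assert summ.value("cost", "sd", "a") == 0.0

    def test_linear_interpolation_percentiles_one_to_hundred(self):
        samples = [PsaSample(i, {}, float(i + 1), 0.0, 0.0, 0.0) for i in range(100)]
        summ = summarize_psa(samples)
        assert summ.value("cost", "median", "a") == pytest.approx(50.5)
        assert summ.value("cost", "p2.5", "a") == pytest.approx(3.475)
        assert summ.value("cost", "p97.5", "a") == pytest.approx(97.525)

    def test_empty_rejected(self):
        with pytest.raises(CeaError):
            summarize_psa([])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=50))
    def test_percentile_ordering_invariant(self, values):
        samples = [PsaSample(i, {}, v, 0.0, 0.0, 0.0) for i, v in enumerate(values)]
        summ = summarize_psa(samples)
        seq = [summ.value("cost", m, "a") for m in ("p2.5", "p10", "median", "p90", "p97.5")]
        assert seq == sorted(seq)


def _noisy_samples(n=500, seed=3):
    rng = np.random.default_rng(seed)
    d_cost = rng.normal(200_000, 20_000, n)
    d_eff = rng.uniform(0.1, 0.3, n)  # strictly positive in every draw
    return [
        PsaSample(i, {}, 0.0, 0.5, float(d_cost[i]), 0.5 + float(d_eff[i]))
        for i in range(n)
    ]


class TestCeac:
    def test_zero_wtp_is_cost_comparison(self):
        samples = _noisy_samples()
        curve = ceac(samples, np.array([0.0]))
        cheaper_b = np.mean([s.cost_b < s.cost_a for s in samples])
        assert curve.prob_b[0] == pytest.approx(cheaper_b)
        assert curve.prob_b[0] == 0.0  # intervention always costlier here

    def test_limit_probability_one_for_large_wtp(self):
        curve = ceac(_noisy_samples(), np.array([1e12]))
        assert curve.prob_b[0] == 1.0

    def test_monotone_when_delta_eff_positive(self):
        curve = ceac(_noisy_samples(), np.linspace(0, 5e6, 200))
        assert np.all(np.diff(curve.prob_b) >= 0)
        assert np.allclose(curve.prob_a + curve.prob_b, 1.0)

    def test_crossover_at_median_draw_icer(self):
        samples = _noisy_samples()
        icers = np.array([(s.cost_b - s.cost_a) / (s.eff_b - s.eff_a) for s in samples])
        med = float(np.median(icers))
        grid = np.linspace(med - 3e5, med + 3e5, 601)  # 1000-BRL steps
        curve = ceac(samples, grid)
        crossover = grid[np.searchsorted(curve.prob_b, 0.5)]
        assert abs(crossover - med) <= 1500.0

    def test_empty_grid_rejected(self):
        with pytest.raises(CeaError):
            ceac(_noisy_samples(10), np.array([]))
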