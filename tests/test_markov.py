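"""Markov engine: unit examples plus a brute-force path-enumeration oracle."""

import itertools

import numpy as np
import pytest

from evocea.costs import EventMix
from evocea.markov import (
    STATES,
    CohortTrace,
    MarkovSpec,
    MarkovValidationError,
    build_transition_matrix,
    discount_factor,
    per_cycle_probability,
    run_trace,
    strategy_result,
)


def make_spec(p=0.042163, **kw):
    defaults = dict(
        p_event_per_cycle=p,
        event_split=EventMix(0.25, 0.25, 0.25, 0.25),
        horizon_cycles=10,
        discount_rate=0.05,
    )
    defaults.update(kw)
    return MarkovSpec(**defaults)


class TestConversions:
    @pytest.mark.parametrize(
        "risk,cycles,expected",
        [(35.0, 10, 0.042163), (22.75, 10, 0.025482), (0.0, 10, 0.0)],
    )
    def test_per_cycle_probability(self, risk, cycles, expected):
        assert per_cycle_probability(risk, cycles) == pytest.approx(expected, abs=1e-6)

    def test_constant_hazard_round_trip(self):
        """(1 - p)^10 recovers the 10-year survival 1 - R."""
        for risk in (5.0, 22.75, 35.0, 80.0):
            p = per_cycle_probability(risk, 10)
            assert (1 - p) ** 10 == pytest.approx(1 - risk / 100.0, abs=1e-12)

    def test_out_of_range_risk_rejected(self):
        with pytest.raises(MarkovValidationError):
            per_cycle_probability(120.0, 10)

    @pytest.mark.parametrize(
        "cycle,rate,expected",
        [(0, 0.05, 1.0), (10, 0.05, 0.613913), (7, 0.0, 1.0)],
    )
    def test_discount_factor(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, abs=1e-6)

    def test_invalid_rate_rejected(self):
        with pytest.raises(MarkovValidationError):
            discount_factor(1, -1.0)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self):
        T = build_transition_matrix(make_spec(p=0.3))
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_death_absorbing(self):
        T = build_transition_matrix(make_spec(p=0.3))
        assert T[4, 4] == 1.0 and T[4, :4].sum() == 0.0

    def test_no_recurrence_freezes_event_states(self):
        T = build_transition_matrix(make_spec(p=0.3, allow_recurrence=False))
        for i in (1, 2, 3):
            assert T[i, i] == 1.0


def enumerate_occupancy(T: np.ndarray, cycles: int) -> np.ndarray:
    """Independent oracle: exhaustive enumeration of all state paths."""
    n_states = T.shape[0]
    occ = np.zeros((cycles + 1, n_states))
    occ[0, 0] = 1.0
    for t in range(1, cycles + 1):
        for partial in itertools.product(range(n_states), repeat=t):
            prob = 1.0
            prev = 0
            for s in partial:
                prob *= T[prev, s]
                prev = s
            occ[t, partial[-1]] += prob
    return occ


def enumerate_no_recurrence_cost(
    spec: MarkovSpec, drug_cost_per_cycle: float, entry_costs: dict
) -> float:
    """Path-level expected discounted cost when events occur only from the
    event-free state (post-event states absorbing): every event is a visible
    state entry, so costs attach to path transitions exactly."""
    T = build_transition_matrix(spec)
    c_entry = [entry_costs.get(s, 0.0) for s in STATES[1:]]
    total = 0.0
    for path in itertools.product(range(5), repeat=spec.horizon_cycles):
        prob, cost, prev = 1.0, 0.0, 0
        for t, s in enumerate(path, start=1):
            prob *= T[prev, s]
            if prob == 0.0:
                break
            disc = (1.0 + spec.discount_rate) ** (-t)
            if prev != 4:  # alive at cycle start: drug dispensed
                cost += drug_cost_per_cycle * disc
            if s != prev and s != 0:  # new entry into an event state
                cost += c_entry[s - 1] * disc
            prev = s
        else:
            total += prob * cost
    return total


class TestRunTrace:
    def test_null_risk_limit(self):
        spec = make_spec(p=0.0, discount_rate=0.0)
        trace = run_trace(spec, drug_cost_per_cycle=730.0, event_cost=1e6)
        assert trace.effectiveness == 1.0
        assert trace.cumulative_discounted_cost == pytest.approx(7300.0)

    def test_event_free_occupancy_recovers_ten_year_risk(self):
        p = per_cycle_probability(35.0, 10)
        trace = run_trace(make_spec(p=p), 730.0, event_cost=0.0)
        assert trace.occupancy[-1, 0] == pytest.approx(0.650, abs=1e-9)

    def test_single_step_all_mi(self):
        spec = make_spec(
            p=0.5, event_split=EventMix(1, 0, 0, 0), horizon_cycles=1
        )
        trace = run_trace(spec, 0.0, event_cost=0.0)
        assert np.allclose(trace.occupancy[1], [0.5, 0.5, 0, 0, 0])

    def test_rows_conserve_probability(self):
        trace = run_trace(make_spec(p=0.3), 730.0, event_cost=100.0)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_death_occupancy_monotone(self):
        trace = run_trace(make_spec(p=0.3), 730.0, event_cost=100.0)
        deaths = trace.occupancy[:, 4]
        assert np.all(np.diff(deaths) >= -1e-15)

    def test_effectiveness_in_unit_interval(self):
        for p in (0.0, 0.1, 0.9, 1.0):
            trace = run_trace(make_spec(p=p), 0.0, event_cost=0.0)
            assert 0.0 <= trace.effectiveness <= 1.0

    @pytest.mark.parametrize("recurrence", [True, False])
    @pytest.mark.parametrize("cycles", [1, 2, 3])
    def test_occupancy_matches_path_enumeration(self, cycles, recurrence):
        spec = make_spec(
            p=0.35,
            event_split=EventMix(0.3, 0.2, 0.4, 0.1),
            horizon_cycles=cycles,
            allow_recurrence=recurrence,
        )
        trace = run_trace(spec, 1.0, event_cost=1.0)
        oracle = enumerate_occupancy(build_transition_matrix(spec), cycles)
        assert np.allclose(trace.occupancy, oracle, atol=1e-12)

    @pytest.mark.parametrize("cycles", [1, 2, 3])
    def test_cost_matches_path_enumeration_without_recurrence(self, cycles):
        spec = make_spec(
            p=0.4,
            event_split=EventMix(0.3, 0.2, 0.4, 0.1),
            horizon_cycles=cycles,
            allow_recurrence=False,
        )
        entry = {"mi": 588.12, "stroke": 463.21, "revasc": 6756.37, "cv_death": 170385.6}
        trace = run_trace(spec, 730.0, entry_costs=entry)
        oracle = enumerate_no_recurrence_cost(spec, 730.0, entry)
        assert trace.cumulative_discounted_cost == pytest.approx(oracle, abs=1e-9)

    def test_scalar_event_cost_equals_weighted_entry_costs(self):
        mix = EventMix(0.3, 0.2, 0.4, 0.1)
        entry = {"mi": 100.0, "stroke": 200.0, "revasc": 300.0, "cv_death": 400.0}
        scalar = sum(w * c for w, c in zip(mix.as_tuple(), entry.values()))
        spec = make_spec(p=0.2, event_split=mix)
        a = run_trace(spec, 10.0, entry_costs=entry)
        b = run_trace(spec, 10.0, event_cost=scalar)
        assert a.cumulative_discounted_cost == pytest.approx(
            b.cumulative_discounted_cost, rel=1e-12
        )

    def test_discounting_reduces_cost(self):
        spec0 = make_spec(p=0.2, discount_rate=0.0)
        spec5 = make_spec(p=0.2, discount_rate=0.05)
        c0 = run_trace(spec0, 730.0, event_cost=1000.0).cumulative_discounted_cost
        c5 = run_trace(spec5, 730.0, event_cost=1000.0).cumulative_discounted_cost
        assert c5 < c0

    def test_higher_risk_lowers_effectiveness_and_raises_event_cost(self):
        effs, csts = [], []
        for p in (0.0, 0.05, 0.1, 0.2, 0.4):
            # event costs dominate (no drug cost): cost must rise with risk
            trace = run_trace(make_spec(p=p), 0.0, event_cost=10_000.0)
            effs.append(trace.effectiveness)
            csts.append(trace.cumulative_discounted_cost)
        assert all(a > b for a, b in zip(effs, effs[1:]))
        assert all(a < b for a, b in zip(csts, csts[1:]))

    def test_event_cost_xor_entry_costs_required(self):
        spec = make_spec()
        with pytest.raises(MarkovValidationError):
            run_trace(spec, 0.0)
        with pytest.raises(MarkovValidationError):
            run_trace(spec, 0.0, event_cost=1.0, entry_costs={"mi": 1.0})

    def test_half_cycle_correction_discounts_less(self):
        spec = make_spec(p=0.2)
        spec_hc = make_spec(p=0.2, half_cycle_correction=True)
        c = run_trace(spec, 730.0, event_cost=100.0).cumulative_discounted_cost
        c_hc = run_trace(spec_hc, 730.0, event_cost=100.0).cumulative_discounted_cost
        assert c_hc > c  # costs discounted at t - 1/2


class TestStrategyResultAndExport:
    def test_null_risk_undiscounted_equals_regimen_cost(self):
        spec = make_spec(p=0.0, discount_rate=0.0)
        res = strategy_result(run_trace(spec, 730.0, event_cost=0.0), name="atorv")
        assert res.cost == pytest.approx(7300.00)
        assert res.effectiveness == 1.0

    def test_trace_dataframe_layout(self):
        trace = run_trace(make_spec(p=0.1), 730.0, event_cost=100.0)
        df = trace.to_dataframe()
        assert list(df.columns) == ["cycle"] + list(STATES) + ["discounted_cost"]
        assert len(df) == 11
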