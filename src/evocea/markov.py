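"""Discrete-time Markov cohort engine.

Five states: event-free, post-MI, post-stroke, post-revascularization, and
cardiovascular death (absorbing). Each annual cycle, the composite-event
hazard moves a fraction ``p_event_per_cycle`` of every alive state's
occupancy into the event states, split by the composite's component
weights; survivors of an event carry the same per-cycle hazard thereafter
(recurrence allowed). The per-cycle probability is the constant-hazard
conversion of the 10-year cumulative risk, so the event-free occupancy
after N cycles is exactly the 10-year survival 1 - R.

Costs: a per-cycle drug cost accrues on alive occupancy at the start of
each cycle (patients dying during a cycle are dosed for that cycle); event
costs accrue once per event incidence — including recurrent events of the
same type, which do not change state — with the human-capital death payoff
charged on transition into cardiovascular death. All costs are discounted
exponentially at ``discount_rate`` per year with end-of-cycle timing
(cycle t weighted by (1+r)^-t); an optional half-cycle correction shifts
the exponent to t - 1/2.

Effectiveness is, by default, the probability of remaining event-free over
the whole horizon (undiscounted); discounted event-free life-years are an
alternative definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .costs import EventMix

__all__ = [
    "STATES",
    "MarkovSpec",
    "CohortTrace",
    "StrategyResult",
    "per_cycle_probability",
    "discount_factor",
    "build_transition_matrix",
    "run_trace",
    "strategy_result",
]

STATES = ("event_free", "mi", "stroke", "revasc", "cv_death")
_EVENT_STATES = ("mi", "stroke", "revasc", "cv_death")


class MarkovValidationError(ValueError):
    pass


def per_cycle_probability(cum_risk_10y: float, horizon_cycles: int) -> float:
    """Constant-hazard conversion of a cumulative risk (percent) to a
    per-cycle transition probability: 1 - (1 - R)^(1/N)."""
    if not (0.0 <= cum_risk_10y <= 100.0):
        raise MarkovValidationError(f"cumulative risk must be in [0, 100], got {cum_risk_10y}")
    if horizon_cycles < 1:
        raise MarkovValidationError("horizon_cycles must be >= 1")
    return 1.0 - (1.0 - cum_risk_10y / 100.0) ** (1.0 / horizon_cycles)


def discount_factor(cycle: float, rate: float) -> float:
    """(1 + rate)^(-cycle); cycle 0 is undiscounted."""
    if cycle < 0:
        raise MarkovValidationError("cycle must be >= 0")
    if rate <= -1.0:
        raise MarkovValidationError("rate must be > -1")
    return (1.0 + rate) ** (-cycle)


@dataclass(frozen=True)
class MarkovSpec:
    p_event_per_cycle: float
    event_split: EventMix
    horizon_cycles: int = 10
    cycle_length: float = 1.0  # years
    discount_rate: float = 0.05  # per year
    effectiveness_definition: str = "event_free_at_horizon"
    half_cycle_correction: bool = False
    allow_recurrence: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_event_per_cycle <= 1.0):
            raise MarkovValidationError("p_event_per_cycle must be in [0, 1]")
        if self.horizon_cycles < 1:
            raise MarkovValidationError("horizon_cycles must be >= 1")
        if self.cycle_length <= 0:
            raise MarkovValidationError("cycle_length must be > 0")
        if self.discount_rate <= -1.0:
            raise MarkovValidationError("discount_rate must be > -1")
        if self.effectiveness_definition not in (
            "event_free_at_horizon",
            "discounted_event_free_years",
        ):
            raise MarkovValidationError(
                f"unknown effectiveness definition {self.effectiveness_definition!r}"
            )


def build_transition_matrix(spec: MarkovSpec) -> np.ndarray:
    """Row-stochastic 5x5 one-cycle transition matrix.

    Alive states face the event hazard p split by the (renormalized)
    component weights; a recurrent event of the current type keeps the
    patient in place, so post-event diagonals are (1-p) + p*w_self.
    Rows are validated to sum to 1 within 1e-12.
    """
    p = spec.p_event_per_cycle
    w = np.asarray(spec.event_split.normalized().as_tuple())
    T = np.zeros((5, 5))
    T[0, 0] = 1.0 - p
    T[0, 1:] = p * w
    for i in (1, 2, 3):
        if spec.allow_recurrence:
            T[i, 1:] = p * w
            T[i, i] += 1.0 - p
        else:
            T[i, i] = 1.0
    T[4, 4] = 1.0
    rows = T.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise MarkovValidationError(f"transition rows must sum to 1, got {rows}")
    return T


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy history and accumulated payoffs for one strategy."""

    occupancy: np.ndarray  # (horizon_cycles + 1, 5)
    per_cycle_cost: np.ndarray  # discounted, (horizon_cycles,)
    cumulative_discounted_cost: float
    effectiveness: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(df)))
        df["discounted_cost"] = np.concatenate([[0.0], self.per_cycle_cost])
        return df


@dataclass(frozen=True)
class StrategyResult:
    cost: float
    effectiveness: float
    name: str = ""


def run_trace(
    spec: MarkovSpec,
    drug_cost_per_cycle: float,
    event_cost: Optional[float] = None,
    *,
    entry_costs: Optional[Mapping[str, float]] = None,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted costs.

    Event costing takes either a scalar ``event_cost`` charged per event
    incidence regardless of type, or per-state ``entry_costs`` (keys among
    'mi', 'stroke', 'revasc', 'cv_death'). With the composite split fixed,
    a scalar equal to the split-weighted mean of per-state costs yields the
    same expected total.
    """
    if event_cost is None and entry_costs is None:
        raise MarkovValidationError("provide event_cost or entry_costs")
    if event_cost is not None and entry_costs is not None:
        raise MarkovValidationError("event_cost and entry_costs are mutually exclusive")
    if entry_costs is not None:
        unknown = set(entry_costs) - set(_EVENT_STATES)
        if unknown:
            raise MarkovValidationError(f"unknown entry-cost states: {sorted(unknown)}")
        c_entry = np.array([float(entry_costs.get(s, 0.0)) for s in _EVENT_STATES])
    else:
        c_entry = np.full(4, float(event_cost))

    T = build_transition_matrix(spec)
    w = np.asarray(spec.event_split.normalized().as_tuple())
    p = spec.p_event_per_cycle
    n = spec.horizon_cycles
    occ = np.zeros((n + 1, 5))
    occ[0, 0] = 1.0
    per_cycle = np.zeros(n)
    for t in range(1, n + 1):
        prev = occ[t - 1]
        occ[t] = prev @ T
        alive = float(prev[:4].sum())
        at_risk = alive if spec.allow_recurrence else float(prev[0])
        incidence = at_risk * p * w  # events of each type this cycle
        stage_cost = alive * drug_cost_per_cycle + float(incidence @ c_entry)
        tau = t - 0.5 if spec.half_cycle_correction else t
        per_cycle[t - 1] = stage_cost * discount_factor(tau, spec.discount_rate)

    if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):  # conservation guard
        raise MarkovValidationError("occupancy rows drifted from 1")

    if spec.effectiveness_definition == "event_free_at_horizon":
        eff = float(occ[n, 0])
    else:
        disc = (1.0 + spec.discount_rate) ** (-np.arange(1, n + 1, dtype=float))
        eff = float((occ[1:, 0] * disc).sum() * spec.cycle_length)
    return CohortTrace(
        occupancy=occ,
        per_cycle_cost=per_cycle,
        cumulative_discounted_cost=float(per_cycle.sum()),
        effectiveness=eff,
    )


def strategy_result(trace: CohortTrace, name: str = "") -> StrategyResult:
    """Totals consumed by the CEA layer."""
    return StrategyResult(
        cost=trace.cumulative_discounted_cost,
        effectiveness=trace.effectiveness,
        name=name,
    )
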