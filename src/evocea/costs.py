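"""Monetary payoffs: drug regimens, hospitalizations, premature-death cost.

All values are constant 2017 BRL. Hospitalization unit costs are public-payer
reimbursement values (myocardial infarction, ischemic stroke, myocardial
revascularization); drug costs are the wholesale acquisition price of a
40 mg atorvastatin tablet and the retail price of a 140 mg evolocumab
syringe. The indirect cost of a premature cardiovascular death follows the
human-capital approach: years of life lost (cohort life expectancy minus
mean age at death) times the mean annual income adjusted for the
unemployment rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostInputs",
    "Regimen",
    "EventMix",
    "DeathCostParams",
    "DEFAULT_COSTS",
    "DEFAULT_EVENT_MIX",
    "DEFAULT_DEATH_PARAMS",
    "atorvastatin_only_regimen",
    "combined_regimen",
    "regimen_cost",
    "years_of_life_lost",
    "premature_death_cost",
    "expected_event_cost",
]


class CostValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CostInputs:
    """Unit monetary parameters, 2017 BRL."""

    c_mi: float = 588.12
    c_stroke: float = 463.21
    c_revasc: float = 6756.37
    atorvastatin_tablet_40mg: float = 1.00
    evolocumab_syringe_140mg: float = 901.61
    annual_income_adjusted: float = 22128.00
    currency_year: int = 2017

    def __post_init__(self) -> None:
        for name in (
            "c_mi",
            "c_stroke",
            "c_revasc",
            "atorvastatin_tablet_40mg",
            "evolocumab_syringe_140mg",
            "annual_income_adjusted",
        ):
            if getattr(self, name) < 0:
                raise CostValidationError(f"{name} must be >= 0")


DEFAULT_COSTS = CostInputs()


@dataclass(frozen=True)
class Regimen:
    """A drug strategy over the model horizon.

    Dosing arithmetic follows the source costing: twice-monthly evolocumab
    is 24 doses/year (the calendar reading of "every 15 days"); a
    strict-interval reading (365/15 ≈ 24.33 doses/year) is available via
    :func:`combined_regimen`.
    """

    name: str
    atorvastatin_tablets_per_day: float = 2.0  # 80 mg/day as 2 x 40 mg
    evolocumab_doses_per_year: float = 0.0
    horizon: float = 10.0  # years

    def __post_init__(self) -> None:
        if self.atorvastatin_tablets_per_day < 0 or self.evolocumab_doses_per_year < 0:
            raise CostValidationError("dose counts must be non-negative")
        if self.horizon < 0:
            raise CostValidationError("horizon must be >= 0")


def atorvastatin_only_regimen(horizon: float = 10.0) -> Regimen:
    return Regimen(name="atorvastatin", horizon=horizon)


def combined_regimen(horizon: float = 10.0, dosing: str = "calendar") -> Regimen:
    """Atorvastatin 80 mg/day + evolocumab 140 mg every 15 days.

    dosing='calendar' -> 24 doses/year; dosing='strict' -> 365/15 doses/year.
    """
    if dosing == "calendar":
        doses = 24.0
    elif dosing == "strict":
        doses = 365.0 / 15.0
    else:
        raise CostValidationError(f"unknown dosing mode {dosing!r}")
    return Regimen(
        name="atorvastatin+evolocumab", evolocumab_doses_per_year=doses, horizon=horizon
    )


def regimen_cost(reg: Regimen, costs: CostInputs = DEFAULT_COSTS) -> float:
    """Undiscounted drug cost over the horizon, BRL.

    Discounting, when enabled, is applied by the Markov engine on the
    per-cycle share of this total.
    """
    atorv = reg.atorvastatin_tablets_per_day * 365.0 * reg.horizon * costs.atorvastatin_tablet_40mg
    evo = reg.evolocumab_doses_per_year * reg.horizon * costs.evolocumab_syringe_140mg
    return atorv + evo


@dataclass(frozen=True)
class EventMix:
    """Weights of the composite endpoint's components (MI, ischemic stroke,
    revascularization, cardiovascular death).

    Must lie on the simplex; a tolerance of 2e-3 on the sum accommodates
    four proportions each rounded to three decimals. Use
    :meth:`normalized` to rescale exactly.
    """

    w_mi: float
    w_stroke: float
    w_revasc: float
    w_death: float

    def __post_init__(self) -> None:
        ws = (self.w_mi, self.w_stroke, self.w_revasc, self.w_death)
        if any(w < 0 for w in ws):
            raise CostValidationError("event-mix weights must be >= 0")
        if abs(sum(ws) - 1.0) > 2e-3:
            raise CostValidationError(
                f"event-mix weights must sum to 1 (got {sum(ws):.6f})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_mi, self.w_stroke, self.w_revasc, self.w_death)

    def normalized(self) -> "EventMix":
        s = sum(self.as_tuple())
        return EventMix(*(w / s for w in self.as_tuple()))


# Externally sourced default: first-event counts in the FOURIER placebo arm
# (MI 639, ischemic stroke 262, coronary revascularization 965, CV death 240).
DEFAULT_EVENT_MIX = EventMix(
    w_mi=639 / 2106, w_stroke=262 / 2106, w_revasc=965 / 2106, w_death=240 / 2106
)


@dataclass(frozen=True)
class DeathCostParams:
    """Human-capital inputs for the premature-death cost.

    The cohort's sex-adjusted life expectancy is 75 years 8 months; deaths
    over the 10-year horizon occur on average at year 5, i.e. at age 68 for
    a cohort aged 63 at entry. Years of life lost are rounded to
    ``rounding_yll`` decimals before costing (7.667 -> 7.7).
    """

    mean_age: float = 63.0
    mean_age_at_death: float = 68.0
    life_expectancy: float = 75.0 + 8.0 / 12.0
    rounding_yll: int = 1

    def __post_init__(self) -> None:
        if self.mean_age_at_death < self.mean_age:
            raise CostValidationError("mean_age_at_death must be >= mean_age")
        if self.life_expectancy < self.mean_age_at_death:
            raise CostValidationError("life_expectancy must be >= mean_age_at_death")


DEFAULT_DEATH_PARAMS = DeathCostParams()


def years_of_life_lost(p: DeathCostParams = DEFAULT_DEATH_PARAMS) -> float:
    """Life expectancy minus mean age at death, rounded half-up."""
    raw = p.life_expectancy - p.mean_age_at_death
    q = 10.0 ** p.rounding_yll
    return math.floor(raw * q + 0.5) / q


def premature_death_cost(
    p: DeathCostParams = DEFAULT_DEATH_PARAMS, costs: CostInputs = DEFAULT_COSTS
) -> float:
    """Indirect cost of one premature cardiovascular death, BRL."""
    return years_of_life_lost(p) * costs.annual_income_adjusted


def expected_event_cost(
    mix: EventMix, costs: CostInputs = DEFAULT_COSTS, death_cost: float | None = None
) -> float:
    """Weighted mean cost of one composite event, BRL.

    ``death_cost`` defaults to :func:`premature_death_cost` under the
    default death parameters.
    """
    if death_cost is None:
        death_cost = premature_death_cost(costs=costs)
    return (
        mix.w_mi * costs.c_mi
        + mix.w_stroke * costs.c_stroke
        + mix.w_revasc * costs.c_revasc
        + mix.w_death * death_cost
    )
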