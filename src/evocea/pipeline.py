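"""End-to-end model assembly: cohort -> risks -> payoffs -> Markov -> ICER.

The base case compares high-intensity atorvastatin monotherapy against
atorvastatin plus evolocumab over a 10-year horizon. The scalar parameter
vector exposed to the sensitivity machinery is:

    baseline_risk_10y        cohort 10-year composite risk, percent
    rrr                      relative risk reduction of the add-on, fraction
    c_mi, c_stroke, c_revasc hospitalization unit costs, BRL
    atorvastatin_tablet_40mg / evolocumab_syringe_140mg  drug prices, BRL
    annual_income_adjusted   human-capital income, BRL/year
    discount_rate            per year, fraction

Replication overrides let the published point estimates (mean risk 35%,
mean LDL-c 111 mg/dL, and the externally computed global cost/effectiveness
pairs) stand in for model-derived quantities where the original payoff
bookkeeping is not reproducible from printed inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from . import cea, costs, markov, risk
from .cohort import CohortSpec, generate_cohort, summarize_cohort, cohort_to_csv
from .costs import (
    CostInputs,
    DeathCostParams,
    EventMix,
    Regimen,
    expected_event_cost,
    premature_death_cost,
    regimen_cost,
    years_of_life_lost,
)
from .markov import MarkovSpec, StrategyResult, per_cycle_probability, run_trace, strategy_result
from .risk import TranslationParams, cohort_baseline_risk, ldl_on_treatment, relative_risk_reduction

__all__ = [
    "ModelSettings",
    "BaseCaseReport",
    "base_params_from_settings",
    "evaluate_strategies",
    "cea_model",
    "run_base_case",
    "run_dsa",
    "run_psa_pipeline",
    "PARAM_BOUNDS",
    "PARAM_KINDS",
]

PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "baseline_risk_10y": (0.0, 100.0),
    "rrr": (0.0, 1.0),
    "discount_rate": (0.0, 1.0),
}

PARAM_KINDS: dict[str, str] = {
    "baseline_risk_10y": "beta_percent",  # handled below: beta on risk/100
    "rrr": "beta",
    "c_mi": "gamma",
    "c_stroke": "gamma",
    "c_revasc": "gamma",
    "atorvastatin_tablet_40mg": "gamma",
    "evolocumab_syringe_140mg": "gamma",
    "annual_income_adjusted": "gamma",
    "discount_rate": "fixed",
}


@dataclass(frozen=True)
class ModelSettings:
    """Everything the strategy evaluator needs besides the scalar params."""

    regimen_a: Regimen
    regimen_b: Regimen
    event_mix: EventMix
    death_params: DeathCostParams
    horizon_cycles: int = 10
    cycle_length: float = 1.0
    effectiveness_definition: str = "event_free_at_horizon"
    half_cycle_correction: bool = False
    allow_recurrence: bool = True


def default_settings(horizon_cycles: int = 10) -> ModelSettings:
    return ModelSettings(
        regimen_a=costs.atorvastatin_only_regimen(horizon=float(horizon_cycles)),
        regimen_b=costs.combined_regimen(horizon=float(horizon_cycles)),
        event_mix=costs.DEFAULT_EVENT_MIX,
        death_params=costs.DEFAULT_DEATH_PARAMS,
        horizon_cycles=horizon_cycles,
    )


def base_params_from_settings(
    baseline_risk_10y: float,
    rrr: float,
    cost_inputs: CostInputs = costs.DEFAULT_COSTS,
    discount_rate: float = 0.05,
) -> dict[str, float]:
    return {
        "baseline_risk_10y": baseline_risk_10y,
        "rrr": rrr,
        "c_mi": cost_inputs.c_mi,
        "c_stroke": cost_inputs.c_stroke,
        "c_revasc": cost_inputs.c_revasc,
        "atorvastatin_tablet_40mg": cost_inputs.atorvastatin_tablet_40mg,
        "evolocumab_syringe_140mg": cost_inputs.evolocumab_syringe_140mg,
        "annual_income_adjusted": cost_inputs.annual_income_adjusted,
        "discount_rate": discount_rate,
    }


def _drug_cost_per_cycle(reg: Regimen, ci: CostInputs, cycle_length: float) -> float:
    per_year = (
        reg.atorvastatin_tablets_per_day * 365.0 * ci.atorvastatin_tablet_40mg
        + reg.evolocumab_doses_per_year * ci.evolocumab_syringe_140mg
    )
    return per_year * cycle_length


def evaluate_strategies(
    params: Mapping[str, float], settings: ModelSettings
) -> tuple[StrategyResult, StrategyResult]:
    """Run both strategy traces under one scalar parameter vector."""
    ci = CostInputs(
        c_mi=params["c_mi"],
        c_stroke=params["c_stroke"],
        c_revasc=params["c_revasc"],
        atorvastatin_tablet_40mg=params["atorvastatin_tablet_40mg"],
        evolocumab_syringe_140mg=params["evolocumab_syringe_140mg"],
        annual_income_adjusted=params["annual_income_adjusted"],
    )
    death_cost = years_of_life_lost(settings.death_params) * ci.annual_income_adjusted
    entry = {
        "mi": ci.c_mi,
        "stroke": ci.c_stroke,
        "revasc": ci.c_revasc,
        "cv_death": death_cost,
    }
    baseline = min(max(params["baseline_risk_10y"], 0.0), 100.0)
    rrr = min(max(params["rrr"], 0.0), 1.0)
    treated = baseline * (1.0 - rrr)
    results = []
    for reg, risk10 in ((settings.regimen_a, baseline), (settings.regimen_b, treated)):
        spec = MarkovSpec(
            p_event_per_cycle=per_cycle_probability(risk10, settings.horizon_cycles),
            event_split=settings.event_mix,
            horizon_cycles=settings.horizon_cycles,
            cycle_length=settings.cycle_length,
            discount_rate=params["discount_rate"],
            effectiveness_definition=settings.effectiveness_definition,
            half_cycle_correction=settings.half_cycle_correction,
            allow_recurrence=settings.allow_recurrence,
        )
        trace = run_trace(
            spec,
            _drug_cost_per_cycle(reg, ci, settings.cycle_length),
            entry_costs=entry,
        )
        results.append(strategy_result(trace, name=reg.name))
    return results[0], results[1]


def cea_model(settings: ModelSettings):
    """A params -> CEAResult closure for the DSA."""

    def _model(params: Mapping[str, float]) -> cea.CEAResult:
        a, b = evaluate_strategies(params, settings)
        return cea.icer(a, b)

    return _model


@dataclass
class BaseCaseReport:
    """Every intermediate quantity of one base-case run."""

    cohort_summary: Optional[object]
    baseline_risk_10y: float
    mean_ldl: float
    ldl_on_treatment: float
    delta_ldl: float
    rrr: float
    treated_risk_10y: float
    arr: float
    drug_cost_a: float
    drug_cost_b: float
    yll: float
    death_cost: float
    mean_event_cost: float
    p_event_a: float
    p_event_b: float
    model_result_a: StrategyResult
    model_result_b: StrategyResult
    model_cea: cea.CEAResult
    replication_cea: Optional[cea.CEAResult]
    traces: dict[str, markov.CohortTrace]

    @property
    def headline_cea(self) -> cea.CEAResult:
        return self.replication_cea if self.replication_cea is not None else self.model_cea

    def to_json_dict(self) -> dict:
        def cea_dict(r: Optional[cea.CEAResult]):
            return None if r is None else dataclasses.asdict(r)

        return {
            "baseline_risk_10y": self.baseline_risk_10y,
            "mean_ldl": self.mean_ldl,
            "ldl_on_treatment": self.ldl_on_treatment,
            "delta_ldl": self.delta_ldl,
            "rrr": self.rrr,
            "treated_risk_10y": self.treated_risk_10y,
            "arr": self.arr,
            "drug_cost_atorvastatin": self.drug_cost_a,
            "drug_cost_combined": self.drug_cost_b,
            "years_of_life_lost": self.yll,
            "premature_death_cost": self.death_cost,
            "mean_event_cost": self.mean_event_cost,
            "p_event_per_cycle_atorvastatin": self.p_event_a,
            "p_event_per_cycle_combined": self.p_event_b,
            "model_result_atorvastatin": dataclasses.asdict(self.model_result_a),
            "model_result_combined": dataclasses.asdict(self.model_result_b),
            "model_cea": cea_dict(self.model_cea),
            "replication_cea": cea_dict(self.replication_cea),
        }


def run_base_case(
    cohort_spec: CohortSpec = CohortSpec(),
    translation: TranslationParams = TranslationParams(),
    cost_inputs: CostInputs = costs.DEFAULT_COSTS,
    settings: Optional[ModelSettings] = None,
    discount_rate: float = 0.05,
    baseline_risk_override: Optional[float] = None,
    mean_ldl_override: Optional[float] = None,
    replication_strategy_results: Optional[tuple[StrategyResult, StrategyResult]] = None,
    out_dir: Optional[Path] = None,
) -> BaseCaseReport:
    """Deterministic base case; optionally writes JSON + CSV reports.

    With overrides set (replication mode), the published mean risk / mean
    LDL-c / global cost-effect pairs replace their model-derived
    counterparts; the model-derived values are still computed and reported.
    """
    settings = settings or default_settings()
    patients = generate_cohort(cohort_spec)
    summary = summarize_cohort(patients)
    mean_ldl = (
        float(mean_ldl_override)
        if mean_ldl_override is not None
        else float(np.mean([p.ldl for p in patients]))
    )
    baseline = cohort_baseline_risk(patients, override=baseline_risk_override)
    ldl_rx = ldl_on_treatment(mean_ldl, translation)
    delta = mean_ldl - ldl_rx
    rrr = relative_risk_reduction(delta, translation)
    est = risk.treated_risk(baseline, rrr, delta_ldl=delta)

    params = base_params_from_settings(baseline, rrr, cost_inputs, discount_rate)
    res_a, res_b = evaluate_strategies(params, settings)
    model_cea = cea.icer(res_a, res_b)
    repl_cea = (
        cea.icer(*replication_strategy_results)
        if replication_strategy_results is not None
        else None
    )

    death_cost = premature_death_cost(settings.death_params, cost_inputs)
    traces = {}
    for reg, risk10 in (
        (settings.regimen_a, baseline),
        (settings.regimen_b, est.treated_risk_10y),
    ):
        spec = MarkovSpec(
            p_event_per_cycle=per_cycle_probability(risk10, settings.horizon_cycles),
            event_split=settings.event_mix,
            horizon_cycles=settings.horizon_cycles,
            cycle_length=settings.cycle_length,
            discount_rate=discount_rate,
            effectiveness_definition=settings.effectiveness_definition,
            half_cycle_correction=settings.half_cycle_correction,
            allow_recurrence=settings.allow_recurrence,
        )
        traces[reg.name] = run_trace(
            spec,
            _drug_cost_per_cycle(reg, cost_inputs, settings.cycle_length),
            entry_costs={
                "mi": cost_inputs.c_mi,
                "stroke": cost_inputs.c_stroke,
                "revasc": cost_inputs.c_revasc,
                "cv_death": death_cost,
            },
        )

    report = BaseCaseReport(
        cohort_summary=summary,
        baseline_risk_10y=baseline,
        mean_ldl=mean_ldl,
        ldl_on_treatment=ldl_rx,
        delta_ldl=delta,
        rrr=rrr,
        treated_risk_10y=est.treated_risk_10y,
        arr=est.arr,
        drug_cost_a=regimen_cost(settings.regimen_a, cost_inputs),
        drug_cost_b=regimen_cost(settings.regimen_b, cost_inputs),
        yll=years_of_life_lost(settings.death_params),
        death_cost=death_cost,
        mean_event_cost=expected_event_cost(
            settings.event_mix, cost_inputs, death_cost=death_cost
        ),
        p_event_a=per_cycle_probability(baseline, settings.horizon_cycles),
        p_event_b=per_cycle_probability(est.treated_risk_10y, settings.horizon_cycles),
        model_result_a=res_a,
        model_result_b=res_b,
        model_cea=model_cea,
        replication_cea=repl_cea,
        traces=traces,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "base_case.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        summary.to_csv(out_dir / "cohort_summary.csv", index=False)
        cohort_to_csv(patients, out_dir / "cohort.csv")
        for name, trace in traces.items():
            trace.to_dataframe().to_csv(
                out_dir / f"trace_{name.replace('+', '_')}.csv", index=False
            )
    return report


def run_dsa(
    report: BaseCaseReport,
    settings: Optional[ModelSettings] = None,
    cost_inputs: CostInputs = costs.DEFAULT_COSTS,
    discount_rate: float = 0.05,
    fraction: float = 0.20,
) -> cea.DsaResult:
    settings = settings or default_settings()
    params = base_params_from_settings(
        report.baseline_risk_10y, report.rrr, cost_inputs, discount_rate
    )
    return cea.one_way_dsa(params, cea_model(settings), fraction=fraction, bounds=PARAM_BOUNDS)


def run_psa_pipeline(
    report: BaseCaseReport,
    settings: Optional[ModelSettings] = None,
    cost_inputs: CostInputs = costs.DEFAULT_COSTS,
    discount_rate: float = 0.05,
    n_draws: int = 1000,
    seed: int = 0,
    rel_halfwidth: float = 0.20,
    distributions: Optional[dict[str, cea.Distribution]] = None,
) -> list[cea.PsaSample]:
    settings = settings or default_settings()
    params = base_params_from_settings(
        report.baseline_risk_10y, report.rrr, cost_inputs, discount_rate
    )
    if distributions is None:
        kinds = dict(PARAM_KINDS)
        distributions = {}
        for name, value in params.items():
            kind = kinds.get(name, "gamma")
            sd = abs(value) * rel_halfwidth / cea._DISPERSION_Z
            if kind == "fixed" or value == 0.0:
                distributions[name] = cea.Distribution("fixed", value)
            elif kind == "beta_percent":
                # risk is in percent; sample a beta on the probability scale
                distributions[name] = cea.Distribution(
                    "beta", value / 100.0, sd / 100.0, scale=100.0
                )
            else:
                distributions[name] = cea.Distribution(kind, value, sd)

    def model(params_: Mapping[str, float]) -> tuple[StrategyResult, StrategyResult]:
        return evaluate_strategies(params_, settings)

    return cea.run_psa(model, params, distributions, n_draws=n_draws, seed=seed)
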