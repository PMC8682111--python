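"""Run configuration: schema-validated YAML/JSON with strict keys.

Monetary values may be written as decimal strings ("901.61") to keep golden
config files free of binary-float drift; they are parsed through
``decimal.Decimal`` before conversion. Unknown keys are rejected with the
offending field path in the error.
"""

from __future__ import annotations

from decimal import Decimal
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import cea, costs
from .cohort import CohortSpec
from .costs import CostInputs, DeathCostParams, EventMix, Regimen
from .markov import StrategyResult
from .pipeline import ModelSettings
from .risk import TranslationParams

__all__ = ["RunConfig", "load_config", "dump_config", "paper_replication_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Strict):
    n: int = 61
    seed: int = 0
    mean_age: float = 63.0
    sd_age: float = 11.0
    prop_male: float = 0.52
    prop_htn: float = 0.83
    prop_dm: float = 0.42
    prop_smoking: float = 0.31
    prop_prior_mi: float = 0.54
    prop_prior_stroke: float = 0.0
    prop_ezetimibe: float = 0.10
    prop_ckd: float = 0.0
    prop_pad: float = 0.0
    prop_fh: float = 0.0
    mean_ldl: float = 111.0
    sd_ldl: float = 34.0
    mean_hdl: float = 45.0
    sd_hdl: float = 13.0
    mean_tg: float = 159.0
    sd_tg: float = 97.0
    ldl_floor: float = 70.0

    def to_domain(self) -> CohortSpec:
        return CohortSpec(**self.model_dump())


class TranslationConfig(_Strict):
    ldl_reduction_fraction: float = 0.59
    rrr_per_block: float = 0.21
    block_size: float = 39.0
    scaling: Literal["linear", "compounding"] = "linear"
    rounding: Literal["paper", "raw"] = "paper"

    def to_domain(self) -> TranslationParams:
        return TranslationParams(**self.model_dump())


class CostConfig(_Strict):
    c_mi: Decimal = Decimal("588.12")
    c_stroke: Decimal = Decimal("463.21")
    c_revasc: Decimal = Decimal("6756.37")
    atorvastatin_tablet_40mg: Decimal = Decimal("1.00")
    evolocumab_syringe_140mg: Decimal = Decimal("901.61")
    annual_income_adjusted: Decimal = Decimal("22128.00")
    currency_year: int = 2017

    def to_domain(self) -> CostInputs:
        d = self.model_dump()
        return CostInputs(**{k: float(v) if isinstance(v, Decimal) else v for k, v in d.items()})


class RegimenConfig(_Strict):
    name: str
    atorvastatin_tablets_per_day: float = 2.0
    evolocumab_doses_per_year: float = 0.0
    horizon: float = 10.0

    def to_domain(self) -> Regimen:
        return Regimen(**self.model_dump())


class EventMixConfig(_Strict):
    w_mi: float = costs.DEFAULT_EVENT_MIX.w_mi
    w_stroke: float = costs.DEFAULT_EVENT_MIX.w_stroke
    w_revasc: float = costs.DEFAULT_EVENT_MIX.w_revasc
    w_death: float = costs.DEFAULT_EVENT_MIX.w_death

    def to_domain(self) -> EventMix:
        return EventMix(**self.model_dump())


class DeathConfig(_Strict):
    mean_age: float = 63.0
    mean_age_at_death: float = 68.0
    life_expectancy: float = 75.0 + 8.0 / 12.0
    rounding_yll: int = 1

    def to_domain(self) -> DeathCostParams:
        return DeathCostParams(**self.model_dump())


class MarkovConfig(_Strict):
    horizon_cycles: int = 10
    cycle_length: float = 1.0
    discount_rate: float = 0.05
    effectiveness_definition: Literal[
        "event_free_at_horizon", "discounted_event_free_years"
    ] = "event_free_at_horizon"
    half_cycle_correction: bool = False
    allow_recurrence: bool = True


class DistributionConfig(_Strict):
    kind: Literal["fixed", "gamma", "beta", "normal"]
    mean: float
    sd: float = 0.0
    scale: float = 1.0

    def to_domain(self) -> cea.Distribution:
        return cea.Distribution(**self.model_dump())


class PsaConfig(_Strict):
    n_draws: int = 1000
    seed: int = 0
    rel_halfwidth: float = 0.20
    distributions: Optional[dict[str, DistributionConfig]] = None


class DsaConfig(_Strict):
    fraction: float = 0.20


class StrategyOverride(_Strict):
    cost: Decimal
    effectiveness: float

    def to_domain(self, name: str) -> StrategyResult:
        return StrategyResult(cost=float(self.cost), effectiveness=self.effectiveness, name=name)


class ReplicationOverrides(_Strict):
    """Published point estimates standing in for model-derived quantities."""

    baseline_risk_10y: Optional[float] = None
    mean_ldl: Optional[float] = None
    strategy_a: Optional[StrategyOverride] = None
    strategy_b: Optional[StrategyOverride] = None


class RunConfig(_Strict):
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    translation: TranslationConfig = Field(default_factory=TranslationConfig)
    costs: CostConfig = Field(default_factory=CostConfig)
    regimen_a: RegimenConfig = Field(
        default_factory=lambda: RegimenConfig(name="atorvastatin")
    )
    regimen_b: RegimenConfig = Field(
        default_factory=lambda: RegimenConfig(
            name="atorvastatin+evolocumab", evolocumab_doses_per_year=24.0
        )
    )
    event_mix: EventMixConfig = Field(default_factory=EventMixConfig)
    death: DeathConfig = Field(default_factory=DeathConfig)
    markov: MarkovConfig = Field(default_factory=MarkovConfig)
    psa: PsaConfig = Field(default_factory=PsaConfig)
    dsa: DsaConfig = Field(default_factory=DsaConfig)
    replication_overrides: Optional[ReplicationOverrides] = None

    def settings(self) -> ModelSettings:
        return ModelSettings(
            regimen_a=self.regimen_a.to_domain(),
            regimen_b=self.regimen_b.to_domain(),
            event_mix=self.event_mix.to_domain(),
            death_params=self.death.to_domain(),
            horizon_cycles=self.markov.horizon_cycles,
            cycle_length=self.markov.cycle_length,
            effectiveness_definition=self.markov.effectiveness_definition,
            half_cycle_correction=self.markov.half_cycle_correction,
            allow_recurrence=self.markov.allow_recurrence,
        )

    def replication_results(self) -> Optional[tuple[StrategyResult, StrategyResult]]:
        ro = self.replication_overrides
        if ro is None or ro.strategy_a is None or ro.strategy_b is None:
            return None
        return (
            ro.strategy_a.to_domain(self.regimen_a.name),
            ro.strategy_b.to_domain(self.regimen_b.name),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def paper_replication_config() -> RunConfig:
    """The packaged configuration reproducing the published base case."""
    from importlib import resources

    with resources.files("evocea.data").joinpath("paper_replication.yaml").open() as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))
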