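"""Ten-year cardiovascular risk: category bands and LDL-lowering translation.

Baseline risk comes from published 10-year risk bands for statin-treated
high-risk categories; a patient is assigned the eligible band with the
highest midpoint, and the band's midpoint is the point estimate. The
treatment effect of adding a PCSK9 inhibitor is translated from lipids:
evolocumab lowers LDL-c by a further 59% on top of high-intensity statin,
and meta-analytic evidence attributes a 21% relative reduction in major
vascular events to each 39 mg/dL of LDL-c lowering. The default translation
scales that per-block effect linearly in the achieved LDL-c decrement and
rounds the relative risk reduction to the nearest whole percent (matching
how the source analysis applied it); compounding (1 - 0.79^(d/39)) and
unrounded modes are available for sensitivity exploration.

The trial effect was observed over ~26 months; applying its RRR over a
10-year horizon assumes the relative effect is constant in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional, Sequence

import pandas as pd

from .cohort import PatientProfile

__all__ = [
    "RiskCategory",
    "TranslationParams",
    "RiskEstimate",
    "NoCategoryError",
    "load_risk_categories",
    "category_midpoint",
    "assign_category",
    "cohort_baseline_risk",
    "ldl_on_treatment",
    "relative_risk_reduction",
    "treated_risk",
]


class RiskValidationError(ValueError):
    pass


class NoCategoryError(ValueError):
    """Patient matches no high-risk category (malformed input for this cohort)."""


@dataclass(frozen=True)
class RiskCategory:
    """A published 10-year risk band (percent bounds)."""

    name: str
    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.high <= 100):
            raise RiskValidationError(
                f"risk band requires 0 < low <= high <= 100, got ({self.low}, {self.high})"
            )


def category_midpoint(cat: RiskCategory) -> float:
    """Point risk for a band: the arithmetic midpoint (low + high) / 2, percent."""
    return (cat.low + cat.high) / 2.0


# Eligibility predicates per category. All cohort members have clinical
# atherosclerotic disease (CAD with ACS in the past year) by inclusion, so
# predicates only test the distinguishing comorbidity. "Poorly controlled
# risk factors" is operationalized as active smoking.
_PREDICATES: dict[str, Callable[[PatientProfile], bool]] = {
    "ascvd_diabetes_ckd": lambda p: p.diabetes and p.ckd,
    "ascvd_diabetes_no_ckd": lambda p: p.diabetes and not p.ckd,
    "ascvd_ckd": lambda p: p.ckd,
    "recent_acs": lambda p: p.recent_acs,
    "cad_poor_risk_control": lambda p: p.smoking,
    "cad_pad": lambda p: p.pad,
    "cad_age_ge_65": lambda p: p.age >= 65,
    "stroke_tia_male": lambda p: p.prior_stroke and p.sex == "male",
    "cad_fh": lambda p: p.familial_hyperchol or p.ldl >= 190,
}


def load_risk_categories() -> list[RiskCategory]:
    """The packaged risk-band table, in published order."""
    with resources.files("evocea.data").joinpath("risk_categories.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        RiskCategory(name=r.name, low=float(r.low), high=float(r.high), label=r.label)
        for r in df.itertuples(index=False)
    ]


_CATEGORIES: Optional[list[RiskCategory]] = None


def _categories() -> list[RiskCategory]:
    global _CATEGORIES
    if _CATEGORIES is None:
        _CATEGORIES = load_risk_categories()
    return _CATEGORIES


def assign_category(
    patient: PatientProfile, categories: Optional[Sequence[RiskCategory]] = None
) -> RiskCategory:
    """The eligible category with the highest midpoint risk.

    Ties break by table order (first listed wins). Raises
    :class:`NoCategoryError` if no band applies — unreachable for cohorts
    from :func:`evocea.cohort.generate_cohort`, where ``recent_acs`` always
    holds.
    """
    cats = list(categories) if categories is not None else _categories()
    eligible = [c for c in cats if _PREDICATES[c.name](patient)]
    if not eligible:
        raise NoCategoryError(f"patient {patient.id} matches no risk category")
    return max(eligible, key=lambda c: category_midpoint(c))  # max is stable: first of ties


def cohort_baseline_risk(
    patients: Sequence[PatientProfile], override: Optional[float] = None
) -> float:
    """Cohort 10-year baseline risk (percent): mean of per-patient category
    midpoints, or ``override`` verbatim in replication mode."""
    if override is not None:
        return float(override)
    if not patients:
        raise RiskValidationError("empty cohort and no override risk given")
    return float(
        sum(category_midpoint(assign_category(p)) for p in patients) / len(patients)
    )


@dataclass(frozen=True)
class TranslationParams:
    """LDL-to-events translation.

    ldl_reduction_fraction : additional proportional LDL-c lowering on statin.
    rrr_per_block          : relative risk reduction per ``block_size`` mg/dL.
    scaling                : 'linear' (rrr_per_block * d / block_size, capped
                             at 1) or 'compounding' (1 - (1-rrr)^(d/block)).
    rounding               : 'paper' rounds the RRR to the nearest whole
                             percent before use; 'raw' keeps full precision.
    """

    ldl_reduction_fraction: float = 0.59
    rrr_per_block: float = 0.21
    block_size: float = 39.0
    scaling: str = "linear"
    rounding: str = "paper"

    def __post_init__(self) -> None:
        if not (0 < self.ldl_reduction_fraction < 1):
            raise RiskValidationError("ldl_reduction_fraction must be in (0, 1)")
        if not (0 < self.rrr_per_block < 1):
            raise RiskValidationError("rrr_per_block must be in (0, 1)")
        if self.block_size <= 0:
            raise RiskValidationError("block_size must be > 0")
        if self.scaling not in ("linear", "compounding"):
            raise RiskValidationError(f"unknown scaling {self.scaling!r}")
        if self.rounding not in ("paper", "raw"):
            raise RiskValidationError(f"unknown rounding {self.rounding!r}")


@dataclass(frozen=True)
class RiskEstimate:
    baseline_risk_10y: float  # percent
    treated_risk_10y: float  # percent
    rrr: float  # fraction
    arr: float  # percentage points
    delta_ldl: float = float("nan")  # mg/dL

    def __post_init__(self) -> None:
        if not (0 <= self.treated_risk_10y <= self.baseline_risk_10y <= 100):
            raise RiskValidationError(
                "requires 0 <= treated <= baseline <= 100, got "
                f"({self.treated_risk_10y}, {self.baseline_risk_10y})"
            )


def ldl_on_treatment(ldl: float, params: TranslationParams) -> float:
    """On-treatment LDL-c: ldl * (1 - ldl_reduction_fraction), mg/dL."""
    if ldl <= 0:
        raise RiskValidationError(f"ldl must be > 0, got {ldl}")
    return ldl * (1.0 - params.ldl_reduction_fraction)


def relative_risk_reduction(delta_ldl: float, params: TranslationParams) -> float:
    """RRR (fraction) attributed to an LDL-c decrement of ``delta_ldl`` mg/dL."""
    if delta_ldl < 0:
        raise RiskValidationError(f"delta_ldl must be >= 0, got {delta_ldl}")
    blocks = delta_ldl / params.block_size
    if params.scaling == "linear":
        rrr = min(params.rrr_per_block * blocks, 1.0)
    else:
        rrr = 1.0 - (1.0 - params.rrr_per_block) ** blocks
    if params.rounding == "paper":
        # half-up to the nearest whole percent, as applied in the source analysis
        rrr = math.floor(rrr * 100.0 + 0.5) / 100.0
    return rrr


def treated_risk(
    baseline: float, rrr: float, delta_ldl: float = float("nan")
) -> RiskEstimate:
    """Treated 10-year risk: baseline * (1 - rrr); ARR = baseline - treated."""
    if not (0 <= baseline <= 100):
        raise RiskValidationError(f"baseline risk must be in [0, 100], got {baseline}")
    if not (0 <= rrr <= 1):
        raise RiskValidationError(f"rrr must be in [0, 1], got {rrr}")
    treated = baseline * (1.0 - rrr)
    return RiskEstimate(
        baseline_risk_10y=baseline,
        treated_risk_10y=treated,
        rrr=rrr,
        arr=baseline - treated,
        delta_ldl=delta_ldl,
    )
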