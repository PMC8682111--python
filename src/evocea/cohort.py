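"""Synthetic secondary-prevention cohorts.

Generates seeded patient samples with the marginal structure of a
61-patient outpatient coronary-artery-disease cohort: age 63 +/- 11 years,
52% male, 83% hypertension, 42% diabetes, 31% smoking, 54% prior MI,
LDL-c 111 +/- 34 mg/dL with an eligibility floor of 70 mg/dL (statin-treated
patients failing to reach target). Continuous variables are drawn from
truncated normals whose *underlying* location/scale are moment-matched so
that the truncated distribution itself has the stated mean and SD — a naive
floor-70 truncation of N(111, 34) would inflate the sample mean well above
111.

Comorbidity flags are sampled independently per patient: only marginal
frequencies are reported for the source sample, so independence is the
minimal-assumption model. A ``flag_correlation`` hook is reserved on
:class:`CohortSpec` for future joint structure.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PatientProfile",
    "CohortSpec",
    "TABLE_DEFAULT_SPEC",
    "generate_cohort",
    "summarize_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "fit_truncated_normal",
]

AGE_MIN, AGE_MAX = 40.0, 85.0  # trial eligibility window
HDL_FLOOR = 20.0
TG_FLOOR = 40.0


class CohortValidationError(ValueError):
    """Raised when a spec or patient field violates its constraints."""


@dataclass(frozen=True)
class PatientProfile:
    """One synthetic patient: demographics, comorbidity flags, lipid panel."""

    id: int
    age: float
    sex: str  # "male" | "female"
    hypertension: bool
    diabetes: bool
    smoking: bool
    prior_mi: bool
    prior_stroke: bool
    ckd: bool
    pad: bool
    recent_acs: bool
    familial_hyperchol: bool
    ezetimibe: bool
    ldl: float
    hdl: float
    tg: float

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise CohortValidationError(f"age must be in [{AGE_MIN}, {AGE_MAX}], got {self.age}")
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.ldl < 70.0:
            raise CohortValidationError(f"ldl must be >= 70 mg/dL, got {self.ldl}")
        for name in ("ldl", "hdl", "tg"):
            if getattr(self, name) <= 0:
                raise CohortValidationError(f"{name} must be strictly positive")


_PROPORTION_FIELDS = (
    "prop_male",
    "prop_htn",
    "prop_dm",
    "prop_smoking",
    "prop_prior_mi",
    "prop_prior_stroke",
    "prop_ezetimibe",
    "prop_ckd",
    "prop_pad",
    "prop_fh",
)


@dataclass(frozen=True)
class CohortSpec:
    """Target marginals and seed for cohort generation.

    Proportions are population fractions in [0, 1]; continuous variables are
    given as (mean, SD) of the *realized* (truncated) distribution.
    """

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
    flag_correlation: Optional[object] = None  # reserved, unused

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortValidationError(f"n must be >= 1, got {self.n}")
        for name in _PROPORTION_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CohortValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("sd_age", "sd_ldl", "sd_hdl", "sd_tg"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (70.0 <= self.ldl_floor):
            raise CohortValidationError(f"ldl_floor must be >= 70, got {self.ldl_floor}")
        if self.mean_ldl < self.ldl_floor:
            raise CohortValidationError("mean_ldl must be >= ldl_floor")


#: Default spec reproducing the source sample's marginals (n = 61).
TABLE_DEFAULT_SPEC = CohortSpec()


@lru_cache(maxsize=64)
def fit_truncated_normal(
    mean: float, sd: float, lower: float = -np.inf, upper: float = np.inf
) -> tuple[float, float]:
    """Underlying (mu, sigma) such that N(mu, sigma) truncated to
    [lower, upper] has the requested mean and SD.

    Solved by root-finding on the truncated moments; sigma parametrized on
    the log scale to stay positive. With sd == 0 the distribution is a point
    mass at ``mean``.
    """
    if sd == 0:
        return float(mean), 0.0
    if np.isinf(upper) and sd >= (mean - lower):
        # a lower-truncated normal cannot exceed the exponential bound
        # sd/(mean - lower) -> 1 as the truncation becomes extreme
        raise CohortValidationError(
            f"sd {sd} is infeasible for a floor at {lower} with mean {mean} "
            f"(requires sd < mean - floor = {mean - lower})"
        )

    def resid(x: np.ndarray) -> list[float]:
        mu, lsig = x
        sig = float(np.exp(lsig))
        a, b = (lower - mu) / sig, (upper - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)])
    if not sol.success:
        raise CohortValidationError(
            f"truncated-normal moment fit failed for mean={mean}, sd={sd} "
            f"on [{lower}, {upper}] (moments may be infeasible under truncation)"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_truncated(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    mu, sig = fit_truncated_normal(mean, sd, lower, upper)
    a, b = (lower - mu) / sig, (upper - mu) / sig
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> list[PatientProfile]:
    """Draw ``spec.n`` patients; identical spec (incl. seed) => identical cohort.

    All patients carry ``recent_acs=True``: cohort inclusion required an
    acute coronary syndrome within the past year, so recent ACS is a
    constant of the population, not a sampled flag.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    age = _draw_truncated(rng, n, spec.mean_age, spec.sd_age, AGE_MIN, AGE_MAX)
    ldl = _draw_truncated(rng, n, spec.mean_ldl, spec.sd_ldl, spec.ldl_floor)
    hdl = _draw_truncated(rng, n, spec.mean_hdl, spec.sd_hdl, HDL_FLOOR)
    tg = _draw_truncated(rng, n, spec.mean_tg, spec.sd_tg, TG_FLOOR)
    flags = {
        name: rng.random(n) < getattr(spec, name)
        for name in _PROPORTION_FIELDS
    }
    patients = []
    for i in range(n):
        patients.append(
            PatientProfile(
                id=i,
                age=float(age[i]),
                sex="male" if flags["prop_male"][i] else "female",
                hypertension=bool(flags["prop_htn"][i]),
                diabetes=bool(flags["prop_dm"][i]),
                smoking=bool(flags["prop_smoking"][i]),
                prior_mi=bool(flags["prop_prior_mi"][i]),
                prior_stroke=bool(flags["prop_prior_stroke"][i]),
                ckd=bool(flags["prop_ckd"][i]),
                pad=bool(flags["prop_pad"][i]),
                recent_acs=True,
                familial_hyperchol=bool(flags["prop_fh"][i]),
                ezetimibe=bool(flags["prop_ezetimibe"][i]),
                ldl=float(ldl[i]),
                hdl=float(hdl[i]),
                tg=float(tg[i]),
            )
        )
    return patients


def _mean_sd(x: pd.Series) -> tuple[float, float]:
    return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0


def summarize_cohort(patients: list[PatientProfile]) -> pd.DataFrame:
    """Descriptive table: mean (SD) for continuous fields, n (%) for flags,
    plus LDL strata counts (70-99, >= 100 mg/dL)."""
    if not patients:
        raise CohortValidationError("cannot summarize an empty cohort")
    df = pd.DataFrame([asdict(p) for p in patients])
    n = len(df)
    rows: list[dict] = [{"variable": "n", "value": n, "dispersion_or_pct": np.nan}]

    def cont(label: str, col: str) -> None:
        m, s = _mean_sd(df[col])
        rows.append({"variable": label, "value": m, "dispersion_or_pct": s})

    def flag(label: str, mask: pd.Series) -> None:
        k = int(mask.sum())
        rows.append({"variable": label, "value": k, "dispersion_or_pct": 100.0 * k / n})

    cont("age_mean_sd", "age")
    flag("male_n_pct", df["sex"] == "male")
    for label, col in [
        ("hypertension_n_pct", "hypertension"),
        ("diabetes_n_pct", "diabetes"),
        ("smoking_n_pct", "smoking"),
        ("prior_mi_n_pct", "prior_mi"),
        ("prior_stroke_n_pct", "prior_stroke"),
        ("ezetimibe_n_pct", "ezetimibe"),
    ]:
        flag(label, df[col])
    cont("ldl_mean_sd", "ldl")
    flag("ldl_70_99_n_pct", (df["ldl"] >= 70) & (df["ldl"] < 100))
    flag("ldl_ge_100_n_pct", df["ldl"] >= 100)
    cont("hdl_mean_sd", "hdl")
    cont("tg_mean_sd", "tg")
    return pd.DataFrame(rows)


_PATIENT_COLUMNS = [f.name for f in fields(PatientProfile)]


def cohort_to_csv(patients: list[PatientProfile], path_or_buf) -> None:
    """One row per patient, columns exactly the PatientProfile fields."""
    pd.DataFrame([asdict(p) for p in patients], columns=_PATIENT_COLUMNS).to_csv(
        path_or_buf, index=False, float_format="%.17g"
    )


def cohort_from_csv(path_or_buf) -> list[PatientProfile]:
    # round_trip parser: the default fast path can be 1 ulp off, breaking
    # byte-exact reproducibility of generated cohorts
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    missing = set(_PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    bool_cols = [
        f.name for f in fields(PatientProfile) if f.type in ("bool",)
    ]
    out = []
    for rec in df[_PATIENT_COLUMNS].to_dict("records"):
        for c in bool_cols:
            rec[c] = bool(rec[c])
        rec["id"] = int(rec["id"])
        out.append(PatientProfile(**rec))
    return out
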