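"""Incremental cost-effectiveness and sensitivity analysis.

The comparison statistic is the incremental cost-effectiveness ratio
(ICER): the extra cost of the combined strategy per additional composite
cardiovascular outcome avoided, delta_cost / delta_eff. Robustness is
probed two ways:

* one-way deterministic sensitivity (DSA): each scalar parameter is set to
  0.8x and 1.2x its base value with the others held fixed, and the ICER
  range per parameter (tornado ordering) and overall is reported;
* probabilistic sensitivity (PSA): second-order Monte Carlo over parameter
  distributions (gamma for costs, beta for probabilities and the relative
  risk reduction), each draw re-running the full cohort model; summarized
  Table-style (mean, SD, median, percentiles 2.5/10/90/97.5 per strategy)
  and as a cost-effectiveness acceptability curve (CEAC): the fraction of
  draws in which each strategy has the higher net monetary benefit at each
  willingness-to-pay value.

Percentiles use linear interpolation between closest ranks (numpy's
default), pinned here so summary values are reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .markov import StrategyResult

__all__ = [
    "CEAResult",
    "DsaEntry",
    "DsaResult",
    "PsaSample",
    "PsaSummary",
    "CeacCurve",
    "Distribution",
    "icer",
    "one_way_dsa",
    "default_psa_distributions",
    "run_psa",
    "summarize_psa",
    "ceac",
]


class CeaError(ValueError):
    pass


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison; strategy a is the comparator, b the intervention."""

    cost_a: float
    cost_b: float
    eff_a: float
    eff_b: float
    delta_cost: float
    delta_eff: float
    icer: Optional[float]  # None when delta_eff == 0
    dominance: str  # 'none' | 'a_dominates' | 'b_dominates'


def icer(a: StrategyResult, b: StrategyResult) -> CEAResult:
    """ICER of b vs a with dominance classification.

    A strategy dominates when it is cheaper and more effective; with
    delta_eff == 0 the ratio is undefined and left as None (no division).
    """
    for r in (a, b):
        if not (math.isfinite(r.cost) and math.isfinite(r.effectiveness)):
            raise CeaError("strategy results must be finite")
    d_cost = b.cost - a.cost
    d_eff = b.effectiveness - a.effectiveness
    if d_cost < 0 and d_eff > 0:
        dom = "b_dominates"
    elif d_cost > 0 and d_eff < 0:
        dom = "a_dominates"
    else:
        dom = "none"
    ratio = d_cost / d_eff if d_eff != 0 else None
    return CEAResult(
        cost_a=a.cost,
        cost_b=b.cost,
        eff_a=a.effectiveness,
        eff_b=b.effectiveness,
        delta_cost=d_cost,
        delta_eff=d_eff,
        icer=ratio,
        dominance=dom,
    )


@dataclass(frozen=True)
class DsaEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: Optional[float]
    icer_high: Optional[float]

    @property
    def width(self) -> float:
        vals = [v for v in (self.icer_low, self.icer_high) if v is not None]
        return max(vals) - min(vals) if len(vals) == 2 else float("inf")


@dataclass(frozen=True)
class DsaResult:
    base_icer: Optional[float]
    entries: list[DsaEntry]  # tornado order: widest range first
    icer_min: float
    icer_max: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "low_value": e.low_value,
                    "high_value": e.high_value,
                    "icer_low": e.icer_low,
                    "icer_high": e.icer_high,
                    "range_width": e.width,
                }
                for e in self.entries
            ]
        )


def one_way_dsa(
    base_params: Mapping[str, float],
    model: Callable[[Mapping[str, float]], CEAResult],
    fraction: float = 0.20,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> DsaResult:
    """One-way variation of each parameter to (1 - f) and (1 + f) times base.

    ``bounds`` clamps varied values (e.g. probabilities to [0, 1]); a clamp
    emits a warning. Entries are ordered by ICER range width (tornado).
    """
    if fraction < 0:
        raise CeaError("fraction must be >= 0")
    bounds = bounds or {}
    base = model(base_params)
    entries = []
    for name, value in base_params.items():
        lo_v, hi_v = value * (1.0 - fraction), value * (1.0 + fraction)
        if name in bounds:
            b_lo, b_hi = bounds[name]
            for tag, v in (("low", lo_v), ("high", hi_v)):
                if v < b_lo or v > b_hi:
                    warnings.warn(
                        f"DSA {tag} value for {name} clamped to [{b_lo}, {b_hi}]",
                        stacklevel=2,
                    )
            lo_v = min(max(lo_v, b_lo), b_hi)
            hi_v = min(max(hi_v, b_lo), b_hi)
        res_lo = model({**base_params, name: lo_v})
        res_hi = model({**base_params, name: hi_v})
        entries.append(
            DsaEntry(
                parameter=name,
                low_value=lo_v,
                high_value=hi_v,
                icer_low=res_lo.icer,
                icer_high=res_hi.icer,
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    all_icers = [base.icer] + [e.icer_low for e in entries] + [e.icer_high for e in entries]
    finite = [v for v in all_icers if v is not None]
    return DsaResult(
        base_icer=base.icer,
        entries=entries,
        icer_min=min(finite),
        icer_max=max(finite),
    )


@dataclass(frozen=True)
class Distribution:
    """A sampling distribution for one PSA parameter.

    kind: 'fixed', 'gamma', 'beta', or 'normal'; gamma/beta are
    parametrized by method of moments from (mean, sd). Zero sd degrades to
    'fixed'. Draws are multiplied by ``scale`` (e.g. a beta on the
    probability scale feeding a percent-scale parameter uses scale=100).
    """

    kind: str
    mean: float
    sd: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "gamma", "beta", "normal"):
            raise CeaError(f"unknown distribution kind {self.kind!r}")
        if self.sd < 0:
            raise CeaError("sd must be >= 0")
        if self.kind == "beta" and not (0.0 <= self.mean <= 1.0):
            raise CeaError("beta mean must be in [0, 1]")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed" or self.sd == 0.0:
            return np.full(size, self.mean * self.scale)
        if self.kind == "normal":
            x = rng.normal(self.mean, self.sd, size)
        elif self.kind == "gamma":
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            x = rng.gamma(shape, scale, size)
        else:
            # beta, method of moments; sd capped below the Bernoulli bound
            m = self.mean
            v = min(self.sd**2, m * (1 - m) * 0.999)
            nu = m * (1 - m) / v - 1.0
            x = rng.beta(m * nu, (1 - m) * nu, size)
        return x * self.scale


#: Half-width of the +/-20% anchor interpreted as a 95% interval.
_DISPERSION_Z = 1.959963984540054


def default_psa_distributions(
    base_params: Mapping[str, float],
    kinds: Mapping[str, str],
    rel_halfwidth: float = 0.20,
) -> dict[str, Distribution]:
    """Gamma for costs, beta for probabilities/fractions, with sd chosen so
    that mean +/- ``rel_halfwidth``*mean is the central 95% interval under a
    normal approximation."""
    out: dict[str, Distribution] = {}
    for name, value in base_params.items():
        kind = kinds.get(name, "gamma")
        sd = abs(value) * rel_halfwidth / _DISPERSION_Z
        if value == 0.0:
            out[name] = Distribution("fixed", 0.0)
        else:
            out[name] = Distribution(kind, value, sd)
    return out


@dataclass(frozen=True)
class PsaSample:
    draw_id: int
    params: dict[str, float]
    cost_a: float
    eff_a: float
    cost_b: float
    eff_b: float


def run_psa(
    model: Callable[[Mapping[str, float]], tuple[StrategyResult, StrategyResult]],
    base_params: Mapping[str, float],
    distributions: Mapping[str, Distribution],
    n_draws: int = 1000,
    seed: int = 0,
) -> list[PsaSample]:
    """Seeded second-order Monte Carlo: each draw samples every parameter
    from its distribution and re-runs the full cost/effect pipeline."""
    if n_draws < 1:
        raise CeaError("n_draws must be >= 1")
    unknown = set(distributions) - set(base_params)
    if unknown:
        raise CeaError(f"distributions for unknown parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    draws = {
        name: (
            distributions[name].sample(rng, n_draws)
            if name in distributions
            else np.full(n_draws, base_params[name])
        )
        for name in base_params
    }
    samples = []
    for i in range(n_draws):
        params = {name: float(draws[name][i]) for name in base_params}
        res_a, res_b = model(params)
        samples.append(
            PsaSample(
                draw_id=i,
                params=params,
                cost_a=res_a.cost,
                eff_a=res_a.effectiveness,
                cost_b=res_b.cost,
                eff_b=res_b.effectiveness,
            )
        )
    return samples


_MEASURES = ("mean", "sd", "median", "p2.5", "p10", "p90", "p97.5")


def _column_summary(x: np.ndarray) -> dict[str, float]:
    q = np.percentile(x, [2.5, 10, 50, 90, 97.5])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "median": float(q[2]),
        "p2.5": float(q[0]),
        "p10": float(q[1]),
        "p90": float(q[3]),
        "p97.5": float(q[4]),
    }


@dataclass(frozen=True)
class PsaSummary:
    """Per-strategy cost and effectiveness summaries of the PSA draws."""

    table: pd.DataFrame  # index (attribute, measure), columns strategy names

    def value(self, attribute: str, measure: str, strategy: str) -> float:
        return float(self.table.loc[(attribute, measure), strategy])


def summarize_psa(
    samples: Sequence[PsaSample], names: tuple[str, str] = ("a", "b")
) -> PsaSummary:
    if not samples:
        raise CeaError("no PSA samples to summarize")
    cols = {
        (names[0], "cost"): np.array([s.cost_a for s in samples]),
        (names[0], "effectiveness"): np.array([s.eff_a for s in samples]),
        (names[1], "cost"): np.array([s.cost_b for s in samples]),
        (names[1], "effectiveness"): np.array([s.eff_b for s in samples]),
    }
    rows = {}
    for (strategy, attribute), x in cols.items():
        for measure, v in _column_summary(x).items():
            rows.setdefault((attribute, measure), {})[strategy] = v
    idx = pd.MultiIndex.from_product(
        [("cost", "effectiveness"), _MEASURES], names=["attribute", "measure"]
    )
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(idx)
    table.index = idx
    return PsaSummary(table=table)


@dataclass(frozen=True)
class CeacCurve:
    """Acceptability: P(strategy is cost-effective) over a WTP grid."""

    wtp: np.ndarray
    prob_a: np.ndarray  # comparator
    prob_b: np.ndarray  # intervention

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "prob_a": self.prob_a, "prob_b": self.prob_b})


#: Default grid spans the region where the acceptability curves cross.
DEFAULT_WTP_GRID = np.arange(0.0, 2_000_000.0 + 1, 10_000.0)


def ceac(
    samples: Sequence[PsaSample], wtp_grid: Optional[np.ndarray] = None
) -> CeacCurve:
    """At each willingness-to-pay λ, the fraction of draws in which the
    intervention's incremental net benefit λ·delta_eff - delta_cost is
    positive; the comparator takes the complement."""
    if not samples:
        raise CeaError("no PSA samples")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise CeaError("empty WTP grid")
    d_cost = np.array([s.cost_b - s.cost_a for s in samples])
    d_eff = np.array([s.eff_b - s.eff_a for s in samples])
    inb = grid[:, None] * d_eff[None, :] - d_cost[None, :]
    prob_b = (inb > 0).mean(axis=1)
    return CeacCurve(wtp=grid, prob_a=1.0 - prob_b, prob_b=prob_b)
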