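# Methods

## Decision problem

Two strategies for secondary cardiovascular prevention in statin-treated
patients with recent acute coronary syndrome and LDL-c ≥ 70 mg/dL are
compared over a 10-year horizon from a societal perspective in 2017
Brazilian reais: high-intensity atorvastatin (80 mg/day) alone versus
atorvastatin plus evolocumab 140 mg every 15 days. The outcome unit is one
composite cardiovascular event avoided (myocardial infarction, ischemic
stroke, myocardial revascularization, or cardiovascular death); no QALY
weighting is applied.

## Synthetic cohort

The generator emulates the marginal structure of a 61-patient outpatient
coronary-disease sample: age 63 ± 11 (bounded to the 40–85 eligibility
window), 52% male, 83% hypertension, 42% diabetes, 31% smoking, 54% prior
MI, 10% ezetimibe, LDL-c 111 ± 34 mg/dL with a 70 mg/dL floor, HDL-c
45 ± 13, triglycerides 159 ± 97. Every patient carries `recent_acs=True`
(an inclusion criterion, not a sampled trait); chronic kidney disease,
peripheral artery disease and familial hypercholesterolemia default to
prevalence 0 but are configurable.

Continuous variables are drawn from truncated normals whose *underlying*
location/scale are moment-fitted (root-finding on the truncated moments)
so that the realized distribution has the stated mean and SD. A naive
truncation of N(111, 34) at 70 would inflate the sample mean to ≈118;
moment fitting keeps it at 111 and implies P(LDL ≥ 100) ≈ 0.53, close to
the reported 57%. A floor-truncated normal cannot achieve sd ≥ mean −
floor (the exponential tail bound); infeasible requests raise a named
validation error. Comorbidity flags are sampled independently because only
marginals are reported; a correlation hook is reserved on `CohortSpec`.

What passing tests show about real data is therefore limited: marginal
frequencies and lipid moments are faithful, but joint comorbidity
structure, within-patient correlation between lipids and risk factors, and
any secular trends are not modelled.

## Baseline and treated risk

Each patient is assigned the eligible published 10-year risk band with the
highest midpoint; ties break by table order. The parent "clinical
atherosclerotic disease + diabetes" band is represented by its with-CKD
(28–43) and without-CKD (26–29) sub-bands, since the aggregate row would
otherwise shadow the without-CKD band under highest-midpoint selection.
"Poorly controlled risk factors" is operationalized as active smoking, the
one unambiguously uncontrolled modifiable factor available in the patient
record. The cohort baseline risk is the mean of per-patient midpoints; in
replication mode the published 35% is used directly.

The treatment effect is translated from lipids: a 59% additional LDL-c
reduction on statin background, and a 21% relative risk reduction per
39 mg/dL of LDL-c lowering. The default scaling is linear in the LDL-c
decrement with the RRR rounded to the nearest whole percent before use —
this is the arithmetic that makes the published chain exact (0.21 ·
65.5/39 = 0.3527 → 35%; 35% · 0.65 = 22.75%). A compounding scaling,
1 − 0.79^(d/39), and an unrounded mode are provided for sensitivity
exploration; linear RRR is capped at 1. The roughly 26-month trial effect
is assumed constant over the 10-year horizon.

## Markov engine

Five states: event-free, post-MI, post-stroke, post-revascularization,
cardiovascular death (absorbing). Cycle length is 1 year, 10 cycles — the
simplest structure consistent with an annually-reported 10-year risk. The
per-cycle event probability is the constant-hazard conversion
p = 1 − (1 − R)^(1/10), so event-free occupancy at the horizon equals the
10-year survival exactly. Events are split across the four components by
the composite mix; survivors of an event carry the same hazard thereafter
(recurrence on by default; post-event states can be frozen). Background
non-cardiovascular mortality is not modelled.

Costing: per-cycle drug cost accrues on alive occupancy at cycle start
(patients dying within a cycle are dosed for that cycle); each event
incidence — including same-type recurrences, which do not change state —
is charged its component cost, with the human-capital death payoff charged
on entry to cardiovascular death. Costs are discounted at 5%/year with
end-of-cycle timing ((1+r)^−t); a half-cycle correction (exponent
t − 1/2) is available but off by default.

Effectiveness defaults to the probability of remaining event-free over the
horizon (undiscounted); discounted event-free life-years are available as
an alternative. Neither definition reproduces the externally computed
global effectiveness values 0.54/0.73, whose payoff bookkeeping is not
derivable from the printed inputs; those values, and the matching global
costs 46,522.44/236,141.85, are therefore accepted as *replication
overrides* — explicit inputs, clearly separated from model-derived
results — wherever downstream quantities (the published incremental cost
of 189,619.41, and the published ICER of 1,011,188.07, which implies an
unrounded effectiveness increment of ≈0.1875 rather than 0.19) are
reported.

## Costs

All values constant 2017 BRL, no inflation indexing. Hospitalization
reimbursements: MI 588.12, ischemic stroke 463.21, revascularization
6,756.37. Atorvastatin 1.00 per 40 mg tablet (2 tablets/day); evolocumab
901.61 per 140 mg syringe at 24 doses/year — the calendar reading of
"every 15 days", which reproduces the published 10-year combined total of
223,686.40 exactly; a strict-interval mode (365/15 doses/year) is
available. Premature cardiovascular death is valued by the human-capital
approach: life expectancy 75 y 8 m minus mean age at death 68 (death
assumed at year 5 of the horizon for a cohort aged 63) = 7.667 years,
rounded half-up to 7.7 before multiplication by the unemployment-adjusted
annual income of 22,128.00, giving 170,385.60. The event-mix weights
default to placebo-arm first-event counts of the evolocumab outcomes
trial (MI 639, stroke 262, revascularization 965, CV death 240); weights
are validated to the simplex within 2×10⁻³ (rounding of published
proportions) and can be renormalized exactly.

## Sensitivity analysis

*Deterministic:* each scalar parameter (baseline risk, RRR, the three
hospitalization costs, both drug prices, income, discount rate) is set to
0.8× and 1.2× its base value one at a time; probabilities are clamped to
their support with a warning. Per-parameter ICER ranges are reported in
tornado order; the overall range always brackets the base ICER.

*Probabilistic:* 1000 seeded draws by default; gamma distributions for
costs and incomes, beta for the baseline risk (on the probability scale)
and the RRR, parametrized by method of moments with SD = 0.2·mean/1.96 —
i.e. the ±20% deterministic band read as a central 95% interval. The
source analysis does not state its PSA distributions; these defaults are
standard practice and fully overridable in the config, and the published
Monte Carlo summary table is used only as a dispersion calibration
reference in testing, not as a fit target. Each draw re-runs the full
cohort model (second-order uncertainty); patient-level (first-order)
noise is out of scope. Summaries report mean, SD, median and percentiles
2.5/10/90/97.5 per strategy using linear interpolation between closest
ranks. The acceptability curve evaluates, on a WTP grid of 0–2,000,000
BRL in 10,000-BRL steps, the fraction of draws with positive incremental
net benefit λ·ΔE − ΔC; when ΔE > 0 in every draw the curve is monotone
and crosses 0.5 at the draws' median ICER.

## Numerical choices

- Transition-matrix rows validated to sum to 1 within 1e-12; occupancy
  rows within 1e-9 during propagation.
- Half-up rounding for the published monetary/YLL roundings (`floor(x·10^k
  + 0.5)/10^k`), avoiding banker's rounding surprises.
- Percentile convention pinned to linear interpolation (numpy default).
- Cohort CSV round-trips exactly: floats written at 17 significant digits
  and parsed with the `round_trip` parser.
- Monetary config values accepted as decimal strings and parsed via
  `Decimal`.
- Seeds: every stochastic component (cohort generation, PSA) takes an
  explicit integer seed; identical inputs give byte-identical outputs.

## Problem sizes

The default test and analysis sizes are the study's own: a 61-patient
cohort, 10 annual cycles, 1000 PSA draws. Marginal-convergence checks use
100,000 generated patients (vectorized, sub-second); the brute-force
path-enumeration oracle validates traces up to 3 cycles, where exhaustive
enumeration is exact and cheap.

## Known limitations

- The global cost/effectiveness pairs and the published ICER, DSA range
  and PSA table are not derivable from printed inputs (see above); the
  package reproduces their *arithmetic relationships* and reports its own
  model-based counterparts alongside the replication overrides.
- Constant relative treatment effect over 10 years; no treatment
  discontinuation, adverse events, or waning.
- No background mortality; composite components compete only through the
  event split.
- Independence of comorbidity flags; category assignment depends on the
  flags actually generated, so cohort-derived baseline risk (≈34–36%)
  varies by seed around the published 35%.
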