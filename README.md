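# evocea

Cost-effectiveness of adding evolocumab, a PCSK9-inhibitor monoclonal
antibody, to high-intensity atorvastatin for secondary cardiovascular
prevention in the Brazilian public health system (SUS), implemented as a
tested, configurable Markov cohort decision model.

The package is aimed at health-economics analysts and methodologists: it
reproduces the published deterministic arithmetic of the analysis exactly
(drug costing, human-capital death cost, LDL-to-risk translation,
incremental cost) and makes every modelling choice — cycle structure,
discounting, effectiveness definition, sensitivity distributions —
explicit and overridable.

## The model

- **Cohort.** A seeded synthetic sample of 61 statin-treated patients with
  recent acute coronary syndrome, matching the source marginals (age
  63 ± 11, 52% male, 83% hypertension, 42% diabetes, 31% smoking, 54%
  prior MI, LDL-c 111 ± 34 mg/dL with a 70 mg/dL floor). Continuous
  variables use moment-fitted truncated normals, so the *realized* mean/SD
  match the targets despite truncation.
- **Baseline risk.** Each patient is assigned the highest-midpoint 10-year
  risk band they qualify for (published bands for statin-treated high-risk
  categories); the cohort risk is the mean midpoint. The published point
  estimate is R = 35%.
- **Treatment effect.** Evolocumab lowers LDL-c a further 59%
  (111 → 45.5 mg/dL); each 39 mg/dL of LDL-c lowering is credited with a
  21% relative risk reduction, scaled linearly and rounded to the nearest
  percent: RRR = round(0.21 · 65.5/39) = 35%, so the treated risk is
  35% · 0.65 = 22.75% (ARR 12.25 points).
- **Markov engine.** States {event-free, MI, stroke, revascularization, CV
  death}; annual cycles over 10 years; per-cycle event probability
  p = 1 − (1 − R)^(1/10); event mix from placebo-arm proportions; costs
  (drugs per cycle, hospitalization per event, human-capital cost of
  premature death: 7.7 years of life lost × R$ 22,128/year =
  R$ 170,385.60) discounted at 5%/year.
- **Decision statistics.** ICER = ΔC/ΔE per composite outcome avoided;
  one-way ±20% deterministic sensitivity (tornado); 1000-draw
  probabilistic sensitivity (gamma costs, beta probabilities) with a
  Table-style summary and a cost-effectiveness acceptability curve.

## Worked example

```python
from evocea.config import paper_replication_config
from evocea.cli import _base_case

report = _base_case(paper_replication_config())
print(report.drug_cost_a, report.drug_cost_b)   # 7300.0 223686.4
print(report.rrr, report.treated_risk_10y)      # 0.35 22.75
print(report.death_cost)                        # 170385.6
print(round(report.headline_cea.delta_cost, 2)) # 189619.41
print(round(report.model_cea.icer, 2))          # 1325040.83
```

The first four lines are the published deterministic quantities: 10-year
drug costs per patient (R$ 7,300 atorvastatin alone; R$ 223,686.40 with
twice-monthly evolocumab), the 35% relative risk reduction and the 22.75%
treated 10-year risk, and the R$ 170,385.60 indirect cost of a premature
cardiovascular death. `headline_cea.delta_cost` is the incremental cost of
the combined strategy computed from the published global per-patient
costs, used here as replication inputs. `model_cea.icer` is this package's
own Markov-model ICER (R$ 1.33M per composite outcome avoided under the
default effectiveness definition) — the same order as the published ratio,
and on the same side of any plausible willingness-to-pay threshold: the
add-on therapy is not cost-effective at current prices.

Command-line equivalents:

```bash
evocea replicate-paper --out out/          # self-checking replication run
evocea base-case --out out/                # JSON + CSV reports
evocea dsa --out out/dsa.csv               # ±20% tornado table
evocea psa --seed 7 --out out/             # 1000-draw Monte Carlo
evocea ceac --out out/ceac.csv             # acceptability curve
```

## Layout

- `src/evocea/cohort.py` — synthetic cohort generator and summaries
- `src/evocea/risk.py` — risk bands, category assignment, LDL translation
- `src/evocea/costs.py` — drug, hospitalization and death costing
- `src/evocea/markov.py` — cohort trace engine with discounting
- `src/evocea/cea.py` — ICER, DSA, PSA, CEAC
- `src/evocea/pipeline.py`, `config.py`, `cli.py` — assembly, YAML config
  schema, command line
- `docs/methods.md` — modelling assumptions, parameter defaults, and
  known limitations
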