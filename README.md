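# diadem

**Discrete-event microsimulation of linked diabetes and depression care
pathways, with cost-effectiveness analysis of screening and
collaborative-care policies.**

Around one in ten adults with type-2 diabetes has comorbid depression.
The two conditions interact: diabetes-related complications raise the
hazard of developing depression, and time spent depressed raises the
hazard of developing further complications.  `diadem` is a patient-level
discrete-event simulation of this linked system for adults with type-2
diabetes managed in English primary care.  It is aimed at health
economists and modellers who want to evaluate changes to the depression
care pathway — who gets screened, how depression is treated — in terms of
lifetime costs (NHS and personal social services perspective), QALYs, and
incremental cost-effectiveness ratios (ICERs).

## The model

Two inter-linked sub-models run on each simulated patient's continuous
timeline:

- **Depression natural history.**  Onset (5.4%/year each for minor and
  major depression among the never-depressed), minor→major progression
  (exponential rate fitted to 42% progressed at 2 years), spontaneous
  recovery (mean 0.354 y minor, 0.877 y major), and relapse (mean 1.359 y
  for anyone with a history).  All waiting times are exponential.
- **Diabetes complications and mortality.**  A pluggable risk engine draws
  annual complication events (microvascular: IHD, blindness, renal
  failure; macrovascular: heart failure, MI, stroke, diabetic ulcer,
  amputation) and death.  The default engine is a documented surrogate
  (constant per-complication hazards, Gompertz mortality); externally
  published coefficient sets can be loaded from file.

The **bi-directional linkage** works through hazard ratios.  Depressed
time in the preceding year multiplies complication hazards via

> m = 1 + f_minor·(HR_minor − 1) + f_major·(HR_major − 1)

with HR 1.31/1.36 (minor/major) for microvascular and 1.00/1.25 for
macrovascular events, so half a year of depression yields half the
elevation; time on treatment for an ultimately-responding patient does not
count.  Conversely, any complication history multiplies the depression
onset/relapse hazard by 1.5.

**Identification and treatment.**  GP appointments arrive as a Poisson
process (12.5/year, falling to 8/year while depressed); an annual diabetes
review is attended with probability 0.904 (× 0.9 minor, × 0.65 major).
Unidentified patients may be screened with the two-item Whooley questions
(sensitivity 95%, specificity 66%) followed by a perfect structured
interview; under current practice a GP appointment includes a screen with
probability 0.05 (0.20 with a depression history) and the review with
probability 0.859.  Identified episodes trigger one treatment course;
responders remit at course end if that beats spontaneous recovery, and
have their −0.3 major-depression utility decrement halved while treated.

**Policies.**  Four care pathways are compared under common random
numbers: current practice (CP); collaborative care (P1: response
probability × 1.79, dropout ÷ 1.33, per-course add-on cost); improved
opportunistic screening (P2: every contact of an unidentified patient is
screened, £2/screen); and both combined (P3).  Costs and utility accrue to
a per-patient ledger, are discounted at 3.5%/year, scaled to a reporting
cohort of 2,000,000 adults, and summarised as an incremental analysis with
strict and extended dominance.

## Worked example

```python
from diadem import (ModelConfig, all_policies, generate_cohort,
                    run_comparison, incremental_icer)

cfg = ModelConfig()                 # all published parameter values preloaded
cfg.cohort.n_patients = 2_000
cfg.cohort.seed = 1
cohort = generate_cohort(cfg.cohort)
results = run_comparison(cohort, all_policies(), cfg, seed=1)

for pid, r in results.items():
    print(f"{pid:24s} QALYs={r.qalys/1e6:6.3f}M  cost=£{r.total_cost/1e9:5.2f}bn  "
          f"identified={100*r.episodes_identified/r.episodes_total:4.1f}%")

analysis = incremental_icer(results)
for s in analysis.strategies:
    tag = "dominated" if s.dominated or s.extended_dominated else (
        f"ICER £{s.icer:,.0f}/QALY vs {s.comparator}" if s.icer else "reference")
    print(f"{s.policy_id:24s} {tag}")
```

prints (2,000 patients, seed 1):

```
current_practice         QALYs=17.813M  cost=£60.50bn  identified=54.1%
collaborative_care       QALYs=18.078M  cost=£62.27bn  identified=54.0%
opportunistic_screening  QALYs=17.901M  cost=£73.99bn  identified=81.2%
combined                 QALYs=18.269M  cost=£77.60bn  identified=81.0%
current_practice         reference
collaborative_care       ICER £6,662/QALY vs current_practice
opportunistic_screening  dominated
combined                 ICER £80,360/QALY vs collaborative_care
```

Totals are scaled to the 2,000,000-adult reporting cohort.  Collaborative
care buys QALYs cheaply (better depression treatment also avoids
complications); screening alone identifies far more episodes (54% → 81%)
but at a cost that makes it dominated; adding screening on top of
collaborative care carries a much higher ICER.  Absolute £/QALY levels
depend on the surrogate risk engine and the placeholder treatment-effect
inputs (see `docs/methods.md`), so the incremental *structure* is the
meaningful output here, not the billions.

The same analysis is available from the shell:

```bash
diadem simulate --n 2000 --seed 1 --policies all --out runs/base
diadem icer --results runs/base
diadem sweep --seed 1 --n 2000 --out runs/sweep.csv     # one-way sensitivity
```

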