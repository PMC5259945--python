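# Methods

This note documents the model implemented by `diadem`: its structure and
assumptions, the parameters that matter, what the synthetic cohort does
and does not emulate, the numerical choices, and known limitations.

## Model structure

Each patient is simulated on a continuous timeline by a discrete-event
scheduler until death or age 105.  Two sub-models interact:

1. **Depression natural history** — a continuous-time state machine over
   {depression-free, minor episode, major episode} with onset,
   minor→major progression, spontaneous recovery and relapse.
2. **Diabetes complications and mortality** — annual-cycle event draws
   embedded at the patient's entry anniversaries: one independent draw per
   complication type per year, plus a death draw; event times are uniform
   within the year.

The linkage is bi-directional.  Complication hazards for the coming year
are multiplied by `1 + f_minor·(HR_minor−1) + f_major·(HR_major−1)`, where
`f_minor`/`f_major` are the fractions of the *preceding* year spent in each
depression state, excluding time on treatment for patients who ultimately
respond.  The multiplier is applied on the hazard scale
(`p' = 1 − (1−p)^m`).  In the other direction, any complication history
multiplies the depression onset/relapse hazard by a single ratio
(default 1.5), identical whether one or several complications are present;
when the first complication occurs mid-wait the pending onset time is
re-drawn at the elevated rate, which is exact for exponential clocks.

## Waiting-time distributions

Every "time to X" input is modelled as exponential with the stated mean,
and annual probabilities are converted to rates by `r = −ln(1−p)`.  The
exponential is the natural reading of annual-probability inputs and makes
the state machine memoryless, so rate changes (depression state switching
the GP contact rate, complications elevating onset) are handled exactly by
re-drawing the remaining wait.  The minor→major progression rate is fitted
to a fraction-by-horizon input: `r = −ln(1−0.42)/2 ≈ 0.2724/yr`.  Within a
minor episode, progression and recovery run as competing exponential
risks, so the probability that progression wins is
`r_prog/(r_prog + r_rec) ≈ 0.088`.

One consequence worth knowing: with minor and major onset running as two
competing 5.4%/year processes, the observable probability that a
depression-free patient-year *ends in a major onset* is slightly below the
per-process input (≈ 5.25%), because a minor onset occasionally arrives
first.

## Parameters

Defaults live in `diadem.config`; every value is overridable through the
config file or dotted-path overrides (the sensitivity harness uses the
same mechanism).  The key groups:

| Group | Values (defaults) |
|---|---|
| Onset/relapse | 5.4%/yr minor and major; relapse mean 1.359 y; relapse severity re-drawn 50/50 |
| Episode resolution | recovery means 0.354 y (minor), 0.877 y (major); 42% progression at 2 y |
| Contacts | GP 12.5/yr (8/yr while depressed); review attendance 0.904 (× 0.9 / × 0.65); review screen 0.859 |
| Screening | screen/contact 0.05 (0.20 with history); Whooley 95%/66%; interview 100%/100% |
| Treatment | response 0.5, dropout 0.3, duration 0.25 y (placeholders, see below); collaborative care RR 1.79 response, ÷ 1.33 dropout, £240/course add-on |
| Linkage | micro HR 1.31/1.36, macro 1.00/1.25 (minor/major); complication→depression HR 1.5 |
| Economics | utility 0.807 baseline, −0.3 major depression (× 0.5 for treated responders), complication decrements as sourced; 2013 GBP unit costs; 3.5%/yr discount |

**Placeholder inputs.**  Base treatment response/dropout probabilities and
course durations, the structured-interview unit cost (£150), the
collaborative-care add-on (£240/course), baseline depression prevalence
(8% major, 8% minor, 25% prior history) and the societal day-rates are not
published inputs; they are this package's documented defaults, chosen to
be clinically plausible, and are the first candidates for sensitivity
analysis.  Treatment modality is mapped from severity: minor → 6
low-intensity psychotherapy sessions (£88 each); major → 12 high-intensity
sessions plus 91 days of antidepressants (£0.073/day).

**Surrogate risk engine.**  The published diabetes outcome equations used
by models of this class are not redistributable, so the default engine is
a surrogate: constant annual complication hazards (e.g. MI 1.35%/yr, renal
failure 0.25%/yr) chosen to give a cohort entering around age 65 roughly
0.2 microvascular and 0.6 macrovascular events per person over a lifetime,
and Gompertz mortality `h(age) = a·e^{b·age}` (a = 5.96·10⁻⁵, b = 0.085,
≈ 1.5%/yr at 65, doubling every ~8 years) with additive log-hazard
contributions per complication in history (renal failure largest at 1.1).
MI, stroke and ulcer may recur; the other types occur at most once.
Risk-factor trajectories are constant over time.  Users holding published
coefficient sets can supply them as a JSON file
(`complications.hazard_model: linear`), keyed by complication with
`intercept`, `age`, per-risk-factor and `hist_<type>` terms under a
cloglog link.

## Synthetic cohort

`generate_cohort` draws baseline profiles from independent parametric
distributions: truncated-normal age (65 ± 11, 18–100), diabetes duration
(8 ± 6 y, ≥ 0), HbA1c, systolic blood pressure, BMI, and a Bernoulli
smoking flag; depression state is a three-way draw from the configured
prevalences, and anyone currently depressed carries a history flag.  It
deliberately does **not** model correlation between risk factors, secular
trends, baseline complication history, or informative missingness — so
passing tests demonstrate the mechanics of the care-pathway model, not
calibration to any real diabetes population.  Correlated baselines can be
injected by building `PatientProfile` objects directly or loading a cohort
CSV.

## Discrete-event mechanics and numerical choices

- **Common random numbers.**  Each (patient, process) pair owns an
  independent counter-based stream; screen-offer decisions always consume
  one uniform even at probability 1, and annual cycles consume exactly two
  uniforms per at-risk complication type, so policies that only shift
  probabilities replay identical draws everywhere else.  With all linkage
  hazard ratios set to 1, complication counts are bit-identical across the
  four policies — an asserted decoupling property.
- **Tie-breaking.**  Simultaneous events are dispatched in a fixed
  priority order (death, anniversary, complication, transition, course
  end, onset, contact); ties other than at anniversaries have probability
  zero in continuous time.
- **Discounting** uses the continuous exponent `(1+r)^−t` (annual-step
  available as a switch); rate-type costs and utility integrate the
  discount factor in closed form over each piecewise-constant segment.
- **Utility composition** is additive with clamping to [−0.594, 1]; the
  MI event-year (−0.065) and prior-history (+0.008) values, and the
  positive blindness decrement (+0.033), are applied exactly as sourced,
  signs included.  A multiplicative composition is available as a switch.
- **Costing**: event-year complication costs post as lumps at the event;
  subsequent-year costs accrue as a continuous rate in later years (paused
  in a year with a recurrence, which posts a fresh event cost); ongoing
  diabetes management (£252/yr) accrues for life.  Category totals are
  conserved exactly against entry-level sums.
- **Degenerate inputs**: zero rates produce infinite waiting times (no
  events) rather than errors; probability 1 screens are allowed; annual
  probabilities must stay below 1.

## Open design decisions taken

- Relapse severity is re-drawn 50/50 rather than inheriting the previous
  episode's severity (the evidence is silent; inheritance makes the
  severity mix absorb into major over a lifetime).
- The annual review is treated as a primary-care appointment, so the
  universal-screening policies screen at attended reviews with
  probability 1.
- The history flag that raises the current-practice screen probability to
  0.20 uses *true* lifetime history, identified or not.
- The dropout relative risk 1.33 is applied as a division of the dropout
  probability; multiplying retention instead is a config switch.
- The £2 screen cost applies to every administered screen in all policy
  arms (with £0/£4 sensitivity variants).
- Dropouts leave at a uniform point in the course with pro-rated resource
  use; completing non-responders pay full cost and receive no benefit.
- Depression has no direct effect on mortality; it acts only through
  complications.
- Severe hypoglycaemia is available as an optional Poisson event process
  (cost £390, decrement −0.00186 per event) with default rate 0.

## Problem sizes

Analysis-scale runs use 10,000-patient cohorts (the reporting scale-up to
2,000,000 adults is a linear multiplier, asserted as such).  Parameter-
recovery checks use 10⁵ draws with 4-standard-error tolerances; the
hazard-ratio recovery uses two 60,000-patient cohorts over 4 years.  The
test suite and the acceptance script each complete in about a minute on a
single core.

## Known limitations

- The identified-episode fraction under universal screening is bounded by
  episode duration: minor episodes (mean ≈ 0.35 y) end before a screen
  reaches them more often than major ones, capping the model's lifetime
  identification percentage near 81% under the default 50/50 severity mix
  even though major episodes alone identify at ≈ 88%.
- Absolute cost and QALY totals inherit the surrogate risk engine and the
  placeholder treatment inputs; incremental comparisons between policies
  are the intended output.
- No probabilistic sensitivity analysis: uncertainty is explored only
  through one-way scenario sweeps (`diadem sweep`).
- Single treatment course per episode; no stepped care, no
  instrument-level detail beyond the two-stage screen, no suicide-specific
  mortality, no HbA1c-mediated causal pathway between depression and
  complication risk.
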