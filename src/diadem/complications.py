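"""Diabetes complications and mortality.

The risk engine is pluggable.  The default surrogate uses constant annual
event hazards per complication type and Gompertz-in-age mortality with
additive log-hazard contributions from complication history; a
coefficient-file loader accepts externally published regression models
(linear predictor on age, risk factors and history, cloglog link).  Risk-
factor trajectories are held constant over time.

Depression raises complication hazards through class-specific hazard
ratios (microvascular: IHD, blindness, renal failure; macrovascular:
heart failure, MI, stroke, diabetic ulcer, amputation), weighted by the
fraction of the preceding year spent in each depression state — half a
year with depression yields half the hazard elevation.  Time spent
depressed while on treatment and ultimately responding does not count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .config import (COMPLICATION_TYPES, ComplicationParams, ConfigError,
                     MICROVASCULAR, RECURRENT_TYPES)


@dataclass
class DepressionExposure:
    """Risk-counting fractions of the preceding year spent depressed."""

    f_minor: float = 0.0
    f_major: float = 0.0

    def __post_init__(self) -> None:
        assert self.f_minor >= -1e-9 and self.f_major >= -1e-9
        assert self.f_minor + self.f_major <= 1.0 + 1e-9


@dataclass
class ComplicationRecord:
    type: str
    t_event: float
    first_occurrence: bool = True


def effective_hazard_multiplier(exposure: DepressionExposure,
                                hr_minor: float, hr_major: float) -> float:
    """Exposure-weighted hazard multiplier for one vascular class.

    Linear in exposure: ``1 + f_minor*(hr_minor-1) + f_major*(hr_major-1)``,
    so a full depressed year reproduces the hazard ratio exactly and half a
    year halves the elevation.
    """
    return (1.0 + exposure.f_minor * (hr_minor - 1.0)
            + exposure.f_major * (hr_major - 1.0))


# ---------------------------------------------------------------------------
# Hazard models
# ---------------------------------------------------------------------------

class SurrogateHazardModel:
    """Constant annual complication hazards + Gompertz mortality."""

    def __init__(self, params: ComplicationParams):
        self.params = params

    def annual_event_prob(self, ctype: str, age: float,
                          risk_factors: dict[str, float],
                          history: set[str]) -> float:
        return self.params.base_annual_prob[ctype]

    def annual_death_prob(self, age: float, risk_factors: dict[str, float],
                          history: set[str]) -> float:
        h = self.params.mortality_gompertz_a * math.exp(
            self.params.mortality_gompertz_b * age)
        h *= math.exp(sum(self.params.mortality_log_hr.get(c, 0.0) for c in history))
        return -math.expm1(-h)


class LinearHazardModel:
    """Externally supplied regression coefficients, cloglog link.

    Per complication (and ``mortality``): annual probability
    ``1 - exp(-exp(lp))`` with
    ``lp = intercept + age_coef*age + sum(rf coefs) + sum(history coefs)``.
    History coefficients are keyed ``hist_<type>``.
    """

    def __init__(self, coefficients: dict[str, dict[str, float]]):
        for ctype in COMPLICATION_TYPES + ("mortality",):
            if ctype not in coefficients:
                raise ConfigError(f"hazard coefficient set missing {ctype!r}")
        self.coefficients = coefficients

    def _lp(self, coefs: dict[str, float], age: float,
            risk_factors: dict[str, float], history: set[str]) -> float:
        lp = coefs.get("intercept", 0.0) + coefs.get("age", 0.0) * age
        for name, value in risk_factors.items():
            lp += coefs.get(name, 0.0) * value
        for c in history:
            lp += coefs.get(f"hist_{c}", 0.0)
        return lp

    def annual_event_prob(self, ctype, age, risk_factors, history) -> float:
        return -math.expm1(-math.exp(
            self._lp(self.coefficients[ctype], age, risk_factors, history)))

    def annual_death_prob(self, age, risk_factors, history) -> float:
        return -math.expm1(-math.exp(
            self._lp(self.coefficients["mortality"], age, risk_factors, history)))


def load_hazard_model(params: ComplicationParams):
    """Instantiate the configured hazard model (surrogate or coefficient file)."""
    if params.hazard_model == "surrogate":
        return SurrogateHazardModel(params)
    if params.hazard_model_file is None:
        raise ConfigError("hazard_model 'linear' requires hazard_model_file")
    with open(params.hazard_model_file) as fh:
        return LinearHazardModel(json.load(fh))


# ---------------------------------------------------------------------------
# Annual-cycle updates
# ---------------------------------------------------------------------------

def adjusted_annual_prob(base_prob: float, multiplier: float) -> float:
    """Apply a hazard multiplier on the hazard scale of an annual probability."""
    if not 0.0 <= base_prob < 1.0:
        raise ConfigError(f"annual event probability must be in [0, 1), got {base_prob!r}")
    return -math.expm1(multiplier * math.log1p(-base_prob))


def annual_complication_update(age: float, risk_factors: dict[str, float],
                               history: set[str], exposure: DepressionExposure,
                               params: ComplicationParams, model,
                               rng: np.random.Generator,
                               year_start: float = 0.0,
                               ) -> list[ComplicationRecord]:
    """Draw this year's complication events for one patient.

    One independent draw per complication type (single-occurrence types are
    skipped once in history); event probabilities are the model's base
    annual probabilities with the class hazard multiplier applied on the
    hazard scale.  Event times are uniform within the year.  Exactly two
    uniforms are consumed per at-risk type regardless of the multiplier, so
    policies sharing random streams share event draws.
    """
    mult_micro = effective_hazard_multiplier(exposure, params.hr_micro_minor,
                                             params.hr_micro_major)
    mult_macro = effective_hazard_multiplier(exposure, params.hr_macro_minor,
                                             params.hr_macro_major)
    events = []
    for ctype in COMPLICATION_TYPES:
        if ctype not in RECURRENT_TYPES and ctype in history:
            continue
        u_event, u_time = rng.random(), rng.random()
        base = model.annual_event_prob(ctype, age, risk_factors, history)
        mult = mult_micro if ctype in MICROVASCULAR else mult_macro
        if u_event < adjusted_annual_prob(base, mult):
            events.append(ComplicationRecord(
                type=ctype, t_event=year_start + u_time,
                first_occurrence=ctype not in history))
    events.sort(key=lambda e: e.t_event)
    return events


def mortality_update(age: float, risk_factors: dict[str, float],
                     history: set[str], params: ComplicationParams, model,
                     rng: np.random.Generator, year_start: float = 0.0,
                     ) -> float | None:
    """Death time within the coming year, or None on survival.

    Consumes exactly two uniforms (event draw + within-year time) so the
    stream stays aligned across policies.
    """
    u_event, u_time = rng.random(), rng.random()
    q = model.annual_death_prob(age, risk_factors, history)
    if u_event < q:
        return year_start + u_time
    return None


# ---------------------------------------------------------------------------
# Cohort-level incidence study (vectorised)
# ---------------------------------------------------------------------------

def simulate_complication_incidence(n_patients: int, n_years: int,
                                    exposure: DepressionExposure,
                                    params: ComplicationParams,
                                    rng: np.random.Generator,
                                    types: tuple[str, ...] | None = None,
                                    ) -> dict[str, dict[str, int]]:
    """Run the annual complication draw on a fresh cohort with a fixed
    depression exposure, returning per-type event and at-risk counts.

    Patients carry no history into the study and accrue it as events
    occur (single-occurrence types leave the risk set).  This is the
    harness used to recover the depression->complication hazard ratios
    empirically.
    """
    types = types or COMPLICATION_TYPES
    model = load_hazard_model(params)
    counts = {t: {"events": 0, "at_risk_years": 0} for t in types}
    for t in types:
        mult = effective_hazard_multiplier(exposure, *params.hr_pair(t))
        base = model.annual_event_prob(t, 65.0, {}, set())
        p = adjusted_annual_prob(base, mult)
        at_risk = n_patients
        for _ in range(n_years):
            events = int(rng.binomial(at_risk, p))
            counts[t]["events"] += events
            counts[t]["at_risk_years"] += at_risk
            if t not in RECURRENT_TYPES:
                at_risk -= events
    return counts


def pooled_hazard(counts: dict[str, dict[str, int]]) -> float:
    """Pooled annual event hazard over complication types, from per-type
    event fractions via the probability->hazard transform."""
    total = 0.0
    for c in counts.values():
        if c["at_risk_years"] == 0:
            continue
        p_hat = c["events"] / c["at_risk_years"]
        total += -math.log1p(-min(p_hat, 1.0 - 1e-12))
    return total
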