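"""Primary-care contact and depression-screening processes.

GP appointments arrive as a Poisson process whose rate follows the current
depression state (patients with depression attend less often).  Once a
year, on the patient's diabetes anniversary, an annual review is offered
and attended with a state-dependent probability.  At either kind of
contact a patient without currently-identified depression may receive a
two-stage screen: the two-item Whooley questionnaire (imperfect) followed,
on a positive result, by a confirmatory structured interview (perfect by
default).  Under the improved-screening policies every contact of an
unidentified patient includes a screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigError, Policy, ScreeningParams


@dataclass
class ScreenEvent:
    """Outcome of one screening opportunity."""

    time: float
    setting: str                      # "gp_appointment" | "annual_review"
    whooley_result: str = "not_done"  # "positive" | "negative" | "not_done"
    interview_result: str = "not_done"  # "confirmed" | "ruled_out" | "not_done"
    cost_incurred: float = 0.0

    @property
    def identified(self) -> bool:
        return self.interview_result == "confirmed"


def visit_rate(params: ScreeningParams, depression_state: str) -> float:
    """GP appointments per year for the current depression state."""
    return {
        "none": params.gp_visits_per_year_none,
        "minor": params.gp_visits_per_year_minor,
        "major": params.gp_visits_per_year_major,
    }[depression_state]


def sample_next_contact(params: ScreeningParams, depression_state: str,
                        rng: np.random.Generator) -> float:
    """Waiting time to the next GP appointment (exponential; inf if the
    visit rate is zero)."""
    rate = visit_rate(params, depression_state)
    if rate <= 0.0:
        return math.inf
    return rng.exponential(1.0 / rate)


def review_attendance_prob(params: ScreeningParams, depression_state: str) -> float:
    """Probability of attending the annual diabetes review this year."""
    rr = {"none": 1.0, "minor": params.review_rr_minor,
          "major": params.review_rr_major}[depression_state]
    return params.p_attend_review * rr


def screen_offer_prob(params: ScreeningParams, setting: str, policy: Policy,
                      history: bool) -> float:
    """Probability that this contact includes a depression screen, for a
    patient without currently-identified depression."""
    if setting == "gp_appointment":
        if policy.universal_screen_enabled:
            return 1.0
        return params.p_screen_history if history else params.p_screen_no_history
    if setting == "annual_review":
        # The annual review is treated as a primary-care appointment, so the
        # universal-screening policies raise its screen inclusion to 1.
        return 1.0 if policy.universal_screen_enabled else params.p_review_includes_screen
    raise ConfigError(f"unknown screening setting {setting!r}")


def apply_screen(true_state: str, setting: str, policy: Policy, history: bool,
                 params: ScreeningParams, rng: np.random.Generator,
                 screen_cost: float = 0.0, interview_cost: float = 0.0,
                 ) -> ScreenEvent:
    """Run one screening opportunity for an unidentified patient.

    Consumes one uniform for the screen-offer decision (always, so policies
    that only change the offer probability share subsequent draws), one for
    the Whooley stage if offered, and one for the interview if positive.
    """
    event = ScreenEvent(time=math.nan, setting=setting)
    p_offer = screen_offer_prob(params, setting, policy, history)
    if rng.random() >= p_offer:
        return event
    event.cost_incurred += screen_cost
    depressed = true_state in ("minor", "major")
    p_positive = params.whooley_sens if depressed else 1.0 - params.whooley_spec
    if rng.random() < p_positive:
        event.whooley_result = "positive"
        event.cost_incurred += interview_cost
        p_confirm = params.interview_sens if depressed else 1.0 - params.interview_spec
        event.interview_result = ("confirmed" if rng.random() < p_confirm
                                  else "ruled_out")
    else:
        event.whooley_result = "negative"
    return event
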