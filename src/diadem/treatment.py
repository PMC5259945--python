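"""Depression treatment pathway.

Each identified episode triggers at most one treatment course.  Severity
selects the modality mix: minor depression receives low-intensity
psychotherapy, major depression pharmacotherapy plus high-intensity
psychotherapy.  Dropout is drawn first; dropouts leave at a uniform point
in the course (resource use pro-rated) and get no benefit.  Completers
respond with the (policy-adjusted) response probability.  Responders remit
at course end if that is earlier than their sampled spontaneous recovery;
while on treatment they also have their major-depression utility
decrement halved and their depressed time excluded from the
complication-risk exposure window.  Collaborative care raises response and
lowers dropout via relative risks and adds a per-course coordination cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CostParams, TreatmentParams


@dataclass
class TreatmentCourse:
    """One course of depression treatment, linked to an episode."""

    severity: str                # severity at course start
    t_start: float
    t_end: float                 # dropout time or scheduled course end
    collaborative_care: bool
    responded: bool = False
    dropped_out: bool = False
    cost: float = 0.0

    def __post_init__(self) -> None:
        assert not (self.responded and self.dropped_out), \
            "response and dropout are mutually exclusive"


def apply_collaborative_care(base_p_response: float, base_p_dropout: float,
                             params: TreatmentParams) -> tuple[float, float]:
    """Collaborative-care-adjusted (response, dropout) probabilities.

    Response is multiplied by ``cc_rr_response`` and capped at 1.  The
    dropout relative risk quantifies a *reduction*: by default dropout is
    divided by ``cc_rr_dropout``; with ``cc_dropout_mode='retention'`` the
    retention probability ``1 - p`` is multiplied instead (capped so the
    result stays a probability).
    """
    p_response = min(1.0, base_p_response * params.cc_rr_response)
    if params.cc_dropout_mode == "divide":
        p_dropout = base_p_dropout / params.cc_rr_dropout
    else:
        p_dropout = max(0.0, 1.0 - (1.0 - base_p_dropout) * params.cc_rr_dropout)
    return p_response, p_dropout


def course_cost(severity: str, collaborative_care: bool,
                params: TreatmentParams, costs: CostParams) -> float:
    """Full-course resource cost for one modality mix, in GBP."""
    if severity == "minor":
        base = params.sessions_minor * costs.therapy_session
    else:
        base = (params.sessions_major * costs.therapy_session
                + params.drug_days_major * costs.drug_daily)
    if collaborative_care:
        base += params.cc_addon_cost
    return base


def plan_course(severity: str, t_start: float, collaborative_care: bool,
                params: TreatmentParams, costs: CostParams,
                rng: np.random.Generator) -> TreatmentCourse:
    """Draw dropout then response and lay out the course timeline.

    Consumes one uniform for dropout, then either one for the dropout time
    (dropouts) or one for response (completers), keeping draw counts
    aligned across policies that only shift the probabilities.
    """
    p_response, p_dropout = params.p_response, params.p_dropout
    if collaborative_care:
        p_response, p_dropout = apply_collaborative_care(p_response, p_dropout, params)
    full_cost = course_cost(severity, collaborative_care, params, costs)
    if rng.random() < p_dropout:
        frac = rng.random()
        return TreatmentCourse(severity, t_start, t_start + frac * params.duration,
                               collaborative_care, dropped_out=True,
                               cost=full_cost * frac)
    responded = rng.random() < p_response
    return TreatmentCourse(severity, t_start, t_start + params.duration,
                           collaborative_care, responded=responded,
                           cost=full_cost)
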