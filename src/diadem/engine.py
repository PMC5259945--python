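"""The discrete-event scheduler.

:func:`simulate_patient` runs one patient's continuous-time timeline under
one policy: depression onsets, within-episode transitions, GP contacts,
annual reviews, screening, treatment milestones, and annual complication/
mortality cycles embedded at the patient's diabetes anniversaries.  Every
stochastic process draws from its own per-(patient, process) stream, so
running the same cohort under different policies shares random numbers for
all processes a policy does not touch (common random numbers).

:func:`run_comparison` runs a cohort under several policies and scales the
aggregate results to a reporting cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cohort import PatientProfile
from .complications import (DepressionExposure, annual_complication_update,
                            load_hazard_model, mortality_update,
                            MICROVASCULAR)
from .config import COMPLICATION_TYPES, ModelConfig, Policy
from .economics import Ledger, PatientTotals, StateSnapshot, accumulate, utility_at
from .natural_history import (DepressionEpisode, Rates,
                              sample_onset_time, sample_progression_or_recovery)
from .rng import PatientStreams
from .screening import (apply_screen, review_attendance_prob,
                        sample_next_contact)
from .treatment import plan_course

_INF = math.inf


@dataclass
class PatientOutcome:
    """Everything one simulated timeline produces."""

    totals: PatientTotals
    episodes: list[DepressionEpisode]
    complication_counts: dict[str, int]
    n_contacts: int
    n_reviews_attended: int
    n_screens: int
    n_interviews: int
    n_courses: int
    died: bool
    t_end: float

    @property
    def episodes_total(self) -> int:
        return len(self.episodes)

    @property
    def episodes_identified(self) -> int:
        return sum(1 for e in self.episodes if e.identified)


def simulate_patient(profile: PatientProfile, policy: Policy, cfg: ModelConfig,
                     seed: int, model=None) -> PatientOutcome:
    """Simulate one patient from baseline to death or the age horizon."""
    if model is None:
        model = load_hazard_model(cfg.complications)
    nh, sp, tp = cfg.natural_history, cfg.screening, cfg.treatment
    costs, up, soc = cfg.costs, cfg.utilities, cfg.societal
    rates = Rates.from_params(nh)
    streams = PatientStreams(seed, profile.id)
    rf = profile.risk_factors

    horizon = max(0.0, cfg.max_age - profile.age)
    t = 0.0
    state = profile.depression_state
    history = profile.depression_history
    episodes: list[DepressionEpisode] = []
    episode: DepressionEpisode | None = None
    if state != "none":
        episode = DepressionEpisode(severity=state, t_start=0.0)
        episodes.append(episode)
    course = None
    comp_history: set[str] = set()
    event_year: set[str] = set()
    hypo_this_year = 0
    complication_counts = {c: 0 for c in COMPLICATION_TYPES}
    n_contacts = n_reviews = n_screens = n_interviews = n_courses = 0

    ledger = Ledger(profile.id)

    # --- piecewise-constant trackers ------------------------------------
    def snapshot() -> StateSnapshot:
        on_tx = episode is not None and episode.on_treatment
        resp = episode is not None and episode.responder
        return StateSnapshot(frozenset(comp_history), frozenset(event_year),
                             hypo_this_year, state, on_tx, resp)

    u_current = utility_at(snapshot(), up)
    u_seg_start = 0.0

    def refresh_utility() -> None:
        nonlocal u_current, u_seg_start
        u_new = utility_at(snapshot(), up)
        if u_new != u_current:
            ledger.add_utility(u_seg_start, t, u_current)
            u_current, u_seg_start = u_new, t

    comp_rate = 0.0
    comp_rate_start = 0.0

    def set_comp_rate(new_rate: float) -> None:
        nonlocal comp_rate, comp_rate_start
        if new_rate != comp_rate:
            ledger.add_rate(comp_rate_start, t, comp_rate, "complication_mgmt")
            comp_rate, comp_rate_start = new_rate, t

    def subsequent_rate() -> float:
        return sum(costs.complication[c][1] for c in comp_history
                   if c not in event_year)

    # exposure accumulators for the current year (risk-counting time)
    exp_minor = exp_major = 0.0
    # baseline state assumed held through the year preceding entry
    if state == "minor":
        exp_minor = 1.0
    elif state == "major":
        exp_major = 1.0

    def advance(t_new: float) -> None:
        """Accrue exposure and societal days over (t, t_new)."""
        nonlocal exp_minor, exp_major, t
        dt = t_new - t
        assert dt >= -1e-12, "event-queue time regression"
        if dt > 0.0:
            counts = not (episode is not None and episode.on_treatment
                          and episode.responder)
            if state == "minor" and counts:
                exp_minor += dt
            elif state == "major" and counts:
                exp_major += dt
            n_comp = len(comp_history)
            sick = {"none": soc.sick_days_none, "minor": soc.sick_days_minor,
                    "major": soc.sick_days_major}[state]
            care = {"none": soc.informal_care_none, "minor": soc.informal_care_minor,
                    "major": soc.informal_care_major}[state]
            ledger.sick_days += dt * (sick + soc.per_complication_sick * n_comp)
            ledger.informal_care_days += dt * (care + soc.per_complication_informal * n_comp)
        t = t_new

    # --- pending events --------------------------------------------------
    t_onset, onset_severity = _INF, "minor"
    if state == "none":
        dt_onset, onset_severity = sample_onset_time(
            rates, history, bool(comp_history), streams.onset, nh.p_relapse_major)
        t_onset = t + dt_onset
    t_transition, transition_kind = _INF, ""
    if episode is not None:
        transition_kind, dt_tr = sample_progression_or_recovery(
            episode, rates, streams.transition)
        t_transition = t + dt_tr
    t_course_end = _INF
    t_contact = t + sample_next_contact(sp, state, streams.contact)
    t_hypo = (t + streams.hypo.exponential(1.0 / cfg.complications.severe_hypo_rate)
              if cfg.complications.severe_hypo_rate > 0.0 else _INF)
    t_anniv = 1.0
    pending_comps: list = []
    comp_idx = 0
    t_death = _INF

    def draw_annual_cycle(year_start: float) -> None:
        nonlocal pending_comps, comp_idx, t_death
        exposure = DepressionExposure(min(1.0, exp_minor), min(1.0, exp_major))
        age_now = profile.age + year_start
        pending_comps = annual_complication_update(
            age_now, rf, comp_history, exposure, cfg.complications, model,
            streams.complication, year_start)
        comp_idx = 0
        death = mortality_update(age_now, rf, comp_history, cfg.complications,
                                 model, streams.mortality, year_start)
        t_death = death if death is not None else _INF
        pending_comps = [e for e in pending_comps if e.t_event < t_death]

    draw_annual_cycle(0.0)
    exp_minor = exp_major = 0.0

    def reschedule_contact() -> None:
        nonlocal t_contact
        t_contact = t + sample_next_contact(sp, state, streams.contact)

    def reschedule_onset() -> None:
        nonlocal t_onset, onset_severity
        dt_onset, onset_severity = sample_onset_time(
            rates, history, bool(comp_history), streams.onset, nh.p_relapse_major)
        t_onset = t + dt_onset

    def start_treatment() -> None:
        nonlocal course, t_course_end, n_courses
        assert episode is not None and episode.identified, \
            "treatment requires an identified open episode"
        course = plan_course(state, t, policy.cc_enabled, tp, costs,
                             streams.treatment)
        episode.on_treatment = True
        episode.responder = course.responded
        ledger.add_cost(t, "treatment", course.cost)
        t_course_end = course.t_end
        n_courses += 1

    def run_screen(setting: str, rng) -> None:
        nonlocal n_screens, n_interviews
        result = apply_screen(state, setting, policy, history, sp, rng)
        if result.whooley_result == "not_done":
            return
        n_screens += 1
        ledger.add_cost(t, "screening", costs.opportunistic_screen)
        if result.interview_result != "not_done":
            n_interviews += 1
            ledger.add_cost(t, "interview", costs.structured_interview)
        if result.identified:
            assert state != "none", "perfect interview cannot confirm a non-case"
            episode.identified = True
            start_treatment()
            refresh_utility()

    def close_episode() -> None:
        """Spontaneous recovery or treatment-end remission."""
        nonlocal episode, state, course, t_course_end, t_transition
        episode.close(t)
        episode = None
        state = "none"
        course = None
        t_course_end = _INF
        t_transition = _INF
        reschedule_onset()
        reschedule_contact()
        refresh_utility()

    # --- main loop --------------------------------------------------------
    died = False
    while True:
        t_next = min(t_onset, t_transition, t_course_end, t_contact, t_anniv,
                     t_hypo, t_death, horizon)
        t_next_comp = pending_comps[comp_idx].t_event if comp_idx < len(pending_comps) else _INF
        t_next = min(t_next, t_next_comp)

        if t_next >= horizon:
            advance(horizon)
            break
        if t_next == t_death:
            advance(t_death)
            died = True
            break

        advance(t_next)

        if t_next == t_anniv:
            # close the completed year: draw the coming year's complications
            # and mortality from the exposure just accrued, then reset the
            # year-scoped state and offer the annual review.
            draw_annual_cycle(t)
            exp_minor = exp_major = 0.0
            event_year.clear()
            hypo_this_year = 0
            set_comp_rate(subsequent_rate())
            refresh_utility()
            t_anniv += 1.0
            if streams.review.random() < review_attendance_prob(sp, state):
                n_reviews += 1
                ledger.add_cost(t, "review", costs.annual_review)
                if not (episode is not None and episode.identified):
                    run_screen("annual_review", streams.screen)
        elif t_next == t_next_comp:
            record = pending_comps[comp_idx]
            comp_idx += 1
            first_ever = not comp_history
            record.first_occurrence = record.type not in comp_history
            comp_history.add(record.type)
            event_year.add(record.type)
            complication_counts[record.type] += 1
            ledger.add_cost(t, "complication_mgmt", costs.complication[record.type][0])
            set_comp_rate(subsequent_rate())
            if first_ever and state == "none" and rates.hr_complication != 1.0:
                reschedule_onset()  # onset hazard steps up; memoryless redraw
            refresh_utility()
        elif t_next == t_transition:
            if transition_kind == "progression":
                episode.severity = "major"
                state = "major"
                transition_kind, dt_tr = sample_progression_or_recovery(
                    episode, rates, streams.transition)
                t_transition = t + dt_tr
                refresh_utility()
            else:
                close_episode()
        elif t_next == t_course_end:
            finished = course
            course = None
            t_course_end = _INF
            if finished.responded and episode is not None:
                close_episode()
            elif episode is not None:
                episode.on_treatment = False
                refresh_utility()
        elif t_next == t_onset:
            state = onset_severity
            history = True
            episode = DepressionEpisode(severity=state, t_start=t)
            episodes.append(episode)
            t_onset = _INF
            transition_kind, dt_tr = sample_progression_or_recovery(
                episode, rates, streams.transition)
            t_transition = t + dt_tr
            reschedule_contact()
            refresh_utility()
        elif t_next == t_contact:
            n_contacts += 1
            ledger.add_cost(t, "gp", costs.gp_appointment)
            if not (episode is not None and episode.identified):
                run_screen("gp_appointment", streams.screen)
            reschedule_contact()
        elif t_next == t_hypo:
            hypo_this_year += 1
            ledger.add_cost(t, "complication_mgmt", costs.severe_hypo)
            t_hypo = t + streams.hypo.exponential(
                1.0 / cfg.complications.severe_hypo_rate)
            refresh_utility()

    # --- close the timeline ----------------------------------------------
    if episode is not None:
        episode.close(t)
    ledger.add_utility(u_seg_start, t, u_current)
    set_comp_rate(0.0)  # flushes the final complication-management segment
    ledger.add_rate(0.0, t, costs.diabetes_annual, "ongoing_mgmt")
    ledger.close(t)
    totals = accumulate(ledger, cfg.discount_rate, cfg.discounting)
    return PatientOutcome(
        totals=totals, episodes=episodes,
        complication_counts=complication_counts,
        n_contacts=n_contacts, n_reviews_attended=n_reviews,
        n_screens=n_screens, n_interviews=n_interviews, n_courses=n_courses,
        died=died, t_end=t,
    )


# ---------------------------------------------------------------------------
# Cohort-level comparison
# ---------------------------------------------------------------------------

@dataclass
class PolicyResult:
    """Aggregate outcomes for one policy, scaled to the reporting cohort."""

    policy_id: str
    n_simulated: int
    scaling_factor: float
    life_years: float = 0.0
    qalys: float = 0.0
    qalys_undiscounted: float = 0.0
    cost_by_category: dict[str, float] = field(default_factory=dict)
    cost_by_category_undiscounted: dict[str, float] = field(default_factory=dict)
    complication_counts: dict[str, int] = field(default_factory=dict)
    episodes_total: float = 0.0
    episodes_identified: float = 0.0
    episodes_unidentified: float = 0.0
    informal_care_days: float = 0.0
    sick_days: float = 0.0
    n_screens: float = 0.0
    n_interviews: float = 0.0
    n_courses: float = 0.0
    deaths: float = 0.0

    @property
    def total_cost(self) -> float:
        return sum(self.cost_by_category.values())

    @property
    def total_cost_undiscounted(self) -> float:
        return sum(self.cost_by_category_undiscounted.values())

    @property
    def microvascular_total(self) -> float:
        return sum(v for k, v in self.complication_counts.items()
                   if k in MICROVASCULAR)

    @property
    def macrovascular_total(self) -> float:
        return sum(v for k, v in self.complication_counts.items()
                   if k not in MICROVASCULAR)

    def to_row(self) -> dict:
        row = {
            "policy": self.policy_id,
            "n_simulated": self.n_simulated,
            "scaling_factor": self.scaling_factor,
            "life_years": self.life_years,
            "qalys": self.qalys,
            "qalys_undiscounted": self.qalys_undiscounted,
            "total_cost": self.total_cost,
            "total_cost_undiscounted": self.total_cost_undiscounted,
            "episodes_total": self.episodes_total,
            "episodes_identified": self.episodes_identified,
            "episodes_unidentified": self.episodes_unidentified,
            "microvascular_total": self.microvascular_total,
            "macrovascular_total": self.macrovascular_total,
            "informal_care_days": self.informal_care_days,
            "sick_days": self.sick_days,
            "deaths": self.deaths,
        }
        row.update({f"cost_{k}": v for k, v in self.cost_by_category.items()})
        row.update({f"cost_undisc_{k}": v
                    for k, v in self.cost_by_category_undiscounted.items()})
        row.update({f"n_{k}": v for k, v in self.complication_counts.items()})
        return row


def run_policy(cohort: list[PatientProfile], policy: Policy, cfg: ModelConfig,
               seed: int, model=None) -> PolicyResult:
    """Simulate every patient in ``cohort`` under ``policy`` and aggregate."""
    if model is None:
        model = load_hazard_model(cfg.complications)
    n = len(cohort)
    scale = cfg.reporting_cohort / n if n else 0.0
    res = PolicyResult(policy.id, n, scale,
                       cost_by_category={},
                       complication_counts={c: 0 for c in COMPLICATION_TYPES})
    cost_d: dict[str, float] = {}
    cost_u: dict[str, float] = {}
    for profile in cohort:
        out = simulate_patient(profile, policy, cfg, seed, model)
        res.life_years += out.totals.life_years
        res.qalys += out.totals.qalys
        res.qalys_undiscounted += out.totals.qalys_undiscounted
        for k, v in out.totals.cost_by_category.items():
            cost_d[k] = cost_d.get(k, 0.0) + v
        for k, v in out.totals.cost_by_category_undiscounted.items():
            cost_u[k] = cost_u.get(k, 0.0) + v
        for k, v in out.complication_counts.items():
            res.complication_counts[k] += v
        res.episodes_total += out.episodes_total
        res.episodes_identified += out.episodes_identified
        res.episodes_unidentified += out.episodes_total - out.episodes_identified
        res.informal_care_days += out.totals.informal_care_days
        res.sick_days += out.totals.sick_days
        res.n_screens += out.n_screens
        res.n_interviews += out.n_interviews
        res.n_courses += out.n_courses
        res.deaths += out.died

    # scale extensive quantities to the reporting cohort
    res.cost_by_category = {k: v * scale for k, v in cost_d.items()}
    res.cost_by_category_undiscounted = {k: v * scale for k, v in cost_u.items()}
    res.complication_counts = {k: v * scale for k, v in res.complication_counts.items()}
    for name in ("life_years", "qalys", "qalys_undiscounted", "episodes_total",
                 "episodes_identified", "episodes_unidentified",
                 "informal_care_days", "sick_days", "n_screens", "n_interviews",
                 "n_courses", "deaths"):
        setattr(res, name, getattr(res, name) * scale)
    return res


def run_comparison(cohort: list[PatientProfile], policies: list[Policy],
                   cfg: ModelConfig, seed: int) -> dict[str, PolicyResult]:
    """Run every policy on the same cohort with common random numbers."""
    if not cohort:
        raise ValueError("cohort must contain at least one patient")
    model = load_hazard_model(cfg.complications)
    return {p.id: run_policy(cohort, p, cfg, seed, model) for p in policies}


def results_to_frame(results: dict[str, PolicyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results.values()])
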