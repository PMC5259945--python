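"""Discrete-event scheduler: degenerate timelines, common-random-numbers
contracts, a hand-traced golden patient, and direction-of-effect checks."""

import math

import pytest

from diadem import ModelConfig, Policy, generate_cohort, run_policy, simulate_patient
from diadem.cohort import PatientProfile
from diadem.rng import PatientStreams

CP = Policy.from_id("CP")
P1 = Policy.from_id("P1")
P2 = Policy.from_id("P2")


def _quiet_config() -> ModelConfig:
    """No depression, no complications, (almost) no mortality."""
    cfg = ModelConfig()
    cfg.natural_history.annual_incidence_minor = 0.0
    cfg.natural_history.annual_incidence_major = 0.0
    cfg.cohort.baseline_prevalence_major = 0.0
    cfg.cohort.baseline_prevalence_minor = 0.0
    cfg.complications.base_annual_prob = {
        k: 0.0 for k in cfg.complications.base_annual_prob}
    cfg.complications.mortality_gompertz_a = 1e-300
    return cfg


def test_all_hazards_zero_gives_contacts_only():
    """With every hazard off, the timeline contains only scheduled contacts
    and reviews until the horizon: no episodes, no complications, no death."""
    cfg = _quiet_config()
    profile = PatientProfile(id=0, age=65.0, sex="female", diabetes_duration=5.0)
    out = simulate_patient(profile, CP, cfg, seed=3)
    assert out.episodes_total == 0
    assert sum(out.complication_counts.values()) == 0
    assert not out.died
    assert out.t_end == pytest.approx(cfg.max_age - 65.0)
    assert out.n_contacts > 0
    # utility constant at baseline for the whole timeline
    assert out.totals.qalys_undiscounted == pytest.approx(0.807 * out.t_end)


def test_common_random_numbers_never_depressed_policies_identical():
    """A patient who never develops depression follows bit-identical
    timelines under current practice and collaborative care."""
    cfg = _quiet_config()
    cfg.complications.base_annual_prob["mi"] = 0.02  # complications back on
    cfg.complications.mortality_gompertz_a = 5.96e-5
    profile = PatientProfile(id=4, age=60.0, sex="male", diabetes_duration=3.0)
    a = simulate_patient(profile, CP, cfg, seed=9)
    b = simulate_patient(profile, P1, cfg, seed=9)
    assert a.t_end == b.t_end
    assert a.totals.cost_by_category == b.totals.cost_by_category
    assert a.totals.qalys == b.totals.qalys
    assert a.complication_counts == b.complication_counts


def test_golden_hand_traced_patient():
    """Hand-traced trajectory: prevalent major depression -> screened at
    the first GP contact -> identified -> treated -> responds -> remits at
    course end, with the utility path 0.507 / 0.657 / 0.807."""
    cfg = _quiet_config()
    cfg.cohort.baseline_prevalence_major = 1.0
    # deterministic screening & treatment outcome
    cfg.screening.p_screen_history = 1.0
    cfg.screening.whooley_sens = 1.0
    cfg.screening.whooley_spec = 1.0  # no false positives after recovery
    cfg.treatment.p_dropout = 0.0
    cfg.treatment.p_response = 1.0
    # push spontaneous recovery and relapse far beyond the horizon
    cfg.natural_history.mean_time_recovery_major = 1e9
    cfg.natural_history.mean_time_relapse = 1e9
    profile = PatientProfile(id=7, age=65.0, sex="female", diabetes_duration=2.0,
                             depression_state="major", depression_history=True)
    out = simulate_patient(profile, CP, cfg, seed=31)

    # replay the contact stream to predict the first appointment time
    replay = PatientStreams(31, 7)
    t1 = replay.contact.exponential(1.0 / 8.0)  # major-depression visit rate

    assert out.episodes_total == 1
    ep = out.episodes[0]
    assert ep.identified and ep.responder
    assert ep.t_end == pytest.approx(t1 + cfg.treatment.duration)
    assert out.n_interviews == 1 and out.n_courses == 1
    T = out.t_end
    expected_qalys = (0.507 * t1 + 0.657 * cfg.treatment.duration
                      + 0.807 * (T - t1 - cfg.treatment.duration))
    assert out.totals.qalys_undiscounted == pytest.approx(expected_qalys)


def test_policy_collapse_when_screen_probabilities_match():
    """Setting every current-practice screen probability to 1 makes current
    practice and the screening policy exactly identical."""
    cfg = ModelConfig()
    cfg.cohort.n_patients = 150
    cfg.cohort.seed = 23
    cfg.screening.p_screen_no_history = 1.0
    cfg.screening.p_screen_history = 1.0
    cfg.screening.p_review_includes_screen = 1.0
    cohort = generate_cohort(cfg.cohort)
    a = run_policy(cohort, CP, cfg, seed=23).to_row()
    b = run_policy(cohort, P2, cfg, seed=23).to_row()
    a.pop("policy"), b.pop("policy")
    assert a == b


def test_determinism_under_fixed_seed():
    cfg = ModelConfig()
    cfg.cohort.n_patients = 60
    cfg.cohort.seed = 29
    cohort = generate_cohort(cfg.cohort)
    a = run_policy(cohort, P2, cfg, seed=29).to_row()
    b = run_policy(cohort, P2, cfg, seed=29).to_row()
    assert a == b


def test_episode_identification_accounting(four_policy_run):
    """identified + unidentified = total episodes, exactly, per policy."""
    _, results = four_policy_run
    for r in results.values():
        assert r.episodes_identified + r.episodes_unidentified == pytest.approx(
            r.episodes_total)


def test_screening_policy_identifies_more_episodes(four_policy_run):
    """Universal opportunistic screening raises the identified fraction and
    lowers unidentified episode counts; collaborative care does not change
    identification."""
    _, results = four_policy_run
    frac = {pid: r.episodes_identified / r.episodes_total
            for pid, r in results.items()}
    assert frac["opportunistic_screening"] > frac["current_practice"] + 0.1
    assert frac["combined"] > frac["current_practice"] + 0.1
    assert frac["collaborative_care"] == pytest.approx(
        frac["current_practice"], abs=0.02)
    # only the screening policies cut unidentified episodes; collaborative
    # care leaves identification untouched (its episode totals drift up
    # slightly because treated patients live longer and relapse again)
    for pid in ("opportunistic_screening", "combined"):
        assert (results[pid].episodes_unidentified
                < 0.5 * results["current_practice"].episodes_unidentified)


def test_policies_reduce_complications(four_policy_run):
    """All three policy changes reduce total diabetes-related complication
    counts versus current practice (bi-directional linkage direction)."""
    _, results = four_policy_run
    cp = sum(results["current_practice"].complication_counts.values())
    for pid in ("collaborative_care", "opportunistic_screening", "combined"):
        assert sum(results[pid].complication_counts.values()) < cp


def test_scaling_is_linear():
    """Doubling the reporting-cohort scaling factor doubles every extensive
    quantity exactly."""
    cfg = ModelConfig()
    cfg.cohort.n_patients = 40
    cfg.cohort.seed = 37
    cohort = generate_cohort(cfg.cohort)
    base = run_policy(cohort, CP, cfg, seed=37)
    cfg.reporting_cohort *= 2
    doubled = run_policy(cohort, CP, cfg, seed=37)
    assert doubled.qalys == pytest.approx(2 * base.qalys, rel=1e-12)
    assert doubled.total_cost == pytest.approx(2 * base.total_cost, rel=1e-12)
    assert doubled.episodes_total == pytest.approx(2 * base.episodes_total, rel=1e-12)
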