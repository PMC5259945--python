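"""Diabetes risk engine: exposure-weighted hazard multipliers, hazard-ratio
recovery, mortality surrogate, and the policy-decoupling linkage property."""

import json
import math

import pytest

from diadem import (ComplicationParams, DepressionExposure, ModelConfig,
                    Policy, effective_hazard_multiplier, generate_cohort,
                    run_policy, simulate_patient)
from diadem.complications import (LinearHazardModel, SurrogateHazardModel,
                                  adjusted_annual_prob, load_hazard_model,
                                  mortality_update, pooled_hazard,
                                  simulate_complication_incidence)
from diadem.config import MICROVASCULAR, MACROVASCULAR, COMPLICATION_TYPES, ConfigError
from diadem.rng import substream


@pytest.mark.parametrize("f_minor, f_major, hr_minor, hr_major, expected", [
    (0.0, 1.0, 1.31, 1.36, 1.36),   # full-year major exposure = printed HR
    (0.0, 0.5, 1.31, 1.36, 1.18),   # half-year halves the elevation
    (0.0, 0.0, 1.31, 1.36, 1.0),    # no depression, no elevation
    (1.0, 0.0, 1.31, 1.36, 1.31),
    (0.5, 0.5, 1.00, 1.25, 1.125),
])
def test_effective_hazard_multiplier(f_minor, f_major, hr_minor, hr_major, expected):
    mult = effective_hazard_multiplier(
        DepressionExposure(f_minor, f_major), hr_minor, hr_major)
    assert mult == pytest.approx(expected)


def test_multiplier_one_is_passthrough():
    assert adjusted_annual_prob(0.0135, 1.0) == pytest.approx(0.0135)
    with pytest.raises(ConfigError):
        adjusted_annual_prob(1.2, 1.0)


def test_complication_classes_partition():
    assert MICROVASCULAR | MACROVASCULAR == set(COMPLICATION_TYPES)
    assert not MICROVASCULAR & MACROVASCULAR


def _empirical_hr(types, exposure, n=60_000, years=4, seed=21):
    params = ComplicationParams()
    dep = simulate_complication_incidence(
        n, years, exposure, params, substream(seed, 0), types)
    ctrl = simulate_complication_incidence(
        n, years, DepressionExposure(0.0, 0.0), params, substream(seed, 1), types)
    return pooled_hazard(dep) / pooled_hazard(ctrl)


def test_microvascular_hazard_ratio_major_depression():
    """A cohort held permanently in major depression shows a 1.36-fold
    microvascular event hazard versus a never-depressed cohort."""
    hr = _empirical_hr(tuple(MICROVASCULAR), DepressionExposure(0.0, 1.0))
    assert hr == pytest.approx(1.36, rel=0.05)


def test_macrovascular_hazard_ratio_minor_depression_is_null():
    """Minor depression carries no macrovascular excess (HR 1.00)."""
    hr = _empirical_hr(tuple(MACROVASCULAR), DepressionExposure(1.0, 0.0))
    assert hr == pytest.approx(1.00, rel=0.05)


def test_mortality_zero_slope_recovers_baseline(rng):
    """With a flat age slope and no history contributions the surrogate's
    annual death probability is 1 - exp(-a)."""
    params = ComplicationParams(mortality_gompertz_a=0.02, mortality_gompertz_b=0.0)
    model = SurrogateHazardModel(params)
    q = -math.expm1(-0.02)
    n = 100_000
    deaths = sum(
        mortality_update(70.0, {}, set(), params, model, rng) is not None
        for _ in range(n))
    assert abs(deaths / n - q) < 4 * math.sqrt(q * (1 - q) / n)


def test_complication_history_raises_mortality():
    params = ComplicationParams()
    model = SurrogateHazardModel(params)
    q0 = model.annual_death_prob(70.0, {}, set())
    q1 = model.annual_death_prob(70.0, {}, {"renal_failure"})
    assert q1 > q0


def test_life_expectancy_at_65_is_plausible(rng):
    """Remaining life expectancy at 65 under the default surrogate is
    finite and below 40 years (simulation oracle, no complications)."""
    params = ComplicationParams()
    model = SurrogateHazardModel(params)
    total = 0.0
    n = 2_000
    for _ in range(n):
        year = 0
        while year < 60:
            d = mortality_update(65.0 + year, {}, set(), params, model, rng,
                                 year_start=year)
            if d is not None:
                total += d
                break
            year += 1
        else:
            total += 60
    le = total / n
    assert 5.0 < le < 40.0


def test_linear_hazard_model_loader(tmp_path):
    coefs = {c: {"intercept": -5.0} for c in COMPLICATION_TYPES}
    coefs["mortality"] = {"intercept": -6.0, "age": 0.05}
    path = tmp_path / "coefs.json"
    path.write_text(json.dumps(coefs))
    params = ComplicationParams(hazard_model="linear", hazard_model_file=str(path))
    model = load_hazard_model(params)
    assert isinstance(model, LinearHazardModel)
    assert model.annual_event_prob("mi", 65.0, {}, set()) == pytest.approx(
        -math.expm1(-math.exp(-5.0)))
    bad = {c: {} for c in COMPLICATION_TYPES}  # no mortality block
    path.write_text(json.dumps(bad))
    with pytest.raises(ConfigError):
        load_hazard_model(params)


def test_risk_factors_constant_over_time():
    """Risk-factor trajectories do not drift: a simulated patient's
    baseline factors are untouched by the run."""
    cfg = ModelConfig()
    cfg.cohort.n_patients = 3
    cohort = generate_cohort(cfg.cohort)
    before = {p.id: dict(p.risk_factors) for p in cohort}
    for p in cohort:
        simulate_patient(p, Policy.from_id("CP"), cfg, seed=2)
    assert {p.id: p.risk_factors for p in cohort} == before


def test_decoupling_when_all_linkage_hrs_are_one():
    """With every depression<->complication hazard ratio at 1, complication
    counts are exactly identical across all four policies under common
    random numbers — the model's key falsifiable linkage property."""
    cfg = ModelConfig()
    cfg.cohort.n_patients = 150
    cfg.cohort.seed = 17
    cfg.natural_history.hr_complication_on_depression = 1.0
    for name in ("hr_micro_minor", "hr_micro_major", "hr_macro_minor",
                 "hr_macro_major"):
        setattr(cfg.complications, name, 1.0)
    cohort = generate_cohort(cfg.cohort)
    counts = {}
    for pid in ("CP", "P1", "P2", "P3"):
        res = run_policy(cohort, Policy.from_id(pid), cfg, seed=17)
        counts[pid] = res.complication_counts
    assert counts["CP"] == counts["P1"] == counts["P2"] == counts["P3"]
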