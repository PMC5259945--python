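"""Depression natural history: rate conversions, onset, progression,
recovery, relapse, and the complication->depression hazard elevation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from diadem import (NaturalHistoryParams, annual_prob_to_rate,
                    fraction_by_horizon_to_rate, rate_to_annual_prob,
                    sample_onset_time, sample_progression_or_recovery)
from diadem.natural_history import DepressionEpisode, Rates


@pytest.mark.parametrize("p, expected", [
    (0.0, 0.0),
    (0.054, -math.log(0.946)),   # ~0.05551
])
def test_annual_prob_to_rate_values(p, expected):
    assert annual_prob_to_rate(p) == pytest.approx(expected, abs=1e-12)


def test_fraction_by_horizon_rate():
    # 42% progressed at 2 years -> rate -ln(0.58)/2
    assert fraction_by_horizon_to_rate(0.42, 2.0) == pytest.approx(
        -math.log(0.58) / 2.0, abs=1e-12)


@pytest.mark.parametrize("bad", [1.0, 1.5, -0.01])
def test_prob_to_rate_domain_error(bad):
    with pytest.raises(ValueError):
        annual_prob_to_rate(bad)


@settings(max_examples=100, deadline=None)
@given(st.floats(0.0, 0.999))
def test_rate_probability_round_trip(p):
    assert rate_to_annual_prob(annual_prob_to_rate(p)) == pytest.approx(p, abs=1e-12)


def test_relapse_waiting_time_mean(rng):
    """Patients with a history of depression relapse after a mean wait of
    1.359 years (within 3 standard errors at n=1e5)."""
    params = NaturalHistoryParams()
    n = 100_000
    times = [sample_onset_time(params, history=True, complication_present=False,
                               rng=rng)[0] for _ in range(n)]
    se = 1.359 / math.sqrt(n)  # exponential: sd = mean
    assert abs(np.mean(times) - 1.359) < 3 * se


def test_complication_elevates_onset_hazard(rng):
    """A present diabetes complication multiplies the onset hazard by 1.5,
    so mean onset times shrink by that factor."""
    params = NaturalHistoryParams()
    n = 100_000
    t_plain = [sample_onset_time(params, True, False, rng)[0] for _ in range(n)]
    t_comp = [sample_onset_time(params, True, True, rng)[0] for _ in range(n)]
    ratio = np.mean(t_plain) / np.mean(t_comp)
    assert ratio == pytest.approx(1.5, rel=0.02)


def test_hr_one_makes_onset_independent_of_complications(rng):
    """With the linkage hazard ratio set to 1, onset times are
    statistically indistinguishable with and without a complication."""
    params = NaturalHistoryParams(hr_complication_on_depression=1.0)
    n = 20_000
    a = [sample_onset_time(params, True, False, rng)[0] for _ in range(n)]
    b = [sample_onset_time(params, True, True, rng)[0] for _ in range(n)]
    assert stats.ks_2samp(a, b).pvalue > 1e-3


def test_zero_rate_never_fires(rng):
    params = NaturalHistoryParams(annual_incidence_minor=0.0,
                                  annual_incidence_major=0.0)
    t, _ = sample_onset_time(params, history=False, complication_present=False,
                             rng=rng)
    assert t == math.inf


def test_progression_fraction_recovery_disabled(rng):
    """With spontaneous recovery disabled, 42% of minor episodes progress
    to major depression within 2 years."""
    rates = Rates.from_params(NaturalHistoryParams())
    rates_no_recovery = Rates(**{**vars(rates), "recovery_minor": 0.0})
    n = 100_000
    progressed = 0
    for _ in range(n):
        ep = DepressionEpisode("minor", 0.0)
        event, wait = sample_progression_or_recovery(ep, rates_no_recovery, rng)
        assert event == "progression"
        progressed += wait <= 2.0
    se = math.sqrt(0.42 * 0.58 / n)
    assert abs(progressed / n - 0.42) < 4 * se


def test_major_recovery_mean(rng):
    """Mean spontaneous recovery time for major depression is 0.877 years."""
    rates = Rates.from_params(NaturalHistoryParams())
    n = 100_000
    waits = []
    for _ in range(n):
        event, wait = sample_progression_or_recovery(
            DepressionEpisode("major", 0.0), rates, rng)
        assert event == "recovery"
        waits.append(wait)
    se = 0.877 / math.sqrt(n)
    assert abs(np.mean(waits) - 0.877) < 3 * se


def test_competing_risk_progression_probability(rng):
    """P(progression beats recovery) for a minor episode matches the
    closed form rate_prog / (rate_prog + rate_rec) ~ 0.0879."""
    rates = Rates.from_params(NaturalHistoryParams())
    expected = rates.progression / (rates.progression + rates.recovery_minor)
    assert expected == pytest.approx(0.0879, abs=5e-4)  # closed-form oracle
    n = 100_000
    wins = sum(
        sample_progression_or_recovery(DepressionEpisode("minor", 0.0), rates,
                                       rng)[0] == "progression"
        for _ in range(n))
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(wins / n - expected) < 4 * se


def test_relapse_severity_mix(rng):
    """Relapse severity is re-drawn: about half of relapse episodes are
    major under the default 50/50 split."""
    params = NaturalHistoryParams()
    n = 50_000
    majors = sum(sample_onset_time(params, True, False, rng)[1] == "major"
                 for _ in range(n))
    assert abs(majors / n - 0.5) < 4 * math.sqrt(0.25 / n)
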