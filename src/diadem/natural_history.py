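"""Depression natural history.

Onset, minor→major progression, spontaneous recovery, and relapse are all
modelled as exponential waiting times (memoryless, matching the
annual-probability form of the inputs).  Incidence among the never-
depressed runs as two independent competing onset processes (minor and
major); relapse among those with a history uses a single mean waiting time
with the episode severity re-drawn.  While a patient has any diabetes-
related complication, the onset/relapse hazard is multiplied by a single
hazard ratio (the same whether one or several complications are present).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import NaturalHistoryParams


def annual_prob_to_rate(p: float) -> float:
    """Convert an annual event probability to a constant event rate per year.

    Inverse of ``p = 1 - exp(-rate)``.  Raises ``ValueError`` for p >= 1
    (no finite rate) or p < 0.
    """
    if p < 0.0 or p >= 1.0:
        raise ValueError(f"annual probability must be in [0, 1), got {p!r}")
    return -math.log1p(-p)


def rate_to_annual_prob(rate: float) -> float:
    if rate < 0.0:
        raise ValueError(f"rate must be >= 0, got {rate!r}")
    return -math.expm1(-rate)


def fraction_by_horizon_to_rate(fraction: float, horizon: float) -> float:
    """Rate of an exponential clock hitting ``fraction`` of subjects by
    ``horizon`` years (e.g. 42% progressed at 2 years)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction!r}")
    if horizon <= 0.0:
        raise ValueError(f"horizon must be > 0, got {horizon!r}")
    return -math.log1p(-fraction) / horizon


@dataclass
class DepressionEpisode:
    """One depressive episode on a patient's timeline."""

    severity: str                 # "minor" | "major"
    t_start: float
    t_end: float | None = None    # None while open
    identified: bool = False
    on_treatment: bool = False
    responder: bool = False

    @property
    def open(self) -> bool:
        return self.t_end is None

    def close(self, t: float) -> None:
        assert self.t_end is None, "episode already closed"
        assert t >= self.t_start
        self.t_end = t


@dataclass(frozen=True)
class Rates:
    """Event rates (per year) derived from :class:`NaturalHistoryParams`."""

    onset_minor: float
    onset_major: float
    progression: float
    recovery_minor: float
    recovery_major: float
    relapse: float
    hr_complication: float

    @classmethod
    def from_params(cls, p: NaturalHistoryParams) -> "Rates":
        return cls(
            onset_minor=annual_prob_to_rate(p.annual_incidence_minor),
            onset_major=annual_prob_to_rate(p.annual_incidence_major),
            progression=fraction_by_horizon_to_rate(p.progression_fraction,
                                                    p.progression_horizon),
            recovery_minor=1.0 / p.mean_time_recovery_minor,
            recovery_major=1.0 / p.mean_time_recovery_major,
            relapse=1.0 / p.mean_time_relapse,
            hr_complication=p.hr_complication_on_depression,
        )


def _exp_time(rng: np.random.Generator, rate: float) -> float:
    if rate <= 0.0:
        return math.inf
    return rng.exponential(1.0 / rate)


def sample_onset_time(params: NaturalHistoryParams | Rates, history: bool,
                      complication_present: bool, rng: np.random.Generator,
                      p_relapse_major: float = 0.5) -> tuple[float, str]:
    """Waiting time from depression-free to the next episode, with severity.

    No history: the minimum of two competing exponential clocks (minor and
    major incidence).  History: a single relapse clock with severity
    re-drawn (``p_relapse_major``).  A present complication multiplies
    every onset rate by the configured hazard ratio.
    """
    rates = params if isinstance(params, Rates) else Rates.from_params(params)
    mult = rates.hr_complication if complication_present else 1.0
    if history:
        t = _exp_time(rng, rates.relapse * mult)
        severity = "major" if rng.random() < p_relapse_major else "minor"
        return t, severity
    t_minor = _exp_time(rng, rates.onset_minor * mult)
    t_major = _exp_time(rng, rates.onset_major * mult)
    if t_minor <= t_major:
        return t_minor, "minor"
    return t_major, "major"


def sample_progression_or_recovery(episode: DepressionEpisode,
                                   params: NaturalHistoryParams | Rates,
                                   rng: np.random.Generator,
                                   ) -> tuple[str, float]:
    """Next natural-history transition for an open episode.

    Minor episodes face competing exponential risks of progression to major
    and spontaneous recovery; major episodes face spontaneous recovery
    only.  Returns ``(event, waiting_time)`` with event in
    ``{"progression", "recovery"}``; the waiting time is measured from now.
    """
    assert episode.open, "episode must be open"
    rates = params if isinstance(params, Rates) else Rates.from_params(params)
    if episode.severity == "major":
        return "recovery", _exp_time(rng, rates.recovery_major)
    t_prog = _exp_time(rng, rates.progression)
    t_rec = _exp_time(rng, rates.recovery_minor)
    if t_prog < t_rec:
        return "progression", t_prog
    return "recovery", t_rec
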