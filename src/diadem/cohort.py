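"""Synthetic baseline cohorts.

Generates seeded cohorts of adults with type-2 diabetes with the structure
the simulation assumes: demographics, diabetes duration, continuous risk
factors, and a baseline depression state/history.  The distributions are
simple parametric stand-ins (independent truncated normals, Bernoulli
flags) for the national-audit baseline data the underlying model class is
usually parameterised from; every distribution parameter is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig, ConfigError, RiskFactorSpec
from .rng import substream

DEPRESSION_STATES = ("none", "minor", "major")


@dataclass
class PatientProfile:
    """Baseline state of one simulated individual."""

    id: int
    age: float
    sex: str                      # "female" | "male"
    diabetes_duration: float      # years since diagnosis
    risk_factors: dict[str, float] = field(default_factory=dict)
    depression_state: str = "none"
    depression_history: bool = False
    alive: bool = True

    def validate(self) -> None:
        assert self.age >= 18.0, "age must be >= 18"
        assert self.diabetes_duration >= 0.0
        assert self.depression_state in DEPRESSION_STATES
        if self.depression_state != "none":
            assert self.depression_history, \
                "depression_history must hold whenever depression_state != none"


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_factor(rng: np.random.Generator, spec: RiskFactorSpec,
                   size: int) -> np.ndarray:
    if spec.dist == "bernoulli":
        return (rng.random(size) < spec.mean).astype(float)
    return _sample_truncnorm(rng, spec.mean, spec.sd, spec.low, spec.high, size)


def generate_cohort(config: CohortConfig) -> list[PatientProfile]:
    """Generate ``config.n_patients`` baseline profiles, deterministically
    for a fixed ``config.seed``.

    Baseline depression state is drawn as (major, minor, none) with the
    configured prevalences; anyone currently depressed has
    ``depression_history=True``, and the depression-free additionally carry
    a prior history with probability ``baseline_history_prob``.
    """
    config.validate()
    n = config.n_patients
    if n == 0:
        return []
    rng = substream(config.seed, 0xC0)

    age = _sample_truncnorm(rng, config.age_mean, config.age_sd,
                            config.age_low, config.age_high, n)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    duration = _sample_truncnorm(rng, config.duration_mean, config.duration_sd,
                                 0.0, config.duration_high, n)
    factors = {name: _sample_factor(rng, spec, n)
               for name, spec in config.risk_factors.items()}

    u = rng.random(n)
    p_major = config.baseline_prevalence_major
    p_minor = config.baseline_prevalence_minor
    state = np.where(u < p_major, "major",
                     np.where(u < p_major + p_minor, "minor", "none"))
    prior_history = rng.random(n) < config.baseline_history_prob
    history = (state != "none") | prior_history

    cohort = []
    for i in range(n):
        profile = PatientProfile(
            id=i,
            age=float(age[i]),
            sex=str(sex[i]),
            diabetes_duration=float(duration[i]),
            risk_factors={name: float(vals[i]) for name, vals in factors.items()},
            depression_state=str(state[i]),
            depression_history=bool(history[i]),
        )
        profile.validate()
        cohort.append(profile)
    return cohort


def cohort_to_frame(cohort: list[PatientProfile]) -> pd.DataFrame:
    """One row per patient; risk factors become ``rf_<name>`` columns."""
    rows = []
    for p in cohort:
        row = {
            "id": p.id, "age": p.age, "sex": p.sex,
            "diabetes_duration": p.diabetes_duration,
            "depression_state": p.depression_state,
            "depression_history": p.depression_history,
            "alive": p.alive,
        }
        row.update({f"rf_{k}": v for k, v in p.risk_factors.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientProfile]:
    """Inverse of :func:`cohort_to_frame`."""
    rf_cols = [c for c in df.columns if c.startswith("rf_")]
    cohort = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        profile = PatientProfile(
            id=int(d["id"]), age=float(d["age"]), sex=str(d["sex"]),
            diabetes_duration=float(d["diabetes_duration"]),
            risk_factors={c[3:]: float(d[c]) for c in rf_cols},
            depression_state=str(d["depression_state"]),
            depression_history=bool(d["depression_history"]),
            alive=bool(d["alive"]),
        )
        profile.validate()
        cohort.append(profile)
    return cohort


def save_cohort_csv(cohort: list[PatientProfile], path: str) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def load_cohort_csv(path: str) -> list[PatientProfile]:
    return frame_to_cohort(pd.read_csv(path))
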