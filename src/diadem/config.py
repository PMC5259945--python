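"""Model configuration.

Every tunable quantity in the simulation lives in one of the dataclasses
below, grouped the way the model is organised: the synthetic baseline
cohort, depression natural history, primary-care contact and screening
processes, depression treatment, the diabetes risk engine, and the
economic (cost / utility / societal) inputs.  A :class:`ModelConfig`
aggregates all of them plus run-level settings (discount rate, horizon,
reporting-cohort size).

Configs round-trip through plain dicts and YAML, and support dotted-path
overrides (``natural_history.mean_time_relapse``) which is the hook the
one-way sensitivity harness uses.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the offending field."""


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_positive(value: float, name: str) -> None:
    if not value > 0.0:
        raise ConfigError(f"{name} must be > 0, got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    if not value >= 0.0:
        raise ConfigError(f"{name} must be >= 0, got {value!r}")


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

@dataclass
class RiskFactorSpec:
    """Parametric distribution for one continuous/binary baseline risk factor.

    ``dist`` is one of ``normal`` (truncated to [low, high]) or
    ``bernoulli`` (``mean`` is the success probability).
    """

    dist: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    low: float = float("-inf")
    high: float = float("inf")

    def validate(self, name: str) -> None:
        if self.dist not in ("normal", "bernoulli"):
            raise ConfigError(f"risk factor {name!r}: unknown dist {self.dist!r}")
        if self.dist == "normal":
            if not self.sd > 0:
                raise ConfigError(f"risk factor {name!r}: sd must be > 0")
            if not self.low < self.high:
                raise ConfigError(f"risk factor {name!r}: low must be < high")
        else:
            _check_prob(self.mean, f"risk factor {name!r} bernoulli mean")


def _default_risk_factors() -> dict[str, RiskFactorSpec]:
    # Plausible type-2-diabetes primary-care population; see docs/methods.md.
    return {
        "hba1c": RiskFactorSpec("normal", 7.5, 1.2, 4.0, 15.0),     # %
        "sbp": RiskFactorSpec("normal", 135.0, 15.0, 80.0, 220.0),  # mmHg
        "bmi": RiskFactorSpec("normal", 30.5, 5.5, 15.0, 60.0),     # kg/m^2
        "smoker": RiskFactorSpec("bernoulli", 0.16),
    }


@dataclass
class CohortConfig:
    """Baseline cohort of adults with type-2 diabetes managed in primary care."""

    n_patients: int = 10_000
    seed: int = 0
    age_mean: float = 65.0
    age_sd: float = 11.0
    age_low: float = 18.0
    age_high: float = 100.0
    female_fraction: float = 0.44
    duration_mean: float = 8.0   # years since diabetes diagnosis
    duration_sd: float = 6.0
    duration_high: float = 50.0
    risk_factors: dict[str, RiskFactorSpec] = field(default_factory=_default_risk_factors)
    baseline_prevalence_major: float = 0.08
    baseline_prevalence_minor: float = 0.08
    baseline_history_prob: float = 0.25

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        if not self.age_sd > 0 or not self.duration_sd > 0:
            raise ConfigError("age_sd and duration_sd must be > 0")
        if not 18.0 <= self.age_low < self.age_high:
            raise ConfigError("require 18 <= age_low < age_high")
        _check_prob(self.female_fraction, "female_fraction")
        _check_prob(self.baseline_prevalence_major, "baseline_prevalence_major")
        _check_prob(self.baseline_prevalence_minor, "baseline_prevalence_minor")
        if self.baseline_prevalence_major + self.baseline_prevalence_minor > 1.0:
            raise ConfigError("baseline depression prevalences sum to > 1")
        _check_prob(self.baseline_history_prob, "baseline_history_prob")
        for name, spec in self.risk_factors.items():
            spec.validate(name)


# ---------------------------------------------------------------------------
# Depression natural history
# ---------------------------------------------------------------------------

@dataclass
class NaturalHistoryParams:
    """Incidence, progression, recovery and relapse of minor/major depression.

    Annual incidences are probabilities per year (converted internally to
    exponential rates); all "time to X" quantities are exponential means in
    years.  ``hr_complication_on_depression`` multiplies the onset/relapse
    hazard while the patient has any diabetes-related complication history.
    """

    annual_incidence_minor: float = 0.054
    annual_incidence_major: float = 0.054
    progression_fraction: float = 0.42    # minor -> major ...
    progression_horizon: float = 2.0      # ... by this many years
    mean_time_recovery_minor: float = 0.354
    mean_time_recovery_major: float = 0.877
    mean_time_relapse: float = 1.359
    p_relapse_major: float = 0.5          # severity of a relapse episode
    hr_complication_on_depression: float = 1.5

    def validate(self) -> None:
        for name in ("annual_incidence_minor", "annual_incidence_major"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {p!r}")
        _check_prob(self.progression_fraction, "progression_fraction")
        if self.progression_fraction >= 1.0:
            raise ConfigError("progression_fraction must be < 1")
        _check_positive(self.progression_horizon, "progression_horizon")
        _check_positive(self.mean_time_recovery_minor, "mean_time_recovery_minor")
        _check_positive(self.mean_time_recovery_major, "mean_time_recovery_major")
        _check_positive(self.mean_time_relapse, "mean_time_relapse")
        _check_prob(self.p_relapse_major, "p_relapse_major")
        _check_positive(self.hr_complication_on_depression, "hr_complication_on_depression")


# ---------------------------------------------------------------------------
# Screening & identification
# ---------------------------------------------------------------------------

@dataclass
class ScreeningParams:
    """GP contact process, annual diabetes review, and the two-stage screen.

    The two-stage screen is the two-item Whooley questionnaire followed, on
    a positive result, by a confirmatory structured interview (perfect by
    default).
    """

    gp_visits_per_year_none: float = 12.5
    gp_visits_per_year_minor: float = 8.0
    gp_visits_per_year_major: float = 8.0
    p_screen_no_history: float = 0.05
    p_screen_history: float = 0.20
    p_attend_review: float = 0.904
    review_rr_minor: float = 0.9
    review_rr_major: float = 0.65
    p_review_includes_screen: float = 0.859
    whooley_sens: float = 0.95
    whooley_spec: float = 0.66
    interview_sens: float = 1.0
    interview_spec: float = 1.0

    def validate(self) -> None:
        for name in ("gp_visits_per_year_none", "gp_visits_per_year_minor",
                     "gp_visits_per_year_major"):
            _check_nonneg(getattr(self, name), name)
        for name in ("p_screen_no_history", "p_screen_history", "p_attend_review",
                     "review_rr_minor", "review_rr_major", "p_review_includes_screen",
                     "whooley_sens", "whooley_spec", "interview_sens", "interview_spec"):
            _check_prob(getattr(self, name), name)


# ---------------------------------------------------------------------------
# Depression treatment
# ---------------------------------------------------------------------------

@dataclass
class TreatmentParams:
    """One treatment course per identified episode.

    Base response/dropout probabilities and the course duration are
    placeholders exposed to the sensitivity harness (the evidence behind
    them is meta-analytic and not part of this package's inputs).
    Collaborative care multiplies response by ``cc_rr_response`` and reduces
    dropout by ``cc_rr_dropout`` (division by default; set
    ``cc_dropout_mode='retention'`` to instead multiply the retention
    probability).
    """

    p_response: float = 0.5
    p_dropout: float = 0.3
    duration: float = 0.25               # years
    sessions_minor: int = 6              # low-intensity psychotherapy
    sessions_major: int = 12             # high-intensity psychotherapy
    drug_days_major: float = 91.25       # pharmacotherapy days per major course
    cc_rr_response: float = 1.79
    cc_rr_dropout: float = 1.33
    cc_dropout_mode: str = "divide"      # or "retention"
    cc_addon_cost: float = 240.0         # per-course collaborative-care add-on, GBP

    def validate(self) -> None:
        _check_prob(self.p_response, "p_response")
        _check_prob(self.p_dropout, "p_dropout")
        _check_positive(self.duration, "duration")
        _check_positive(self.cc_rr_response, "cc_rr_response")
        _check_positive(self.cc_rr_dropout, "cc_rr_dropout")
        if self.cc_dropout_mode not in ("divide", "retention"):
            raise ConfigError(f"cc_dropout_mode must be 'divide' or 'retention', "
                              f"got {self.cc_dropout_mode!r}")
        _check_nonneg(self.cc_addon_cost, "cc_addon_cost")
        if self.sessions_minor < 0 or self.sessions_major < 0 or self.drug_days_major < 0:
            raise ConfigError("treatment resource counts must be >= 0")


# ---------------------------------------------------------------------------
# Diabetes complications & mortality
# ---------------------------------------------------------------------------

COMPLICATION_TYPES = (
    "ihd", "blindness", "renal_failure",
    "heart_failure", "mi", "stroke", "ulcer", "amputation",
)

MICROVASCULAR = frozenset({"ihd", "blindness", "renal_failure"})
MACROVASCULAR = frozenset({"heart_failure", "mi", "stroke", "ulcer", "amputation"})

#: complication types that may recur; the rest occur at most once per patient
RECURRENT_TYPES = frozenset({"mi", "stroke", "ulcer"})


def _default_base_annual_prob() -> dict[str, float]:
    # Surrogate constant annual event probabilities, chosen so a cohort
    # entering around age 65 experiences plausible lifetime complication
    # frequencies (order ~0.2 microvascular and ~0.6 macrovascular events
    # per person); see docs/methods.md.
    return {
        "ihd": 0.010,
        "blindness": 0.004,
        "renal_failure": 0.0025,
        "heart_failure": 0.008,
        "mi": 0.0135,
        "stroke": 0.010,
        "ulcer": 0.0025,
        "amputation": 0.003,
    }


def _default_mortality_log_hr() -> dict[str, float]:
    # Additive log-hazard contributions of complication history to mortality.
    return {
        "ihd": 0.25,
        "blindness": 0.05,
        "renal_failure": 1.1,
        "heart_failure": 0.7,
        "mi": 0.5,
        "stroke": 0.5,
        "ulcer": 0.15,
        "amputation": 0.5,
    }


@dataclass
class ComplicationParams:
    """Pluggable diabetes risk engine plus the depression->complication linkage.

    The default engine is a surrogate: constant annual event hazards per
    complication and Gompertz-in-age mortality with additive log-hazard
    shifts per complication in history.  Users holding externally published
    coefficient sets can load them via
    :func:`diadem.complications.load_hazard_model`.
    """

    base_annual_prob: dict[str, float] = field(default_factory=_default_base_annual_prob)
    hr_micro_minor: float = 1.31
    hr_micro_major: float = 1.36
    hr_macro_minor: float = 1.00
    hr_macro_major: float = 1.25
    mortality_gompertz_a: float = 5.96e-5   # annual hazard scale
    mortality_gompertz_b: float = 0.085     # per-year-of-age log slope
    mortality_log_hr: dict[str, float] = field(default_factory=_default_mortality_log_hr)
    severe_hypo_rate: float = 0.0           # events per year; off by default
    hazard_model: str = "surrogate"         # or "linear" with coefficients file
    hazard_model_file: str | None = None

    def validate(self) -> None:
        for ctype in COMPLICATION_TYPES:
            if ctype not in self.base_annual_prob:
                raise ConfigError(f"base_annual_prob missing complication {ctype!r}")
            p = self.base_annual_prob[ctype]
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"base_annual_prob[{ctype!r}] must be in [0, 1), got {p!r}")
        for name in ("hr_micro_minor", "hr_micro_major", "hr_macro_minor", "hr_macro_major"):
            _check_positive(getattr(self, name), name)
        _check_positive(self.mortality_gompertz_a, "mortality_gompertz_a")
        _check_nonneg(self.mortality_gompertz_b, "mortality_gompertz_b")
        _check_nonneg(self.severe_hypo_rate, "severe_hypo_rate")
        if self.hazard_model not in ("surrogate", "linear"):
            raise ConfigError(f"unknown hazard_model {self.hazard_model!r}")

    def class_of(self, ctype: str) -> str:
        return "micro" if ctype in MICROVASCULAR else "macro"

    def hr_pair(self, ctype: str) -> tuple[float, float]:
        """(hr_minor, hr_major) for a complication type's vascular class."""
        if ctype in MICROVASCULAR:
            return self.hr_micro_minor, self.hr_micro_major
        return self.hr_macro_minor, self.hr_macro_major


# ---------------------------------------------------------------------------
# Economics
# ---------------------------------------------------------------------------

def _default_complication_costs() -> dict[str, tuple[float, float]]:
    # (event-year, subsequent-year) management cost, 2013 GBP.
    return {
        "heart_failure": (3559.0, 1010.0),
        "ihd": (3139.0, 790.0),
        "mi": (6522.0, 744.0),
        "stroke": (3793.0, 399.0),
        "blindness": (1397.0, 450.0),
        "ulcer": (1855.0, 21.0),
        "amputation": (13556.0, 481.0),
        "renal_failure": (34806.0, 34806.0),
    }


@dataclass
class CostParams:
    """Unit costs (NHS & personal social services perspective)."""

    gp_appointment: float = 37.0
    annual_review: float = 397.0
    opportunistic_screen: float = 2.0
    structured_interview: float = 150.0   # placeholder, config-exposed
    diabetes_annual: float = 252.0        # ongoing management, no complications
    complication: dict[str, tuple[float, float]] = field(
        default_factory=_default_complication_costs)
    severe_hypo: float = 390.0
    drug_daily: float = 0.073
    therapy_session: float = 88.0
    currency_year: int = 2013

    def validate(self) -> None:
        for name in ("gp_appointment", "annual_review", "opportunistic_screen",
                     "structured_interview", "diabetes_annual", "severe_hypo",
                     "drug_daily", "therapy_session"):
            _check_nonneg(getattr(self, name), name)
        for ctype in COMPLICATION_TYPES:
            if ctype not in self.complication:
                raise ConfigError(f"complication costs missing {ctype!r}")
            ev, sub = self.complication[ctype]
            _check_nonneg(ev, f"complication[{ctype!r}] event-year cost")
            _check_nonneg(sub, f"complication[{ctype!r}] subsequent-year cost")


def _default_decrements() -> dict[str, float]:
    # Signs preserved exactly as sourced, including the counterintuitive
    # positive entries (MI prior history, blindness).
    return {
        "mi_event": -0.065,
        "mi_history": 0.008,
        "ihd": -0.028,
        "stroke": -0.165,
        "heart_failure": -0.101,
        "amputation": -0.172,
        "blindness": 0.033,
        "renal_failure": -0.263,
        "ulcer": -0.016,
        "severe_hypo_event": -0.00186,
        "minor_depression": 0.0,
        "major_depression": -0.3,
    }


@dataclass
class UtilityParams:
    """EQ-5D-based utility composition: baseline plus additive decrements."""

    baseline: float = 0.807
    decrements: dict[str, float] = field(default_factory=_default_decrements)
    responder_multiplier: float = 0.5   # on the depression decrement, during
                                        # treatment, responders only
    floor: float = -0.594               # EQ-5D floor
    composition: str = "additive"       # or "multiplicative"

    def validate(self) -> None:
        _check_prob(self.baseline, "utility baseline")
        _check_nonneg(self.responder_multiplier, "responder_multiplier")
        if self.composition not in ("additive", "multiplicative"):
            raise ConfigError(f"unknown utility composition {self.composition!r}")


@dataclass
class SocietalParams:
    """Per-state daily rates behind the societal (non-NHS) outputs.

    Placeholder values: the published outputs these feed are reported
    quantities whose input rates are not public.
    """

    sick_days_none: float = 2.0        # days/year off paid employment
    sick_days_minor: float = 10.0
    sick_days_major: float = 40.0
    informal_care_none: float = 2.0    # days/year of unpaid care received
    informal_care_minor: float = 8.0
    informal_care_major: float = 30.0
    per_complication_sick: float = 5.0       # add-on per complication type in history
    per_complication_informal: float = 10.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_nonneg(getattr(self, f.name), f.name)


# ---------------------------------------------------------------------------
# Policies and the top-level config
# ---------------------------------------------------------------------------

POLICY_IDS = ("current_practice", "collaborative_care",
              "opportunistic_screening", "combined")

POLICY_SHORT = {"CP": "current_practice", "P1": "collaborative_care",
                "P2": "opportunistic_screening", "P3": "combined"}


@dataclass(frozen=True)
class Policy:
    """A care-pathway policy: collaborative care and/or universal screening."""

    id: str
    cc_enabled: bool
    universal_screen_enabled: bool

    @classmethod
    def from_id(cls, policy_id: str) -> "Policy":
        pid = POLICY_SHORT.get(policy_id, policy_id)
        flags = {
            "current_practice": (False, False),
            "collaborative_care": (True, False),
            "opportunistic_screening": (False, True),
            "combined": (True, True),
        }
        if pid not in flags:
            raise ConfigError(f"unknown policy {policy_id!r}; "
                              f"expected one of {POLICY_IDS} or {tuple(POLICY_SHORT)}")
        cc, scr = flags[pid]
        return cls(pid, cc, scr)


def all_policies() -> list[Policy]:
    return [Policy.from_id(pid) for pid in POLICY_IDS]


@dataclass
class ModelConfig:
    """Everything needed for one simulation run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    treatment: TreatmentParams = field(default_factory=TreatmentParams)
    complications: ComplicationParams = field(default_factory=ComplicationParams)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    societal: SocietalParams = field(default_factory=SocietalParams)
    discount_rate: float = 0.035
    discounting: str = "continuous"     # or "annual"
    max_age: float = 105.0              # hard horizon; "lifetime" in practice
    reporting_cohort: int = 2_000_000

    def validate(self) -> None:
        self.cohort.validate()
        self.natural_history.validate()
        self.screening.validate()
        self.treatment.validate()
        self.complications.validate()
        self.costs.validate()
        self.utilities.validate()
        self.societal.validate()
        _check_nonneg(self.discount_rate, "discount_rate")
        if self.discounting not in ("continuous", "annual"):
            raise ConfigError(f"unknown discounting mode {self.discounting!r}")
        _check_positive(self.max_age, "max_age")
        if self.reporting_cohort <= 0:
            raise ConfigError("reporting_cohort must be > 0")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # tuples -> lists for YAML friendliness
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        cfg = cls()
        for name, value in d.items():
            if not hasattr(cfg, name):
                raise ConfigError(f"unknown config section {name!r}")
            current = getattr(cfg, name)
            if dataclasses.is_dataclass(current):
                setattr(cfg, name, _dataclass_from_dict(type(current), value, name))
            else:
                setattr(cfg, name, value)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        """Stable content hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dataclass_from_dict(klass, d: dict[str, Any], section: str):
    obj = klass()
    if not isinstance(d, dict):
        raise ConfigError(f"config section {section!r} must be a mapping")
    for name, value in d.items():
        if not hasattr(obj, name):
            raise ConfigError(f"unknown parameter {section}.{name}")
        current = getattr(obj, name)
        if section == "cohort" and name == "risk_factors":
            value = {k: (v if isinstance(v, RiskFactorSpec)
                         else _dataclass_from_dict(RiskFactorSpec, v, f"{section}.{name}.{k}"))
                     for k, v in value.items()}
        elif isinstance(current, dict) and name == "complication":
            value = {k: tuple(v) for k, v in value.items()}
        setattr(obj, name, value)
    return obj


def apply_overrides(config: ModelConfig, overrides: dict[str, Any]) -> ModelConfig:
    """Return a deep copy of ``config`` with dotted-path overrides applied.

    ``{"natural_history.mean_time_relapse": 2.0}`` sets
    ``config.natural_history.mean_time_relapse``.  Unknown paths raise
    :class:`ConfigError`.
    """
    cfg = copy.deepcopy(config)
    for path, value in overrides.items():
        parts = path.split(".")
        obj: Any = cfg
        for part in parts[:-1]:
            if dataclasses.is_dataclass(obj) and hasattr(obj, part):
                obj = getattr(obj, part)
            elif isinstance(obj, dict) and part in obj:
                obj = obj[part]
            else:
                raise ConfigError(f"unknown parameter path {path!r}")
        leaf = parts[-1]
        if dataclasses.is_dataclass(obj) and hasattr(obj, leaf):
            setattr(obj, leaf, value)
        elif isinstance(obj, dict) and leaf in obj:
            obj[leaf] = value
        else:
            raise ConfigError(f"unknown parameter path {path!r}")
    cfg.validate()
    return cfg
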