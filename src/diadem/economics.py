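"""Cost and utility accounting.

Every cost the simulation incurs is logged to a per-patient ledger either
as a point entry (a lump cost at an instant: an appointment, a screen, an
event-year complication cost) or as a rate segment (a cost accruing
continuously: ongoing diabetes management, subsequent-year complication
management).  Utility is logged as piecewise-constant segments.
Aggregation applies discounting at 3.5%/year (continuous exponent by
default; annual-step available) and produces per-patient totals: costs by
category (discounted and undiscounted), life-years, QALYs, and societal
day counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import ModelConfig, UtilityParams

#: closed set of cost categories (mirrors the reporting breakdown)
CATEGORIES = ("screening", "interview", "treatment", "gp", "review",
              "complication_mgmt", "ongoing_mgmt")


@dataclass
class LedgerEntry:
    """A lump cost at one instant."""

    time: float
    category: str
    amount: float

    def __post_init__(self) -> None:
        assert self.time >= 0.0
        assert self.category in CATEGORIES, f"unknown category {self.category!r}"


@dataclass
class RateSegment:
    """A cost accruing at ``rate`` GBP/year over [t0, t1)."""

    t0: float
    t1: float
    rate: float
    category: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.t0 <= self.t1
        assert self.category in CATEGORIES


@dataclass
class UtilitySegment:
    t0: float
    t1: float
    utility: float


@dataclass
class StateSnapshot:
    """The utility-relevant state of a patient at an instant."""

    complication_history: frozenset[str] = frozenset()
    event_year_types: frozenset[str] = frozenset()   # events in current annual cycle
    hypo_events_this_year: int = 0
    depression_state: str = "none"                   # "none" | "minor" | "major"
    on_treatment: bool = False
    responder: bool = False


def utility_at(state: StateSnapshot, params: UtilityParams) -> float:
    """Compose the utility of a health state.

    Baseline plus additive decrements for every condition present; MI uses
    its event-year decrement in the year of the event and its prior-history
    decrement afterwards; the depression decrement is multiplied by the
    responder multiplier while on treatment and ultimately responding.
    The result is clamped to [floor, 1].
    """
    dec = params.decrements
    terms = []
    for ctype in state.complication_history | state.event_year_types:
        if ctype == "mi":
            terms.append(dec["mi_event"] if "mi" in state.event_year_types
                         else dec["mi_history"])
        elif ctype in dec:
            terms.append(dec[ctype])
    terms.append(dec["severe_hypo_event"] * state.hypo_events_this_year)
    if state.depression_state != "none":
        d = dec[f"{state.depression_state}_depression"]
        if state.on_treatment and state.responder:
            d *= params.responder_multiplier
        terms.append(d)
    if params.composition == "additive":
        u = params.baseline + sum(terms)
    else:
        u = params.baseline
        for t in terms:
            u *= max(0.0, 1.0 + t)
    return min(1.0, max(params.floor, u))


def discount(amount: float, time: float, rate: float = 0.035,
             mode: str = "continuous") -> float:
    """Present value of ``amount`` incurred at ``time`` years.

    Continuous mode uses ``amount / (1+rate)**time``; annual mode
    discounts by completed years (``floor(time)``).
    """
    if rate < 0.0:
        raise ValueError(f"discount rate must be >= 0, got {rate!r}")
    if time < 0.0:
        raise ValueError(f"time must be >= 0, got {time!r}")
    exponent = math.floor(time) if mode == "annual" else time
    return amount / (1.0 + rate) ** exponent


def _discounted_segment(t0: float, t1: float, rate: float, mode: str) -> float:
    """∫_{t0}^{t1} v(t) dt with v the discount factor; multiplies a constant
    annual rate into present-valued year-equivalents."""
    if t1 <= t0:
        return 0.0
    if rate == 0.0:
        return t1 - t0
    if mode == "annual":
        total, t = 0.0, t0
        while t < t1 - 1e-12:
            t_next = min(t1, math.floor(t) + 1.0)
            total += (t_next - t) / (1.0 + rate) ** math.floor(t)
            t = t_next
        return total
    rho = math.log(1.0 + rate)
    return (math.exp(-rho * t0) - math.exp(-rho * t1)) / rho


@dataclass
class Ledger:
    """Per-patient record of all costs, utility, and societal day accrual."""

    patient_id: int
    entries: list[LedgerEntry] = field(default_factory=list)
    rate_segments: list[RateSegment] = field(default_factory=list)
    utility_segments: list[UtilitySegment] = field(default_factory=list)
    sick_days: float = 0.0
    informal_care_days: float = 0.0
    t_end: float | None = None    # death or horizon; set when timeline closes

    def add_cost(self, time: float, category: str, amount: float) -> None:
        if amount != 0.0:
            self.entries.append(LedgerEntry(time, category, amount))

    def add_rate(self, t0: float, t1: float, rate: float, category: str) -> None:
        if t1 > t0 and rate != 0.0:
            self.rate_segments.append(RateSegment(t0, t1, rate, category))

    def add_utility(self, t0: float, t1: float, utility: float) -> None:
        if t1 > t0:
            self.utility_segments.append(UtilitySegment(t0, t1, utility))

    def close(self, t_end: float) -> None:
        self.t_end = t_end


@dataclass
class PatientTotals:
    """Aggregated, discounted outcomes for one closed patient timeline."""

    patient_id: int
    life_years: float
    qalys: float
    qalys_undiscounted: float
    cost_by_category: dict[str, float]
    cost_by_category_undiscounted: dict[str, float]
    sick_days: float
    informal_care_days: float

    @property
    def total_cost(self) -> float:
        return sum(self.cost_by_category.values())

    @property
    def total_cost_undiscounted(self) -> float:
        return sum(self.cost_by_category_undiscounted.values())


def accumulate(ledger: Ledger, discount_rate: float = 0.035,
               mode: str = "continuous") -> PatientTotals:
    """Aggregate a closed ledger into per-patient totals.

    QALYs are the time integral of utility times the discount factor;
    category cost totals reconcile exactly with the entry-level sums.
    """
    if ledger.t_end is None:
        raise ValueError("cannot accumulate an open patient timeline")
    disc: dict[str, float] = {c: 0.0 for c in CATEGORIES}
    undisc: dict[str, float] = {c: 0.0 for c in CATEGORIES}
    for e in ledger.entries:
        undisc[e.category] += e.amount
        disc[e.category] += discount(e.amount, e.time, discount_rate, mode)
    for s in ledger.rate_segments:
        undisc[s.category] += s.rate * (s.t1 - s.t0)
        disc[s.category] += s.rate * _discounted_segment(s.t0, s.t1, discount_rate, mode)
    q = qu = 0.0
    for s in ledger.utility_segments:
        qu += s.utility * (s.t1 - s.t0)
        q += s.utility * _discounted_segment(s.t0, s.t1, discount_rate, mode)
    return PatientTotals(
        patient_id=ledger.patient_id,
        life_years=ledger.t_end,
        qalys=q,
        qalys_undiscounted=qu,
        cost_by_category=disc,
        cost_by_category_undiscounted=undisc,
        sick_days=ledger.sick_days,
        informal_care_days=ledger.informal_care_days,
    )
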