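"""Incremental cost-effectiveness analysis and the one-way sensitivity harness.

Strategies are ordered by discounted cost; strictly dominated strategies
(costlier with fewer QALYs than some alternative) and strategies ruled out
by extended dominance (a higher ICER than the next costlier strategy on
the frontier) are flagged and excluded from the efficient frontier, whose
pairwise ICERs are then strictly increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cohort import generate_cohort
from .config import ConfigError, ModelConfig, Policy, all_policies, apply_overrides
from .engine import PolicyResult, run_comparison


@dataclass
class StrategySummary:
    policy_id: str
    cost: float
    qalys: float
    dominated: bool = False           # strict dominance
    extended_dominated: bool = False
    icer: float | None = None         # vs previous frontier strategy
    comparator: str | None = None


@dataclass
class IncrementalAnalysis:
    strategies: list[StrategySummary] = field(default_factory=list)

    @property
    def frontier(self) -> list[StrategySummary]:
        return [s for s in self.strategies
                if not s.dominated and not s.extended_dominated]

    def icer_of(self, policy_id: str) -> float | None:
        for s in self.strategies:
            if s.policy_id == policy_id:
                return s.icer
        raise KeyError(policy_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.strategies])


def incremental_icer(results: list[PolicyResult] | dict[str, PolicyResult],
                     ) -> IncrementalAnalysis:
    """Full incremental analysis over two or more strategies.

    Uses discounted total cost and discounted QALYs.  A strategy that is
    costlier with no QALY gain over a cheaper one (ΔQALY <= 0) is treated
    as dominated rather than producing a division by zero.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least 2 strategies")
    strategies = sorted(
        (StrategySummary(r.policy_id, r.total_cost, r.qalys) for r in results),
        key=lambda s: (s.cost, -s.qalys))

    # strict dominance: costlier and not more effective than some alternative
    for s in strategies:
        for other in strategies:
            if other is s:
                continue
            if (other.cost <= s.cost and other.qalys >= s.qalys
                    and (other.cost < s.cost or other.qalys > s.qalys)):
                s.dominated = True
                break

    # extended dominance: iteratively drop frontier members whose ICER
    # exceeds that of the next costlier member
    def pair_icer(prev: StrategySummary, cur: StrategySummary) -> float | None:
        dq, dc = cur.qalys - prev.qalys, cur.cost - prev.cost
        if dq > 0:
            return dc / dq
        # ΔQALY <= 0: costlier-and-no-better is a dominated-equivalent
        # (flagged by the strict-dominance pass); identical strategies
        # (ΔC = ΔQ = 0) emit no ICER at all.
        return math.inf if dc > 0 else None

    def compute_frontier_icers(front: list[StrategySummary]) -> None:
        for prev, cur in zip(front, front[1:]):
            cur.comparator = prev.policy_id
            cur.icer = pair_icer(prev, cur)

    front = [s for s in strategies if not s.dominated]
    while True:
        compute_frontier_icers(front)
        removed = False
        for i in range(1, len(front) - 1):
            nxt_icer = pair_icer(front[i], front[i + 1])
            if (front[i].icer is not None and nxt_icer is not None
                    and nxt_icer < front[i].icer):
                front[i].extended_dominated = True
                front[i].icer = None
                front[i].comparator = None
                front.pop(i)
                removed = True
                break
        if not removed:
            break
    for s in strategies:
        if s.dominated:
            s.icer, s.comparator = None, None
    return IncrementalAnalysis(strategies)


# ---------------------------------------------------------------------------
# One-way sensitivity harness
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    name: str
    overrides: dict[str, object] = field(default_factory=dict)


def sensitivity_sweep(scenarios: list[Scenario], base_config: ModelConfig,
                      seed: int, policies: list[Policy] | None = None,
                      ) -> pd.DataFrame:
    """Run the full policy comparison once per scenario under the base seed.

    Each scenario overrides one or more named parameters (dotted paths into
    the config); the empty override reproduces the base run exactly.
    Returns one row per scenario with discounted cost/QALYs per policy and
    the frontier ICERs.
    """
    policies = policies or all_policies()
    rows = []
    for scenario in scenarios:
        cfg = apply_overrides(base_config, scenario.overrides)
        cohort = generate_cohort(cfg.cohort)
        results = run_comparison(cohort, policies, cfg, seed)
        analysis = incremental_icer(results)
        row: dict[str, object] = {"scenario": scenario.name}
        for pid, r in results.items():
            row[f"cost_{pid}"] = r.total_cost
            row[f"qalys_{pid}"] = r.qalys
        for s in analysis.strategies:
            row[f"icer_{s.policy_id}"] = s.icer
            row[f"dominated_{s.policy_id}"] = s.dominated or s.extended_dominated
        rows.append(row)
    return pd.DataFrame(rows)


def load_scenarios(path: str) -> list[Scenario]:
    """Read a scenario file: a YAML list of {name, overrides} mappings."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigError("scenario file must contain a list of scenarios")
    scenarios = []
    for item in raw:
        if "name" not in item:
            raise ConfigError("each scenario needs a 'name'")
        scenarios.append(Scenario(item["name"], item.get("overrides", {}) or {}))
    return scenarios


def default_scenarios() -> list[Scenario]:
    """The bundled one-way scenario set (relapse time, linkage hazard
    ratios, depression disutility, screening and collaborative-care costs)."""
    from importlib.resources import files
    path = files("diadem.data").joinpath("default_scenarios.yaml")
    return load_scenarios(str(path))
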