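"""Societal cost-utility analysis.

Incremental nonpublic sector costs are converted to QALY equivalents at the
societal threshold (default £60 000/QALY) and added to health QALYs to give
*societal QALYs*; ICERs are incremental public sector cost per societal
QALY gained between successive strategies on the strong/extended dominance
frontier.  Net benefits versus a named comparator are reported as
incremental net monetary benefit (INMB = λ·ΔQ − ΔC) and incremental net
health benefit (INHB = ΔQ − ΔC/λ) at a public threshold λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .microsim import StrategySummary

__all__ = ["CEAConfig", "StrategyPoint", "CEAResult", "societal_qalys", "icer",
           "inmb", "inhb", "dominance_frontier", "point_from_summary",
           "points_from_summaries", "ON_FRONTIER", "DOMINATED", "EXT_DOMINATED"]

ON_FRONTIER = "on-frontier"
DOMINATED = "strongly dominated"
EXT_DOMINATED = "extendedly dominated"


@dataclass(frozen=True)
class CEAConfig:
    lambda_public: float = 30000.0
    lambda_societal: float = 60000.0
    cost_basis: str = "all-cause"    # or "fall-related"

    def __post_init__(self):
        if self.lambda_public <= 0 or self.lambda_societal <= 0:
            raise ValueError("cost-effectiveness thresholds must be > 0")
        if self.cost_basis not in ("all-cause", "fall-related"):
            raise ValueError(f"unknown cost basis {self.cost_basis!r}")


def societal_qalys(health_qalys: float, net_nonpublic_cost: float,
                   lambda_societal: float) -> float:
    """Health QALYs plus the QALY equivalent of net nonpublic savings.

    A nonpublic saving (negative net cost) adds QALY equivalents.
    """
    if lambda_societal <= 0:
        raise ValueError("lambda_societal must be > 0")
    return health_qalys - net_nonpublic_cost / lambda_societal


@dataclass(frozen=True)
class StrategyPoint:
    """One strategy's aggregate (cost, QALY) position for the CEA layer."""

    strategy: str
    public_cost: float
    health_qalys: float
    net_nonpublic_cost: float = 0.0
    lambda_societal: float = 60000.0

    @property
    def societal_qalys(self) -> float:
        return societal_qalys(self.health_qalys, self.net_nonpublic_cost,
                              self.lambda_societal)


def point_from_summary(summary: StrategySummary,
                       config: CEAConfig = CEAConfig()) -> StrategyPoint:
    """Collapse a strategy summary into its societal CEA point."""
    return StrategyPoint(
        strategy=summary.strategy,
        public_cost=summary.public_cost(config.cost_basis),
        health_qalys=summary.total("qalys"),
        net_nonpublic_cost=float(summary.net_nonpublic_cost_by_quartile().sum()),
        lambda_societal=config.lambda_societal)


def points_from_summaries(summaries: dict[str, StrategySummary],
                          config: CEAConfig = CEAConfig()) -> list[StrategyPoint]:
    return [point_from_summary(s, config) for s in summaries.values()]


def icer(delta_public_cost: float, delta_societal_qalys: float) -> int:
    """Incremental public cost per societal QALY gained, to the nearest pound.

    Callers must screen dominance first: a non-positive QALY increment has
    no meaningful ICER.
    """
    if delta_societal_qalys <= 0:
        raise ValueError("ICER requires a positive societal QALY increment; "
                         "screen for dominance first")
    return int(round(delta_public_cost / delta_societal_qalys))


def inmb(delta_societal_qalys: float, delta_public_cost: float,
         lambda_public: float) -> float:
    """Incremental net monetary benefit, GBP: λ·ΔQ − ΔC."""
    if lambda_public <= 0:
        raise ValueError("lambda_public must be > 0")
    return lambda_public * delta_societal_qalys - delta_public_cost


def inhb(delta_societal_qalys: float, delta_public_cost: float,
         lambda_public: float) -> float:
    """Incremental net health benefit, QALYs: ΔQ − ΔC/λ."""
    if lambda_public <= 0:
        raise ValueError("lambda_public must be > 0")
    return delta_societal_qalys - delta_public_cost / lambda_public


@dataclass
class CEAResult:
    """Dominance classification and frontier ICERs for a set of strategies."""

    classification: dict[str, str]        # strategy -> ON_FRONTIER / DOMINATED / ...
    frontier: list[str]                   # on-frontier strategies by increasing cost
    comparator: dict[str, str | None]     # frontier strategy -> next-cheapest
    icers: dict[str, float | None]        # frontier strategy -> full-precision ICER
    points: dict[str, StrategyPoint]

    def icer_rounded(self, strategy: str) -> int | None:
        value = self.icers.get(strategy)
        return None if value is None else int(round(value))

    def table(self, lambda_public: float | None = None,
              baseline: str | None = None) -> pd.DataFrame:
        """Tabular layout: strategy, incrementals vs a baseline, ICER, status.

        ``baseline`` defaults to the cheapest frontier strategy.  When a
        public threshold is given, INMB and INHB versus the baseline are
        appended.
        """
        if baseline is None:
            baseline = self.frontier[0]
        base = self.points[baseline]
        rows = []
        ordered = sorted(self.points.values(), key=lambda p: p.public_cost)
        for pt in ordered:
            dq = pt.societal_qalys - base.societal_qalys
            dc = pt.public_cost - base.public_cost
            on = self.classification[pt.strategy] == ON_FRONTIER
            row = {
                "strategy": pt.strategy,
                "incremental_public_cost": round(dc),
                "incremental_societal_qalys": round(dq, 4),
                "icer": self.icer_rounded(pt.strategy) if on else None,
                "comparator": self.comparator.get(pt.strategy) if on else None,
                "classification": self.classification[pt.strategy],
            }
            if lambda_public is not None:
                row["inmb"] = inmb(dq, dc, lambda_public)
                row["inhb"] = inhb(dq, dc, lambda_public)
            rows.append(row)
        return pd.DataFrame(rows)


def dominance_frontier(points: list[StrategyPoint]) -> CEAResult:
    """Classify strategies by strong and extended dominance.

    Strong dominance: another strategy has no higher cost and no lower
    societal QALYs, with at least one strict; exact cost-and-QALY ties keep
    the lexicographically first name.  Extended dominance is then removed
    iteratively until sequential ICERs strictly increase along the frontier.
    """
    if len(points) < 2:
        raise ValueError("dominance analysis needs at least 2 strategies")
    names = [p.strategy for p in points]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be unique")

    pts = {p.strategy: (p.public_cost, p.societal_qalys) for p in points}
    classification: dict[str, str] = {}
    for name, (c, q) in pts.items():
        for other, (c2, q2) in pts.items():
            if other == name:
                continue
            if c2 == c and q2 == q:
                if other < name:           # deterministic tie-break
                    classification[name] = DOMINATED
                    break
                continue
            if c2 <= c and q2 >= q:
                classification[name] = DOMINATED
                break

    survivors = sorted((n for n in pts if n not in classification),
                       key=lambda n: (pts[n][0], n))
    # survivors have strictly increasing cost and QALYs; peel extended dominance
    while True:
        icers = [(pts[b][0] - pts[a][0]) / (pts[b][1] - pts[a][1])
                 for a, b in zip(survivors, survivors[1:])]
        bad = next((i for i in range(len(icers) - 1)
                    if icers[i] >= icers[i + 1]), None)
        if bad is None:
            break
        classification[survivors[bad + 1]] = EXT_DOMINATED
        del survivors[bad + 1]

    for name in survivors:
        classification[name] = ON_FRONTIER
    comparator: dict[str, str | None] = {survivors[0]: None}
    icer_map: dict[str, float | None] = {survivors[0]: None}
    for a, b in zip(survivors, survivors[1:]):
        comparator[b] = a
        icer_map[b] = (pts[b][0] - pts[a][0]) / (pts[b][1] - pts[a][1])
    return CEAResult(classification=classification, frontier=survivors,
                     comparator=comparator, icers=icer_map,
                     points={p.strategy: p for p in points})
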