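"""Alternative scenarios and deterministic multi-seed scenario runs.

Eight ±20% scenarios around the main analysis: baseline frailty, frailty
progression rate, cognitive-impairment incidence, intervention demand
(recommended-level rates only — usual-care rates never change) and GP
access rate.  Scenario outcomes are deterministic in the sense of using
point-estimate parameters; first-order (individual-level) variability is
averaged out by re-running with several seeds (default 10) and averaging
the summaries, which are then fed to the CEA and DCEA layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stream_seed
from .cea import CEAConfig, CEAResult, dominance_frontier, points_from_summaries
from .dcea import DCEAConfig, dcea_table
from .microsim import (OUTCOME_FIELDS, STRATEGY_NAMES, StrategySummary,
                       make_strategy, run_strategy)
from .parameters import PATHWAYS, ParameterSet
from .population import PopulationSpec

__all__ = ["Scenario", "SCENARIOS", "get_scenario", "apply_scenario",
           "average_summaries", "deterministic_scenario_run", "ScenarioResult"]


@dataclass(frozen=True)
class Scenario:
    """A named ±20% modification of one model knob."""

    name: str
    knob: str          # baseline_frailty | frailty_progression | cognitive_incidence
    #                    | demand | gp_access | none
    multiplier: float  # 0.8, 1.0 or 1.2

    def __post_init__(self):
        if self.multiplier not in (0.8, 1.0, 1.2):
            raise ValueError("scenario multiplier must be 0.8, 1.0 or 1.2")


def _build_catalogue() -> dict[str, Scenario]:
    catalogue = {"main": Scenario("main", "none", 1.0)}
    for knob in ("frailty_baseline", "frailty_progression",
                 "cognitive_incidence", "demand", "gp_access"):
        target = "baseline_frailty" if knob == "frailty_baseline" else knob
        catalogue[f"{knob}_up20"] = Scenario(f"{knob}_up20", target, 1.2)
        catalogue[f"{knob}_down20"] = Scenario(f"{knob}_down20", target, 0.8)
    return catalogue


SCENARIOS: dict[str, Scenario] = _build_catalogue()


def get_scenario(name: str) -> Scenario:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid names: "
                         f"{', '.join(sorted(SCENARIOS))}")
    return SCENARIOS[name]


def apply_scenario(params: ParameterSet, scenario: Scenario | str) -> ParameterSet:
    """A modified copy of the parameter set; the input is never mutated.

    Demand scenarios scale recommended-level demand only, so usual-care
    access stays bit-identical across all demand scenarios; probabilities
    are capped at 1.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    out = params.copy()
    m = scenario.multiplier
    if scenario.knob == "none":
        pass
    elif scenario.knob == "baseline_frailty":
        out.adjustments.baseline_frailty = params.adjustments.baseline_frailty * m
    elif scenario.knob == "frailty_progression":
        out.adjustments.frailty_progression = params.adjustments.frailty_progression * m
    elif scenario.knob == "cognitive_incidence":
        out.adjustments.cognitive_incidence = params.adjustments.cognitive_incidence * m
    elif scenario.knob == "demand":
        for pw in PATHWAYS:
            acc = getattr(out.access_params, pw)
            acc.demand_recommended = min(1.0, acc.demand_recommended * m)
    elif scenario.knob == "gp_access":
        out.access_params.gp_access_rate = min(
            1.0, out.access_params.gp_access_rate * m)
    else:  # pragma: no cover - catalogue is closed
        raise ValueError(f"unknown scenario knob {scenario.knob!r}")
    return out.validate()


def average_summaries(per_seed: list[dict[str, StrategySummary]]
                      ) -> dict[str, StrategySummary]:
    """Fieldwise arithmetic mean of strategy summaries across seeds."""
    if not per_seed:
        raise ValueError("need at least one seed's summaries")
    strategies = list(per_seed[0])
    out = {}
    for name in strategies:
        items = [d[name] for d in per_seed]
        out[name] = StrategySummary(
            strategy=name,
            persons=np.mean([s.persons for s in items], axis=0),
            **{f: np.mean([getattr(s, f) for s in items], axis=0)
               for f in OUTCOME_FIELDS})
    return out


@dataclass
class ScenarioResult:
    scenario: Scenario
    seeds: tuple[int, ...]
    summaries: dict[str, StrategySummary]   # averaged over seeds
    cea: CEAResult
    dcea: "object"                          # pandas DataFrame from dcea_table


def deterministic_scenario_run(
    params: ParameterSet, scenario: Scenario | str,
    strategies: tuple[str, ...] = STRATEGY_NAMES,
    population_spec: PopulationSpec = PopulationSpec(),
    n_seeds: int = 10, master_seed: int = 0,
    horizon: int | None = None,
    cea_config: CEAConfig = CEAConfig(),
    dcea_config: DCEAConfig = DCEAConfig(),
    dcea_families: tuple[str, ...] = ("atkinson",),
) -> ScenarioResult:
    """Point-estimate run of every strategy under a scenario, averaged over seeds.

    The seed list derives only from ``master_seed``, so every scenario
    re-uses the same seeds as the main analysis.  Within one seed all
    strategies run under common random numbers.
    """
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1 (got {n_seeds})")
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    scen_params = apply_scenario(params, scenario)
    seeds = tuple(stream_seed(master_seed, "scenario-seed", k)
                  for k in range(n_seeds))
    per_seed = []
    for seed in seeds:
        per_seed.append({name: run_strategy(
            scen_params, make_strategy(name, scen_params),
            population_spec, seed, horizon) for name in strategies})
    avg = average_summaries(per_seed)
    cea = dominance_frontier(points_from_summaries(avg, cea_config))
    table = dcea_table(avg, dcea_config, families=dcea_families)
    return ScenarioResult(scenario=scenario, seeds=seeds, summaries=avg,
                          cea=cea, dcea=table)
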