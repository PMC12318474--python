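"""Probabilistic sensitivity analysis (PSA) orchestration.

Each run draws one parameter set from the second-order uncertainty
distributions and simulates every strategy under common random numbers
within the run; expected outcomes are the arithmetic means across runs.
The cost-effectiveness acceptability curve (CEAC) gives, per public
threshold λ, the probability that each strategy has the highest net
monetary benefit (NMB = λ·societal QALYs − public cost); the acceptability
frontier (CEAF) marks the strategy with the highest *expected* NMB at each
λ.  Societal QALYs hold the societal threshold constant (default £60 000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_seed
from .cea import CEAConfig, StrategyPoint, societal_qalys
from .microsim import (OUTCOME_FIELDS, STRATEGY_NAMES, StrategySummary,
                       make_strategy, run_strategy)
from .parameters import ParameterSet
from .population import PopulationSpec
from .sampling import PSADistributionSpec, sample_psa_parameters

__all__ = ["PSAResult", "CEACTable", "run_psa", "expected_outcomes",
           "ceac_ceaf", "ceac_from_points", "incremental_scatter",
           "default_lambda_grid"]


def default_lambda_grid() -> np.ndarray:
    """£0-£50 000 in £500 steps (plotting grid for CEAC/CEAF)."""
    return np.arange(0.0, 50001.0, 500.0)


@dataclass
class PSAResult:
    """Per-run, per-strategy, per-quartile discounted outcomes.

    ``frame`` has one row per (run, strategy, quartile 1-4); totals are the
    quartile sums.  ``seeds`` records the per-run simulation seeds.
    """

    frame: pd.DataFrame
    strategies: tuple[str, ...]
    n_runs: int
    seeds: tuple[int, ...] = ()         # per-run parameter-draw seeds
    sim_seed: int = 0                   # shared first-order simulation seed
    cost_basis: str = "all-cause"

    def validate(self) -> "PSAResult":
        runs = self.frame["run"].nunique()
        if runs != self.n_runs:
            raise ValueError(f"expected {self.n_runs} runs, found {runs}")
        per_run = self.frame.groupby("run")["strategy"].nunique()
        if (per_run != len(self.strategies)).any():
            raise ValueError("every run must contain every strategy")
        if self.seeds and len(set(self.seeds)) != len(self.seeds):
            raise ValueError("run seeds must be distinct")
        return self

    def totals(self) -> pd.DataFrame:
        """One row per (run, strategy), quartiles summed."""
        cols = ["persons", *OUTCOME_FIELDS]
        return (self.frame.groupby(["run", "strategy"], sort=False)[cols]
                .sum().reset_index())

    def points(self, lambda_societal: float = 60000.0) -> pd.DataFrame:
        """Per-run strategy points: public cost, health and societal QALYs."""
        tot = self.totals()
        tot["public_cost"] = tot["cost_public_allcause"] + tot["cost_int_public"]
        if self.cost_basis == "fall-related":
            tot["public_cost"] = tot["cost_public_fall"] + tot["cost_int_public"]
        tot["net_nonpublic_cost"] = (
            tot["cost_oop"] + tot["cost_informal"] + tot["cost_int_copay"]
            + tot["cost_int_participant_time"] + tot["cost_int_caregiver_time"]
            - tot["value_prod_paid"] - tot["value_prod_unpaid"])
        tot["health_qalys"] = tot["qalys"]
        tot["societal_qalys"] = societal_qalys(
            tot["health_qalys"], tot["net_nonpublic_cost"], lambda_societal)
        return tot[["run", "strategy", "public_cost", "health_qalys",
                    "net_nonpublic_cost", "societal_qalys"]]


def run_psa(base_params: ParameterSet, spec: PSADistributionSpec,
            strategies: tuple[str, ...] = STRATEGY_NAMES, n_runs: int = 800,
            master_seed: int = 0,
            population_spec: PopulationSpec = PopulationSpec(),
            horizon: int | None = None) -> PSAResult:
    """Run the PSA: ``n_runs`` parameter draws × all strategies.

    Every strategy in every run shares one simulation seed, so first-order
    (individual-level) variability is held fixed and run-to-run differences
    isolate second-order parameter uncertainty; the per-run parameter-draw
    seeds are distinct.  Deterministic given ``master_seed``.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1 (got {n_runs})")
    rows = []
    seeds = []
    sim_seed = stream_seed(master_seed, "psa-sim")
    for i in range(n_runs):
        draw_seed = stream_seed(master_seed, "psa-draw", i)
        seeds.append(draw_seed)
        params_i = sample_psa_parameters(spec, base_params, draw_seed)
        for name in strategies:
            summary = run_strategy(params_i, make_strategy(name, params_i),
                                   population_spec, sim_seed, horizon)
            for g in range(4):
                row = {"run": i, "strategy": name, "quartile": g + 1,
                       "persons": int(summary.persons[g])}
                row.update({f: float(getattr(summary, f)[g])
                            for f in OUTCOME_FIELDS})
                rows.append(row)
    return PSAResult(frame=pd.DataFrame(rows), strategies=tuple(strategies),
                     n_runs=n_runs, seeds=tuple(seeds),
                     sim_seed=sim_seed).validate()


def expected_outcomes(psa: PSAResult) -> dict[str, StrategySummary]:
    """Arithmetic mean of every outcome field across runs, per strategy."""
    if psa.n_runs < 1:
        raise ValueError("expected_outcomes needs at least one run")
    cols = ["persons", *OUTCOME_FIELDS]
    mean = (psa.frame.groupby(["strategy", "quartile"], sort=False)[cols]
            .mean().reset_index())
    out = {}
    for name in psa.strategies:
        grp = mean[mean["strategy"] == name].sort_values("quartile")
        out[name] = StrategySummary(
            strategy=name, persons=grp["persons"].to_numpy(),
            **{f: grp[f].to_numpy() for f in OUTCOME_FIELDS})
    return out


def expected_points(psa: PSAResult,
                    config: CEAConfig = CEAConfig()) -> list[StrategyPoint]:
    """Strategy points of the expected (mean) outcomes."""
    pts = psa.points(config.lambda_societal)
    mean = pts.groupby("strategy", sort=False).mean(numeric_only=True)
    return [StrategyPoint(strategy=name,
                          public_cost=row["public_cost"],
                          health_qalys=row["health_qalys"],
                          net_nonpublic_cost=row["net_nonpublic_cost"],
                          lambda_societal=config.lambda_societal)
            for name, row in mean.iterrows()]


@dataclass
class CEACTable:
    """CEAC probabilities and the CEAF strategy per threshold λ."""

    frame: pd.DataFrame                 # columns: lambda, <one per strategy>, ceaf
    strategies: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> "CEACTable":
        probs = self.frame[list(self.strategies)].to_numpy()
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("CEAC probabilities must sum to 1 at every lambda")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("CEAC probabilities must lie in [0, 1]")
        return self


def ceac_from_points(points: pd.DataFrame, lambda_grid: np.ndarray,
                     strategies: tuple[str, ...] | None = None) -> CEACTable:
    """CEAC/CEAF from a per-run strategy-point table.

    ``points`` needs columns run, strategy, public_cost, societal_qalys.
    Per run and λ the winner maximises NMB; exact ties split the count
    equally.  The CEAF strategy maximises the *mean* NMB over runs.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0 or np.any(lam < 0) or np.any(np.diff(lam) < 0):
        raise ValueError("lambda grid must be nonempty, nonnegative and sorted")
    wide_q = points.pivot(index="run", columns="strategy", values="societal_qalys")
    wide_c = points.pivot(index="run", columns="strategy", values="public_cost")
    if strategies is None:
        strategies = tuple(wide_q.columns)
    q = wide_q[list(strategies)].to_numpy()      # runs × strategies
    c = wide_c[list(strategies)].to_numpy()
    n_runs = q.shape[0]
    rows = []
    for lmb in lam:
        nmb = lmb * q - c
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        ceaf = strategies[int(np.argmax(nmb.mean(axis=0)))]
        row = {"lambda": lmb, **dict(zip(strategies, probs)), "ceaf": ceaf}
        rows.append(row)
    table = CEACTable(frame=pd.DataFrame(rows), strategies=tuple(strategies))
    table.n_runs = n_runs
    return table.validate()


def ceac_ceaf(psa: PSAResult, lambda_grid: np.ndarray | None = None,
              lambda_societal: float = 60000.0) -> CEACTable:
    """CEAC and CEAF of a PSA result over a public-threshold grid."""
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    return ceac_from_points(psa.points(lambda_societal), lambda_grid,
                            psa.strategies)


def incremental_scatter(psa: PSAResult, comparator: str = "UC",
                        lambda_societal: float = 60000.0) -> pd.DataFrame:
    """Per-run (Δsocietal QALY, Δpublic cost) pairs versus a comparator."""
    pts = psa.points(lambda_societal)
    if comparator not in set(pts["strategy"]):
        raise ValueError(f"comparator {comparator!r} not present in PSA runs")
    base = (pts[pts["strategy"] == comparator]
            .set_index("run")[["public_cost", "societal_qalys"]])
    others = pts[pts["strategy"] != comparator].copy()
    others["delta_societal_qalys"] = (
        others["societal_qalys"].to_numpy()
        - base.loc[others["run"], "societal_qalys"].to_numpy())
    others["delta_public_cost"] = (
        others["public_cost"].to_numpy()
        - base.loc[others["run"], "public_cost"].to_numpy())
    return others[["run", "strategy", "delta_societal_qalys",
                   "delta_public_cost"]].reset_index(drop=True)
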