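"""Distributional cost-effectiveness analysis (DCEA) across SES quartiles.

The outcome of interest is the per-capita societal net health benefit (NHB)
accruing to each socioeconomic quartile:

    NHB_g = (QALYs_g − nonpublic net cost_g / λ_soc − public cost_g / λ_pub) / n_g

The equally distributed equivalent (EDE) collapses the quartile
distribution into the uniform level a social welfare function deems
equivalent.  Two standard families are provided: the Atkinson EDE
(relative, scale-invariant inequality aversion ε) and the Kolm EDE
(absolute, translation-invariant aversion α).  The strategy with the
highest EDE NHB is optimal on efficiency and equity combined; incremental
EDE NHB (EDE INHB) versus a comparator above 0 favours the strategy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .microsim import StrategySummary

__all__ = ["DCEAConfig", "per_capita_nhb_by_quartile", "atkinson_ede",
           "kolm_ede", "ede_inhb", "dcea_table", "optimal_strategy",
           "progressivity"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DCEAConfig:
    epsilons: tuple[float, ...] = (0.0, 5.0, 11.0, 15.0, 20.0, 30.0)
    alphas: tuple[float, ...] = (0.05, 0.15, 0.5, 1.0)
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lambdas_public: tuple[float, ...] = (20000.0, 30000.0)
    lambda_societal: float = 60000.0
    comparator: str = "UC"

    def __post_init__(self):
        if any(e < 0 for e in self.epsilons):
            raise ValueError("Atkinson epsilon must be >= 0")
        if any(a <= 0 for a in self.alphas):
            raise ValueError("Kolm alpha must be > 0")
        w = np.asarray(self.weights)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("quartile weights must be positive and sum to 1")


def per_capita_nhb_by_quartile(summary: StrategySummary, lambda_public: float,
                               lambda_societal: float = 60000.0,
                               cost_basis: str = "all-cause") -> np.ndarray:
    """Per-capita societal NHB (QALYs) for quartiles 1..4."""
    if np.any(summary.persons <= 0):
        raise ValueError("every quartile needs at least one simulated person")
    if lambda_public <= 0 or lambda_societal <= 0:
        raise ValueError("thresholds must be > 0")
    nhb = (summary.qalys
           - summary.net_nonpublic_cost_by_quartile() / lambda_societal
           - summary.public_cost_by_quartile(cost_basis) / lambda_public)
    return nhb / summary.persons


def atkinson_ede(values: Sequence[float], weights: Sequence[float],
                 epsilon: float) -> float:
    """Atkinson equally distributed equivalent at relative aversion ε.

    ε = 0 gives the weighted mean, ε = 1 the weighted geometric mean,
    otherwise ``(Σ w x^(1−ε))^(1/(1−ε))``.  Requires strictly positive
    values for ε > 0; use the Kolm index for distributions with
    non-positive outcomes.
    """
    x = np.asarray(values, dtype=float)
    w = _check_weights(weights, x)
    if epsilon < 0:
        raise ValueError("Atkinson epsilon must be >= 0")
    if epsilon == 0:
        return float(w @ x)
    if np.any(x <= 0):
        raise ValueError("Atkinson EDE requires strictly positive values for "
                         "epsilon > 0; use the Kolm index for non-positive "
                         "outcomes")
    if epsilon == 1:
        return float(np.exp(w @ np.log(x)))
    power = 1.0 - epsilon
    return float((w @ x ** power) ** (1.0 / power))


def kolm_ede(values: Sequence[float], weights: Sequence[float],
             alpha: float) -> float:
    """Kolm equally distributed equivalent at absolute aversion α > 0:
    ``−(1/α)·ln(Σ w exp(−α x))``; accepts any real values."""
    x = np.asarray(values, dtype=float)
    w = _check_weights(weights, x)
    if alpha <= 0:
        raise ValueError("Kolm alpha must be > 0")
    # shift for numerical stability; the Kolm EDE is translation-equivariant
    shift = x.max()
    return float(shift - np.log(w @ np.exp(-alpha * (x - shift))) / alpha)


def _check_weights(weights, x) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be positive and sum to 1")
    return w


def ede_inhb(ede_by_strategy: Mapping[str, float], comparator: str
             ) -> dict[str, float]:
    """Incremental EDE NHB of every strategy versus the comparator."""
    if comparator not in ede_by_strategy:
        raise ValueError(f"comparator {comparator!r} missing from EDE table")
    base = ede_by_strategy[comparator]
    return {name: ede - base for name, ede in ede_by_strategy.items()}


def dcea_table(summaries: Mapping[str, StrategySummary],
               config: DCEAConfig = DCEAConfig(),
               families: tuple[str, ...] = ("atkinson", "kolm"),
               cost_basis: str = "all-cause") -> pd.DataFrame:
    """EDE NHB and EDE INHB per strategy × inequality index × threshold.

    Columns: strategy, lambda_public, index_family, index_value, ede_nhb,
    ede_inhb (versus the configured comparator) and an optimal flag marking
    the EDE-maximising strategy per (family, index, λ) row group.
    """
    if config.comparator not in summaries:
        raise ValueError(f"comparator {config.comparator!r} missing")
    indices = []
    if "atkinson" in families:
        indices += [("atkinson", e) for e in config.epsilons]
    if "kolm" in families:
        indices += [("kolm", a) for a in config.alphas]
    rows = []
    for lam in config.lambdas_public:
        nhb = {name: per_capita_nhb_by_quartile(
                   s, lam, config.lambda_societal, cost_basis)
               for name, s in summaries.items()}
        for family, value in indices:
            ede = {}
            for name, quartiles in nhb.items():
                if family == "atkinson":
                    ede[name] = atkinson_ede(quartiles, config.weights, value)
                else:
                    ede[name] = kolm_ede(quartiles, config.weights, value)
            incr = ede_inhb(ede, config.comparator)
            best = optimal_strategy(ede)
            for name in summaries:
                rows.append({
                    "strategy": name, "lambda_public": lam,
                    "index_family": family, "index_value": value,
                    "ede_nhb": ede[name], "ede_inhb": incr[name],
                    "optimal": name == best,
                })
    return pd.DataFrame(rows)


def optimal_strategy(ede_by_strategy: Mapping[str, float]) -> str:
    """The EDE-maximising strategy; exact ties resolve lexicographically."""
    best = max(ede_by_strategy.values())
    winners = sorted(n for n, v in ede_by_strategy.items() if v == best)
    if len(winners) > 1:
        logger.warning("EDE tie between %s; keeping %s", winners, winners[0])
    return winners[0]


def progressivity(inhb_by_quartile: Sequence[float]) -> str:
    """Classify a quartile INHB profile (ordered least -> most deprived).

    Strictly increasing magnitude toward deprivation is unambiguously
    progressive; strictly decreasing is unambiguously regressive; anything
    else is mixed.
    """
    x = np.asarray(inhb_by_quartile, dtype=float)
    if x.shape != (4,):
        raise ValueError("expected four quartile values")
    d = np.diff(x)
    if np.all(d > 0):
        return "unambiguously progressive"
    if np.all(d < 0):
        return "unambiguously regressive"
    return "mixed"
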