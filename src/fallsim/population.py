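"""Synthetic cohorts of community-dwelling adults aged 60 and over.

The baseline cohort mixes ages over 60-95 with an exponential-decay mass;
annual entry cohorts are aged exactly 60.  Socioeconomic-status (SES)
quartiles are equally sized by construction.  Baseline frailty is drawn
from a scaled Beta distribution with an age trend, then modified by the SES
frailty gradient, which in turn shifts the prevalence of falls history,
low physical activity, cognitive impairment, fear of falling and abnormal
gait/balance through their frailty-linked prevalence equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .parameters import CharacteristicPrevalence, ParameterSet

__all__ = ["Individual", "Cohort", "PopulationSpec",
           "generate_baseline_cohort", "generate_entry_cohort"]

#: column order of the per-individual table (CSV export contract)
INDIVIDUAL_FIELDS = (
    "id", "age", "sex", "ses_quartile", "falls_history", "frailty",
    "physical_activity_low", "cognitive_impairment", "fear_of_falling",
    "abnormal_gait_balance", "alive", "in_ltc", "entry_year",
)


@dataclass
class Individual:
    """One simulated person's state at a point in model time."""

    id: int
    age: float
    sex: str                       # "F" or "M"
    ses_quartile: int              # 1 least deprived ... 4 most deprived
    falls_history: bool
    frailty: float                 # 0-100 cumulative-deficit index
    physical_activity_low: bool
    cognitive_impairment: bool
    fear_of_falling: bool
    abnormal_gait_balance: bool
    alive: bool = True
    in_ltc: bool = False
    entry_year: int = 0
    # discounted accumulators
    qalys: float = 0.0
    cost_public_allcause: float = 0.0
    cost_public_fall: float = 0.0
    cost_oop: float = 0.0
    value_prod_paid: float = 0.0
    value_prod_unpaid: float = 0.0
    cost_informal: float = 0.0
    cost_int_public: float = 0.0
    cost_int_copay: float = 0.0
    cost_int_participant_time: float = 0.0
    cost_int_caregiver_time: float = 0.0


class Cohort:
    """A column-oriented sequence of :class:`Individual`.

    Backed by numpy arrays for the simulation engine; indexing materialises
    an :class:`Individual` view for the per-person operation surface.
    """

    def __init__(self, arrays: dict[str, np.ndarray], created_cycle: int, seed: int):
        n = len(arrays["id"])
        for k, v in arrays.items():
            if len(v) != n:
                raise ValueError(f"column {k!r} has length {len(v)} != {n}")
        self.arrays = arrays
        self.created_cycle = created_cycle
        self.seed = seed

    def __len__(self) -> int:
        return len(self.arrays["id"])

    def __getitem__(self, i: int) -> Individual:
        a = self.arrays
        return Individual(
            id=int(a["id"][i]), age=float(a["age"][i]),
            sex="F" if a["female"][i] else "M",
            ses_quartile=int(a["ses_quartile"][i]),
            falls_history=bool(a["falls_history"][i]),
            frailty=float(a["frailty"][i]),
            physical_activity_low=bool(a["physical_activity_low"][i]),
            cognitive_impairment=bool(a["cognitive_impairment"][i]),
            fear_of_falling=bool(a["fear_of_falling"][i]),
            abnormal_gait_balance=bool(a["abnormal_gait_balance"][i]),
            entry_year=int(a["entry_year"][i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def to_frame(self) -> pd.DataFrame:
        """One row per individual, columns exactly the Individual state fields."""
        a = self.arrays
        n = len(self)
        return pd.DataFrame({
            "id": a["id"],
            "age": a["age"],
            "sex": np.where(a["female"], "F", "M"),
            "ses_quartile": a["ses_quartile"],
            "falls_history": a["falls_history"].astype(int),
            "frailty": a["frailty"],
            "physical_activity_low": a["physical_activity_low"].astype(int),
            "cognitive_impairment": a["cognitive_impairment"].astype(int),
            "fear_of_falling": a["fear_of_falling"].astype(int),
            "abnormal_gait_balance": a["abnormal_gait_balance"].astype(int),
            "alive": np.ones(n, dtype=int),
            "in_ltc": np.zeros(n, dtype=int),
            "entry_year": a["entry_year"],
        }, columns=list(INDIVIDUAL_FIELDS))


@dataclass(frozen=True)
class PopulationSpec:
    """Baseline and annual-entry cohort sizes for one simulation run.

    The default keeps the simulated 60+ population roughly stationary:
    annual entries of 3% of the baseline size approximately replace deaths
    given the mortality schedule.
    """

    n_baseline: int = 20000
    entry_size: int | None = None
    entry_fraction: float = 0.03

    def resolved_entry_size(self) -> int:
        if self.entry_size is not None:
            return int(self.entry_size)
        return int(round(self.entry_fraction * self.n_baseline))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _prevalence(p: CharacteristicPrevalence, age: np.ndarray, frailty: np.ndarray):
    return _sigmoid(p.intercept + p.age_slope * (age - 60.0)
                    + p.frailty_slope * frailty / 100.0)


def _equal_quartiles(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quartile labels 1..4, equally sized (±1), randomly interleaved."""
    base, extra = divmod(n, 4)
    counts = [base + (1 if q < extra else 0) for q in range(4)]
    labels = np.repeat(np.arange(1, 5), counts)
    rng.shuffle(labels)
    return labels.astype(np.int8)


def _draw_cohort(n: int, ages: np.ndarray, params: ParameterSet, seed: int,
                 entry_year: int) -> Cohort:
    rng = np.random.default_rng(seed)
    pop = params.population
    ses = _equal_quartiles(n, rng)
    female = rng.random(n) < pop.female_prob
    frailty_mult = np.asarray(params.ses_gradients.frailty)[ses - 1]
    base_frailty = rng.beta(pop.frailty_beta_a, pop.frailty_beta_b, n) * pop.frailty_scale
    frailty = (base_frailty
               * (1.0 + pop.frailty_age_slope * (ages - 60.0))
               * frailty_mult
               * params.adjustments.baseline_frailty)
    frailty = np.clip(frailty, 0.0, 100.0)
    cols = {
        "id": np.arange(n, dtype=np.int64),
        "age": ages.astype(np.float64),
        "female": female,
        "ses_quartile": ses,
        "frailty": frailty,
        "entry_year": np.full(n, entry_year, dtype=np.int32),
    }
    for name in ("falls_history", "physical_activity_low", "cognitive_impairment",
                 "fear_of_falling", "abnormal_gait_balance"):
        prev_name = "low_activity" if name == "physical_activity_low" else name
        p = _prevalence(getattr(pop, prev_name), ages, frailty)
        cols[name] = rng.random(n) < p
    return Cohort(cols, created_cycle=entry_year, seed=seed)


def generate_baseline_cohort(n: int, params: ParameterSet, seed: int) -> Cohort:
    """A baseline cohort of ``n`` community-dwelling adults aged 60+.

    Ages follow a truncated-exponential mass over 60 to ``population.max_age``;
    all members are alive and community-dwelling at creation.
    """
    if n < 1:
        raise ValueError(f"baseline cohort size must be >= 1 (got {n})")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
    pop = params.population
    span = pop.max_age - 60.0
    scale = pop.age_exponential_scale
    # inverse-CDF draw of an exponential truncated to [0, span]
    u = rng.random(n) * -np.expm1(-span / scale)
    ages = 60.0 - scale * np.log1p(-u)
    return _draw_cohort(n, ages, params, seed, entry_year=0)


def generate_entry_cohort(cycle: int, n: int, params: ParameterSet, seed: int) -> Cohort:
    """An entry cohort of ``n`` individuals aged exactly 60 entering at ``cycle``."""
    if cycle < 1:
        raise ValueError(f"entry cycle must be >= 1 (got {cycle})")
    if n < 0:
        raise ValueError(f"entry cohort size must be >= 0 (got {n})")
    ages = np.full(n, 60.0)
    return _draw_cohort(n, ages, params, seed, entry_year=cycle)
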