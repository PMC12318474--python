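"""Annual-cycle individual simulation of falls, frailty and care pathways.

One run simulates a baseline cohort of community-dwelling adults aged 60+
plus one entry cohort of 60-year-olds per cycle, under a named strategy
that sets the provision level (usual vs recommended) of the three falls
prevention pathways:

* **R** (reactive): referral after a medically attended (MA) fall in the
  previous cycle;
* **P** (proactive): risk screening at GP contact — positive when falls
  history and abnormal gait/balance co-occur (conjunction by default);
* **SR** (self-referred): open to every community-dwelling person, uptake
  governed by demand.

Within each cycle events occur in a fixed order: intervention assignment,
mortality (fatal fall, then other-cause), nonfatal fall classification for
survivors, accrual of that cycle's utility and costs (discounted to the
cycle index), frailty and time-varying characteristic updates, and finally
long-term care (LTC) admission.  Death and LTC admission are absorbing
exits.  Each MA fall carries a 28% hospitalisation probability; the
hospitalised MA fall is costed at hip-fracture level.

All stochastic draws are counter-based on ``(seed, person id, cycle,
event)``, so the eight strategies are compared under common random
numbers: with a null intervention (relative risk 1, zero costs) every
strategy produces bit-identical summaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import event_uniform, stream_seed
from .parameters import PATHWAYS, ParameterSet
from .population import (Cohort, Individual, PopulationSpec,
                         generate_baseline_cohort, generate_entry_cohort)

__all__ = [
    "FallerType", "StrategyConfig", "CycleEvent", "StrategySummary",
    "STRATEGY_NAMES", "make_strategy", "run_strategy", "discount_factor",
    "fall_probability", "classify_faller", "mortality_step", "update_frailty",
    "update_time_varying", "ltc_admission", "cycle_outcomes",
    "eligible_reactive", "eligible_proactive", "eligible_self_referred",
    "assign_intervention",
]


class FallerType(enum.IntEnum):
    """Nonfatal faller type of a surviving person-cycle (exhaustive, exclusive)."""

    NO_FALL = 0
    SINGLE_NON_MA = 1
    SINGLE_MA = 2
    RECURRENT_NON_MA = 3
    RECURRENT_WITH_MA = 4


#: parameter-dictionary key per fall-bearing type
FALL_TYPE_KEY = {
    FallerType.SINGLE_NON_MA: "single_non_ma",
    FallerType.SINGLE_MA: "single_ma",
    FallerType.RECURRENT_NON_MA: "recurrent_non_ma",
    FallerType.RECURRENT_WITH_MA: "recurrent_with_ma",
}

STRATEGY_NAMES = ("UC", "R", "P", "SR", "R+P", "R+SR", "P+SR", "RC")


@dataclass(frozen=True)
class StrategyConfig:
    """Provision levels and access probabilities of the three pathways."""

    name: str
    levels: dict[str, str]          # pathway -> "usual" | "recommended"
    supply: dict[str, float]        # pathway -> supply probability
    demand: dict[str, float]        # pathway -> demand probability
    precedence: tuple[str, ...] = ("R", "P", "SR")
    screening_rule: str = "and"

    def validate(self) -> "StrategyConfig":
        for pw in PATHWAYS:
            if self.levels.get(pw) not in ("usual", "recommended"):
                raise ValueError(f"strategy {self.name!r}: pathway {pw} level must "
                                 "be 'usual' or 'recommended'")
            if self.levels[pw] == "recommended" and self.supply[pw] != 1.0:
                raise ValueError(f"strategy {self.name!r}: recommended pathway {pw} "
                                 "must have supply probability 1")
            if not 0.0 <= self.supply[pw] <= 1.0 or not 0.0 <= self.demand[pw] <= 1.0:
                raise ValueError(f"strategy {self.name!r}: pathway {pw} supply/demand "
                                 "must be probabilities")
        if sorted(self.precedence) != sorted(PATHWAYS):
            raise ValueError(f"strategy {self.name!r}: precedence must permute R, P, SR")
        if self.name == "RC" and any(v != "recommended" for v in self.levels.values()):
            raise ValueError("RC must set every pathway to recommended")
        if self.name == "UC" and any(v != "usual" for v in self.levels.values()):
            raise ValueError("UC must set every pathway to usual")
        return self


def make_strategy(name: str, params: ParameterSet) -> StrategyConfig:
    """Build the named strategy from the access parameters.

    ``name`` is one of UC, R, P, SR, R+P, R+SR, P+SR, RC: the pathways named
    are provided at the recommended level (supply probability 1), all others
    stay at usual-care levels.
    """
    if name not in STRATEGY_NAMES:
        raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}")
    scaled = set(PATHWAYS) if name == "RC" else (
        set() if name == "UC" else set(name.split("+")))
    levels, supply, demand = {}, {}, {}
    for pw in PATHWAYS:
        acc = getattr(params.access_params, pw)
        if pw in scaled:
            levels[pw] = "recommended"
            supply[pw] = acc.supply_recommended
            demand[pw] = acc.demand_recommended
        else:
            levels[pw] = "usual"
            supply[pw] = acc.supply_usual
            demand[pw] = acc.demand_usual
    return StrategyConfig(name=name, levels=levels, supply=supply, demand=demand,
                          screening_rule=params.access_params.screening_rule).validate()


@dataclass
class CycleEvent:
    """What happened to one person in one cycle (debug/event-log surface)."""

    person_id: int
    cycle: int
    intervention: str | None = None
    faller_type: FallerType = FallerType.NO_FALL
    hospitalised_ma: int = 0
    died: str | None = None           # None | "fatal_fall" | "other_cause"
    admitted_ltc: bool = False
    utility: float = 0.0
    costs: dict[str, float] = field(default_factory=dict)


#: accumulator columns of a strategy summary, in output order
OUTCOME_FIELDS = (
    "qalys", "cost_public_allcause", "cost_public_fall", "cost_oop",
    "value_prod_paid", "value_prod_unpaid", "cost_informal",
    "cost_int_public", "cost_int_copay", "cost_int_participant_time",
    "cost_int_caregiver_time",
)


@dataclass
class StrategySummary:
    """Discounted aggregate outcomes of one strategy run, by SES quartile.

    Each outcome field is a length-4 array (quartile 1..4); totals are the
    sums over quartiles.  Productivity value is a positive value stream and
    enters the societal ledger as a negative cost.
    """

    strategy: str
    persons: np.ndarray
    qalys: np.ndarray
    cost_public_allcause: np.ndarray
    cost_public_fall: np.ndarray
    cost_oop: np.ndarray
    value_prod_paid: np.ndarray
    value_prod_unpaid: np.ndarray
    cost_informal: np.ndarray
    cost_int_public: np.ndarray
    cost_int_copay: np.ndarray
    cost_int_participant_time: np.ndarray
    cost_int_caregiver_time: np.ndarray

    def total(self, fieldname: str) -> float:
        return float(np.sum(getattr(self, fieldname)))

    @property
    def total_persons(self) -> int:
        return int(np.sum(self.persons))

    def public_cost(self, basis: str = "all-cause") -> float:
        """Total public sector cost on the chosen basis, intervention spend included."""
        if basis == "all-cause":
            return self.total("cost_public_allcause") + self.total("cost_int_public")
        if basis == "fall-related":
            return self.total("cost_public_fall") + self.total("cost_int_public")
        raise ValueError(f"unknown cost basis {basis!r}")

    def net_nonpublic_cost_by_quartile(self) -> np.ndarray:
        """Out-of-pocket + informal care + copayment + time costs - productivity value."""
        return (self.cost_oop + self.cost_informal + self.cost_int_copay
                + self.cost_int_participant_time + self.cost_int_caregiver_time
                - self.value_prod_paid - self.value_prod_unpaid)

    def public_cost_by_quartile(self, basis: str = "all-cause") -> np.ndarray:
        if basis == "all-cause":
            return self.cost_public_allcause + self.cost_int_public
        if basis == "fall-related":
            return self.cost_public_fall + self.cost_int_public
        raise ValueError(f"unknown cost basis {basis!r}")

    def to_frame(self) -> pd.DataFrame:
        """One row per quartile plus a totals row (quartile 0 labelled 'total')."""
        rows = []
        for g in range(4):
            row = {"strategy": self.strategy, "quartile": g + 1,
                   "persons": int(self.persons[g])}
            row.update({f: float(getattr(self, f)[g]) for f in OUTCOME_FIELDS})
            rows.append(row)
        total = {"strategy": self.strategy, "quartile": "total",
                 "persons": self.total_persons}
        total.update({f: self.total(f) for f in OUTCOME_FIELDS})
        rows.append(total)
        return pd.DataFrame(rows)

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> dict[str, "StrategySummary"]:
        """Rebuild summaries from :meth:`to_frame` output (totals rows ignored)."""
        out = {}
        quart = frame[frame["quartile"].astype(str) != "total"].copy()
        quart["quartile"] = quart["quartile"].astype(int)
        for name, grp in quart.groupby("strategy", sort=False):
            grp = grp.sort_values("quartile")
            out[name] = StrategySummary(
                strategy=name,
                persons=grp["persons"].to_numpy(dtype=float),
                **{f: grp[f].to_numpy(dtype=float) for f in OUTCOME_FIELDS})
        return out


# ---------------------------------------------------------------------- #
# shared formula helpers (scalar- and array-friendly)

def _sigmoid(x):
    # logits beyond +/-60 are saturated; clipping avoids exp overflow
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _fall_linear_predictor(params: ParameterSet, age, female, falls_history,
                           frailty, low_activity, cognitive, fear, gait):
    c = params.fall_risk_coefficients
    return (c.intercept + c.age * (age - 60.0) + c.female * female
            + c.falls_history * falls_history + c.frailty * frailty / 100.0
            + c.low_activity * low_activity + c.cognitive_impairment * cognitive
            + c.fear_of_falling * fear + c.abnormal_gait_balance * gait)


def _fatal_fall_prob(params: ParameterSet, age, frailty):
    p = params.fatal_fall_params
    return _sigmoid(p.intercept + p.age_slope * (age - 60.0)
                    + p.frailty_slope * frailty / 100.0)


def _other_cause_prob(params: ParameterSet, age, female, frailty, ses_mult=1.0):
    m = params.other_cause_mortality_params
    q60 = np.where(female, m.q60_female, m.q60_male)
    q = (q60 * np.exp(m.log_increase_per_year * (age - 60.0))
         * (1.0 + m.frailty_multiplier * frailty / 100.0) * ses_mult)
    return np.clip(q, 0.0, m.cap)


def _incidence_prob(p, age, frailty, multiplier=1.0):
    raw = _sigmoid(p.intercept + p.age_slope * (age - 60.0)
                   + p.frailty_slope * frailty / 100.0) * multiplier
    return np.clip(raw, 0.0, 1.0)


def _ltc_prob(params: ParameterSet, age, frailty):
    p = params.ltc_admission_params
    return _sigmoid(p.intercept + p.age_slope * (age - 60.0)
                    + p.frailty_slope * frailty / 100.0)


def _base_utility(params: ParameterSet, age, female, ses_mult=1.0):
    u = params.utility_params
    base = np.where(female, u.base_60_female, u.base_60_male)
    return (base - u.age_slope * (age - 60.0)) * ses_mult


def _frailty_increment(params: ParameterSet, age, faller_addon, multiplier=None):
    prog = params.frailty_progression
    e0, e1 = prog.age_band_edges
    b0, b1, b2 = prog.base_increments
    base = np.where(age < e0, b0, np.where(age < e1, b1, b2))
    if multiplier is None:
        multiplier = params.adjustments.frailty_progression
    return (base + faller_addon) * multiplier


# ---------------------------------------------------------------------- #
# per-person operation surface

def discount_factor(cycle: int, rate: float) -> float:
    """``(1 + rate) ** -cycle``; cycle 0 is undiscounted."""
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0 (got {cycle})")
    return float((1.0 + rate) ** (-cycle))


def fall_probability(person: Individual, params: ParameterSet,
                     active_effect: float = 1.0) -> float:
    """Annual probability of >=1 nonfatal fall.

    The logistic linear predictor over the person's characteristics gives
    baseline odds; SES and any active intervention effect multiply the odds.
    """
    if not 0.0 < active_effect <= 1.0:
        raise ValueError(f"active_effect must lie in (0, 1] (got {active_effect})")
    lp = _fall_linear_predictor(
        params, person.age, person.sex == "F", person.falls_history,
        person.frailty, person.physical_activity_low, person.cognitive_impairment,
        person.fear_of_falling, person.abnormal_gait_balance)
    ses_mult = params.ses_gradients.fall_odds[person.ses_quartile - 1]
    return float(_sigmoid(lp + np.log(ses_mult * active_effect)))


def classify_faller(fell: bool, params: ParameterSet,
                    rng: np.random.Generator) -> tuple[FallerType, int]:
    """Draw the faller type and hospitalised-MA-fall count for one person-cycle."""
    if not fell:
        return FallerType.NO_FALL, 0
    split = params.faller_type_split
    probs = np.asarray(split.probs())
    if abs(probs.sum() - 1.0) > 1e-12:
        raise ValueError("faller_type_split must sum to 1")
    ftype = FallerType(1 + int(np.searchsorted(np.cumsum(probs), rng.random(),
                                               side="right").clip(0, 3)))
    if ftype == FallerType.SINGLE_MA:
        n_ma = 1
    elif ftype == FallerType.RECURRENT_WITH_MA:
        n_ma = 1 + int(rng.random() < split.recurrent_two_ma_prob)
    else:
        n_ma = 0
    hosp = int(rng.binomial(n_ma, params.hospitalisation_prob_per_ma_fall)) if n_ma else 0
    return ftype, hosp


def mortality_step(person: Individual, params: ParameterSet,
                   rng: np.random.Generator) -> str | None:
    """One cycle's mortality draw: ``'fatal_fall'``, ``'other_cause'`` or None."""
    if not person.alive:
        raise ValueError("mortality_step requires a living person")
    if rng.random() < _fatal_fall_prob(params, person.age, person.frailty):
        return "fatal_fall"
    ses_mult = params.ses_gradients.mortality[person.ses_quartile - 1]
    q = _other_cause_prob(params, person.age, person.sex == "F",
                          person.frailty, ses_mult)
    if rng.random() < q:
        return "other_cause"
    return None


def update_frailty(person: Individual, faller_type: FallerType,
                   params: ParameterSet, scenario_multiplier: float | None = None
                   ) -> float:
    """New frailty after one cycle: base age-band increment plus faller add-on."""
    addon = (0.0 if faller_type == FallerType.NO_FALL
             else params.frailty_progression.faller_addons[FALL_TYPE_KEY[faller_type]])
    inc = _frailty_increment(params, person.age, addon, scenario_multiplier)
    return float(np.clip(person.frailty + inc, 0.0, 100.0))


def update_time_varying(person: Individual, faller_type: FallerType,
                        params: ParameterSet, rng: np.random.Generator,
                        cognitive_multiplier: float | None = None) -> Individual:
    """Post-cycle update of falls history, impairments, activity and age."""
    if cognitive_multiplier is None:
        cognitive_multiplier = params.adjustments.cognitive_incidence
    p = replace(person)
    p.falls_history = faller_type != FallerType.NO_FALL
    if not p.cognitive_impairment:
        prob = _incidence_prob(params.cognitive_impairment_incidence,
                               p.age, p.frailty, cognitive_multiplier)
        p.cognitive_impairment = bool(rng.random() < prob)
    if not p.fear_of_falling:
        prob = _incidence_prob(params.fear_of_falling_onset, p.age, p.frailty)
        p.fear_of_falling = bool(rng.random() < prob)
    if not p.abnormal_gait_balance:
        prob = _incidence_prob(params.gait_balance_onset, p.age, p.frailty)
        p.abnormal_gait_balance = bool(rng.random() < prob)
    u = rng.random()
    if p.physical_activity_low:
        p.physical_activity_low = not u < params.activity_transition.recovery_prob
    else:
        prob = _incidence_prob(params.activity_transition.decline, p.age, p.frailty)
        p.physical_activity_low = bool(u < prob)
    p.age += 1.0
    return p


def ltc_admission(person: Individual, params: ParameterSet,
                  rng: np.random.Generator) -> bool:
    """Annual long-term-care admission draw; admission exits the model."""
    if not person.alive:
        raise ValueError("ltc_admission requires a living person")
    return bool(rng.random() < _ltc_prob(params, person.age, person.frailty))


def cycle_outcomes(person: Individual, event: CycleEvent,
                   params: ParameterSet) -> tuple[float, dict[str, float]]:
    """Undiscounted utility and costs of one surviving person-cycle.

    Returns ``(utility, costs)`` where ``costs`` keys the public all-cause
    total (fall-related and intervention spend included), the fall-related
    component, and the nonpublic components.
    """
    up, cp = params.utility_params, params.cost_params
    female = person.sex == "F"
    ses_u = params.ses_gradients.utility[person.ses_quartile - 1]
    acute = (0.0 if event.faller_type == FallerType.NO_FALL
             else up.acute_loss[FALL_TYPE_KEY[event.faller_type]])
    utility = (_base_utility(params, person.age, female, ses_u)
               - up.frailty_decrement * person.frailty
               - acute - event.hospitalised_ma * up.hospitalised_extra_loss)
    utility = float(max(utility, up.floor))

    base_cost = (cp.public_base + cp.public_age_slope * (person.age - 60.0)
                 + cp.public_frailty_slope * person.frailty)
    fall_cost = (0.0 if event.faller_type == FallerType.NO_FALL
                 else cp.fall_public[FALL_TYPE_KEY[event.faller_type]])
    fall_cost += event.hospitalised_ma * cp.hospitalised_ma_cost
    iv = (params.intervention_params[event.intervention]
          if event.intervention else None)
    paid_frac = np.clip((cp.paid_decline_age - person.age)
                        / (cp.paid_decline_age - 60.0), 0.0, 1.0)
    frail_frac = max(0.0, 1.0 - person.frailty / 100.0)
    costs = {
        "public_allcause": base_cost + fall_cost + (iv.public_cost if iv else 0.0),
        "public_fall": fall_cost,
        "oop": cp.oop_base + cp.oop_frailty_slope * person.frailty,
        "prod_paid": cp.paid_value_60 * float(paid_frac) * frail_frac,
        "prod_unpaid": cp.unpaid_value * frail_frac,
        "informal": cp.informal_cost_per_point * person.frailty,
        "int_public": iv.public_cost if iv else 0.0,
        "int_copay": iv.copayment if iv else 0.0,
        "int_participant_time": iv.participant_time_cost if iv else 0.0,
        "int_caregiver_time": iv.caregiver_time_cost if iv else 0.0,
    }
    return utility, costs


# eligibility -------------------------------------------------------------

def _require_community(person: Individual) -> None:
    if not person.alive or person.in_ltc:
        raise ValueError("eligibility requires a living, community-dwelling person")


def eligible_reactive(person: Individual, last_cycle: CycleEvent | None) -> bool:
    """Eligible for the reactive pathway: >=1 MA fall in the previous cycle."""
    _require_community(person)
    if last_cycle is None:
        return False
    return last_cycle.faller_type in (FallerType.SINGLE_MA,
                                      FallerType.RECURRENT_WITH_MA)


def eligible_proactive(person: Individual, params: ParameterSet,
                       rng: np.random.Generator,
                       screening_rule: str = "and") -> bool:
    """Eligible for the proactive pathway: GP contact plus positive screening."""
    _require_community(person)
    rate = np.clip(params.access_params.gp_access_rate
                   * params.ses_gradients.gp_access[person.ses_quartile - 1], 0.0, 1.0)
    if not rng.random() < rate:
        return False
    if screening_rule == "or":
        return person.falls_history or person.abnormal_gait_balance
    return person.falls_history and person.abnormal_gait_balance


def eligible_self_referred(person: Individual) -> bool:
    """Every living, community-dwelling person may self-refer."""
    _require_community(person)
    return True


def assign_intervention(person: Individual, config: StrategyConfig,
                        params: ParameterSet, rng: np.random.Generator,
                        last_cycle: CycleEvent | None = None) -> str | None:
    """At most one pathway per cycle: eligible AND supply AND demand draws,
    resolved in precedence order (reactive before proactive before
    self-referred by default)."""
    _require_community(person)
    eligibility = {
        "R": eligible_reactive(person, last_cycle),
        "P": eligible_proactive(person, params, rng, config.screening_rule),
        "SR": eligible_self_referred(person),
    }
    received = None
    for pw in config.precedence:
        got = (eligibility[pw]
               and rng.random() < config.supply[pw]
               and rng.random() < config.demand[pw])
        if got and received is None:
            received = pw
    return received


# ---------------------------------------------------------------------- #
# vectorised engine

def run_strategy(params: ParameterSet, config: StrategyConfig,
                 population_spec: PopulationSpec, master_seed: int,
                 horizon: int | None = None,
                 collect_events: bool = False):
    """Simulate one strategy and return its :class:`StrategySummary`.

    The baseline cohort and every entry cohort are generated from named
    sub-streams of ``master_seed`` and are therefore identical across
    strategies; all within-simulation draws are counter-based per
    ``(seed, person id, cycle, event)``, giving common random numbers.

    With ``collect_events=True`` returns ``(summary, events)`` where
    ``events`` is a person-cycle event-log DataFrame.
    """
    params.validate()
    config.validate()
    if horizon is None:
        horizon = params.economics.horizon
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1 (got {horizon})")

    cohorts = [generate_baseline_cohort(population_spec.n_baseline, params,
                                        stream_seed(master_seed, "baseline"))]
    entry_n = population_spec.resolved_entry_size()
    for t in range(1, horizon):
        if entry_n > 0:
            cohorts.append(generate_entry_cohort(
                t, entry_n, params, stream_seed(master_seed, "entry", t)))

    def cat(key, dtype=None):
        arr = np.concatenate([c.arrays[key] for c in cohorts])
        return arr.astype(dtype) if dtype is not None else arr

    n_total = sum(len(c) for c in cohorts)
    pid = np.arange(n_total, dtype=np.int64)
    age = cat("age", np.float64)
    female = cat("female", bool)
    ses = cat("ses_quartile", np.int64)
    fh = cat("falls_history", bool)
    frailty = cat("frailty", np.float64)
    low_act = cat("physical_activity_low", bool)
    cog = cat("cognitive_impairment", bool)
    fear = cat("fear_of_falling", bool)
    gait = cat("abnormal_gait_balance", bool)
    entry = cat("entry_year", np.int64)

    alive = np.ones(n_total, dtype=bool)
    in_ltc = np.zeros(n_total, dtype=bool)
    prev_ma = np.zeros(n_total, dtype=np.int8)
    eff_rr = np.ones(n_total, dtype=np.float64)
    eff_left = np.zeros(n_total, dtype=np.int16)
    acc = {f: np.zeros(n_total) for f in OUTCOME_FIELDS}

    g = params.ses_gradients
    ses_fall = np.asarray(g.fall_odds)[ses - 1]
    ses_util = np.asarray(g.utility)[ses - 1]
    ses_mort = np.asarray(g.mortality)[ses - 1]
    ses_gp = np.asarray(g.gp_access)[ses - 1]

    split = np.asarray(params.faller_type_split.probs())
    split_cum = np.cumsum(split)
    p_two_ma = params.faller_type_split.recurrent_two_ma_prob
    p_hosp = params.hospitalisation_prob_per_ma_fall
    acute_loss = np.array([0.0] + [params.utility_params.acute_loss[FALL_TYPE_KEY[t]]
                                   for t in list(FallerType)[1:]])
    fall_cost = np.array([0.0] + [params.cost_params.fall_public[FALL_TYPE_KEY[t]]
                                  for t in list(FallerType)[1:]])
    addons = np.array([0.0] + [params.frailty_progression.faller_addons[FALL_TYPE_KEY[t]]
                               for t in list(FallerType)[1:]])
    iv = params.intervention_params
    iv_rr = {pw: iv[pw].relative_risk for pw in PATHWAYS}
    iv_dur = {pw: iv[pw].effect_duration for pw in PATHWAYS}
    up, cp = params.utility_params, params.cost_params
    rate = params.economics.discount_rate
    seed = int(master_seed)
    events: list[pd.DataFrame] | None = [] if collect_events else None
    conj = config.screening_rule != "or"

    for t in range(horizon):
        idx = np.flatnonzero(alive & ~in_ltc & (entry <= t))
        if idx.size == 0:
            continue
        df = (1.0 + rate) ** (-t)
        p = pid[idx]
        a, fr, qse = age[idx], frailty[idx], ses[idx] - 1

        # --- intervention assignment ------------------------------------
        elig_r = prev_ma[idx] >= 1
        gp_rate = np.clip(params.access_params.gp_access_rate * ses_gp[idx], 0.0, 1.0)
        contact = event_uniform(seed, p, t, "gp_contact") < gp_rate
        screen = (fh[idx] & gait[idx]) if conj else (fh[idx] | gait[idx])
        elig = {"R": elig_r, "P": contact & screen,
                "SR": np.ones(idx.size, dtype=bool)}
        received = np.zeros(idx.size, dtype=np.int8)  # 0 none, else 1+precedence pos
        for k, pw in enumerate(config.precedence, start=1):
            got = (elig[pw]
                   & (event_uniform(seed, p, t, f"supply_{pw}") < config.supply[pw])
                   & (event_uniform(seed, p, t, f"demand_{pw}") < config.demand[pw])
                   & (received == 0))
            received[got] = k
            if np.any(got):
                gi = idx[got]
                eff_rr[gi] = iv_rr[pw]
                eff_left[gi] = iv_dur[pw]
                acc["cost_int_public"][gi] += df * iv[pw].public_cost
                acc["cost_int_copay"][gi] += df * iv[pw].copayment
                acc["cost_int_participant_time"][gi] += df * iv[pw].participant_time_cost
                acc["cost_int_caregiver_time"][gi] += df * iv[pw].caregiver_time_cost

        # --- mortality ---------------------------------------------------
        p_fatal = _fatal_fall_prob(params, a, fr)
        died_fatal = event_uniform(seed, p, t, "fatal_fall") < p_fatal
        q_other = _other_cause_prob(params, a, female[idx], fr, ses_mort[idx])
        died_other = (~died_fatal) & (event_uniform(seed, p, t, "other_cause_death")
                                      < q_other)
        died = died_fatal | died_other
        alive[idx[died]] = False

        sv = idx[~died]            # survivors of this cycle
        if sv.size == 0:
            prev_ma[idx] = 0
            continue
        ps = pid[sv]
        a_s, fr_s, qs = age[sv], frailty[sv], ses[sv] - 1

        # --- nonfatal fall classification --------------------------------
        lp = _fall_linear_predictor(params, a_s, female[sv], fh[sv], fr_s,
                                    low_act[sv], cog[sv], fear[sv], gait[sv])
        rr_act = np.where(eff_left[sv] > 0, eff_rr[sv], 1.0)
        p_fall = _sigmoid(lp + np.log(ses_fall[sv] * rr_act))
        fell = event_uniform(seed, ps, t, "fall") < p_fall
        ftype = np.zeros(sv.size, dtype=np.int8)
        u_type = event_uniform(seed, ps, t, "faller_type")
        ftype[fell] = 1 + np.searchsorted(split_cum, u_type[fell],
                                          side="right").clip(0, 3)
        n_ma = np.zeros(sv.size, dtype=np.int8)
        n_ma[ftype == FallerType.SINGLE_MA] = 1
        rec_ma = ftype == FallerType.RECURRENT_WITH_MA
        n_ma[rec_ma] = 1 + (event_uniform(seed, ps, t, "ma_count")[rec_ma]
                            < p_two_ma)
        u_h = event_uniform(seed, ps, t, "hospitalisation")
        hosp = np.zeros(sv.size, dtype=np.int8)
        one = n_ma == 1
        hosp[one] = (u_h[one] < p_hosp).astype(np.int8)
        two = n_ma == 2
        if np.any(two):
            p0 = (1.0 - p_hosp) ** 2
            p1 = 2.0 * p_hosp * (1.0 - p_hosp)
            hosp[two] = ((u_h[two] >= p0).astype(np.int8)
                         + (u_h[two] >= p0 + p1).astype(np.int8))

        # --- outcome accrual ---------------------------------------------
        utility = (_base_utility(params, a_s, female[sv], ses_util[sv])
                   - up.frailty_decrement * fr_s
                   - acute_loss[ftype] - hosp * up.hospitalised_extra_loss)
        utility = np.maximum(utility, up.floor)
        acc["qalys"][sv] += df * utility
        base_cost = (cp.public_base + cp.public_age_slope * (a_s - 60.0)
                     + cp.public_frailty_slope * fr_s)
        fcost = fall_cost[ftype] + hosp * cp.hospitalised_ma_cost
        acc["cost_public_allcause"][sv] += df * (base_cost + fcost)
        acc["cost_public_fall"][sv] += df * fcost
        acc["cost_oop"][sv] += df * (cp.oop_base + cp.oop_frailty_slope * fr_s)
        paid_frac = np.clip((cp.paid_decline_age - a_s)
                            / (cp.paid_decline_age - 60.0), 0.0, 1.0)
        frail_frac = np.maximum(0.0, 1.0 - fr_s / 100.0)
        acc["value_prod_paid"][sv] += df * cp.paid_value_60 * paid_frac * frail_frac
        acc["value_prod_unpaid"][sv] += df * cp.unpaid_value * frail_frac
        acc["cost_informal"][sv] += df * cp.informal_cost_per_point * fr_s

        # --- frailty and time-varying updates ----------------------------
        new_fr = np.clip(fr_s + _frailty_increment(params, a_s, addons[ftype]),
                         0.0, 100.0)
        frailty[sv] = new_fr
        fh[sv] = ftype != 0
        not_cog = sv[~cog[sv]]
        if not_cog.size:
            pc = _incidence_prob(params.cognitive_impairment_incidence,
                                 age[not_cog], frailty[not_cog],
                                 params.adjustments.cognitive_incidence)
            cog[not_cog] |= event_uniform(seed, pid[not_cog], t, "cognitive") < pc
        not_fear = sv[~fear[sv]]
        if not_fear.size:
            pf = _incidence_prob(params.fear_of_falling_onset,
                                 age[not_fear], frailty[not_fear])
            fear[not_fear] |= event_uniform(seed, pid[not_fear], t,
                                            "fear_of_falling") < pf
        not_gait = sv[~gait[sv]]
        if not_gait.size:
            pg = _incidence_prob(params.gait_balance_onset,
                                 age[not_gait], frailty[not_gait])
            gait[not_gait] |= event_uniform(seed, pid[not_gait], t,
                                            "gait_balance") < pg
        u_act = event_uniform(seed, ps, t, "activity")
        p_dec = _incidence_prob(params.activity_transition.decline, a_s, new_fr)
        was_low = low_act[sv]
        low_act[sv] = np.where(was_low,
                               ~(u_act < params.activity_transition.recovery_prob),
                               u_act < p_dec)
        age[sv] = a_s + 1.0

        # --- LTC admission ------------------------------------------------
        p_ltc = _ltc_prob(params, age[sv], new_fr)
        admitted = event_uniform(seed, ps, t, "ltc") < p_ltc
        in_ltc[sv[admitted]] = True

        prev_ma[idx] = 0
        prev_ma[sv] = n_ma
        left = eff_left[idx]
        eff_left[idx] = np.maximum(left - 1, 0)

        if events is not None:
            pw_name = np.array(["none"] + list(config.precedence))
            log = pd.DataFrame({
                "person_id": pid[idx], "cycle": t,
                "intervention": pw_name[received],
                "died": np.where(died_fatal, "fatal_fall",
                                 np.where(died_other, "other_cause", "")),
            })
            surv_log = pd.DataFrame({
                "person_id": ps, "faller_type": ftype,
                "hospitalised_ma": hosp,
                "admitted_ltc": admitted,
                "utility": utility,
                "cost_public_allcause": base_cost + fcost,
                "cost_public_fall": fcost,
            })
            events.append(log.merge(surv_log, on="person_id", how="left"))

    persons = np.bincount(ses - 1, minlength=4).astype(np.int64)
    by_q = {f: np.bincount(ses - 1, weights=acc[f], minlength=4)
            for f in OUTCOME_FIELDS}
    summary = StrategySummary(strategy=config.name, persons=persons, **by_q)
    if collect_events:
        log = (pd.concat(events, ignore_index=True) if events
               else pd.DataFrame())
        return summary, log
    return summary


def run_all_strategies(params: ParameterSet, population_spec: PopulationSpec,
                       master_seed: int, horizon: int | None = None,
                       strategies: tuple[str, ...] = STRATEGY_NAMES
                       ) -> dict[str, StrategySummary]:
    """Run every named strategy under common random numbers."""
    return {name: run_strategy(params, make_strategy(name, params),
                               population_spec, master_seed, horizon)
            for name in strategies}
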