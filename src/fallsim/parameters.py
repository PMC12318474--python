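"""Model parameterisation: every numeric input of the falls microsimulation.

The :class:`ParameterSet` gathers risk-equation coefficients, transition
probabilities, utilities, costs (GBP, 2023 prices), intervention pathway
descriptions, access rates and socioeconomic (SES) gradients.  All default
values are synthetic: they are chosen so that roughly 30% of the 60+
population has falls history, annual fall probability rises with age and
frailty, and the most deprived SES quartile is strictly worse off on
frailty, fall risk and utility than the least deprived.  Every value can be
overridden from a YAML or JSON configuration file mirroring the field names.

Conventions
-----------
* Frailty is a 0-100 cumulative-deficit index; risk-equation frailty
  coefficients apply to ``frailty / 100``.
* Age enters risk equations as ``age - 60`` (years past model entry age).
* SES quartile 1 is the least deprived, quartile 4 the most deprived.
* Nonfatal faller types are keyed ``single_non_ma``, ``single_ma``,
  ``recurrent_non_ma``, ``recurrent_with_ma`` (MA = medically attended).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "ParameterSet",
    "build_default_parameters",
    "load_parameters",
    "save_parameters",
    "parameters_to_dict",
    "parameters_from_dict",
    "get_param",
    "set_param",
    "FALL_TYPE_KEYS",
    "PATHWAYS",
]

FALL_TYPE_KEYS = ("single_non_ma", "single_ma", "recurrent_non_ma", "recurrent_with_ma")
PATHWAYS = ("R", "P", "SR")


class ParameterError(ValueError):
    """An invariant of the parameter set is violated."""


class ConfigurationError(ValueError):
    """A configuration document or field path does not match the model."""


@dataclass
class FallRiskCoefficients:
    """Logistic regression for >=1 nonfatal fall in a cycle (log-odds scale)."""

    intercept: float = -1.85
    age: float = 0.03            # per year past 60
    female: float = 0.20
    falls_history: float = 0.85
    frailty: float = 1.60        # per unit of frailty/100
    low_activity: float = 0.25
    cognitive_impairment: float = 0.30
    fear_of_falling: float = 0.30
    abnormal_gait_balance: float = 0.45


@dataclass
class FallerTypeSplit:
    """Conditional probabilities over nonfatal faller types given >=1 fall."""

    single_non_ma: float = 0.45
    single_ma: float = 0.20
    recurrent_non_ma: float = 0.20
    recurrent_with_ma: float = 0.15
    #: probability that a recurrent-with-MA cycle carries 2 (rather than 1) MA falls
    recurrent_two_ma_prob: float = 0.35

    def probs(self) -> tuple[float, float, float, float]:
        return (self.single_non_ma, self.single_ma,
                self.recurrent_non_ma, self.recurrent_with_ma)


@dataclass
class FatalFallParams:
    """Annual fatal-fall probability, logistic in age and frailty."""

    intercept: float = -7.6
    age_slope: float = 0.07
    frailty_slope: float = 2.0


@dataclass
class OtherCauseMortalityParams:
    """Gompertz-style annual death probability schedule with a frailty multiplier."""

    q60_male: float = 0.008
    q60_female: float = 0.005
    log_increase_per_year: float = 0.095
    frailty_multiplier: float = 1.5   # q *= 1 + frailty_multiplier * frailty/100
    cap: float = 0.995


@dataclass
class FrailtyProgression:
    """Base annual frailty increment by age band plus per-faller-type add-ons."""

    age_band_edges: tuple[float, float] = (70.0, 80.0)
    base_increments: tuple[float, float, float] = (0.6, 1.0, 1.5)
    faller_addons: dict[str, float] = field(default_factory=lambda: {
        "single_non_ma": 0.3,
        "single_ma": 1.5,
        "recurrent_non_ma": 1.2,
        "recurrent_with_ma": 3.0,
    })


@dataclass
class IncidenceParams:
    """Annual onset probability, logistic in age past 60 and frailty/100."""

    intercept: float = -4.0
    age_slope: float = 0.04
    frailty_slope: float = 1.0


@dataclass
class ActivityTransition:
    """High->low activity decline risk plus a constant recovery probability."""

    decline: IncidenceParams = field(default_factory=lambda: IncidenceParams(
        intercept=-2.6, age_slope=0.04, frailty_slope=1.0))
    recovery_prob: float = 0.05


@dataclass
class LTCAdmissionParams:
    """Annual long-term-care admission probability, logistic in age and frailty."""

    intercept: float = -7.0
    age_slope: float = 0.09
    frailty_slope: float = 3.0


@dataclass
class UtilityParams:
    """EQ-5D-3L utility model: age/sex baseline, frailty decrement, acute losses."""

    base_60_male: float = 0.86
    base_60_female: float = 0.84
    age_slope: float = 0.003          # baseline decrement per year past 60
    frailty_decrement: float = 0.004  # per frailty-index point
    acute_loss: dict[str, float] = field(default_factory=lambda: {
        "single_non_ma": 0.005,
        "single_ma": 0.04,
        "recurrent_non_ma": 0.015,
        "recurrent_with_ma": 0.08,
    })
    #: additional loss per hospitalised MA fall (hip-fracture-level injury)
    hospitalised_extra_loss: float = 0.10
    floor: float = 0.0


@dataclass
class CostParams:
    """Annual costs and value streams, GBP at 2023 prices."""

    # all-cause public sector cost (primary/secondary/community care, prescriptions)
    public_base: float = 1500.0
    public_age_slope: float = 40.0      # per year past 60
    public_frailty_slope: float = 55.0  # per frailty-index point
    # directly fall-related public cost by faller type (non-hospitalised)
    fall_public: dict[str, float] = field(default_factory=lambda: {
        "single_non_ma": 30.0,
        "single_ma": 1450.0,
        "recurrent_non_ma": 80.0,
        "recurrent_with_ma": 1600.0,
    })
    #: additional public cost per hospitalised MA fall (hip-fracture admission)
    hospitalised_ma_cost: float = 12500.0
    # out-of-pocket care expenditure
    oop_base: float = 100.0
    oop_frailty_slope: float = 18.0
    # productivity value streams (positive value, enters societal ledger as
    # negative cost)
    paid_value_60: float = 22000.0
    paid_decline_age: float = 70.0      # paid work tapers linearly to 0 here
    unpaid_value: float = 4500.0
    # informal (unpaid caregiver) care cost
    informal_cost_per_point: float = 60.0


@dataclass
class InterventionParams:
    """One falls-prevention pathway's costs and effect."""

    public_cost: float
    copayment: float
    participant_time_cost: float
    caregiver_time_cost: float
    relative_risk: float     # odds multiplier on nonfatal falls, in (0, 1]
    effect_duration: int     # cycles, starting the cycle of receipt


@dataclass
class PathwayAccess:
    """Supply and demand probabilities for one pathway at each provision level."""

    supply_usual: float
    supply_recommended: float
    demand_usual: float
    demand_recommended: float


@dataclass
class AccessParams:
    """GP access and per-pathway supply/demand under usual vs recommended care."""

    gp_access_rate: float = 0.72
    #: proactive screening positivity rule over falls history and gait/balance
    screening_rule: str = "and"
    R: PathwayAccess = field(default_factory=lambda: PathwayAccess(0.45, 1.0, 0.55, 0.70))
    P: PathwayAccess = field(default_factory=lambda: PathwayAccess(0.25, 1.0, 0.45, 0.60))
    SR: PathwayAccess = field(default_factory=lambda: PathwayAccess(0.55, 1.0, 0.12, 0.20))


@dataclass
class SESGradients:
    """Multiplicative modifiers by SES quartile (least -> most deprived).

    Fall-risk modifiers multiply the odds (equivalent to an intercept shift
    by ``log(m)``); utility modifiers scale the age/sex baseline; mortality
    modifiers scale the other-cause schedule; GP-access modifiers scale the
    contact rate.
    """

    frailty: tuple[float, float, float, float] = (0.85, 0.95, 1.08, 1.25)
    fall_odds: tuple[float, float, float, float] = (0.90, 1.00, 1.08, 1.20)
    utility: tuple[float, float, float, float] = (1.02, 1.00, 0.98, 0.94)
    mortality: tuple[float, float, float, float] = (0.88, 1.00, 1.10, 1.25)
    gp_access: tuple[float, float, float, float] = (1.05, 1.00, 0.95, 0.88)


@dataclass
class CharacteristicPrevalence:
    """Baseline prevalence of a binary characteristic, logistic in age/frailty."""

    intercept: float = -1.0
    age_slope: float = 0.02
    frailty_slope: float = 1.5


@dataclass
class PopulationParams:
    """Baseline cohort distributional assumptions for the 60+ population."""

    age_exponential_scale: float = 8.0   # mass decays over 60-95
    max_age: float = 95.0
    female_prob: float = 0.55
    frailty_beta_a: float = 2.0
    frailty_beta_b: float = 9.0
    frailty_scale: float = 55.0          # Beta draw scaled onto 0-100 index
    frailty_age_slope: float = 0.025     # proportional increase per year past 60
    falls_history: CharacteristicPrevalence = field(
        default_factory=lambda: CharacteristicPrevalence(-1.10, 0.015, 1.2))
    low_activity: CharacteristicPrevalence = field(
        default_factory=lambda: CharacteristicPrevalence(-0.70, 0.010, 1.5))
    cognitive_impairment: CharacteristicPrevalence = field(
        default_factory=lambda: CharacteristicPrevalence(-2.50, 0.050, 1.5))
    fear_of_falling: CharacteristicPrevalence = field(
        default_factory=lambda: CharacteristicPrevalence(-1.30, 0.020, 1.8))
    abnormal_gait_balance: CharacteristicPrevalence = field(
        default_factory=lambda: CharacteristicPrevalence(-1.70, 0.030, 2.0))


@dataclass
class ScenarioAdjustments:
    """Multipliers set by the alternative scenarios (1.0 = main scenario)."""

    baseline_frailty: float = 1.0
    frailty_progression: float = 1.0
    cognitive_incidence: float = 1.0


@dataclass
class Economics:
    discount_rate: float = 0.035
    horizon: int = 40
    public_thresholds: tuple[float, float] = (20000.0, 30000.0)
    societal_threshold: float = 60000.0


@dataclass
class ParameterSet:
    """Every numeric input of the model, with invariant validation."""

    fall_risk_coefficients: FallRiskCoefficients = field(default_factory=FallRiskCoefficients)
    faller_type_split: FallerTypeSplit = field(default_factory=FallerTypeSplit)
    hospitalisation_prob_per_ma_fall: float = 0.28
    fatal_fall_params: FatalFallParams = field(default_factory=FatalFallParams)
    other_cause_mortality_params: OtherCauseMortalityParams = field(
        default_factory=OtherCauseMortalityParams)
    frailty_progression: FrailtyProgression = field(default_factory=FrailtyProgression)
    cognitive_impairment_incidence: IncidenceParams = field(
        default_factory=lambda: IncidenceParams(intercept=-4.6, age_slope=0.06,
                                                frailty_slope=1.2))
    fear_of_falling_onset: IncidenceParams = field(
        default_factory=lambda: IncidenceParams(intercept=-3.0, age_slope=0.03,
                                                frailty_slope=1.0))
    gait_balance_onset: IncidenceParams = field(
        default_factory=lambda: IncidenceParams(intercept=-3.4, age_slope=0.05,
                                                frailty_slope=1.5))
    activity_transition: ActivityTransition = field(default_factory=ActivityTransition)
    ltc_admission_params: LTCAdmissionParams = field(default_factory=LTCAdmissionParams)
    utility_params: UtilityParams = field(default_factory=UtilityParams)
    cost_params: CostParams = field(default_factory=CostParams)
    intervention_params: dict[str, InterventionParams] = field(default_factory=lambda: {
        "R": InterventionParams(650.0, 0.0, 120.0, 40.0, 0.76, 3),
        "P": InterventionParams(500.0, 0.0, 100.0, 30.0, 0.82, 3),
        "SR": InterventionParams(150.0, 50.0, 90.0, 0.0, 0.88, 2),
    })
    access_params: AccessParams = field(default_factory=AccessParams)
    ses_gradients: SESGradients = field(default_factory=SESGradients)
    population: PopulationParams = field(default_factory=PopulationParams)
    adjustments: ScenarioAdjustments = field(default_factory=ScenarioAdjustments)
    economics: Economics = field(default_factory=Economics)

    # ------------------------------------------------------------------ #
    def validate(self) -> "ParameterSet":
        """Raise :class:`ParameterError` on any violated invariant."""
        split = self.faller_type_split
        probs = split.probs()
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("faller_type_split probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ParameterError(
                f"faller_type_split must sum to 1 (got {sum(probs)!r})")
        _check_prob("hospitalisation_prob_per_ma_fall",
                    self.hospitalisation_prob_per_ma_fall)
        _check_prob("faller_type_split.recurrent_two_ma_prob", split.recurrent_two_ma_prob)
        _check_prob("access_params.gp_access_rate", self.access_params.gp_access_rate)
        if self.access_params.screening_rule not in ("and", "or"):
            raise ParameterError("access_params.screening_rule must be 'and' or 'or'")
        for pw in PATHWAYS:
            acc: PathwayAccess = getattr(self.access_params, pw)
            for name in ("supply_usual", "supply_recommended",
                         "demand_usual", "demand_recommended"):
                _check_prob(f"access_params.{pw}.{name}", getattr(acc, name))
            iv = self.intervention_params.get(pw)
            if iv is None:
                raise ParameterError(f"intervention_params missing pathway {pw!r}")
            if not 0.0 < iv.relative_risk <= 1.0:
                raise ParameterError(
                    f"intervention_params.{pw}.relative_risk must lie in (0, 1]")
            for name in ("public_cost", "copayment", "participant_time_cost",
                         "caregiver_time_cost"):
                if getattr(iv, name) < 0:
                    raise ParameterError(
                        f"intervention_params.{pw}.{name} must be >= 0")
            if iv.effect_duration < 1:
                raise ParameterError(
                    f"intervention_params.{pw}.effect_duration must be >= 1")
        for key, val in self.cost_params.fall_public.items():
            if key not in FALL_TYPE_KEYS:
                raise ParameterError(f"cost_params.fall_public: unknown faller type {key!r}")
            if val < 0:
                raise ParameterError(f"cost_params.fall_public[{key!r}] must be >= 0")
        for name in ("public_base", "public_age_slope", "public_frailty_slope",
                     "hospitalised_ma_cost", "oop_base", "oop_frailty_slope",
                     "paid_value_60", "unpaid_value", "informal_cost_per_point"):
            if getattr(self.cost_params, name) < 0:
                raise ParameterError(f"cost_params.{name} must be >= 0")
        prog = self.frailty_progression
        import math
        for inc in (*prog.base_increments, *prog.faller_addons.values()):
            if not math.isfinite(inc):
                raise ParameterError("frailty_progression increments must be finite")
        for key in prog.faller_addons:
            if key not in FALL_TYPE_KEYS:
                raise ParameterError(
                    f"frailty_progression.faller_addons: unknown faller type {key!r}")
        econ = self.economics
        if econ.discount_rate < 0:
            raise ParameterError("economics.discount_rate must be >= 0")
        if econ.horizon < 1:
            raise ParameterError("economics.horizon must be >= 1")
        if any(t <= 0 for t in econ.public_thresholds) or econ.societal_threshold <= 0:
            raise ParameterError("economics thresholds must be > 0")
        for name in ("frailty", "fall_odds", "utility", "mortality", "gp_access"):
            grad = getattr(self.ses_gradients, name)
            if len(grad) != 4 or any(g <= 0 for g in grad):
                raise ParameterError(f"ses_gradients.{name} must be 4 positive values")
        if self.adjustments.baseline_frailty < 0:
            raise ParameterError("adjustments.baseline_frailty must be >= 0")
        return self

    def copy(self) -> "ParameterSet":
        """Deep, independent copy."""
        import copy
        return copy.deepcopy(self)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1] (got {value!r})")


def build_default_parameters() -> ParameterSet:
    """The package's default synthetic parameterisation, validated.

    SES gradients deliberately make quartile 4 (most deprived) strictly
    worse than quartile 1 on frailty, fall risk and utility, so that the
    distributional analysis has genuine inequality to measure.
    """
    return ParameterSet().validate()


# ---------------------------------------------------------------------- #
# configuration round-tripping (YAML canonical, JSON accepted)

def parameters_to_dict(params: ParameterSet) -> dict:
    return _to_plain(dataclasses.asdict(params))


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def parameters_from_dict(data: dict) -> ParameterSet:
    """Build a validated ParameterSet from a plain mapping; unknown keys rejected."""
    return _from_dict(ParameterSet, data, path="").validate()


def _from_dict(cls, data, path: str):
    import typing
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path or 'document'}: expected a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    hints = typing.get_type_hints(cls)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(
            f"{path or 'document'}: unknown key(s) {', '.join(map(repr, unknown))}")
    kwargs = {}
    for name, value in data.items():
        ftype = hints[name]
        origin = getattr(ftype, "__origin__", None)
        sub = f"{path}.{name}" if path else name
        if dataclasses.is_dataclass(ftype):
            kwargs[name] = _from_dict(ftype, value, sub)
        elif origin is tuple:
            kwargs[name] = tuple(value)
        elif origin is dict and dataclasses.is_dataclass(ftype.__args__[1]):
            kwargs[name] = {k: _from_dict(ftype.__args__[1], v, f"{sub}.{k}")
                            for k, v in value.items()}
        else:
            kwargs[name] = value
    return cls(**kwargs)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    data = parameters_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path: str | Path) -> ParameterSet:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return parameters_from_dict(data)


# ---------------------------------------------------------------------- #
# dotted-path access, used by the PSA distribution layer

def get_param(params: ParameterSet, dotted: str):
    """Fetch a (possibly nested) field by dotted path, e.g. ``'cost_params.oop_base'``."""
    obj = params
    for part in dotted.split("."):
        if dataclasses.is_dataclass(obj):
            if part not in {f.name for f in dataclasses.fields(obj)}:
                raise ConfigurationError(f"unknown parameter field {dotted!r} "
                                         f"(no attribute {part!r})")
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"unknown parameter field {dotted!r} "
                                         f"(no key {part!r})")
            obj = obj[part]
        else:
            raise ConfigurationError(f"unknown parameter field {dotted!r}")
    return obj


def set_param(params: ParameterSet, dotted: str, value) -> None:
    """Set a (possibly nested) field in place by dotted path."""
    parts = dotted.split(".")
    obj = get_param(params, ".".join(parts[:-1])) if len(parts) > 1 else params
    leaf = parts[-1]
    if dataclasses.is_dataclass(obj):
        if leaf not in {f.name for f in dataclasses.fields(obj)}:
            raise ConfigurationError(f"unknown parameter field {dotted!r}")
        setattr(obj, leaf, value)
    elif isinstance(obj, dict):
        if leaf not in obj:
            raise ConfigurationError(f"unknown parameter field {dotted!r}")
        obj[leaf] = value
    else:
        raise ConfigurationError(f"unknown parameter field {dotted!r}")
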