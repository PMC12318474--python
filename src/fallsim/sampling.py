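"""Probabilistic sensitivity analysis (PSA) parameter distributions.

Each distributed parameter is a scalar (or fixed-length tuple) field of
:class:`~fallsim.parameters.ParameterSet`, addressed by dotted path and
assigned a standard health-economics family:

* ``beta`` for probabilities and other (0, 1) quantities,
* ``gamma`` for costs and other nonnegative quantities,
* ``lognormal`` for strictly positive multiplicative quantities,
* ``normal`` for unbounded log-odds coefficients.

Hyperparameters are derived from the point estimate and a coefficient of
variation so that the distribution mean equals the point estimate exactly.
Relative risks are drawn from a beta family so that sampled sets keep the
relative-risk bound of (0, 1]; each entry's draw comes from its own named
stream, so adding or removing an entry never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import stream_rng
from .parameters import ConfigurationError, ParameterSet, get_param, set_param

__all__ = ["PSAEntry", "PSADistributionSpec", "default_psa_spec",
           "sample_psa_parameters"]

_FAMILIES = ("beta", "gamma", "lognormal", "normal")


@dataclass(frozen=True)
class PSAEntry:
    """One distributed parameter: dotted field path, family, coefficient of variation."""

    field: str
    family: str
    cv: float = 0.2

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"{self.field}: unknown distribution family {self.family!r}")
        if self.cv < 0:
            raise ConfigurationError(f"{self.field}: cv must be >= 0")


@dataclass
class PSADistributionSpec:
    """A set of :class:`PSAEntry`, validated against a base parameter set."""

    entries: list[PSAEntry] = field(default_factory=list)

    def validate_against(self, base: ParameterSet) -> "PSADistributionSpec":
        seen = set()
        for entry in self.entries:
            if entry.field in seen:
                raise ConfigurationError(f"duplicate PSA entry {entry.field!r}")
            seen.add(entry.field)
            get_param(base, entry.field)  # raises ConfigurationError if unknown
        return self

    def with_cv(self, cv: float) -> "PSADistributionSpec":
        """The same entries with a uniform coefficient of variation."""
        return PSADistributionSpec(
            [PSAEntry(e.field, e.family, cv) for e in self.entries])


def default_psa_spec(cv: float = 0.2) -> PSADistributionSpec:
    """Default second-order uncertainty specification.

    Covers the fall-risk coefficients, fatal-fall and long-term-care
    log-odds intercepts, the hospitalisation probability, intervention
    effects and costs, utility decrements and the main cost drivers.
    """
    entries = [
        PSAEntry("hospitalisation_prob_per_ma_fall", "beta", cv),
        PSAEntry("fall_risk_coefficients.intercept", "normal", cv),
        PSAEntry("fall_risk_coefficients.age", "normal", cv),
        PSAEntry("fall_risk_coefficients.female", "normal", cv),
        PSAEntry("fall_risk_coefficients.falls_history", "normal", cv),
        PSAEntry("fall_risk_coefficients.frailty", "normal", cv),
        PSAEntry("fall_risk_coefficients.low_activity", "normal", cv),
        PSAEntry("fall_risk_coefficients.cognitive_impairment", "normal", cv),
        PSAEntry("fall_risk_coefficients.fear_of_falling", "normal", cv),
        PSAEntry("fall_risk_coefficients.abnormal_gait_balance", "normal", cv),
        PSAEntry("fatal_fall_params.intercept", "normal", cv),
        PSAEntry("ltc_admission_params.intercept", "normal", cv),
        PSAEntry("utility_params.frailty_decrement", "gamma", cv),
        PSAEntry("utility_params.hospitalised_extra_loss", "gamma", cv),
        PSAEntry("cost_params.public_base", "gamma", cv),
        PSAEntry("cost_params.public_frailty_slope", "gamma", cv),
        PSAEntry("cost_params.hospitalised_ma_cost", "gamma", cv),
        PSAEntry("cost_params.fall_public.single_ma", "gamma", cv),
        PSAEntry("cost_params.fall_public.recurrent_with_ma", "gamma", cv),
        PSAEntry("cost_params.oop_frailty_slope", "gamma", cv),
        PSAEntry("cost_params.informal_cost_per_point", "gamma", cv),
        PSAEntry("intervention_params.R.relative_risk", "beta", cv),
        PSAEntry("intervention_params.P.relative_risk", "beta", cv),
        PSAEntry("intervention_params.SR.relative_risk", "beta", cv),
        PSAEntry("intervention_params.R.public_cost", "gamma", cv),
        PSAEntry("intervention_params.P.public_cost", "gamma", cv),
        PSAEntry("intervention_params.SR.public_cost", "gamma", cv),
    ]
    return PSADistributionSpec(entries)


def _draw_scalar(rng: np.random.Generator, family: str, mean: float, cv: float) -> float:
    """One draw whose distribution mean equals ``mean`` exactly."""
    if cv == 0.0 or mean == 0.0 and family != "normal":
        return float(mean)
    sd = abs(mean) * cv
    if family == "normal":
        return float(rng.normal(mean, sd))
    if mean < 0:
        raise ConfigurationError(
            f"{family} family requires a nonnegative point estimate (got {mean!r})")
    if family == "gamma":
        shape = 1.0 / cv**2
        return float(rng.gamma(shape, mean * cv**2))
    if family == "lognormal":
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    # beta: mean in (0, 1); cap the variance below the feasibility bound
    if not 0.0 < mean < 1.0:
        raise ConfigurationError(
            f"beta family requires a point estimate in (0, 1) (got {mean!r})")
    var = min(sd**2, 0.95 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def sample_psa_parameters(
    spec: PSADistributionSpec, base: ParameterSet, seed: int
) -> ParameterSet:
    """One PSA draw of the parameter set.

    Undistributed fields are copied unchanged; identical ``seed`` gives an
    identical draw.  Unknown field names raise :class:`ConfigurationError`
    naming the field.
    """
    spec.validate_against(base)
    sampled = base.copy()
    for entry in spec.entries:
        rng = stream_rng(seed, "psa", entry.field)
        value = get_param(base, entry.field)
        if isinstance(value, (tuple, list)):
            drawn = type(value)(
                _draw_scalar(rng, entry.family, float(v), entry.cv) for v in value)
        else:
            drawn = _draw_scalar(rng, entry.family, float(value), entry.cv)
        set_param(sampled, entry.field, drawn)
    return sampled
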