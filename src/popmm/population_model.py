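"""Stage-2 hierarchy: log-normal population distribution with covariates.

The individual log-parameter vector log(theta) = log[GEZI, SI, p2, V] is
modelled as multivariate normal, log(theta_i) ~ N(m_i, Sigma), where the
subject-level mean m_i shifts the population log-mean mu according to a
declarative covariate model:

* ``power_centered``    — multiplies the typical value by (cov/ref)^coeff
  (continuous covariates, centred at the study median),
* ``proportional_shift`` — multiplies it by (1 + coeff*indicator)
  (categorical covariates; coeff > -1).

Typical values (TV) are exp(mu); inter-individual variability (IIV) is
reported as CV% = 100*sqrt(diag(Sigma)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .minimal_model import PARAM_NAMES, MMParams

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}


class ConfigurationError(ValueError):
    """A covariate referenced by the model is missing or invalid."""


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-to-parameter effect in the stage-2 mean model."""

    parameter: str           # one of GEZI, SI, p2, V
    covariate: str           # column name in the covariate table
    kind: str                # "power_centered" | "proportional_shift"
    reference: float         # median (power) or baseline level (categorical)
    coefficient: float       # exponent (power) or fractional shift phi

    def __post_init__(self):
        if self.parameter not in _PARAM_INDEX:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.kind not in ("power_centered", "proportional_shift"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "proportional_shift" and self.coefficient <= -1:
            raise ValueError("proportional_shift coefficient must be > -1")

    def log_scale_coefficient(self) -> float:
        """The coefficient on the additive log scale.

        For a power effect this is the exponent itself (it multiplies
        log(cov/ref)); for a proportional shift it is log(1 + phi).
        """
        if self.kind == "power_centered":
            return self.coefficient
        return float(np.log1p(self.coefficient))

    def design_value(self, covariates: Mapping[str, object]) -> float:
        """The covariate regressor x such that the log-mean shift is x*psi."""
        if self.covariate not in covariates:
            raise ConfigurationError(
                f"covariate {self.covariate!r} required by the model for "
                f"{self.parameter} is missing")
        value = covariates[self.covariate]
        if self.kind == "power_centered":
            v = float(value)
            if v <= 0 or self.reference <= 0:
                raise ConfigurationError(
                    f"power-centered covariate {self.covariate!r} requires "
                    f"positive values (got {value!r})")
            return float(np.log(v / self.reference))
        return float(value)  # 0/1 indicator


@dataclass(frozen=True)
class CovariateSpec:
    """A declarative set of covariate effects (the stage-2 mean model).

    Coefficients act as initial values when handed to the EM engine, which
    re-estimates them.
    """

    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters of the hierarchy."""

    mu_logtheta: np.ndarray          # 4-vector, log TVs at reference covariates
    Sigma_logtheta: np.ndarray       # 4x4 SPD
    effects: Sequence[CovariateEffect] = field(default_factory=tuple)
    sigma_prop: float = 0.07         # proportional residual-error scale

    def __post_init__(self):
        mu = np.asarray(self.mu_logtheta, dtype=float).reshape(4)
        S = np.asarray(self.Sigma_logtheta, dtype=float).reshape(4, 4)
        _require_spd(S)
        if not self.sigma_prop > 0:
            raise ValueError("sigma_prop must be positive")
        object.__setattr__(self, "mu_logtheta", mu)
        object.__setattr__(self, "Sigma_logtheta", S)
        object.__setattr__(self, "effects", tuple(self.effects))

    def with_effects(self, effects) -> "PopulationParams":
        return replace(self, effects=tuple(effects))


def _require_spd(S: np.ndarray) -> None:
    if not np.allclose(S, S.T):
        raise ValueError("covariance matrix must be symmetric")
    if np.min(np.linalg.eigvalsh(S)) <= 0:
        raise ValueError("covariance matrix must be positive definite")


def typical_values(pop: PopulationParams) -> dict[str, float]:
    """Natural-scale typical values TV = exp(mu) per parameter."""
    tv = np.exp(pop.mu_logtheta)
    return dict(zip(PARAM_NAMES, tv.tolist()))


def iiv_cv(Sigma) -> dict[str, float]:
    """Inter-individual variability as CV% = 100*sqrt(diag(Sigma))."""
    S = np.asarray(Sigma, dtype=float)
    if np.any(np.diag(S) < 0):
        raise ValueError("diagonal of Sigma must be non-negative")
    if not np.allclose(S, S.T) or np.min(np.linalg.eigvalsh(S)) < 0:
        raise ValueError("Sigma must be symmetric positive (semi-)definite")
    return {name: 100.0 * float(np.sqrt(S[i, i]))
            for name, i in _PARAM_INDEX.items()}


def individual_mean_log(pop: PopulationParams,
                        covariates: Mapping[str, object]) -> np.ndarray:
    """Subject-level mean of log(theta): mu plus covariate shifts."""
    m = pop.mu_logtheta.copy()
    for eff in pop.effects:
        m[_PARAM_INDEX[eff.parameter]] += (
            eff.log_scale_coefficient() * eff.design_value(covariates))
    return m


def evaluate_covariate_model(pop: PopulationParams,
                             covariates: Mapping[str, object]) -> dict[str, float]:
    """Subject-level typical values under the covariate model.

    TV_i = TV_ref * prod(1 + phi*indicator) * prod((cov/ref)^exponent);
    computed as exp(individual_mean_log) so the two views agree exactly.
    """
    tv = np.exp(individual_mean_log(pop, covariates))
    return dict(zip(PARAM_NAMES, tv.tolist()))


def sample_individual(pop: PopulationParams, covariates: Mapping[str, object],
                      rng: np.random.Generator) -> MMParams:
    """Draw one individual's parameters from the log-normal hierarchy."""
    m = individual_mean_log(pop, covariates)
    eta = rng.multivariate_normal(m, pop.Sigma_logtheta, method="cholesky")
    return MMParams.from_array(np.exp(eta))


def approx_param_sd(TV: float, cv_percent: float) -> float:
    """Natural-scale +/- spread of a parameter: TV * CV%/100."""
    if TV <= 0:
        raise ValueError("TV must be positive")
    if cv_percent < 0:
        raise ValueError("cv_percent must be non-negative")
    return TV * cv_percent / 100.0


# ---------------------------------------------------------------------------
# Reference population models (published population-analysis estimates).
# Used as generator truths for synthetic cohorts and as EM initial values.
# ---------------------------------------------------------------------------

#: Base model (no covariates): TVs, IIV CV%, GEZI-p2 correlation 0.77,
#: proportional error 0.0706.
BASE_TV = {"GEZI": 0.0178, "SI": 3.59e-5, "p2": 0.0425, "V": 12.4}
BASE_IIV_CV = {"GEZI": 50.9, "SI": 113.0, "p2": 44.0, "V": 34.4}
BASE_SIGMA_PROP = 0.0706
GEZI_P2_CORR = 0.77

#: Final covariate model: reference TVs and effect coefficients.
FINAL_TV = {"GEZI": 0.0210, "SI": 6.26e-5, "p2": 0.0420, "V": 12.0}
FINAL_IIV_CV = {"GEZI": 46.1, "SI": 83.8, "p2": 44.9, "V": 26.8}
FINAL_SIGMA_PROP = 0.0706
BMI_REFERENCE = 25.3   # kg/m^2, study median
WEIGHT_REFERENCE = 75.0  # kg, study median


def _sigma_from_cv(iiv_cv_map: Mapping[str, float],
                   gezi_p2_corr: float) -> np.ndarray:
    sd = np.array([iiv_cv_map[p] / 100.0 for p in PARAM_NAMES])
    S = np.diag(sd ** 2)
    i, j = _PARAM_INDEX["GEZI"], _PARAM_INDEX["p2"]
    S[i, j] = S[j, i] = gezi_p2_corr * sd[i] * sd[j]
    return S


def final_model_effects() -> tuple[CovariateEffect, ...]:
    """The published final covariate model, as declarative effects."""
    return (
        CovariateEffect("GEZI", "t2d", "proportional_shift", 0.0, -0.473),
        CovariateEffect("SI", "t2d", "proportional_shift", 0.0, -0.479),
        CovariateEffect("SI", "im_ivgtt", "proportional_shift", 0.0, -0.345),
        CovariateEffect("SI", "bmi_kg_m2", "power_centered", BMI_REFERENCE, -2.14),
        CovariateEffect("V", "weight_kg", "power_centered", WEIGHT_REFERENCE, 0.865),
    )


def reference_base_population() -> PopulationParams:
    """Published base-model (no covariates) population estimates."""
    mu = np.log([BASE_TV[p] for p in PARAM_NAMES])
    return PopulationParams(mu, _sigma_from_cv(BASE_IIV_CV, GEZI_P2_CORR),
                            effects=(), sigma_prop=BASE_SIGMA_PROP)


def reference_final_population() -> PopulationParams:
    """Published final-model population estimates (with covariates)."""
    mu = np.log([FINAL_TV[p] for p in PARAM_NAMES])
    return PopulationParams(mu, _sigma_from_cv(FINAL_IIV_CV, GEZI_P2_CORR),
                            effects=final_model_effects(),
                            sigma_prop=FINAL_SIGMA_PROP)
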