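"""Core parameter set and closed-form rate/drift functions.

The model couples the frequency ``x`` of an "active" (proenvironmental)
behavior A in a well-mixed population with a continuous perceived
environmental state ``e``.  Individuals switch between A and a "baseline"
behavior B either through social encounters (imitation weighted by payoff
and conformist social pressure) or through their own assessment of the
perceived environment.  The perceived environment relaxes toward the
population's mean per-capita impact ``l_A x + l_B (1 - x)``.

Everything downstream (ODE integration, equilibrium analysis, stochastic
simulation, fluctuation analysis) composes the functions defined here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping

__all__ = [
    "DOMAIN_SLACK",
    "TAU_PRESETS",
    "ELL_PRESETS",
    "DomainError",
    "ModelParams",
    "DerivedParams",
    "SystemState",
    "social_attractiveness",
    "environmental_switch_rates",
    "drift_behavior",
    "drift_behavior_rate_form",
    "drift_environment",
    "total_switching_rate",
    "no_feedback_drift",
    "params_from_differentials",
    "differentials_from_params",
    "impact_mixture",
]

#: Absolute slack absorbing integrator round-off at the domain boundary.
#: Values within the slack are clamped onto the boundary; values beyond it
#: raise :class:`DomainError`.
DOMAIN_SLACK = 1e-12

#: Individual environmental sensitivity values used across the regime maps.
TAU_PRESETS = (0.1, 1.0, 10.0)

#: Environmental reactivity values used across the regime maps.
ELL_PRESETS = (0.1, 0.25)

_PARAM_FIELDS = (
    "kappa", "gamma_A", "gamma_B", "delta_A", "delta_B",
    "tau", "ell", "l_A", "l_B",
)

_MISSING_RATE_MSG = (
    "'{name}' has no default and must be given explicitly; "
    "preset values used throughout the regime maps are "
    "tau in {taus} and ell in {ells}".format(
        name="{name}", taus=TAU_PRESETS, ells=ELL_PRESETS)
)


class DomainError(ValueError):
    """A state or parameter lies outside the model's admissible domain."""


def _clamp(value: float, lo: float, hi: float, name: str, slack: float) -> float:
    if lo - slack <= value <= hi + slack:
        return min(max(value, lo), hi)
    raise DomainError(
        f"{name}={value!r} outside [{lo}, {hi}] beyond slack {slack}")


@dataclass(frozen=True)
class ModelParams:
    """Structural rates and impacts of the behavior-environment model.

    Parameters
    ----------
    kappa : float
        Encounter rate (1/time). Default 1.
    gamma_A, gamma_B : float
        Payoffs of the active and baseline behaviors (dimensionless).
        ``gamma_B`` defaults to 1.
    delta_A, delta_B : float
        Social pressures (conformism weights) of A and B (dimensionless).
        ``delta_B`` defaults to 0.5.
    tau : float
        Individual sensitivity to the environment (1/time). No default:
        must be supplied explicitly (see :data:`TAU_PRESETS`).
    ell : float
        Environmental reactivity (1/time). No default: must be supplied
        explicitly (see :data:`ELL_PRESETS`).
    l_A, l_B : float
        Per-capita environmental impacts of A and B (dimensionless), with
        ``0 < l_A < l_B``. ``l_B`` defaults to 1.
    """

    gamma_A: float
    delta_A: float
    tau: float
    ell: float
    l_A: float
    kappa: float = 1.0
    gamma_B: float = 1.0
    delta_B: float = 0.5
    l_B: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau", "ell"):
            if getattr(self, name) is None:
                raise DomainError(_MISSING_RATE_MSG.format(name=name))
        if not (0.0 < self.l_A < self.l_B):
            raise DomainError(
                f"impacts must satisfy 0 < l_A < l_B, got "
                f"l_A={self.l_A}, l_B={self.l_B}")
        if self.ell <= 0.0:
            raise DomainError(f"ell must be > 0, got {self.ell}")
        for name in ("kappa", "tau", "gamma_A", "gamma_B",
                     "delta_A", "delta_B"):
            if getattr(self, name) < 0.0:
                raise DomainError(
                    f"{name} must be >= 0, got {getattr(self, name)}")

    # -- derived quantities -------------------------------------------------

    @property
    def beta(self) -> float:
        """Payoff differential gamma_A - gamma_B (negative: A is costly)."""
        return self.gamma_A - self.gamma_B

    @property
    def nu(self) -> float:
        """Social norm threshold delta_B / (delta_A + delta_B)."""
        total = self.delta_A + self.delta_B
        if total <= 0.0:
            raise DomainError(
                "social norm threshold undefined: delta_A + delta_B = 0")
        return self.delta_B / total

    @property
    def impact_differential(self) -> float:
        """Environmental impact differential l_B - l_A."""
        return self.l_B - self.l_A

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParams":
        unknown = set(mapping) - set(_PARAM_FIELDS)
        if unknown:
            raise DomainError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"expected a subset of {_PARAM_FIELDS}")
        for name in ("tau", "ell"):
            if name not in mapping:
                raise DomainError(_MISSING_RATE_MSG.format(name=name))
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedParams:
    """Reduced coordinates of the social dynamics.

    ``beta`` is the payoff differential gamma_A - gamma_B; ``nu`` the
    social norm threshold delta_B / (delta_A + delta_B), i.e. the unstable
    frequency above which conformism pulls the population toward all-A
    when the payoff differential vanishes.
    """

    beta: float
    nu: float


@dataclass(frozen=True)
class SystemState:
    """A point (x, e) in [0, 1] x [l_A, l_B].

    ``x`` is the frequency of the active behavior; ``e`` the perceived
    environmental state (larger = perceived as more degraded).
    """

    x: float
    e: float

    def validated(self, params: ModelParams,
                  slack: float = DOMAIN_SLACK) -> "SystemState":
        """Clamp round-off-level excursions; reject genuine violations."""
        x = _clamp(self.x, 0.0, 1.0, "x", slack)
        e = _clamp(self.e, params.l_A, params.l_B, "e", slack)
        return SystemState(x, e)


# ---------------------------------------------------------------------------
# Rates and drifts (deterministic-limit, per-capita normalization)
# ---------------------------------------------------------------------------

def _check_x(x: float, slack: float = DOMAIN_SLACK) -> float:
    return _clamp(float(x), 0.0, 1.0, "x", slack)


def _check_e(e: float, params: ModelParams,
             slack: float = DOMAIN_SLACK) -> float:
    return _clamp(float(e), params.l_A, params.l_B, "e", slack)


def social_attractiveness(x: float, params: ModelParams) -> tuple[float, float]:
    """Social attractiveness rates (lambda_A, lambda_B) at frequency x.

    lambda_A(x) = gamma_A + delta_A * x pulls B-individuals toward A;
    lambda_B(x) = gamma_B + delta_B * (1 - x) pulls A-individuals toward B.
    The delta terms encode conformism: a behavior is more attractive the
    more common it already is.
    """
    x = _check_x(x)
    lam_A = params.gamma_A + params.delta_A * x
    lam_B = params.gamma_B + params.delta_B * (1.0 - x)
    return lam_A, lam_B


def environmental_switch_rates(e: float, params: ModelParams) -> tuple[float, float]:
    """Assessment-driven switch rates (tau_A, tau_B) at environment e.

    tau_A(e) = tau * (e - l_A): the more degraded the environment is
    perceived relative to A's own impact, the faster B-individuals adopt A.
    tau_B(e) = tau * (l_B - e) is the symmetric pull back to baseline.
    Their sum is the constant tau * (l_B - l_A).
    """
    e = _check_e(e, params)
    tau_A = params.tau * (e - params.l_A)
    tau_B = params.tau * (params.l_B - e)
    return tau_A, tau_B


def impact_mixture(x: float, params: ModelParams) -> float:
    """Population mean per-capita impact l_A*x + l_B*(1-x)."""
    return params.l_A * x + params.l_B * (1.0 - x)


def drift_behavior(x: float, e: float, params: ModelParams) -> float:
    """Deterministic drift p(x, e) of the active-behavior frequency.

    p(x,e) = kappa*x*(1-x)*[beta + delta_A*x - delta_B*(1-x)]
             + tau*[e - l_A*(1-x) - l_B*x]
    """
    x = _check_x(x)
    e = _check_e(e, params)
    social = params.kappa * x * (1.0 - x) * (
        params.beta + params.delta_A * x - params.delta_B * (1.0 - x))
    env = params.tau * (e - params.l_A * (1.0 - x) - params.l_B * x)
    return social + env


def drift_behavior_rate_form(x: float, e: float, params: ModelParams) -> float:
    """p(x, e) assembled from the elementary rates.

    kappa*x*(1-x)*(lambda_A - lambda_B) + tau_A(e)*(1-x) - tau_B(e)*x.
    Algebraically identical to :func:`drift_behavior`; kept as an
    independent formulation for consistency checks.
    """
    x = _check_x(x)
    lam_A, lam_B = social_attractiveness(x, params)
    tau_A, tau_B = environmental_switch_rates(e, params)
    return (params.kappa * x * (1.0 - x) * (lam_A - lam_B)
            + tau_A * (1.0 - x) - tau_B * x)


def drift_environment(x: float, e: float, params: ModelParams) -> float:
    """Deterministic drift h(x, e) = ell * e * (l_A*x + l_B*(1-x) - e).

    The perceived environment relaxes logistically toward the population
    mean impact; it vanishes exactly on that mixture line.
    """
    x = _check_x(x)
    e = _check_e(e, params)
    return params.ell * e * (impact_mixture(x, params) - e)


def total_switching_rate(x: float, e: float, params: ModelParams) -> float:
    """Per-capita total switching intensity Omega(x, e).

    Omega = kappa*x*(1-x)*(lambda_A + lambda_B) + tau_A(e)*(1-x) + tau_B(e)*x.
    It is the aggregate rate at which *some* individual switches behavior
    (per capita) and doubles as the diffusion coefficient of the
    linear-noise fluctuation process. Low Omega at a high-x equilibrium is
    the criterion for *consistent* adoption.
    """
    x = _check_x(x)
    lam_A, lam_B = social_attractiveness(x, params)
    tau_A, tau_B = environmental_switch_rates(e, params)
    return (params.kappa * x * (1.0 - x) * (lam_A + lam_B)
            + tau_A * (1.0 - x) + tau_B * x)


def no_feedback_drift(x: float, params: ModelParams) -> float:
    """Imitation-only drift p0(x): the tau = 0 replicator reduction.

    p0(x) = kappa*x*(1-x)*[beta + delta_A*x - delta_B*(1-x)]. Its interior
    root (delta_B - beta)/(delta_A + delta_B) is the tipping frequency of
    the purely social dynamics.
    """
    x = _check_x(x)
    return params.kappa * x * (1.0 - x) * (
        params.beta + params.delta_A * x - params.delta_B * (1.0 - x))


# ---------------------------------------------------------------------------
# (beta, nu) <-> raw parameter conversions
# ---------------------------------------------------------------------------

def params_from_differentials(beta: float, nu: float, *,
                              gamma_B: float = 1.0, delta_B: float = 0.5,
                              kappa: float = 1.0, tau: float, ell: float,
                              l_A: float, l_B: float = 1.0) -> ModelParams:
    """Build a parameter set from the (beta, nu) reduced coordinates.

    Inverts beta = gamma_A - gamma_B and nu = delta_B/(delta_A + delta_B)
    with the remaining parameters anchored (gamma_B = 1, delta_B = 0.5 by
    default, matching the regime-map conventions).
    """
    if not (0.0 < nu <= 1.0):
        raise DomainError(f"nu must be in (0, 1], got {nu}")
    if delta_B <= 0.0:
        raise DomainError(f"delta_B must be > 0, got {delta_B}")
    gamma_A = gamma_B + beta
    if gamma_A < 0.0:
        raise DomainError(
            f"beta={beta} with gamma_B={gamma_B} gives negative gamma_A")
    delta_A = delta_B * (1.0 - nu) / nu
    return ModelParams(kappa=kappa, gamma_A=gamma_A, gamma_B=gamma_B,
                       delta_A=delta_A, delta_B=delta_B, tau=tau, ell=ell,
                       l_A=l_A, l_B=l_B)


def differentials_from_params(params: ModelParams) -> DerivedParams:
    """Extract (beta, nu) from a raw parameter set."""
    return DerivedParams(beta=params.beta, nu=params.nu)
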