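"""Equilibria, stability, limit cycles and regime classification.

On the invariant line e = l_A x + l_B (1 - x) (the only environment value
compatible with h = 0), equilibria of the planar system are the roots in
[0, 1] of the reduced cubic

    p(x, l_A x + l_B (1-x)) = p0(x) + tau (l_B - l_A) (1 - 2x).

Local stability comes from the Jacobian of (p, h); the possible regimes are
monostability, bistability (two stable points separated by an unstable
threshold), and a stable limit cycle around a unique unstable equilibrium.
The cycle case is certified by the Poincare-Bendixson theorem: the domain
box is forward-invariant and compact, so a unique repelling equilibrium
forces an attracting periodic orbit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import (
    DomainError,
    ModelParams,
    drift_behavior,
    drift_environment,
    impact_mixture,
    total_switching_rate,
)
from .ode_dynamics import IntegrationOptions, integrate

__all__ = [
    "STABILITY_EPS",
    "EQUILIBRIUM_RESIDUAL_TOL",
    "Equilibrium",
    "LimitCycle",
    "RegimeReport",
    "InconclusiveCycleError",
    "reduced_polynomial",
    "find_equilibria",
    "jacobian",
    "classify_stability",
    "detect_limit_cycle",
    "classify_regime",
    "consistency_check",
]

#: Eigenvalue real-part threshold separating stable/marginal/unstable.
STABILITY_EPS = 1e-9

#: Largest |(p, h)| magnitude accepted for a point to count as an equilibrium.
EQUILIBRIUM_RESIDUAL_TOL = 1e-9

#: Default thresholds of the "consistent adoption" criterion: the active
#: behavior is consistently adopted at a stable equilibrium with x* >= 0.9
#: and total switching rate Omega(x*, e*) <= 0.05.
CONSISTENCY_X_MIN = 0.9
CONSISTENCY_OMEGA_MAX = 0.05

_ROOT_MERGE_TOL = 1e-8
_BOUNDARY_CLIP_TOL = 1e-10


class InconclusiveCycleError(RuntimeError):
    """Limit-cycle detection did not stabilize within the horizon."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the planar system with its local classification."""

    x_star: float
    e_star: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "unstable" | "marginal"
    omega_star: float
    consistent: bool

    def to_record(self) -> dict:
        return {
            "x_star": self.x_star,
            "e_star": self.e_star,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "stability": self.stability,
            "omega_star": self.omega_star,
            "consistent": self.consistent,
        }


@dataclass(frozen=True)
class LimitCycle:
    """Measured attracting periodic orbit."""

    period: float
    x_range: tuple[float, float]
    e_range: tuple[float, float]


@dataclass
class RegimeReport:
    """Full dynamical classification of a parameter set."""

    equilibria: list[Equilibrium]
    regime: str  # "monostable" | "bistable" | "limit_cycle"
    cycle: LimitCycle | None = None
    warnings: list[str] = field(default_factory=list)

    def stable(self) -> list[Equilibrium]:
        return [eq for eq in self.equilibria if eq.stability == "stable"]

    def to_json(self) -> str:
        payload = {
            "regime": self.regime,
            "equilibria": [eq.to_record() for eq in self.equilibria],
            "cycle": (None if self.cycle is None else {
                "period": self.cycle.period,
                "x_range": list(self.cycle.x_range),
                "e_range": list(self.cycle.e_range),
            }),
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# Reduced cubic and root finding
# ---------------------------------------------------------------------------

def reduced_polynomial(params: ModelParams) -> np.ndarray:
    """Coefficients (highest power first) of p restricted to h = 0.

    Substituting e = l_A x + l_B (1-x) into p leaves
    kappa x(1-x)(beta - delta_B + (delta_A+delta_B) x)
    + tau (l_B - l_A) (1 - 2x), a polynomial of degree <= 3.
    """
    k = params.kappa
    s = params.delta_A + params.delta_B
    b = params.beta - params.delta_B
    td = params.tau * params.impact_differential
    # kappa * (x - x^2)(b + s x) = kappa*(-s x^3 + (s - b) x^2 + b x)
    return np.array([-k * s, k * (s - b), k * b - 2.0 * td, td])


def _roots_in_unit_interval(coeffs: np.ndarray) -> list[float]:
    """Real roots of the (possibly degenerate) cubic restricted to [0, 1]."""
    c = np.asarray(coeffs, dtype=float)
    scale = np.max(np.abs(c))
    if scale == 0.0:
        raise ValueError("identically-zero reduced polynomial: every x on "
                         "the mixture line is an equilibrium (kappa = tau "
                         "= 0 or all social terms vanish)")
    # trim numerically-vanishing leading coefficients before the companion
    # matrix; keeps the eigenproblem well-conditioned when kappa ~ 0
    nz = np.nonzero(np.abs(c) > 1e-14 * scale)[0]
    c = c[nz[0]:]
    if c.size == 1:
        return []
    roots = np.roots(c)  # companion-matrix eigenvalues
    real = [float(r.real) for r in roots if abs(r.imag) <= 1e-9]
    kept: list[float] = []
    for r in sorted(real):
        if -_BOUNDARY_CLIP_TOL <= r <= 1.0 + _BOUNDARY_CLIP_TOL:
            r = min(max(r, 0.0), 1.0)
            if not kept or r - kept[-1] > _ROOT_MERGE_TOL:
                kept.append(r)
    return kept


def jacobian(x: float, e: float, params: ModelParams) -> np.ndarray:
    """Exact Jacobian of (p, h) at (x, e).

    Closed-form partial derivatives; in particular dp/de = tau exactly and
    dh/dx = ell * e * (l_A - l_B).
    """
    k, tau, ell = params.kappa, params.tau, params.ell
    s = params.delta_A + params.delta_B
    b = params.beta - params.delta_B
    dp_dx = (k * ((1.0 - 2.0 * x) * (b + s * x) + s * x * (1.0 - x))
             - tau * params.impact_differential)
    dp_de = tau
    dh_dx = ell * e * (params.l_A - params.l_B)
    dh_de = ell * (impact_mixture(x, params) - 2.0 * e)
    return np.array([[dp_dx, dp_de], [dh_dx, dh_de]])


def _residual(x: float, e: float, params: ModelParams) -> float:
    return max(abs(drift_behavior(x, e, params)),
               abs(drift_environment(x, e, params)))


def classify_stability(x: float, e: float, params: ModelParams,
                       eps: float = STABILITY_EPS
                       ) -> tuple[str, tuple[complex, complex]]:
    """Stability label and eigenvalues at an equilibrium point."""
    if _residual(x, e, params) > EQUILIBRIUM_RESIDUAL_TOL:
        raise ValueError(
            f"({x}, {e}) is not an equilibrium: residual "
            f"{_residual(x, e, params):.3g} > {EQUILIBRIUM_RESIDUAL_TOL}")
    ev = np.linalg.eigvals(jacobian(x, e, params))
    ev = tuple(sorted((complex(v) for v in ev), key=lambda z: z.real))
    top = max(v.real for v in ev)
    if top < -eps:
        label = "stable"
    elif top > eps:
        label = "unstable"
    else:
        label = "marginal"
    return label, ev


def find_equilibria(params: ModelParams,
                    x_min: float = CONSISTENCY_X_MIN,
                    omega_max: float = CONSISTENCY_OMEGA_MAX
                    ) -> list[Equilibrium]:
    """All equilibria in [0,1] x [l_A, l_B], classified and annotated.

    Roots of the reduced cubic, each paired with the forced environment
    value e* = l_A x* + l_B (1 - x*), the Jacobian eigenvalues, the total
    switching rate Omega(x*, e*), and the default consistency flag.
    """
    out = []
    for x_star in _roots_in_unit_interval(reduced_polynomial(params)):
        # polish the companion-matrix root with a few Newton steps on the
        # reduced polynomial so the residual check passes at 1e-9
        coeffs = reduced_polynomial(params)
        dcoeffs = np.polyder(coeffs)
        for _ in range(5):
            f = np.polyval(coeffs, x_star)
            df = np.polyval(dcoeffs, x_star)
            if df == 0.0 or abs(f) < 1e-15:
                break
            x_star = min(max(x_star - f / df, 0.0), 1.0)
        e_star = impact_mixture(x_star, params)
        stability, ev = classify_stability(x_star, e_star, params)
        omega = total_switching_rate(x_star, e_star, params)
        eq = Equilibrium(
            x_star=x_star, e_star=e_star, eigenvalues=ev,
            stability=stability, omega_star=omega,
            consistent=(stability == "stable"
                        and x_star >= x_min and omega <= omega_max))
        out.append(eq)
    return out


def consistency_check(eq: Equilibrium, x_min: float = CONSISTENCY_X_MIN,
                      omega_max: float = CONSISTENCY_OMEGA_MAX) -> bool:
    """Is the behavior consistently adopted at this stable equilibrium?

    True iff x* >= x_min (high adoption) and Omega(x*, e*) <= omega_max
    (few residual switches). Only meaningful at stable equilibria.
    """
    if eq.stability != "stable":
        raise ValueError("consistency is defined at stable equilibria only; "
                         f"got a {eq.stability} point")
    return eq.x_star >= x_min and eq.omega_star <= omega_max


# ---------------------------------------------------------------------------
# Limit cycles
# ---------------------------------------------------------------------------

def _peaks(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima with parabolic sub-sample refinement."""
    v = values
    idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
    t_pk, v_pk = [], []
    for i in idx:
        y0, y1, y2 = v[i - 1], v[i], v[i + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        dt = times[i + 1] - times[i]
        t_pk.append(times[i] + delta * dt)
        v_pk.append(y1 - 0.25 * (y0 - y2) * delta)
    return np.array(t_pk), np.array(v_pk)


def _measure_cycle(params: ModelParams, x0: float, e0: float,
                   transient: float, horizon: float,
                   sample_dt: float) -> LimitCycle:
    opts = IntegrationOptions(t_end=transient + horizon,
                              dense_output_dt=sample_dt)
    traj = integrate(params, x0, e0, opts)
    keep = traj.times >= transient
    t, xs, es = traj.times[keep], traj.x[keep], traj.e[keep]
    t_pk, x_pk = _peaks(t, xs)
    if t_pk.size < 6:
        raise InconclusiveCycleError(
            f"only {t_pk.size} oscillation peaks within horizon {horizon}")
    periods = np.diff(t_pk[-6:])
    heights = x_pk[-6:]
    if (np.std(periods) > 0.01 * np.mean(periods)
            or np.ptp(heights) > 0.01 * max(np.ptp(xs), 1e-12)):
        raise InconclusiveCycleError("peak sequence has not stabilized")
    n_last = int(np.ceil(np.mean(periods) / sample_dt)) + 1
    xs_c, es_c = xs[-n_last:], es[-n_last:]
    return LimitCycle(period=float(np.mean(periods)),
                      x_range=(float(xs_c.min()), float(xs_c.max())),
                      e_range=(float(es_c.min()), float(es_c.max())))


def detect_limit_cycle(params: ModelParams,
                       horizon: float = 600.0,
                       sample_dt: float = 0.05) -> LimitCycle | None:
    """Detect (and measure) an attracting periodic orbit, if any.

    If the unique equilibrium is unstable, Poincare-Bendixson guarantees a
    cycle in the invariant box; it is then measured from a post-transient
    trajectory. If stable equilibria exist, a fan of boundary-adjacent
    starts is integrated; a cycle is reported only when a trajectory fails
    to converge to any equilibrium and its oscillation peaks stabilize.
    Raises :class:`InconclusiveCycleError` when peaks fail to stabilize.
    """
    equilibria = find_equilibria(params)
    stable = [eq for eq in equilibria if eq.stability == "stable"]

    if len(equilibria) == 1 and equilibria[0].stability == "unstable":
        eq = equilibria[0]
        rate = min(max(abs(ev.real) for ev in eq.eigenvalues), params.ell)
        transient = 10.0 / max(rate, 1e-3)
        x0 = min(max(eq.x_star + 0.01, 0.0), 1.0)
        return _measure_cycle(params, x0, eq.e_star, transient, horizon,
                              sample_dt)

    if not stable:
        return None  # marginal-only: no PB argument, no claim

    # stable equilibria exist: probe from near-boundary starts
    eps = 1e-3
    starts = [(eps, params.l_B - eps), (1.0 - eps, params.l_A + eps),
              (eps, params.l_A + eps), (1.0 - eps, params.l_B - eps),
              (0.5, params.l_B - eps)]
    transient = 10.0 / min(1.0, params.ell)
    for x0, e0 in starts:
        opts = IntegrationOptions(t_end=transient + horizon,
                                  dense_output_dt=sample_dt)
        traj = integrate(params, x0, e0, opts)
        xT, eT = traj.terminal_state()
        near_eq = any(abs(xT - eq.x_star) < 1e-3 and abs(eT - eq.e_star) < 1e-3
                      for eq in equilibria)
        if near_eq or traj.at_equilibrium:
            continue
        return _measure_cycle(params, x0, e0, transient, horizon, sample_dt)
    return None


def classify_regime(params: ModelParams,
                    measure_cycle: bool = True) -> RegimeReport:
    """Label the parameter set monostable, bistable, or limit_cycle.

    With ``measure_cycle=False`` the cycle (when its existence follows from
    Poincare-Bendixson) is asserted but not measured — useful in sweeps.
    """
    equilibria = find_equilibria(params)
    notes: list[str] = []
    stable = [eq for eq in equilibria if eq.stability == "stable"]
    marginal = [eq for eq in equilibria if eq.stability == "marginal"]
    if marginal:
        notes.append(
            "marginal equilibrium present (near a bifurcation boundary); "
            "classification by follow-up simulation")
        stable = stable + _simulation_reclassify(params, marginal)

    if len(stable) >= 2:
        if len(stable) > 2:
            notes.append("more than two attractors resolved; reporting "
                         "bistable per the two-basin structure")
        return RegimeReport(equilibria, "bistable", warnings=notes)
    if len(stable) == 1:
        return RegimeReport(equilibria, "monostable", warnings=notes)
    # unique unstable equilibrium: Poincare-Bendixson cycle
    cycle = None
    if measure_cycle:
        cycle = detect_limit_cycle(params)
    return RegimeReport(equilibria, "limit_cycle", cycle=cycle,
                        warnings=notes)


def _simulation_reclassify(params: ModelParams,
                           marginal: Sequence[Equilibrium]
                           ) -> list[Equilibrium]:
    """Probe marginal points by perturbation; return those that attract."""
    attracting = []
    for eq in marginal:
        opts = IntegrationOptions(t_end=200.0 / params.ell)
        traj = integrate(params, min(max(eq.x_star + 1e-3, 0.0), 1.0),
                         eq.e_star, opts)
        xT, eT = traj.terminal_state()
        if abs(xT - eq.x_star) < 1e-2 and abs(eT - eq.e_star) < 1e-2:
            attracting.append(eq)
        else:
            warnings.warn("marginal equilibrium did not re-attract the "
                          "perturbed trajectory", stacklevel=2)
    return attracting
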