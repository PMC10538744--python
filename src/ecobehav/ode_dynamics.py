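"""Deterministic large-population limit: ODE integration and path summaries.

Integrates the planar system

    dx/dt = p(x, e)      (behavior frequency)
    de/dt = h(x, e)      (perceived environmental state)

with an adaptive Runge-Kutta 4(5) scheme. The domain [0,1] x [l_A, l_B] is
forward-invariant analytically; integrated states are projected back when
round-off pushes them out by less than the domain slack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    DOMAIN_SLACK,
    DomainError,
    ModelParams,
    drift_behavior,
    drift_environment,
)

__all__ = ["IntegrationOptions", "Trajectory", "integrate", "rise_time"]

#: sup-norm of (p, h) below which the terminal state is flagged "at
#: equilibrium". Sits above the accumulated integrator drift at default
#: tolerances over long horizons.
EQUILIBRIUM_RESIDUAL = 1e-6


@dataclass(frozen=True)
class IntegrationOptions:
    """Numerical controls for :func:`integrate`."""

    t_end: float = 200.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = np.inf
    dense_output_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("integrator tolerances must be > 0")
        if self.dense_output_dt <= 0:
            raise ValueError("dense_output_dt must be > 0")


@dataclass
class Trajectory:
    """A deterministic path of (x, e) sampled on a regular grid."""

    times: np.ndarray
    x: np.ndarray
    e: np.ndarray
    params: ModelParams
    options: IntegrationOptions
    at_equilibrium: bool = field(default=False)

    def terminal_state(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.e[-1])

    # -- persistence --------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write (t, x, e) columns plus a JSON sidecar of params/options."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("t,x,e\n")
            for t, x, e in zip(self.times, self.x, self.e):
                fh.write(f"{float(t)!r},{float(x)!r},{float(e)!r}\n")
        sidecar = {
            "params": self.params.to_dict(),
            "options": {
                "t_end": self.options.t_end,
                "rel_tol": self.options.rel_tol,
                "abs_tol": self.options.abs_tol,
                "max_step": (None if np.isinf(self.options.max_step)
                             else self.options.max_step),
                "dense_output_dt": self.options.dense_output_dt,
            },
            "at_equilibrium": self.at_equilibrium,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        data = np.atleast_2d(data)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        opts = dict(sidecar["options"])
        if opts.get("max_step") is None:
            opts["max_step"] = np.inf
        return cls(times=data[:, 0], x=data[:, 1], e=data[:, 2],
                   params=ModelParams.from_dict(sidecar["params"]),
                   options=IntegrationOptions(**opts),
                   at_equilibrium=sidecar["at_equilibrium"])


#: Excursion allowed for the integrator's internal trial stages. The field
#: points inward on the boundary, so accepted steps stay within the local
#: error tolerance of the domain; trial stages may overshoot further.
_TRIAL_STAGE_SLACK = 1e-5


def _project(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Project small excursions back into the domain; reject real escapes."""
    x, e = y
    if not (-_TRIAL_STAGE_SLACK <= x <= 1 + _TRIAL_STAGE_SLACK):
        # Integrator escaped well beyond round-off: report, never truncate.
        raise DomainError(f"x={x} left [0,1] during integration")
    out = np.empty(2)
    out[0] = min(max(x, 0.0), 1.0)
    out[1] = min(max(e, params.l_A), params.l_B)
    return out


def integrate(params: ModelParams, x0: float, e0: float,
              options: IntegrationOptions | None = None) -> Trajectory:
    """Integrate the deterministic limit from (x0, e0).

    Returns a :class:`Trajectory` sampled every ``dense_output_dt`` time
    units.  The terminal state is flagged ``at_equilibrium`` when the
    sup-norm of the vector field falls below ``1e-8`` there.
    """
    options = options or IntegrationOptions()
    if not (0.0 <= x0 <= 1.0):
        raise DomainError(f"x0={x0} outside [0, 1]")
    if not (params.l_A <= e0 <= params.l_B):
        raise DomainError(f"e0={e0} outside [{params.l_A}, {params.l_B}]")

    def rhs(_t, y):
        yy = _project(y, params)
        return (drift_behavior(yy[0], yy[1], params),
                drift_environment(yy[0], yy[1], params))

    n = int(np.floor(options.t_end / options.dense_output_dt)) + 1
    t_eval = np.linspace(0.0, options.t_end, n)
    sol = solve_ivp(rhs, (0.0, options.t_end), [x0, e0], method="RK45",
                    t_eval=t_eval, rtol=options.rel_tol,
                    atol=options.abs_tol, max_step=options.max_step)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    xs = np.clip(sol.y[0], 0.0, 1.0)
    es = np.clip(sol.y[1], params.l_A, params.l_B)
    resid = max(abs(drift_behavior(xs[-1], es[-1], params)),
                abs(drift_environment(xs[-1], es[-1], params)))
    return Trajectory(times=sol.t, x=xs, e=es, params=params,
                      options=options,
                      at_equilibrium=resid < EQUILIBRIUM_RESIDUAL)


def rise_time(traj: Trajectory, low: float = 0.01,
              high: float = 0.95) -> float | None:
    """First time x crosses above ``high``, linearly interpolated.

    The trajectory must start at or below ``low`` (the "rise from near
    zero" convention). Returns ``None`` if the path never crosses.
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"need 0 <= low < high <= 1, got ({low}, {high})")
    if traj.x[0] > low:
        raise ValueError(
            f"trajectory starts at x={traj.x[0]:.4g} > low={low}")
    above = np.nonzero(traj.x >= high)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:  # possible only if low == high boundary slack; treat as t0
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    x0, x1 = traj.x[i - 1], traj.x[i]
    if x1 == x0:
        return float(t1)
    return float(t0 + (high - x0) / (x1 - x0) * (t1 - t0))
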