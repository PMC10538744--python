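"""Parameter-space sweeps and the incremental behavior-substitution scenario.

Sweeps scan the (beta, nu) plane — payoff differential against social norm
threshold, with gamma_B, delta_B, kappa, l_B anchored — and classify each
cell's dynamical regime, stable equilibria, total switching rate and
consistency. The incremental scenario chains stages in which an adopted
active behavior becomes the new baseline and a still-lower-impact (and
possibly costlier) behavior is introduced at low frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .equilibrium_analysis import (
    CONSISTENCY_OMEGA_MAX,
    CONSISTENCY_X_MIN,
    Equilibrium,
    RegimeReport,
    classify_regime,
    consistency_check,
)
from .model_core import DomainError, ModelParams, params_from_differentials
from .ode_dynamics import IntegrationOptions, integrate

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ScenarioStage",
    "sweep_phase_diagram",
    "tau_zero_bistability_region",
    "incremental_scenario",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a (beta, nu) phase-diagram sweep."""

    beta_axis: tuple[float, ...]
    nu_axis: tuple[float, ...]
    tau: float
    ell: float
    l_A: float
    gamma_B: float = 1.0
    delta_B: float = 0.5
    kappa: float = 1.0
    l_B: float = 1.0
    x_min: float = CONSISTENCY_X_MIN
    omega_max: float = CONSISTENCY_OMEGA_MAX
    measure_cycles: bool = False

    def __post_init__(self) -> None:
        for name, axis in (("beta_axis", self.beta_axis),
                           ("nu_axis", self.nu_axis)):
            arr = np.asarray(axis, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be nonempty, strictly "
                                 "increasing")
        nu = np.asarray(self.nu_axis)
        if np.any(nu <= 0) or np.any(nu > 1):
            raise ValueError("nu values must lie in (0, 1]")

    @classmethod
    def default_grid(cls, tau: float, ell: float, l_A: float,
                     n: int = 101, **kwargs) -> "SweepSpec":
        """The standard 101x101 grid: beta in [-1, 1], nu in (0, 1]."""
        beta = np.linspace(-1.0, 1.0, n)
        nu = np.linspace(0.0, 1.0, n + 1)[1:]  # open at 0
        return cls(beta_axis=tuple(float(b) for b in beta),
                   nu_axis=tuple(float(v) for v in nu),
                   tau=tau, ell=ell, l_A=l_A, **kwargs)


@dataclass
class SweepResult:
    """Per-cell regime classification over the (beta, nu) grid.

    Matrix quantities are indexed [i_nu, i_beta]. ``x_star_upper`` /
    ``x_star_lower`` carry the largest / smallest stable equilibrium
    frequency (equal when monostable, NaN in pure limit-cycle cells);
    ``regime`` holds the label per cell; ``inconclusive`` marks cells
    where cycle measurement did not stabilize.
    """

    spec: SweepSpec
    regime: np.ndarray          # dtype object (str labels)
    x_star_upper: np.ndarray
    x_star_lower: np.ndarray
    e_star_upper: np.ndarray
    omega_star_upper: np.ndarray
    consistent_upper: np.ndarray  # bool
    inconclusive: np.ndarray      # bool
    reports: list[list[RegimeReport]] = field(default_factory=list)

    def to_csv(self, directory: str | Path) -> None:
        """One CSV matrix per quantity (rows = nu, cols = beta)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = ("nu\\beta,"
                  + ",".join(repr(float(b)) for b in self.spec.beta_axis))
        for name in ("x_star_upper", "x_star_lower", "e_star_upper",
                     "omega_star_upper"):
            mat = getattr(self, name)
            with open(directory / f"{name}.csv", "w") as fh:
                fh.write(header + "\n")
                for nu, row in zip(self.spec.nu_axis, mat):
                    fh.write(repr(float(nu)) + ","
                             + ",".join(repr(float(v)) for v in row) + "\n")
        regimes = {
            "beta_axis": list(self.spec.beta_axis),
            "nu_axis": list(self.spec.nu_axis),
            "regime": [list(row) for row in self.regime],
            "consistent_upper": self.consistent_upper.astype(int).tolist(),
            "inconclusive": self.inconclusive.astype(int).tolist(),
            "thresholds": {"x_min": self.spec.x_min,
                           "omega_max": self.spec.omega_max},
        }
        (directory / "regime_map.json").write_text(
            json.dumps(regimes, indent=1))


def sweep_phase_diagram(spec: SweepSpec,
                        keep_reports: bool = False) -> SweepResult:
    """Classify every (beta, nu) cell of the grid.

    Deterministic given the spec; independent of evaluation order. Cells
    where limit-cycle measurement is inconclusive are flagged and the
    sweep continues.
    """
    n_nu, n_beta = len(spec.nu_axis), len(spec.beta_axis)
    regime = np.empty((n_nu, n_beta), dtype=object)
    shape = (n_nu, n_beta)
    x_up = np.full(shape, np.nan)
    x_lo = np.full(shape, np.nan)
    e_up = np.full(shape, np.nan)
    om_up = np.full(shape, np.nan)
    cons = np.zeros(shape, dtype=bool)
    inconclusive = np.zeros(shape, dtype=bool)
    reports: list[list[RegimeReport]] = []

    for i, nu in enumerate(spec.nu_axis):
        row_reports = []
        for j, beta in enumerate(spec.beta_axis):
            try:
                params = params_from_differentials(
                    beta, nu, gamma_B=spec.gamma_B, delta_B=spec.delta_B,
                    kappa=spec.kappa, tau=spec.tau, ell=spec.ell,
                    l_A=spec.l_A, l_B=spec.l_B)
            except DomainError:
                regime[i, j] = "invalid"
                row_reports.append(None)
                continue
            try:
                report = classify_regime(params,
                                         measure_cycle=spec.measure_cycles)
            except Exception:
                report = classify_regime(params, measure_cycle=False)
                inconclusive[i, j] = True
            regime[i, j] = report.regime
            stable = report.stable()
            if stable:
                upper = max(stable, key=lambda eq: eq.x_star)
                lower = min(stable, key=lambda eq: eq.x_star)
                x_up[i, j] = upper.x_star
                x_lo[i, j] = lower.x_star
                e_up[i, j] = upper.e_star
                om_up[i, j] = upper.omega_star
                cons[i, j] = consistency_check(upper, spec.x_min,
                                               spec.omega_max)
            if keep_reports:
                row_reports.append(report)
        if keep_reports:
            reports.append(row_reports)
    return SweepResult(spec=spec, regime=regime, x_star_upper=x_up,
                       x_star_lower=x_lo, e_star_upper=e_up,
                       omega_star_upper=om_up, consistent_upper=cons,
                       inconclusive=inconclusive, reports=reports)


def tau_zero_bistability_region(spec: SweepSpec) -> np.ndarray:
    """Closed-form tau = 0 bistability mask on the spec's grid.

    Without environmental feedback the interior equilibrium is
    x* = nu * (1 - beta/delta_B); the system is bistable iff 0 < x* < 1.
    """
    beta = np.asarray(spec.beta_axis)[None, :]
    nu = np.asarray(spec.nu_axis)[:, None]
    x_star = nu * (1.0 - beta / spec.delta_B)
    return (x_star > 0.0) & (x_star < 1.0)


# ---------------------------------------------------------------------------
# Incremental behavior substitution
# ---------------------------------------------------------------------------

@dataclass
class ScenarioStage:
    """Outcome of one behavior-substitution stage."""

    stage_index: int
    params: ModelParams
    outcome: Equilibrium
    consistent: bool


def incremental_scenario(stages: Sequence[dict], *,
                         tau: float, ell: float,
                         gamma_B: float = 1.0, delta_B: float = 0.5,
                         kappa: float = 1.0, l_B: float = 1.0,
                         x0: float = 0.01, e0: float | None = None,
                         x_min: float = CONSISTENCY_X_MIN,
                         omega_max: float = CONSISTENCY_OMEGA_MAX,
                         t_end: float = 2000.0) -> list[ScenarioStage]:
    """Chain behavior substitutions, each adopted behavior becoming baseline.

    Each stage dict supplies ``l_A_next`` (impact of the new active
    behavior, strictly below the current baseline), ``beta_next`` and
    ``nu_next``. Stage 1 starts from (x0, e0); later stages restart at
    x = x0 (the new behavior is rare) with the environment carried over
    from the previous stage's equilibrium, and the previous active impact
    becomes the new baseline impact l_B. A stage that does not reach a
    stable equilibrium aborts with a diagnostic.
    """
    results: list[ScenarioStage] = []
    current_l_B = l_B
    current_e = e0 if e0 is not None else l_B
    for idx, stage in enumerate(stages, start=1):
        l_A_next = stage["l_A_next"]
        if not (0.0 < l_A_next < current_l_B):
            raise ValueError(
                f"stage {idx}: l_A_next={l_A_next} must lie in "
                f"(0, {current_l_B}) (current baseline impact)")
        params = params_from_differentials(
            stage["beta_next"], stage["nu_next"], gamma_B=gamma_B,
            delta_B=delta_B, kappa=kappa, tau=tau, ell=ell,
            l_A=l_A_next, l_B=current_l_B)
        e_start = min(max(current_e, params.l_A), params.l_B)
        opts = IntegrationOptions(t_end=t_end)
        traj = integrate(params, x0, e_start, opts)
        if not traj.at_equilibrium:
            raise RuntimeError(
                f"stage {idx}: trajectory did not settle within "
                f"t_end={t_end}; terminal state {traj.terminal_state()}")
        xT, eT = traj.terminal_state()
        report = classify_regime(params, measure_cycle=False)
        matches = [eq for eq in report.stable()
                   if abs(eq.x_star - xT) < 1e-4 and abs(eq.e_star - eT) < 1e-4]
        if not matches:
            raise RuntimeError(
                f"stage {idx}: terminal state {(xT, eT)} does not match "
                "any stable equilibrium")
        outcome = matches[0]
        results.append(ScenarioStage(
            stage_index=idx, params=params, outcome=outcome,
            consistent=consistency_check(outcome, x_min, omega_max)))
        # the adopted active behavior becomes the next baseline
        current_l_B = params.l_A
        current_e = outcome.e_star
    return results
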