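"""Linear-noise (Ornstein-Uhlenbeck) analysis of finite-N fluctuations.

The sqrt(N)-scaled deviations (eta_A, eta_E) of the stochastic process
from the deterministic path converge to a linear diffusion

    d eta = A eta dt + (sqrt(Omega), 0) dW

whose drift A is the Jacobian of (p, h) along the deterministic path and
whose only noisy coordinate is the behavior frequency: the environment
fluctuates solely through its coupling to eta_A. At a stable equilibrium
the stationary covariance Sigma solves the Lyapunov equation
A Sigma + Sigma A^T + D = 0 with D = diag(Omega(x*, e*), 0).

Two fluctuation summaries are reported side by side: the total switching
rate Omega(x*, e*) itself — the headline per-capita diffusion strength and
the quantity entering the consistent-adoption criterion — and the Lyapunov
stationary covariance, which additionally folds in the relaxation induced
by the drift. They coincide only when the drift is a unit-rate decay; both
are surfaced, clearly labeled, rather than conflated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .equilibrium_analysis import EQUILIBRIUM_RESIDUAL_TOL, Equilibrium, jacobian
from .model_core import ModelParams, total_switching_rate
from .pdmp_simulator import PDMPTrajectory

__all__ = [
    "OUSummary",
    "diffusion_coefficient",
    "ou_drift_matrix",
    "stationary_covariance",
    "ou_summary",
    "simulate_ou",
    "empirical_fluctuation_variance",
]


@dataclass
class OUSummary:
    """Stationary fluctuation summary at a stable equilibrium."""

    equilibrium: Equilibrium
    drift_matrix: np.ndarray
    diffusion_value: float  # Omega(x*, e*): per-capita switching rate
    stationary_cov: np.ndarray | None
    valid: bool  # drift Hurwitz, covariance well-defined

    def to_json(self) -> str:
        return json.dumps({
            "equilibrium": self.equilibrium.to_record(),
            "drift_matrix": self.drift_matrix.tolist(),
            "diffusion_value": self.diffusion_value,
            "stationary_cov": (None if self.stationary_cov is None
                               else self.stationary_cov.tolist()),
            "valid": self.valid,
        }, indent=1)


def diffusion_coefficient(x: float, e: float, params: ModelParams) -> float:
    """Infinitesimal variance of the behavior fluctuation: Omega(x, e).

    The noise amplitude multiplying the Brownian increment is its square
    root, so the quadratic variation accrues at rate Omega.
    """
    return total_switching_rate(x, e, params)


def _check_equilibrium(eq: Equilibrium, params: ModelParams) -> None:
    from .model_core import drift_behavior, drift_environment

    resid = max(abs(drift_behavior(eq.x_star, eq.e_star, params)),
                abs(drift_environment(eq.x_star, eq.e_star, params)))
    if resid > EQUILIBRIUM_RESIDUAL_TOL:
        raise ValueError(f"not an equilibrium: residual {resid:.3g}")


def ou_drift_matrix(eq: Equilibrium, params: ModelParams) -> np.ndarray:
    """Drift matrix of the fluctuation process at an equilibrium.

    This is the Jacobian of (p, h) evaluated at (x*, e*); in particular
    its (1, 2) entry is tau exactly.
    """
    _check_equilibrium(eq, params)
    return jacobian(eq.x_star, eq.e_star, params)


def stationary_covariance(eq: Equilibrium,
                          params: ModelParams) -> np.ndarray | None:
    """Stationary covariance of (eta_A, eta_E) at a stable equilibrium.

    Solves A Sigma + Sigma A^T + D = 0 with D = diag(Omega(x*, e*), 0).
    Returns None when the drift is not Hurwitz (no stationary law).
    """
    A = ou_drift_matrix(eq, params)
    if max(np.linalg.eigvals(A).real) >= 0:
        return None
    D = np.diag([diffusion_coefficient(eq.x_star, eq.e_star, params), 0.0])
    sigma = solve_continuous_lyapunov(A, -D)
    return 0.5 * (sigma + sigma.T)  # symmetrize round-off


def ou_summary(eq: Equilibrium, params: ModelParams) -> OUSummary:
    """Assemble drift, diffusion and stationary covariance in one record."""
    A = ou_drift_matrix(eq, params)
    omega = diffusion_coefficient(eq.x_star, eq.e_star, params)
    sigma = stationary_covariance(eq, params)
    return OUSummary(equilibrium=eq, drift_matrix=A, diffusion_value=omega,
                     stationary_cov=sigma, valid=sigma is not None)


def simulate_ou(eq: Equilibrium, params: ModelParams, t_end: float,
                dt: float, seed: int,
                eta0: tuple[float, float] = (0.0, 0.0)
                ) -> dict[str, np.ndarray]:
    """Euler-Maruyama path of the fluctuation process pinned at (x*, e*).

    Noise enters the eta_A component only, with per-step standard
    deviation sqrt(Omega) * sqrt(dt). Returns arrays t, eta_A, eta_E.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    A = ou_drift_matrix(eq, params)
    amp = np.sqrt(diffusion_coefficient(eq.x_star, eq.e_star, params))
    rng = np.random.default_rng(seed)
    n = int(np.floor(t_end / dt)) + 1
    eta = np.empty((n, 2))
    eta[0] = eta0
    sq_dt = np.sqrt(dt)
    noise = rng.standard_normal(n - 1) * amp * sq_dt
    for i in range(n - 1):
        eta[i + 1] = eta[i] + dt * (A @ eta[i])
        eta[i + 1, 0] += noise[i]
    return {"t": np.arange(n) * dt, "eta_A": eta[:, 0], "eta_E": eta[:, 1]}


def empirical_fluctuation_variance(runs: list[PDMPTrajectory],
                                   eq: Equilibrium,
                                   window: tuple[float, float],
                                   n_batches: int = 10) -> dict:
    """N-scaled stationary variance of (X^N, E^N) from PDMP ensembles.

    Pools all replicates over the time window (past burn-in) and reports
    N*Var(X^N) and N*Var(E^N) — the finite-N estimates of the OU
    stationary variances — with batch-means standard errors. Runs whose
    mean drifts across the window by more than two standard errors are
    flagged as not equilibrated.
    """
    if not runs:
        raise ValueError("need at least one run")
    N = runs[0].config.N
    t = runs[0].sampled_t
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2 * n_batches:
        raise ValueError("window too short for batch means")
    X = np.stack([r.sampled_x for r in runs])[:, mask]
    E = np.stack([r.sampled_e for r in runs])[:, mask]

    def batched(values: np.ndarray) -> tuple[float, float]:
        splits = np.array_split(values, n_batches, axis=1)
        per_batch = np.array([N * v.var(ddof=1) for v in splits])
        return (float(N * values.var(ddof=1)),
                float(per_batch.std(ddof=1) / np.sqrt(n_batches)))

    var_x, se_x = batched(X)
    var_e, se_e = batched(E)

    # drift diagnostic: per-run first-half vs second-half window means
    half = X.shape[1] // 2
    diffs = X[:, :half].mean(axis=1) - X[:, half:].mean(axis=1)
    d_mean = diffs.mean()
    d_se = (diffs.std(ddof=1) / np.sqrt(len(runs))
            if len(runs) > 1 else abs(d_mean))
    equilibrated = bool(abs(d_mean) <= 2.0 * max(d_se, 1e-300))
    return {
        "scaled_var_x": var_x, "se_x": se_x,
        "scaled_var_e": var_e, "se_e": se_e,
        "N": N, "n_runs": len(runs),
        "equilibrated": equilibrated,
    }
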