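"""Exact stochastic simulation of the finite-N behavior-environment PDMP.

Behavior counts jump by one individual at a time while the perceived
environment flows deterministically between jumps (a Piecewise
Deterministic Markov Process). Jumps are simulated exactly by thinning
(uniformization): candidate times arrive as a Poisson stream at a constant
dominating rate xi_N that bounds the total event rate everywhere in the
domain; at each candidate one of the four elementary channels

    social B->A, social A->B, assessment B->A, assessment A->B

fires with probability rate/xi_N, otherwise the candidate is a "phantom"
event that changes nothing. Between candidates the environment follows the
logistic flow de/dt = ell*e*(c - e) with c = l_A x + l_B (1-x) held fixed,
which is solvable in closed form (the default); an explicit Euler update
is available for fidelity checks against the reference scheme.

Two execution paths share the algorithm: a compiled kernel that records
the state on a regular time grid (used for large-N ensembles), and a
pure-Python loop that records the full event log.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_core import DomainError, ModelParams

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn
        return wrap if not args or not callable(args[0]) else args[0]


__all__ = [
    "EVENT_TYPES",
    "PDMPConfig",
    "PDMPTrajectory",
    "rate_bound",
    "event_rates",
    "environment_update",
    "simulate_pdmp",
    "simulate_ensemble",
    "ensemble_statistics",
]

#: Event-type labels, indexed by the integer codes stored in event logs.
EVENT_TYPES = ("phantom", "social_B_to_A", "social_A_to_B",
               "env_B_to_A", "env_A_to_B")

#: Event-log length beyond which the simulator keeps only the grid path.
MAX_EVENT_LOG = 10_000_000


@dataclass(frozen=True)
class PDMPConfig:
    """Configuration of a single stochastic run.

    ``x0`` must be a multiple of 1/N (a whole number of individuals).
    ``env_update`` selects the between-jump environment integrator:
    ``"closed_form"`` (exact logistic flow, default) or ``"euler"``
    (explicit steps capped at ``euler_dt``). ``freeze_environment`` holds
    e fixed at e0 — a diagnostic mode in which the jump chain reduces to a
    birth-death process with a known stationary law.
    """

    N: int
    x0: float
    e0: float
    t_end: float
    seed: int
    env_update: str = "closed_form"
    euler_dt: float = 1e-3
    sample_dt: float = 0.1
    record_events: bool = True
    freeze_environment: bool = False

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        k = self.x0 * self.N
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"x0={self.x0} is not a multiple of 1/N (N={self.N})")
        if not (0.0 <= self.x0 <= 1.0):
            raise DomainError(f"x0={self.x0} outside [0, 1]")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.env_update not in ("closed_form", "euler"):
            raise ValueError(f"unknown env_update {self.env_update!r}")

    def to_dict(self) -> dict:
        return {
            "N": self.N, "x0": self.x0, "e0": self.e0,
            "t_end": self.t_end, "seed": self.seed,
            "env_update": self.env_update, "euler_dt": self.euler_dt,
            "sample_dt": self.sample_dt,
            "record_events": self.record_events,
            "freeze_environment": self.freeze_environment,
        }


@dataclass
class PDMPTrajectory:
    """Result of one stochastic run.

    ``sampled_t/x/e`` hold the state on the regular grid (always present).
    When the run records events, ``event_times``/``event_types`` (integer
    codes into :data:`EVENT_TYPES`) and the post-event states are kept;
    ``counts`` tallies events per channel including phantoms.
    """

    sampled_t: np.ndarray
    sampled_x: np.ndarray
    sampled_e: np.ndarray
    counts: np.ndarray
    params: ModelParams
    config: PDMPConfig
    event_times: np.ndarray | None = None
    event_types: np.ndarray | None = None
    event_x: np.ndarray | None = None
    event_e: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def phantom_fraction(self) -> float:
        total = int(self.counts.sum())
        return float(self.counts[0]) / total if total else float("nan")

    def to_csv(self, directory: str | Path, stem: str = "run") -> None:
        """Write sampled path (and event log if kept) plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / f"{stem}_path.csv", "w") as fh:
            fh.write("t,x,e\n")
            for t, x, e in zip(self.sampled_t, self.sampled_x, self.sampled_e):
                fh.write(f"{float(t)!r},{float(x)!r},{float(e)!r}\n")
        if self.event_times is not None:
            with open(directory / f"{stem}_events.csv", "w") as fh:
                fh.write("t,event_type,x,e\n")
                for t, c, x, e in zip(self.event_times, self.event_types,
                                      self.event_x, self.event_e):
                    fh.write(f"{float(t)!r},{EVENT_TYPES[c]},"
                             f"{float(x)!r},{float(e)!r}\n")
        sidecar = {
            "params": self.params.to_dict(),
            "config": self.config.to_dict(),
            "counts": {name: int(c)
                       for name, c in zip(EVENT_TYPES, self.counts)},
            "notes": self.notes,
        }
        (directory / f"{stem}_meta.json").write_text(
            json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def rate_bound(params: ModelParams, N: int) -> float:
    """Dominating rate xi_N for the thinning scheme.

    xi_N = N * [kappa*(gamma_A + gamma_B + max(delta_A, delta_B))
                + tau*(l_B - l_A)] * (1 + 1e-12).
    lambda_A + lambda_B is affine in x (its sup is at an endpoint) and
    tau_A + tau_B is constant, so this strictly dominates the total event
    rate N*Omega(x, e) at every reachable state.
    """
    p = params
    per_capita = (p.kappa * (p.gamma_A + p.gamma_B + max(p.delta_A, p.delta_B))
                  + p.tau * p.impact_differential)
    return N * per_capita * (1.0 + 1e-12)


def event_rates(x: float, e: float, params: ModelParams,
                N: int) -> np.ndarray:
    """The four elementary channel rates at state (x, e).

    Order: [social B->A, social A->B, env B->A, env A->B]. Their sum is
    exactly N * Omega(x, e).
    """
    p = params
    social = N * p.kappa * x * (1.0 - x)
    return np.array([
        social * (p.gamma_A + p.delta_A * x),
        social * (p.gamma_B + p.delta_B * (1.0 - x)),
        N * (1.0 - x) * p.tau * (e - p.l_A),
        N * x * p.tau * (p.l_B - e),
    ])


# ---------------------------------------------------------------------------
# Environment flow between jumps
# ---------------------------------------------------------------------------

def _env_closed_form(e: float, c: float, ell: float, dt: float) -> float:
    """Exact logistic flow of de/dt = ell*e*(c - e) over dt, c fixed."""
    if dt == 0.0 or e == c or e == 0.0:
        return e
    return c * e / (e + (c - e) * math.exp(-ell * c * dt))


def environment_update(e: float, x: float, params: ModelParams, dt: float,
                       method: str = "closed_form",
                       euler_dt: float = 1e-3) -> float:
    """Advance the environment over dt with the behavior frequency fixed.

    ``closed_form`` evaluates the exact logistic solution toward the mean
    impact c = l_A x + l_B (1-x); ``euler`` takes explicit steps of at
    most ``euler_dt``. Both stay inside [l_A, l_B].
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    c = params.l_A * x + params.l_B * (1.0 - x)
    if method == "closed_form":
        e_new = _env_closed_form(e, c, params.ell, dt)
    elif method == "euler":
        if dt > 0.0:
            m = max(1, int(math.ceil(dt / euler_dt)))
            h = dt / m
            for _ in range(m):
                e = e + params.ell * e * (c - e) * h
        e_new = e
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(max(e_new, params.l_A), params.l_B)


# ---------------------------------------------------------------------------
# Compiled grid-sampling kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _kernel_sample(kappa, gA, gB, dA, dB, tau, ell, lA, lB,
                   N, k0, e0, t_end, seed, sample_dt, n_samples,
                   use_euler, euler_dt, freeze_env):  # pragma: no cover
    np.random.seed(seed)
    xs = np.empty(n_samples)
    es = np.empty(n_samples)
    counts = np.zeros(5, dtype=np.int64)
    xi = N * (kappa * (gA + gB + max(dA, dB)) + tau * (lB - lA)) * (1.0 + 1e-12)
    t = 0.0
    k = k0
    e = e0
    next_i = 0
    if xi <= 0.0:
        for i in range(n_samples):
            xs[i] = k / N
            es[i] = e
        return xs, es, counts
    while True:
        t_next = t + np.random.exponential(1.0 / xi)
        x = k / N
        c = lA * x + lB * (1.0 - x)
        while next_i < n_samples:
            ts = next_i * sample_dt
            if ts > t_next or ts > t_end:
                break
            if freeze_env or e == c or e == 0.0:
                e_s = e
            elif use_euler:
                e_s = e
                dtt = ts - t
                m = max(1, int(np.ceil(dtt / euler_dt)))
                h = dtt / m
                for _ in range(m):
                    e_s = e_s + ell * e_s * (c - e_s) * h
            else:
                e_s = c * e / (e + (c - e) * np.exp(-ell * c * (ts - t)))
            xs[next_i] = x
            es[next_i] = min(max(e_s, lA), lB)
            next_i += 1
        if t_next >= t_end or next_i >= n_samples:
            break
        dtt = t_next - t
        if not freeze_env and e != c and e != 0.0:
            if use_euler:
                m = max(1, int(np.ceil(dtt / euler_dt)))
                h = dtt / m
                for _ in range(m):
                    e = e + ell * e * (c - e) * h
            else:
                e = c * e / (e + (c - e) * np.exp(-ell * c * dtt))
            e = min(max(e, lA), lB)
        t = t_next
        a1 = N * kappa * x * (1.0 - x) * (gA + dA * x)
        a2 = N * kappa * x * (1.0 - x) * (gB + dB * (1.0 - x))
        a3 = N * (1.0 - x) * tau * (e - lA)
        a4 = N * x * tau * (lB - e)
        u = np.random.random() * xi
        if u < a1:
            k += 1
            counts[1] += 1
        elif u < a1 + a2:
            k -= 1
            counts[2] += 1
        elif u < a1 + a2 + a3:
            k += 1
            counts[3] += 1
        elif u < a1 + a2 + a3 + a4:
            k -= 1
            counts[4] += 1
        else:
            counts[0] += 1
    return xs, es, counts


# ---------------------------------------------------------------------------
# Simulation entry points
# ---------------------------------------------------------------------------

def simulate_pdmp(params: ModelParams, config: PDMPConfig) -> PDMPTrajectory:
    """Run one exact thinning simulation of the finite-N process.

    Reproducible bit-for-bit from (seed, config, params) on a given
    backend. With ``record_events`` the full event log (times, channel,
    post-event state) is returned; otherwise only the regular-grid path.
    """
    if not (params.l_A <= config.e0 <= params.l_B):
        raise DomainError(
            f"e0={config.e0} outside [{params.l_A}, {params.l_B}]")
    n_samples = int(math.floor(config.t_end / config.sample_dt)) + 1
    grid = np.arange(n_samples) * config.sample_dt
    if config.record_events:
        return _simulate_python(params, config, grid)
    p = params
    xs, es, counts = _kernel_sample(
        p.kappa, p.gamma_A, p.gamma_B, p.delta_A, p.delta_B, p.tau, p.ell,
        p.l_A, p.l_B, config.N, int(round(config.x0 * config.N)),
        config.e0, config.t_end, config.seed, config.sample_dt, n_samples,
        config.env_update == "euler", config.euler_dt,
        config.freeze_environment)
    return PDMPTrajectory(sampled_t=grid, sampled_x=np.asarray(xs),
                          sampled_e=np.asarray(es),
                          counts=np.asarray(counts), params=params,
                          config=config)


def _simulate_python(params: ModelParams, config: PDMPConfig,
                     grid: np.ndarray) -> PDMPTrajectory:
    p = params
    rng = np.random.RandomState(config.seed)
    xi = rate_bound(p, config.N)
    N = config.N
    k = int(round(config.x0 * N))
    e = config.e0
    t = 0.0
    method = "euler" if config.env_update == "euler" else "closed_form"

    ev_t: list[float] = []
    ev_c: list[int] = []
    ev_x: list[float] = []
    ev_e: list[float] = []
    counts = np.zeros(5, dtype=np.int64)
    xs = np.empty(grid.size)
    es = np.empty(grid.size)
    next_i = 0
    notes: list[str] = []
    overflow = False

    def env(e0, x, dt):
        if config.freeze_environment:
            return e0
        return environment_update(e0, x, p, dt, method, config.euler_dt)

    while True:
        if xi <= 0.0:
            t_next = config.t_end
        else:
            t_next = t + rng.exponential(1.0 / xi)
        x = k / N
        while next_i < grid.size and grid[next_i] <= min(t_next, config.t_end):
            xs[next_i] = x
            es[next_i] = env(e, x, grid[next_i] - t)
            next_i += 1
        if t_next >= config.t_end or xi <= 0.0:
            break
        e = env(e, x, t_next - t)
        t = t_next
        a = event_rates(x, e, p, N)
        u = rng.random_sample() * xi
        cum = 0.0
        code = 0
        for j in range(4):
            cum += a[j]
            if u < cum:
                code = j + 1
                break
        if code in (1, 3):
            k += 1
        elif code in (2, 4):
            k -= 1
        counts[code] += 1
        if not overflow:
            ev_t.append(t)
            ev_c.append(code)
            ev_x.append(k / N)
            ev_e.append(e)
            if len(ev_t) > MAX_EVENT_LOG:
                overflow = True
                ev_t, ev_c, ev_x, ev_e = [], [], [], []
                notes.append("event log exceeded the storage cap; "
                             "only the sampled grid path is kept")
                warnings.warn(notes[-1], stacklevel=3)
    traj = PDMPTrajectory(sampled_t=grid, sampled_x=xs, sampled_e=es,
                          counts=counts, params=params, config=config,
                          notes=notes)
    if not overflow:
        traj.event_times = np.array(ev_t)
        traj.event_types = np.array(ev_c, dtype=np.int64)
        traj.event_x = np.array(ev_x)
        traj.event_e = np.array(ev_e)
    return traj


def simulate_ensemble(params: ModelParams, config: PDMPConfig,
                      n_runs: int, base_seed: int | None = None
                      ) -> list[PDMPTrajectory]:
    """Independent replicate runs differing only in seed."""
    base = config.seed if base_seed is None else base_seed
    out = []
    for i in range(n_runs):
        cfg = PDMPConfig(**{**config.to_dict(),
                            "seed": int((base + i) % (2 ** 31 - 1))})
        out.append(simulate_pdmp(params, cfg))
    return out


def ensemble_statistics(runs: list[PDMPTrajectory]) -> dict[str, np.ndarray]:
    """Per-time mean and unbiased variance of (x, e) across replicates.

    All runs must share parameters and configuration up to the seed.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    ref = runs[0]
    ref_cfg = {k: v for k, v in ref.config.to_dict().items() if k != "seed"}
    for r in runs[1:]:
        cfg = {k: v for k, v in r.config.to_dict().items() if k != "seed"}
        if cfg != ref_cfg or r.params != ref.params:
            raise ValueError("runs differ in more than the seed")
    X = np.stack([r.sampled_x for r in runs])
    E = np.stack([r.sampled_e for r in runs])
    return {
        "t": ref.sampled_t,
        "mean_x": X.mean(axis=0),
        "var_x": X.var(axis=0, ddof=1),
        "mean_e": E.mean(axis=0),
        "var_e": E.var(axis=0, ddof=1),
        "n_runs": np.array(len(runs)),
    }
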