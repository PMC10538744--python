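"""Exact thinning simulation: rates, bounds, environment flow, ensembles."""

import numpy as np
import pytest

from ecobehav import (
    DomainError,
    ModelParams,
    PDMPConfig,
    ensemble_statistics,
    environment_update,
    event_rates,
    rate_bound,
    simulate_ensemble,
    simulate_pdmp,
    total_switching_rate,
)


@pytest.fixture
def small_cfg():
    return PDMPConfig(N=50, x0=0.2, e0=0.9, t_end=20.0, seed=7)


class TestConfigValidation:
    def test_x0_must_be_multiple_of_inverse_N(self):
        with pytest.raises(ValueError, match="multiple of 1/N"):
            PDMPConfig(N=50, x0=0.201, e0=0.9, t_end=1.0, seed=0)

    @pytest.mark.parametrize("kwargs", [
        {"N": 0}, {"t_end": 0.0}, {"env_update": "rk4"},
    ])
    def test_rejects_bad_fields(self, kwargs):
        base = dict(N=50, x0=0.2, e0=0.9, t_end=1.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            PDMPConfig(**base)

    def test_e0_checked_against_params(self, default_params):
        cfg = PDMPConfig(N=50, x0=0.2, e0=0.5, t_end=1.0, seed=0)
        with pytest.raises(DomainError):
            simulate_pdmp(default_params, cfg)


class TestRates:
    def test_rate_bound_closed_form(self, default_params):
        # N * [kappa*(gamma_A+gamma_B+max delta) + tau*(l_B-l_A)]
        assert rate_bound(default_params, 100) == pytest.approx(
            253.0, rel=1e-9)

    def test_bound_dominates_everywhere(self, bistable_params):
        p = bistable_params
        xi = rate_bound(p, 200)
        for x in np.linspace(0, 1, 21):
            for e in np.linspace(p.l_A, p.l_B, 11):
                assert event_rates(x, e, p, 200).sum() <= xi

    def test_rates_sum_to_total_switching_rate(self, default_params):
        p = default_params
        for x in (0.0, 0.25, 1.0):
            for e in (p.l_A, 0.85, p.l_B):
                assert event_rates(x, e, p, 77).sum() == pytest.approx(
                    77 * total_switching_rate(x, e, p), abs=1e-12)

    def test_rates_nonnegative_at_boundaries(self, default_params):
        p = default_params
        assert np.all(event_rates(0.0, p.l_A, p, 10) >= 0)
        assert np.all(event_rates(1.0, p.l_B, p, 10) >= 0)


class TestEnvironmentUpdate:
    def test_fixed_point_on_mixture(self, default_params):
        p = default_params
        x = 0.4
        c = p.l_A * x + p.l_B * (1 - x)
        assert environment_update(c, x, p, 5.0) == pytest.approx(c)

    def test_monotone_towards_mixture(self, default_params):
        p = default_params
        e1 = environment_update(p.l_B, 1.0, p, 1.0)
        e2 = environment_update(e1, 1.0, p, 1.0)
        assert p.l_A < e2 < e1 < p.l_B

    def test_euler_converges_to_closed_form(self, default_params):
        p = default_params
        exact = environment_update(0.95, 0.8, p, 2.0, method="closed_form")
        coarse = environment_update(0.95, 0.8, p, 2.0, method="euler",
                                    euler_dt=1e-2)
        fine = environment_update(0.95, 0.8, p, 2.0, method="euler",
                                  euler_dt=1e-4)
        assert abs(fine - exact) < abs(coarse - exact)
        assert fine == pytest.approx(exact, abs=1e-6)

    def test_stays_inside_impact_range(self, default_params):
        p = default_params
        for e0 in (p.l_A, p.l_B):
            e = environment_update(e0, 0.5, p, 100.0)
            assert p.l_A <= e <= p.l_B

    def test_rejects_negative_dt(self, default_params):
        with pytest.raises(ValueError):
            environment_update(0.85, 0.5, default_params, -1.0)


class TestSimulatePDMP:
    def test_increments_are_exact_individuals(self, default_params,
                                              small_cfg):
        traj = simulate_pdmp(default_params, small_cfg)
        jumps = np.diff(traj.event_x) * small_cfg.N
        jumps = jumps[np.abs(jumps) > 1e-12]
        assert np.allclose(np.abs(jumps), 1.0, atol=1e-9)

    def test_phantoms_change_nothing(self, default_params, small_cfg):
        traj = simulate_pdmp(default_params, small_cfg)
        x_prev = np.concatenate([[small_cfg.x0], traj.event_x[:-1]])
        phantom = traj.event_types == 0
        assert phantom.any()
        np.testing.assert_allclose(traj.event_x[phantom], x_prev[phantom])

    def test_counts_match_event_log(self, default_params, small_cfg):
        traj = simulate_pdmp(default_params, small_cfg)
        for code in range(5):
            assert traj.counts[code] == np.sum(traj.event_types == code)

    def test_reproducible_from_seed(self, default_params, small_cfg):
        a = simulate_pdmp(default_params, small_cfg)
        b = simulate_pdmp(default_params, small_cfg)
        np.testing.assert_array_equal(a.sampled_x, b.sampled_x)
        np.testing.assert_array_equal(a.event_times, b.event_times)

    def test_seed_changes_path(self, default_params, small_cfg):
        other = PDMPConfig(**{**small_cfg.to_dict(), "seed": 8})
        a = simulate_pdmp(default_params, small_cfg)
        b = simulate_pdmp(default_params, other)
        assert not np.array_equal(a.sampled_x, b.sampled_x)

    def test_grid_only_kernel_path(self, default_params):
        cfg = PDMPConfig(N=200, x0=0.2, e0=0.9, t_end=30.0, seed=11,
                         record_events=False)
        traj = simulate_pdmp(default_params, cfg)
        assert traj.event_times is None
        assert traj.sampled_t[-1] == pytest.approx(30.0)
        assert np.all((traj.sampled_x >= 0) & (traj.sampled_x <= 1))
        assert np.all((traj.sampled_e >= default_params.l_A)
                      & (traj.sampled_e <= default_params.l_B))

    def test_frozen_environment_holds_e(self, default_params):
        cfg = PDMPConfig(N=50, x0=0.2, e0=0.9, t_end=10.0, seed=3,
                         freeze_environment=True)
        traj = simulate_pdmp(default_params, cfg)
        assert np.all(traj.sampled_e == 0.9)

    def test_absorbing_state_without_feedback(self):
        p = ModelParams(gamma_A=1.0, delta_A=0.5, tau=0.0, ell=0.1, l_A=0.7)
        cfg = PDMPConfig(N=50, x0=0.0, e0=0.85, t_end=10.0, seed=5)
        traj = simulate_pdmp(p, cfg)
        assert np.all(traj.sampled_x == 0.0)

    def test_csv_output(self, tmp_path, default_params, small_cfg):
        traj = simulate_pdmp(default_params, small_cfg)
        traj.to_csv(tmp_path, stem="demo")
        assert (tmp_path / "demo_path.csv").exists()
        assert (tmp_path / "demo_events.csv").exists()
        assert (tmp_path / "demo_meta.json").exists()


class TestFrozenEnvironmentOracle:
    def test_matches_birth_death_stationary_law(self):
        """With e frozen, the jump chain is a birth-death process whose
        stationary distribution follows from detailed balance; the
        long-run occupancy must match it in total variation."""
        p = ModelParams(gamma_A=1.0, delta_A=0.5, tau=0.5, ell=0.1, l_A=0.7)
        N, e = 50, 0.85
        ks = np.arange(N + 1)
        xs = ks / N

        def birth(x):
            return N * (p.kappa * x * (1 - x) * (p.gamma_A + p.delta_A * x)
                        + p.tau * (e - p.l_A) * (1 - x))

        def death(x):
            return N * (p.kappa * x * (1 - x)
                        * (p.gamma_B + p.delta_B * (1 - x))
                        + p.tau * (p.l_B - e) * x)

        log_pi = np.zeros(N + 1)
        for k in range(1, N + 1):
            log_pi[k] = log_pi[k - 1] + np.log(birth(xs[k - 1]) / death(xs[k]))
        pi = np.exp(log_pi - log_pi.max())
        pi /= pi.sum()

        cfg = PDMPConfig(N=N, x0=0.5, e0=e, t_end=20_000.0, seed=314159,
                         sample_dt=0.1, record_events=False,
                         freeze_environment=True)
        traj = simulate_pdmp(p, cfg)
        counts = np.bincount(np.rint(traj.sampled_x * N).astype(int),
                             minlength=N + 1)
        empirical = counts / counts.sum()
        tv = 0.5 * np.abs(empirical - pi).sum()
        assert tv < 0.05


class TestEnsembles:
    def test_statistics_shapes_and_seed_spacing(self, default_params,
                                                small_cfg):
        runs = simulate_ensemble(default_params, small_cfg, n_runs=4)
        assert [r.config.seed for r in runs] == [7, 8, 9, 10]
        stats = ensemble_statistics(runs)
        assert stats["mean_x"].shape == runs[0].sampled_t.shape
        assert int(stats["n_runs"]) == 4
        assert np.all(stats["var_x"] >= 0)

    def test_statistics_rejects_mixed_configs(self, default_params,
                                              small_cfg):
        other = PDMPConfig(**{**small_cfg.to_dict(), "t_end": 10.0})
        runs = [simulate_pdmp(default_params, small_cfg),
                simulate_pdmp(default_params, other)]
        with pytest.raises(ValueError, match="differ"):
            ensemble_statistics(runs)
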