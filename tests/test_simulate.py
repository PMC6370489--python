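import numpy as np
import pytest
from scipy.linalg import expm

import braindyn as bd
from braindyn.errors import IntegrationError, InvalidArgumentError
from braindyn.simulate import simulate_firing_rate, simulate_kuramoto

from conftest import two_node_connectome


def power_iteration(W, iters=500):
    v = np.ones(W.shape[0]) / np.sqrt(W.shape[0])
    for _ in range(iters):
        v = W @ v
        v /= np.linalg.norm(v)
    return float(v @ W @ v)


class TestLeadingEigenvalue:
    def test_identity(self):
        assert bd.leading_eigenvalue(np.eye(4)) == pytest.approx(1.0)

    def test_diagonal(self):
        assert bd.leading_eigenvalue(np.diag([3.0, 1.0, 2.0])) == pytest.approx(3.0)

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(0)
        W = rng.random((6, 6))
        W = (W + W.T) / 2 + 3 * np.eye(6)  # shift to make the top eigenvalue dominant
        assert bd.leading_eigenvalue(W) == pytest.approx(power_iteration(W), abs=1e-8)

    def test_unit_norm_connectome_has_c1_one(self, default_connectome):
        assert bd.leading_eigenvalue(default_connectome.weights) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_non_square_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bd.leading_eigenvalue(np.zeros((2, 3)))


class TestFiringRate:
    def test_exponential_decay_to_e_inverse(self):
        conn = two_node_connectome(0.5)
        cfg = bd.SimulationConfig(model="firing_rate", k=0.0, dt=1e-4,
                                  duration=0.03, discard=0.0, sigma=0.0, seed=0)
        ts = simulate_firing_rate(conn, cfg, r0=np.array([1.0, 1.0]))
        t_idx = int(round(0.020 / cfg.dt))
        assert ts.values[0, t_idx] == pytest.approx(np.exp(-1), rel=0.01)

    def test_zero_state_is_fixed_point(self):
        conn = two_node_connectome(0.5)
        cfg = bd.SimulationConfig(model="firing_rate", k=0.5, dt=1e-4,
                                  duration=0.05, discard=0.0, sigma=0.0, seed=0)
        ts = simulate_firing_rate(conn, cfg, r0=np.zeros(2))
        assert np.all(ts.values == 0.0)

    def test_two_node_decay_matches_matrix_exponential(self):
        c = 0.5
        conn = two_node_connectome(c)
        k = 0.5
        cfg = bd.SimulationConfig(model="firing_rate", k=k, dt=1e-5,
                                  duration=0.1, discard=0.0, sigma=0.0, seed=0)
        r0 = np.array([1.0, 0.3])
        ts = simulate_firing_rate(conn, cfg, r0=r0)
        c1 = bd.leading_eigenvalue(conn.weights)
        A = (-np.eye(2) + (k / c1) * conn.weights) / cfg.tau0
        t = 0.08
        expected = expm(A * t) @ r0
        got = ts.values[:, int(round(t / cfg.dt))]
        assert np.allclose(got, expected, rtol=0.01)

    def test_subcritical_coupling_decays_from_random_state(self, small_connectome):
        cfg = bd.SimulationConfig(model="firing_rate", k=0.9, dt=1e-4,
                                  duration=1.0, discard=0.0, sigma=0.0, seed=3)
        ts = simulate_firing_rate(small_connectome, cfg)
        start = np.linalg.norm(ts.values[:, 0])
        end = np.linalg.norm(ts.values[:, -1])
        assert end < 0.05 * start

    def test_unstable_run_raises_integration_error(self, small_connectome):
        cfg = bd.SimulationConfig(model="firing_rate", k=500.0, dt=1e-3,
                                  duration=5.0, discard=0.0, sigma=0.0, seed=0)
        with pytest.raises(IntegrationError, match="step"):
            simulate_firing_rate(small_connectome, cfg,
                                 r0=np.ones(small_connectome.n_rois))


class TestKuramoto:
    def test_free_rotation_returns_to_start(self):
        conn = two_node_connectome(0.5)
        cfg = bd.SimulationConfig(model="kuramoto", k=0.0, dt=1e-4,
                                  duration=1.0, discard=0.0, sigma=0.0, seed=0)
        ts = simulate_kuramoto(conn, cfg, omega=np.array([2 * np.pi, 2 * np.pi]),
                               theta0=np.zeros(2), store_phases=True)
        final = ts.phases[0, -1]
        # one full revolution at 1 cycle/s (circular distance to 0)
        assert min(final, 2 * np.pi - final) < 1e-3 + 2 * np.pi * cfg.dt

    def test_two_oscillator_phase_locking_rate(self):
        c, k = 0.5, 2.0
        conn = two_node_connectome(c)
        cfg = bd.SimulationConfig(model="kuramoto", k=k, dt=1e-5,
                                  duration=2.0, discard=0.0, sigma=0.0, seed=0)
        ts = simulate_kuramoto(conn, cfg, omega=np.array([10.0, 10.0]),
                               theta0=np.array([0.1, 0.0]), store_phases=True)
        phi = ts.phases[0] - ts.phases[1]
        phi = np.angle(np.exp(1j * phi))
        # linearized rate: phi(t) ~ phi0 exp(-2 k c t); check at the half-life
        t_half = np.log(2) / (2 * k * c)
        got = phi[int(round(t_half / cfg.dt))]
        assert got == pytest.approx(0.05, rel=0.05)

    def test_strong_coupling_fully_synchronizes(self):
        conn = two_node_connectome(0.5)
        cfg = bd.SimulationConfig(model="kuramoto", k=50.0, dt=1e-5,
                                  duration=1.0, discard=0.0, sigma=0.0, seed=0)
        ts = simulate_kuramoto(conn, cfg, omega=np.array([10.0, 11.0]),
                               theta0=np.array([0.0, 2.0]), store_phases=True)
        order = np.abs(np.exp(1j * ts.phases[:, -1]).mean())
        assert order > 1 - 1e-3

    def test_coherence_non_decreasing_in_coupling(self, default_connectome):
        mean_R = []
        for k in (3.0, 13.0, 60.0):
            Rs = []
            for seed in range(5):
                cfg = bd.SimulationConfig(model="kuramoto", k=k, dt=5e-4,
                                          duration=30.0, discard=10.0, seed=seed)
                ts = simulate_kuramoto(default_connectome, cfg, store_phases=True)
                Rs.append(np.abs(np.exp(1j * ts.phases).mean(axis=0)).mean())
            mean_R.append(np.mean(Rs))
        assert mean_R[0] <= mean_R[1] <= mean_R[2]


class TestNumerics:
    @pytest.mark.parametrize("model", ["firing_rate", "kuramoto"])
    def test_euler_dt_halving_converges(self, model, small_connectome):
        ends = []
        for dt in (1e-4, 5e-5):
            cfg = bd.SimulationConfig(model=model, dt=dt, duration=1.0,
                                      discard=0.0, sigma=0.0, seed=5)
            ts = bd.simulate(small_connectome, cfg)
            ends.append(ts.values[:, -1])
        rel = np.linalg.norm(ends[0] - ends[1]) / np.linalg.norm(ends[1])
        assert rel < 0.01

    @pytest.mark.parametrize("model", ["firing_rate", "kuramoto"])
    def test_fixed_seed_is_bit_identical(self, model, small_connectome):
        cfg = bd.SimulationConfig(model=model, dt=1e-3, duration=2.0,
                                  discard=0.0, seed=11)
        a = bd.simulate(small_connectome, cfg)
        b = bd.simulate(small_connectome, cfg)
        assert np.array_equal(a.values, b.values)

    def test_step_count_matches_duration(self, small_connectome):
        cfg = bd.SimulationConfig(model="firing_rate", dt=1e-3, duration=2.0,
                                  discard=0.5, seed=0)
        ts = bd.simulate(small_connectome, cfg)
        assert ts.n_steps == round((2.0 - 0.5) / 1e-3)
        assert np.all(np.isfinite(ts.values))
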