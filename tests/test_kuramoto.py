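import numpy as np
import pytest

from synchrocomp.connectome import NaturalFrequencyMap
from synchrocomp.kuramoto import (LorentzianSpec, OrderParameterSeries,
                                  locked_cluster_frequency,
                                  mean_network_frequency, mean_offdiag,
                                  metastability, model_plv_matrix,
                                  order_parameter, sample_lorentzian,
                                  simulate_network, simulate_uniform)
from conftest import all_to_all_connectome


class TestLorentzianSampling:
    def test_median_at_center(self, lorentzian_alpha):
        draws = sample_lorentzian(100_000, lorentzian_alpha, seed=0)
        assert abs(np.median(draws) - 10.0) < 0.05

    def test_half_mass_within_one_halfwidth(self, lorentzian_alpha):
        # CDF(mu+gamma) - CDF(mu-gamma) = 1/2 for a Cauchy
        draws = sample_lorentzian(100_000, lorentzian_alpha, seed=1)
        frac = np.mean(np.abs(draws - 10.0) <= 1.0)
        assert abs(frac - 0.5) < 0.01

    def test_seeded_determinism(self, lorentzian_alpha):
        a = sample_lorentzian(100, lorentzian_alpha, seed=42)
        b = sample_lorentzian(100, lorentzian_alpha, seed=42)
        assert np.array_equal(a, b)


class TestUniformSimulation:
    def test_uncoupled_drift_is_exact(self, lorentzian_alpha):
        traj = simulate_uniform(5, K=0.0, tau=0.0, spec=lorentzian_alpha,
                                d=0.0, duration=2.0, transient=0.5, seed=3)
        expected = traj.theta[:, [0]] + traj.omega[:, None] * traj.times[None, :]
        assert np.allclose(traj.theta, expected, atol=1e-8)

    def test_identical_oscillators_stay_locked(self, lorentzian_alpha):
        traj = simulate_uniform(20, K=5.0, tau=0.0, spec=lorentzian_alpha,
                                d=0.0, duration=2.0, transient=0.5, seed=0,
                                theta0=np.zeros(20), omega_hz=np.full(20, 10.0))
        assert np.allclose(order_parameter(traj).r, 1.0, atol=1e-9)

    def test_steady_state_matches_reduced_theory(self, lorentzian_alpha):
        # K well above critical at tau=0: r -> sqrt(1 - 2 gamma / K), f -> mu
        traj = simulate_uniform(1000, K=8.0, tau=0.0, spec=lorentzian_alpha,
                                seed=4)
        ops = order_parameter(traj)
        r_sim = ops.r[ops.times > 10.0].mean()
        assert abs(r_sim - np.sqrt(1 - 2 / 8)) < 0.05
        assert abs(locked_cluster_frequency(traj) - 10.0) < 0.15

    def test_seeded_determinism(self, lorentzian_alpha):
        a = simulate_uniform(50, 4.0, 0.005, lorentzian_alpha, d=0.5,
                             duration=2.0, transient=0.5, seed=9)
        b = simulate_uniform(50, 4.0, 0.005, lorentzian_alpha, d=0.5,
                             duration=2.0, transient=0.5, seed=9)
        assert np.array_equal(a.theta, b.theta)

    def test_halving_dt_changes_locked_r_little(self, lorentzian_alpha):
        rs = []
        for dt in (0.001, 0.002):
            traj = simulate_uniform(500, 8.0, 0.010, lorentzian_alpha, dt=dt,
                                    duration=20.0, transient=8.0, seed=12)
            ops = order_parameter(traj)
            rs.append(ops.r[ops.times > 8.0].mean())
        assert abs(rs[0] - rs[1]) < 0.02

    def test_frequency_depression_with_delay(self, lorentzian_alpha):
        # collective frequency is non-increasing in tau at fixed supercritical K
        freqs = []
        for tau in (0.0, 0.005, 0.010, 0.015, 0.020):
            traj = simulate_uniform(500, 8.0, tau, lorentzian_alpha,
                                    duration=20.0, transient=8.0, seed=21)
            freqs.append(locked_cluster_frequency(traj))
        assert np.all(np.diff(freqs) < 0.05)


class TestNetworkSimulation:
    def test_uncoupled_network_drifts_at_natural_frequency(self, connectome32,
                                                           freqs32):
        traj = simulate_network(connectome32, K=0.0, velocity=10.0,
                                freqs=freqs32, duration=3.0, transient=1.0,
                                seed=0)
        expected = traj.theta[:, [0]] + traj.omega[:, None] * traj.times[None, :]
        assert np.allclose(traj.theta, expected, atol=1e-8)

    def test_equivalent_to_mean_field_for_all_to_all_uniform_delay(
            self, lorentzian_alpha):
        """Same physics through both integrators: all-to-all, one delay."""
        n, K, tau_s, v = 64, 6.0, 0.010, 10.0
        conn = all_to_all_connectome(n, distance_mm=tau_s * v * 1e3)
        fm_draw = sample_lorentzian(n, lorentzian_alpha, seed=77)
        fmap = NaturalFrequencyMap(fm_draw, 12, 8, np.ones(n), 0, 1)
        r_net, r_uni = [], []
        for rep in range(10):
            tn = simulate_network(conn, K, v, fmap,
                                  duration=20.0, transient=8.0, seed=rep)
            tu = simulate_uniform(n, K, tau_s, lorentzian_alpha,
                                  duration=20.0, transient=8.0, seed=1000 + rep,
                                  omega_hz=fm_draw)
            r_net.append(order_parameter(tn).r[-12000:].mean())
            r_uni.append(order_parameter(tu).r[-12000:].mean())
        assert abs(np.mean(r_net) - np.mean(r_uni)) < 0.02

    def test_disconnected_cliques_synchronize_separately(self):
        # two 4-cliques with distinct frequencies: per-clique r beats global r
        n = 8
        w = np.zeros((n, n))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0)
        d = 50.0 * (np.ones((n, n)) - np.eye(n))
        from synchrocomp.connectome import Connectome, validate_connectome
        conn = validate_connectome(Connectome(w, d, [str(i) for i in range(n)]))
        omega = np.array([9.0] * 4 + [11.0] * 4) + \
            0.05 * np.arange(n)
        fmap = NaturalFrequencyMap(omega, 12, 8, np.ones(n), 0, 1)
        traj = simulate_network(conn, K=20.0, velocity=20.0, freqs=fmap,
                                duration=10.0, transient=3.0, seed=5)
        post = traj.times > 3.0
        z_all = np.exp(1j * traj.theta[:, post]).mean(axis=0)
        z_a = np.exp(1j * traj.theta[:4, post]).mean(axis=0)
        z_b = np.exp(1j * traj.theta[4:, post]).mean(axis=0)
        assert np.abs(z_a).mean() > np.abs(z_all).mean()
        assert np.abs(z_b).mean() > np.abs(z_all).mean()

    def test_seeded_determinism(self, connectome32, freqs32):
        a = simulate_network(connectome32, 5.0, 10.0, freqs32, d=1.0,
                             duration=3.0, transient=1.0, seed=8)
        b = simulate_network(connectome32, 5.0, 10.0, freqs32, d=1.0,
                             duration=3.0, transient=1.0, seed=8)
        assert np.array_equal(a.theta, b.theta)


class TestOrderParameter:
    def test_aligned_phases_give_unity(self):
        times = np.arange(5.0)
        traj_like = type("T", (), {})()
        traj_like.theta = np.zeros((10, 5))
        traj_like.times = times
        ops = order_parameter(traj_like)
        assert np.allclose(ops.r, 1.0)

    @pytest.mark.parametrize("phases", [
        [0.0, np.pi / 2, np.pi, 3 * np.pi / 2],   # balanced cross
        [0.0, np.pi],                             # antipodal pair
        [0.0, 0.0, np.pi, np.pi],                 # two equal clusters
    ])
    def test_balanced_configurations_cancel(self, phases):
        traj_like = type("T", (), {})()
        traj_like.theta = np.array(phases)[:, None]
        traj_like.times = np.array([0.0])
        assert order_parameter(traj_like).r[0] == pytest.approx(0.0, abs=1e-12)


class TestSummaries:
    def test_metastability_of_constant_r_is_zero(self):
        s = OrderParameterSeries(np.linspace(0, 10, 100), np.full(100, 0.7),
                                 np.zeros(100))
        assert metastability(s) == pytest.approx(0.0, abs=1e-12)

    def test_metastability_of_sine_is_rms(self):
        t = np.arange(0, 10, 0.001)   # whole periods of a 1 Hz sine
        s = OrderParameterSeries(t, 0.5 + 0.1 * np.sin(2 * np.pi * t),
                                 np.zeros_like(t))
        assert metastability(s) == pytest.approx(0.1 / np.sqrt(2), abs=1e-3)

    def test_fully_locked_network_has_negligible_metastability(
            self, lorentzian_alpha):
        traj = simulate_uniform(300, K=50.0, tau=0.0, spec=lorentzian_alpha,
                                duration=15.0, transient=5.0, seed=2)
        ops = order_parameter(traj)
        assert metastability(ops, 5.0) < 0.01

    def test_single_oscillator_frequency(self):
        traj = simulate_uniform(1, K=0.0, tau=0.0, spec=LorentzianSpec(10, 1),
                                duration=5.0, transient=1.0, seed=0,
                                omega_hz=[10.0])
        assert mean_network_frequency(traj, 1.0) == pytest.approx(10.0, abs=1e-9)

    def test_model_plv_locked_identical_oscillators(self, lorentzian_alpha):
        traj = simulate_uniform(6, K=5.0, tau=0.0, spec=lorentzian_alpha,
                                duration=4.0, transient=1.0, seed=0,
                                theta0=np.zeros(6), omega_hz=np.full(6, 10.0))
        plv = model_plv_matrix(traj, 1.0)
        assert np.allclose(plv, 1.0, atol=1e-9)

    def test_model_plv_uncoupled_incommensurate(self):
        traj = simulate_uniform(4, K=0.0, tau=0.0, spec=LorentzianSpec(10, 1),
                                duration=40.0, transient=1.0, seed=0,
                                omega_hz=[9.1, 10.3, 11.7, 8.2])
        plv = model_plv_matrix(traj, 1.0)
        off = plv[np.triu_indices(4, 1)]
        assert np.all(off <= 0.1)

    def test_model_plv_symmetric(self, connectome32, freqs32):
        traj = simulate_network(connectome32, 5.0, 10.0, freqs32,
                                duration=4.0, transient=1.0, seed=3)
        plv = model_plv_matrix(traj, 1.0)
        assert np.array_equal(plv, plv.T)
        assert mean_offdiag(plv) <= 1.0
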