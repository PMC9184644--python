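import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synchrocomp.phase_locking import (EpochedSignals, band_phase, cohort_locking_trends,
                                       define_bands, epoch_locking, pli, plv,
                                       surrogate_null)
from synchrocomp.synthetic_data import make_coupled_signals


class TestBands:
    def test_ssa_centered_on_paf(self):
        assert define_bands(10.0).SSA == (8.0, 12.0)
        assert define_bands(9.0).SSA == (7.0, 11.0)

    def test_fixed_bands_do_not_move(self):
        for paf in (8.0, 10.0, 12.0):
            bands = define_bands(paf)
            assert bands.LA == (6.0, 10.0)
            assert bands.UA == (10.0, 14.0)

    def test_too_low_paf_rejected(self):
        with pytest.raises(ValueError):
            define_bands(1.5)


class TestBandPhase:
    @staticmethod
    def _sine_epochs(f0=10.0, fs=100.0, n_epochs=2):
        t = np.arange(0, 5.0, 1 / fs)
        x = np.sin(2 * np.pi * f0 * t)
        data = np.tile(x, (2, n_epochs, 1))
        return EpochedSignals(data=data, fs=fs)

    def test_sinusoid_phase_advances_linearly(self):
        ep = self._sine_epochs(10.0)
        ph = band_phase(ep, (8.0, 12.0))
        dphi = np.diff(ph[0, 0])
        dphi = np.mod(dphi + np.pi, 2 * np.pi) - np.pi
        mid = dphi[len(dphi) // 4: -len(dphi) // 4]
        assert np.max(np.abs(mid - 2 * np.pi * 10.0 / 100.0)) < 0.01

    def test_phase_invariant_to_amplitude_scaling(self):
        ep = self._sine_epochs()
        scaled = EpochedSignals(data=5.0 * ep.data, fs=ep.fs)
        assert np.allclose(band_phase(ep, (8, 12)), band_phase(scaled, (8, 12)))

    def test_identical_channels_identical_phase(self):
        ep = self._sine_epochs()
        ph = band_phase(ep, (8, 12))
        assert np.array_equal(ph[0], ph[1])

    def test_band_outside_nyquist_rejected(self):
        ep = self._sine_epochs()
        with pytest.raises(ValueError):
            band_phase(ep, (40.0, 60.0))


class TestPLVandPLI:
    def test_zero_difference(self):
        ph = np.linspace(0, 10, 100)
        assert plv(ph, ph) == pytest.approx(1.0)
        assert pli(ph, ph) == pytest.approx(0.0)

    def test_constant_lag(self):
        ph = np.linspace(0, 10, 100)
        assert plv(ph + np.pi / 4, ph) == pytest.approx(1.0)
        assert pli(ph + 0.3, ph) == pytest.approx(1.0)

    def test_alternating_opposite_lags_cancel(self):
        dphi = np.tile([0.3, -0.3], 50)
        assert pli(dphi, np.zeros_like(dphi)) == pytest.approx(0.0)
        dphi = np.tile([0.0, np.pi], 50)
        assert plv(dphi, np.zeros_like(dphi)) == pytest.approx(0.0, abs=1e-12)

    def test_pli_zero_for_symmetric_phase_differences(self):
        # any distribution of lags symmetric about zero has no consistent sign
        rng = np.random.default_rng(0)
        lags = rng.uniform(0.1, 1.5, size=500)
        dphi = np.concatenate([lags, -lags])
        assert pli(dphi, np.zeros_like(dphi)) == pytest.approx(0.0)

    def test_wrapping_handles_differences_beyond_pi(self):
        # a constant lag of +3 rad wraps to +3 (inside (-pi, pi]): sign +1
        # a constant lag of +4 rad wraps to 4 - 2 pi < 0: sign -1, PLI still 1
        base = np.linspace(0, 20, 200)
        assert pli(base + 4.0, base) == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(-np.pi, np.pi))
    def test_plv_invariant_to_common_offset(self, offset):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 2 * np.pi, (2, 200))
        assert plv(a + offset, b + offset) == pytest.approx(plv(a, b), abs=1e-12)


class TestEpochLocking:
    def test_fully_coupled_lagged_input(self):
        sig = make_coupled_signals(4, 100, 60, carrier=10, lag=np.pi / 4,
                                   coupling=1.0, seed=0)
        res = epoch_locking(sig, define_bands(10.0))
        assert res.mean_plv["SSA"] > 0.95
        assert res.mean_pli["SSA"] > 0.95

    def test_independent_noise_locks_weakly(self):
        rng = np.random.default_rng(2)
        sig = EpochedSignals(rng.standard_normal((4, 96, 500)), fs=100.0)
        res = epoch_locking(sig, define_bands(10.0))
        # band-limiting leaves ~2 * bandwidth * epoch_length independent phase
        # samples per epoch (~32 here), so the per-epoch null PLV sits near
        # sqrt(pi/4) / sqrt(32) ~ 0.16 rather than the broadband 1/sqrt(T)
        assert res.mean_plv["SSA"] < 0.25
        assert res.mean_pli["SSA"] < 0.25

    def test_permutation_equivariance(self):
        sig = make_coupled_signals(4, 100, 30, carrier=10, lag=0.5,
                                   coupling=0.7, noise_sd=0.3, seed=3)
        res = epoch_locking(sig, define_bands(10.0))
        perm = [2, 0, 3, 1]
        sig_p = EpochedSignals(sig.data[perm], fs=sig.fs)
        res_p = epoch_locking(sig_p, define_bands(10.0))
        M = res.plv_matrices["SSA"]
        assert np.allclose(res_p.plv_matrices["SSA"], M[np.ix_(perm, perm)])

    def test_single_channel_rejected(self):
        sig = EpochedSignals(np.random.default_rng(0).standard_normal((1, 4, 500)),
                             fs=100.0)
        with pytest.raises(ValueError):
            epoch_locking(sig, define_bands(10.0))

    def test_matrices_bounded_and_symmetric(self):
        sig = make_coupled_signals(5, 100, 30, carrier=10, lag=0.4,
                                   coupling=0.5, noise_sd=0.5, seed=4)
        res = epoch_locking(sig, define_bands(10.0))
        for band in ("LA", "UA", "SSA"):
            for M in (res.plv_matrices[band], res.pli_matrices[band]):
                assert np.all((M >= 0) & (M <= 1))
                assert np.allclose(M, M.T)


class TestSurrogates:
    def test_coupled_input_reaches_minimum_p(self):
        sig = make_coupled_signals(3, 100, 60, carrier=10, lag=0.6,
                                   coupling=1.0, noise_sd=0.1, seed=5)
        res = surrogate_null(sig, (8, 12), "plv", n_surrogates=50, seed=1)
        assert res.p_value == pytest.approx(1 / 51)

    def test_null_destroys_locking_on_coupled_input(self):
        sig = make_coupled_signals(3, 100, 60, carrier=10, lag=0.6,
                                   coupling=0.9, noise_sd=0.2, seed=6)
        res = surrogate_null(sig, (8, 12), "plv", n_surrogates=30, seed=2)
        assert res.null_values.mean() < res.observed

    def test_independent_channels_have_uniformish_p(self):
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(20):
            sig = EpochedSignals(rng.standard_normal((2, 12, 500)), fs=100.0)
            res = surrogate_null(sig, (8, 12), "plv", n_surrogates=19, seed=rep)
            ps.append(res.p_value)
        assert 0.25 < np.mean(ps) < 0.75

    def test_seeded_determinism(self):
        sig = make_coupled_signals(3, 100, 30, carrier=10, lag=0.6,
                                   coupling=0.8, noise_sd=0.3, seed=8)
        a = surrogate_null(sig, (8, 12), "pli", n_surrogates=20, seed=9)
        b = surrogate_null(sig, (8, 12), "pli", n_surrogates=20, seed=9)
        assert np.array_equal(a.null_values, b.null_values)

    def test_too_few_epochs_rejected(self):
        sig = make_coupled_signals(2, 100, 10, carrier=10, seed=0)
        with pytest.raises(ValueError):
            surrogate_null(sig, (8, 12), "plv")


class TestCohortTrends:
    def test_perfect_linear_decline(self):
        ages = np.linspace(20, 80, 30)
        table = pd.DataFrame(dict(age=ages, paf=12 - 0.02 * ages,
                                  plv_SSA=np.random.default_rng(0).uniform(size=30)))
        trends = cohort_locking_trends(table)
        paf_row = trends[trends.variable == "paf"].iloc[0]
        assert paf_row.r == pytest.approx(-1.0)
        assert paf_row.p < 1e-10

    def test_zero_variance_reported_missing(self):
        table = pd.DataFrame(dict(age=[20, 40, 60], paf=[10.0, 10.0, 10.0]))
        trends = cohort_locking_trends(table)
        assert np.isnan(trends[trends.variable == "paf"].iloc[0].r)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cohort_locking_trends(pd.DataFrame(dict(age=[1, 2], paf=[1, 2])))
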