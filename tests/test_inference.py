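import numpy as np
import pytest
from scipy import stats

import famdyn as fd
from famdyn.inference import adaptation_trace


class TestNormalizeAndRank:
    def _tiny_dataset(self):
        # 2 neurons x 3 stimuli x 4 bins at dt = 5 ms, onset at bin 0;
        # z-window covers every bin so the averages are over all bins
        nov = np.array([
            [[1, 1, 1, 1], [3, 3, 3, 3], [2, 2, 2, 2]],
            [[0, 2, 4, 2], [4, 4, 4, 4], [1, 1, 1, 1]],
        ], dtype=float)
        fam = np.array([
            [[2, 2, 2, 2], [1, 1, 1, 1], [4, 4, 4, 4]],
            [[3, 3, 3, 3], [2, 2, 2, 2], [5, 5, 5, 5]],
        ], dtype=float)
        return nov, fam

    def test_hand_computed_rank_average(self):
        nov, fam = self._tiny_dataset()
        novel, familiar = fd.normalize_and_rank(nov, fam, dt=5.0,
                                                z_window=(0.0, 15.0))
        # neuron 0: novel time-averages (1, 3, 2) -> mu = 2, sd = sqrt(2/3)
        # neuron 1: novel time-averages (2, 4, 1) -> mu = 7/3, sd = sqrt(14/9)
        sd0 = np.sqrt(2.0 / 3.0)
        sd1 = np.sqrt(14.0 / 9.0)
        # novel rank-ordering: neuron 0 -> stimuli (0, 2, 1); neuron 1 -> (2, 0, 1)
        top_expected = ((3 - 2) / sd0 + (4 - 7 / 3) / sd1) / 2
        assert novel.values[-1] == pytest.approx(np.full(4, top_expected))
        bottom_expected = ((1 - 2) / sd0 + (1 - 7 / 3) / sd1) / 2
        assert novel.values[0] == pytest.approx(np.full(4, bottom_expected))
        # familiar top rank: stimulus 2 for both neurons (constant traces)
        fam_top = ((4 - 2) / sd0 + (5 - 7 / 3) / sd1) / 2
        assert familiar.values[-1] == pytest.approx(np.full(4, fam_top))

    def test_zero_variance_neuron_rejected_with_identification(self):
        nov, fam = self._tiny_dataset()
        nov[1] = 1.0  # all stimuli identical for neuron 1
        with pytest.raises(ValueError, match="neuron 1"):
            fd.normalize_and_rank(nov, fam, dt=5.0, z_window=(0.0, 15.0))

    def test_passive_viewing_layout_dimensions(self):
        rng = np.random.default_rng(0)
        nov = rng.normal(5, 1, (3, 125, 44))
        fam = rng.normal(5, 1, (3, 125, 44))
        novel, familiar = fd.normalize_and_rank(nov, fam, dt=5.0)
        assert novel.values.shape == (125, 44)
        assert familiar.values.shape == (125, 44)
        assert novel.dt == 5.0

    def test_ranks_sorted_ascending(self):
        rng = np.random.default_rng(1)
        nov = rng.normal(0, 1, (4, 30, 44)) + \
            np.linspace(0, 3, 30)[None, :, None]
        fam = rng.normal(0, 1, (4, 30, 44))
        novel, _ = fd.normalize_and_rank(nov, fam, dt=5.0)
        avg = novel.time_average((80.0, 200.0))
        assert np.all(np.diff(avg) >= 0)


class TestReboundStrength:
    def test_linear_ramp_returns_its_slope(self):
        t = np.arange(80) * 5.0
        assert fd.rebound_strength(0.25 * t, dt=5.0) == pytest.approx(0.25)

    def test_constant_trace_zero(self):
        assert fd.rebound_strength(np.ones(80), dt=5.0) == pytest.approx(0.0, abs=1e-14)

    def test_linearity_in_trace(self):
        rng = np.random.default_rng(2)
        y1, y2 = rng.standard_normal(80), rng.standard_normal(80)
        s = (fd.rebound_strength(2 * y1 + 3 * y2, dt=5.0)
             - 2 * fd.rebound_strength(y1, dt=5.0)
             - 3 * fd.rebound_strength(y2, dt=5.0))
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_damped_cosine_matches_regression_oracle(self):
        t = np.arange(80) * 5.0
        y = np.exp(-t / 300) * np.cos(2 * np.pi * t / 150)
        sel = (t >= 230) & (t <= 320)
        oracle = stats.linregress(t[sel], y[sel]).slope
        assert fd.rebound_strength(y, dt=5.0) == pytest.approx(oracle, abs=1e-10)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            fd.rebound_strength(np.ones(10), dt=5.0)   # trace ends at 45 ms


class TestReconstructInput:
    def test_round_trip_is_exact(self, noise_free_surrogate):
        ds = noise_free_surrogate
        I = fd.reconstruct_input(ds.novel, k=1.8, tau_adapt=200.0)
        # forward-simulate the discrete update with the reconstructed input
        r = np.zeros_like(ds.novel.values)
        r[:, 0] = ds.novel.values[:, 0]
        a = adaptation_trace(ds.novel.values, 5.0, 200.0)
        for t in range(r.shape[1] - 1):
            r[:, t + 1] = -1.8 * a[:, t] + I[:, t]
        assert r == pytest.approx(ds.novel.values, abs=1e-12)

    def test_reconstructed_input_matches_generator_truth(self, noise_free_surrogate):
        ds = noise_free_surrogate
        I = fd.reconstruct_input(ds.novel, k=1.8, tau_adapt=200.0)
        assert I == pytest.approx(ds.inputs[:, :-1], abs=1e-10)

    def test_steady_trace_closed_form(self):
        # r = a = 1 everywhere: I = Phi^{-1}(1) + 1.8 * 1 = 2.8
        m = fd.RankTimeMatrix(np.ones((3, 10)), dt=5.0)
        I = fd.reconstruct_input(m, k=1.8, tau_adapt=200.0)
        assert I == pytest.approx(2.8)

    def test_noninvertible_transfer_rejected(self):
        m = fd.RankTimeMatrix(np.ones((3, 10)), dt=5.0)
        phi = fd.TransferFunction.shifted_rectified(0.0)
        with pytest.raises(ValueError):
            fd.reconstruct_input(m, transfer=phi)


class TestFitPostsynapticDependence:
    def test_noise_free_recovery_is_exact(self, noise_free_surrogate):
        ds = noise_free_surrogate
        res = fd.fit_postsynaptic_dependence(ds.novel, ds.familiar)
        assert np.max(np.abs(res.f_R - ds.truth_f_R)) <= 1e-8
        assert np.max(np.abs(res.f_F - ds.truth_f_F)) <= 1e-8
        assert np.all(res.residuals <= 1e-16)

    def test_weights_do_not_change_consistent_solution(self, noise_free_surrogate):
        ds = noise_free_surrogate
        weighted = fd.fit_postsynaptic_dependence(ds.novel, ds.familiar,
                                                  late_weight=5.0)
        unweighted = fd.fit_postsynaptic_dependence(ds.novel, ds.familiar,
                                                    late_weight=1.0)
        assert weighted.f_R == pytest.approx(unweighted.f_R, abs=1e-9)
        assert weighted.f_F == pytest.approx(unweighted.f_F, abs=1e-9)

    def test_late_bins_carry_weight_five(self, noise_free_surrogate):
        ds = fd.generate_surrogate_dataset(n_bins=80, noise_sd=0.0, seed=3)
        res = fd.fit_postsynaptic_dependence(ds.novel, ds.familiar)
        t = ds.familiar.times[:-1]
        assert np.all(res.weights[t >= 230.0] == 5.0)
        assert np.all(res.weights[t < 230.0] == 1.0)

    def test_noisy_recovery_preserves_structure(self, noisy_surrogate):
        ds = noisy_surrogate
        res = fd.fit_postsynaptic_dependence(ds.novel, ds.familiar)
        rho = stats.spearmanr(ds.truth_f_R, res.f_R).statistic
        assert rho > 0.95
        assert res.f_F.mean() < 0.0

    def test_rmse_decreases_with_noise(self):
        rmses = []
        for sd in (0.2, 0.1, 0.05):
            ds = fd.generate_surrogate_dataset(noise_sd=sd, seed=21)
            res = fd.fit_postsynaptic_dependence(ds.novel, ds.familiar)
            rmses.append(np.sqrt(np.mean((res.f_R - ds.truth_f_R) ** 2)
                                 + np.mean((res.f_F - ds.truth_f_F) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]


class TestDeriveTransfer:
    def test_affine_rates_recover_affine_transfer(self):
        n = 125
        q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        rates = 2.0 * q + 1.0
        phi = fd.derive_transfer_from_novel(rates)
        x = np.linspace(q[0], q[-1], 50)
        assert phi(x) == pytest.approx(2.0 * x + 1.0, abs=1e-9)
        assert phi.inverse(phi(0.3)) == pytest.approx(0.3, abs=1e-9)

    def test_order_violations_cleaned_isotonically(self):
        rates = np.array([0.0, 1.0, 0.5, 2.0, 3.0])
        phi = fd.derive_transfer_from_novel(rates)
        assert np.all(np.diff(phi.table_y) >= 0)

    def test_round_trip_through_known_monotone_transfer(self):
        # rates generated through a known curve from Gaussian inputs are
        # recovered on the sampled range within interpolation error
        n = 200
        q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        true = lambda x: 3.0 / (1 + np.exp(-x))      # monotone
        phi = fd.derive_transfer_from_novel(true(q))
        x = np.linspace(-1.5, 1.5, 40)
        assert phi(x) == pytest.approx(true(x), abs=5e-3)

    def test_needs_at_least_three_ranks(self):
        with pytest.raises(ValueError):
            fd.derive_transfer_from_novel(np.array([0.0, 1.0]))


class TestFitSTDParams:
    def test_self_consistent_recovery(self, std_reference_traces):
        ref = std_reference_traces
        fit = fd.fit_std_params(ref["novel"], ref["familiar"], dt=ref["dt"])
        assert fit.fg_strength == pytest.approx(ref["truth_fg"], rel=0.01)
        assert fit.depletion_strength == pytest.approx(ref["truth_gamma"],
                                                       rel=0.01)

    def test_degenerate_gamma_zero_is_linear_gain_fit(self):
        # familiar trace from a stable linear gain fg < 1 and gamma = 0
        from famdyn.inference import _std_trace_on_data_grid
        n_bins, dt = 44, 5.0
        t = np.arange(n_bins) * dt
        wave = fd.DriveWaveform(1, 1, 150, 50)
        r_nov = np.zeros(n_bins)
        r_nov[1:] = (4.0 * wave(t) / wave(75 * np.log(3)))[:-1]
        r_fam = _std_trace_on_data_grid(0.6, 0.0, r_nov[1:], 0.0,
                                        5.0, 200.0, dt)
        fit = fd.fit_std_params(r_nov, r_fam, dt=dt, grid_size=40)
        assert fit.fg_strength == pytest.approx(0.6, abs=0.05)
        assert fit.depletion_strength <= 0.01

    def test_mismatched_traces_rejected(self):
        with pytest.raises(ValueError):
            fd.fit_std_params(np.ones(10), np.ones(11))
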