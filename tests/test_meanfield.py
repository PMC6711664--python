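import numpy as np
import pytest

import famdyn as fd
from conftest import count_local_maxima, has_rebound


class TestReducedDynamics:
    def test_unlearned_network_decouples(self, fig5_params):
        traj = fd.simulate_meanfield(fig5_params, 400.0, learned=False)
        assert np.all(traj.m == 0.0)
        assert np.all(traj.n == 0.0)

    def test_zero_coefficients_match_unlearned(self, fig5_params):
        from dataclasses import replace
        p0 = replace(fig5_params, fgbar_R=0.0, fbar_R=0.0, fbar_F=0.0,
                     fgbar_F=0.0, drive_m=0.0)
        learned = fd.simulate_meanfield(p0, 400.0, learned=True)
        unlearned = fd.simulate_meanfield(p0, 400.0, learned=False)
        assert learned.rbar == pytest.approx(unlearned.rbar, abs=1e-12)
        assert np.all(learned.m == 0.0)

    def test_familiar_shows_rebound_novel_does_not(self, fig5_params):
        fam = fd.simulate_meanfield(fig5_params, 800.0, learned=True)
        nov = fd.simulate_meanfield(fig5_params, 800.0, learned=False)
        assert has_rebound(fam.rbar)
        assert not has_rebound(nov.rbar)

    def test_constant_input_shifts_fixed_point_linearly(self, fig5_params):
        from dataclasses import replace
        base = fd.simulate_meanfield(replace(fig5_params, drive_mean=1.0),
                                     6000.0, learned=False)
        shifted = fd.simulate_meanfield(replace(fig5_params, drive_mean=1.5),
                                        6000.0, learned=False)
        gain = 1.0 / (1.0 - fig5_params.recurrent_scale
                      + fig5_params.adapt_strength)
        assert shifted.rbar[-1] - base.rbar[-1] == pytest.approx(
            0.5 * gain, rel=1e-6)


class TestNetworkEquivalence:
    def test_meanfield_matches_full_network(self):
        """4-variable reduction vs a 500-unit linear network built from
        the same separable rules (zero-sum g)."""
        rng = np.random.default_rng(3)
        N = 500
        xi = rng.gamma(3.0, 1.0, N)
        rule_R = fd.SeparableRule(0.9 * xi / np.var(xi), xi - xi.mean())
        g_F = rng.standard_normal(N)
        g_F -= g_F.mean()
        rule_F = fd.SeparableRule(-0.7 + 0.1 * rng.standard_normal(N), g_F)
        amps = rng.gamma(3.0, 1.0, N)
        wave = fd.DriveWaveform(1, 1, 400, 20)
        coef = fd.meanfield_coefficients(rule_R, rule_F, amps)

        W = fd.uniform_recurrent_weights(N, 0.0) + fd.separable_delta(rule_R)
        f_F = rule_F.post_dependence
        cF = float(np.mean(g_F * amps))
        drive = lambda t: (amps + f_F * cF) * wave(t)
        net = fd.simulate_network(fd.NetworkParams(n_units=N, dt=0.5), W,
                                  drive, duration=1000.0)

        mf = fd.MeanFieldParams(
            adapt_strength=1.8, fgbar_R=coef.fgbar_R, fbar_R=coef.fbar_R,
            fbar_F=coef.fbar_F, fgbar_F=coef.fgbar_F,
            drive_mean=lambda t: float(np.mean(amps)) * wave(t),
            drive_m=lambda t: coef.input_m * wave(t),
            drive_f=lambda t: cF * wave(t), dt=0.5)
        red = fd.simulate_meanfield(mf, 1000.0, learned=True)

        r_scale = np.max(np.abs(red.rbar))
        m_scale = np.max(np.abs(red.m))
        assert np.max(np.abs(red.rbar - net.mean_rate())) <= 1e-6 * r_scale
        assert np.max(np.abs(red.m - net.overlap(rule_R.pre_dependence))) \
            <= 1e-6 * m_scale

    def test_equivalence_over_random_coefficient_draws(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            N = 60
            f_R = rng.standard_normal(N)
            g_R = rng.standard_normal(N)
            g_R -= g_R.mean()
            amps = rng.standard_normal(N)
            coef = fd.meanfield_coefficients(fd.SeparableRule(f_R, g_R), None, amps)
            wave = fd.DriveWaveform(1, 1, 200, 30)
            W = fd.separable_delta(fd.SeparableRule(f_R, g_R))
            k = float(rng.uniform(0.5, 2.5))
            net = fd.simulate_network(
                fd.NetworkParams(n_units=N, adapt_strength=k, dt=0.5), W,
                lambda t: amps * wave(t), duration=400.0)
            mf = fd.MeanFieldParams(
                adapt_strength=k, fgbar_R=coef.fgbar_R, fbar_R=coef.fbar_R,
                drive_mean=lambda t: coef.input_mean * wave(t),
                drive_m=lambda t: coef.input_m * wave(t), dt=0.5)
            red = fd.simulate_meanfield(mf, 400.0, learned=True)
            scale = max(np.max(np.abs(red.m)), 1e-12)
            assert np.max(np.abs(red.m - net.overlap(g_R))) <= 1e-6 * scale


class TestGlobalInhibition:
    def test_constant_drive_relaxes_monotonically(self):
        p = fd.GlobalInhibitionParams(fgbar_R=0.9, drive_m=1.0, dt=0.5)
        traj = fd.simulate_global_inhibition(p, 400.0)
        # first-order m: no overshoot of the fixed point I/(1 - fg)
        fp = 1.0 / (1.0 - 0.9)
        assert np.all(np.diff(traj.m) >= -1e-12)
        assert traj.m[-1] <= fp + 1e-9

    def test_zero_inhibition_reduces_to_leaky_integrator(self):
        p = fd.GlobalInhibitionParams(adapt_strength=0.0, drive_mean=2.0,
                                      dt=0.5)
        traj = fd.simulate_global_inhibition(p, 200.0)
        # r(t) = 2 (1 - e^{-t/tau_R}) up to Euler error
        expect = 2.0 * (1 - np.exp(-traj.times / p.tau_rate))
        assert traj.rbar == pytest.approx(expect, abs=0.05)

    def test_no_rebound_in_overlap(self, fig5_params):
        p = fd.GlobalInhibitionParams(fgbar_R=0.9, adapt_strength=1.8,
                                      drive_m=fig5_params.drive_m, dt=0.5)
        traj = fd.simulate_global_inhibition(p, 800.0)
        assert count_local_maxima(traj.m, int(np.argmax(traj.m))) == 0


class TestReducedSTD:
    def test_linear_fixed_point_without_depletion(self):
        _, r, x = fd.simulate_std_reduced(0.5, 0.0, 200.0, 2.0, 6000.0)
        assert np.all(x == 1.0)
        assert r[-1] == pytest.approx(2.0 / (1 - 0.5), rel=1e-6)

    def test_joint_fixed_point_resource_half(self):
        # choose drive so that gamma tau_x r* = 1 at the fixed point
        fg, tau_x = 0.5, 200.0
        r_star = 2.0
        gamma = 1.0 / (tau_x * r_star)
        # tau_r dr/dt = 0: r = fg x r + I with x = 1/2
        I = r_star * (1 - fg * 0.5)
        _, r, x = fd.simulate_std_reduced(fg, gamma, tau_x, I, 10000.0,
                                          dt=0.1)
        assert r[-1] == pytest.approx(r_star, abs=1e-6)
        assert x[-1] == pytest.approx(0.5, abs=1e-6)

    def test_best_fit_parameters_show_no_strong_rebound(self):
        wave = fd.DriveWaveform(1, 1, 150, 50)
        peak = wave(75 * np.log(3))
        _, r, _ = fd.simulate_std_reduced(
            2.56, 0.125, 200.0, lambda t: 6.0 / peak * wave(t), 600.0)
        i_peak = int(np.argmax(r))
        i_trough = i_peak + int(np.argmin(r[i_peak:]))
        post = r[i_trough:]
        assert post.max() - r[i_trough] <= 0.1 * r[i_peak]


class TestCompetition:
    def test_uncoupled_populations_match_single_stimulus(self):
        params, drives, _ = fd.presets.fig7_competition_setup()
        from dataclasses import replace
        p0 = replace(params, mutual_inhibition=0.0)
        both = fd.simulate_competition(p0, drives, (0.0, 500.0), 1500.0)
        single = fd.simulate_competition(p0, drives, (0.0, 1e9), 1500.0)
        assert both.m[0] == pytest.approx(single.m[0], abs=1e-12)
        # population 2 is a time-shifted copy of population 1
        dt = p0.dt
        shift = int(round(500.0 / dt))
        assert both.m[1][shift:] == pytest.approx(both.m[0][:-shift],
                                                  abs=1e-12)

    def test_population2_silent_before_onset(self):
        params, drives, onsets = fd.presets.fig7_competition_setup()
        traj = fd.simulate_competition(params, drives, onsets, 1500.0)
        pre = traj.times < onsets[1]
        assert np.all(traj.m[1][pre] == 0.0)

    def test_competition_strengthens_oscillation_at_similar_frequency(self):
        params, drives, onsets = fd.presets.fig7_competition_setup()
        traj = fd.simulate_competition(params, drives, onsets, 2500.0)
        single = fd.simulate_competition(params, drives, (0.0, 1e9), 2500.0)
        t = traj.times
        m1 = traj.m[0]
        # transient suppression just after stimulus-2 onset
        at_onset = m1[np.searchsorted(t, onsets[1])]
        just_after = m1[(t > onsets[1]) & (t < onsets[1] + 150)]
        assert just_after.min() < at_onset
        # stronger oscillation: peak-to-trough amplitude grows
        pre_win = (t >= 150) & (t < onsets[1])
        post_win = t >= onsets[1] + 50
        amp_pre = m1[pre_win].max() - m1[pre_win].min()
        amp_post = m1[post_win].max() - m1[post_win].min()
        assert amp_post > amp_pre
        # similar frequency: compare peak-to-peak intervals (within 20%)
        def peak_interval(y, sel):
            yy = y.copy()
            yy[~sel] = -np.inf
            idx = np.flatnonzero((yy[1:-1] > yy[:-2]) & (yy[1:-1] > yy[2:])) + 1
            return np.mean(np.diff(t[idx]))
        T_comp = peak_interval(m1, post_win)
        T_single = peak_interval(single.m[0], single.times >= 150)
        assert abs(T_comp - T_single) <= 0.2 * T_single


class TestSuccessivePresentation:
    def test_novel_second_peak_suppressed(self):
        p = fd.presets.fig5_successive_params(n_stimuli=2)
        nov = fd.simulate_meanfield(p, 450.0, learned=False)
        t = nov.times
        p1 = nov.rbar[(t >= 0) & (t < 150)].max()
        p2 = nov.rbar[(t >= 150) & (t < 300)].max()
        assert p2 < p1

    def test_familiar_second_response_less_suppressed(self):
        """Evoked second-stimulus responses (peak minus the trace value
        at that stimulus's onset): adaptation suppresses the novel one
        far more than the familiar one."""
        p = fd.presets.fig5_successive_params(n_stimuli=2)
        fam = fd.simulate_meanfield(p, 450.0, learned=True)
        nov = fd.simulate_meanfield(p, 450.0, learned=False)
        t = fam.times
        i_on = np.searchsorted(t, 150.0)

        def evoked_ratio(y):
            p1 = y[(t >= 0) & (t < 150)].max() - y[0]
            p2 = y[(t >= 150) & (t < 300)].max() - y[i_on]
            return p2 / p1

        assert evoked_ratio(fam.rbar) > evoked_ratio(nov.rbar)
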