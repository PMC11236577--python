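"""Derived measurements: passive properties, noise calibration,
interruption timing and statistics, rescue thresholds, trace metrics."""

import numpy as np
import pytest

from pvin import analysis as an
from pvin import bifurcation as bf
from pvin.integrate import resting_state


class TestPassive:
    def test_tau_equals_RC_within_5pc(self, params):
        props = an.measure_passive(params)
        assert props.fit_ok
        assert props.tau_ms == pytest.approx(
            props.R_in_MOhm * props.C_pF * 1e-3, rel=0.05)

    def test_leak_only_cell_analytic(self, passive_params):
        props = an.measure_passive(passive_params)
        R_expected = 1.0 / (passive_params.g_L * 1e-3
                            * passive_params.area) / 1e6   # MΩ
        assert props.R_in_MOhm == pytest.approx(R_expected, rel=1e-3)
        assert props.V_rest_mV == pytest.approx(passive_params.E_L,
                                                abs=1e-6)
        assert props.C_pF == pytest.approx(passive_params.C_total_pF,
                                           rel=0.01)


class TestNoiseCalibration:
    def test_linear_cell_obeys_ohms_law(self, passive_params):
        """A passive cell with R MΩ needs 5 mV / R of current for a
        5 mV shift, independent of the frozen q."""
        R_MOhm = 1.0 / (passive_params.g_L * 1e-3
                        * passive_params.area) / 1e6
        eq = bf.find_equilibrium(passive_params, 0.1, 100.0,
                                 v_guess=passive_params.E_L + 8.0,
                                 v_window=20.0)
        hopf = bf.HopfPoint(parameter="q", value=0.1, state=eq,
                            eig_pair=1j)
        sigma = an.calibrate_noise_sigma(passive_params, hopf,
                                         I_hold_pA=100.0)
        assert sigma == pytest.approx(5.0 / R_MOhm * 1e3, rel=1e-6)

    def test_ca1_sigma_from_hopf(self, params, hopf_450):
        sigma = an.calibrate_noise_sigma(params, hopf_450)
        # 5 mV on a ~30 MΩ local slope: order 150-200 pA
        assert 120.0 < sigma < 220.0


class TestInterruptionTiming:
    def test_known_gap_recovered(self):
        st = np.concatenate([np.arange(0.0, 500.0, 20.0),
                             np.arange(1100.0, 1500.0, 20.0)])
        out = an.interruption_duration(st, 500.0, record_end_ms=1500.0)
        assert out.duration_ms == pytest.approx(600.0)

    def test_spike_at_offset_gives_zero(self):
        st = np.arange(0.0, 1500.0, 20.0)   # fires right through
        out = an.interruption_duration(st, 700.0, record_end_ms=1500.0)
        assert out.duration_ms == 0.0

    def test_permanent_flagged(self):
        st = np.arange(0.0, 500.0, 20.0)
        out = an.interruption_duration(st, 600.0, record_end_ms=4000.0)
        assert out.permanent and np.isinf(out.duration_ms)

    def test_noiseless_interruption_order_one_second(self, params):
        """The canonical mock IPSP silences the model for on the order
        of a second beyond the stimulus."""
        _, out = an.run_interruption(params)
        assert not out.permanent
        assert 500.0 < out.duration_ms < 3000.0
        assert out.duration_ms > 20.0 * out.pre_isi_ms


class TestInterruptionStats:
    def test_zero_sigma_reproduces_deterministic(self, params):
        _, det = an.run_interruption(params)
        stats = an.interruption_stats(params, 0.0, seeds=[1, 2, 3])
        assert np.all(stats.durations_ms == det.duration_ms)
        assert stats.sd_ms == 0.0

    def test_mean_sd_recomputable(self, params, hopf_450):
        sigma = an.calibrate_noise_sigma(params, hopf_450)
        stats = an.interruption_stats(params, sigma, seeds=range(4))
        assert stats.n == 4
        assert stats.mean_ms == pytest.approx(stats.durations_ms.mean())
        assert stats.sd_ms == pytest.approx(
            stats.durations_ms.std(ddof=1))

    def test_requires_two_trials(self, params):
        with pytest.raises(ValueError):
            an.interruption_stats(params, 0.0, seeds=[1])

    def test_interruption_mechanism(self, params, hopf_450):
        """Mechanistic check.  Noiseless: firing resumes only once q
        has decayed below the Hopf value (slow passage delays the
        resumption, never hastens it).  With noise the trajectory can
        be kicked across the shrinking unstable cycle before the Hopf
        is reached, so noise can only shorten the interruption, never
        prolong it beyond the deterministic slow passage."""
        res0, det = an.run_interruption(params)
        t_resume = det.offset_ms + det.duration_ms
        i = np.searchsorted(res0.t, t_resume - 2.0)
        assert res0.q[i] < hopf_450.value + 0.002

        sigma = an.calibrate_noise_sigma(params, hopf_450)
        for seed in range(5):
            _, out = an.run_interruption(params, sigma_pA=sigma,
                                         seed=seed)
            assert out.duration_ms <= det.duration_ms


class TestFastSlow:
    def test_trajectory_tracks_stable_branch(self, params, hopf_450):
        """During the post-IPSP silence the (V, q) trajectory rides the
        frozen-q stable equilibrium branch until the Hopf is crossed."""
        from pvin import model_core as mc

        res, out = an.run_interruption(params)
        sel = ((res.t > out.offset_ms + 100.0)
               & (res.t < out.offset_ms + out.duration_ms - 100.0))
        V, q = res.V[sel], res.q[sel]
        on_branch = q > hopf_450.value * 1.05
        q_eq = mc.equilibrium_q_of_V(V[on_branch], 450.0, params)
        assert np.abs(q_eq - q[on_branch]).max() < 0.01

    def test_subthreshold_oscillation_grows_before_resumption(
            self, params, hopf_450):
        """After the Hopf crossing the voltage envelope grows
        monotonically until the first spike."""
        res, out = an.run_interruption(params)
        t_resume = out.offset_ms + out.duration_ms
        # start at the Hopf crossing of q(t); measure the oscillation
        # as the linearly detrended peak-to-peak per block (the slow
        # drift along the branch otherwise hides the small cycles)
        post = res.t > out.offset_ms
        t_hb = res.t[post][np.argmax(res.q[post] < hopf_450.value)]
        sel = (res.t > t_hb) & (res.t < t_resume - 2.0)
        t, V = res.t[sel], res.V[sel]
        nblk = 16
        n = V.size // nblk
        env = []
        for i in range(nblk):
            tb, vb = t[i * n:(i + 1) * n], V[i * n:(i + 1) * n]
            env.append(np.ptp(vb - np.polyval(np.polyfit(tb, vb, 1), tb)))
        env = np.array(env)
        k = int(np.argmin(env))
        assert k < nblk - 2                  # growth phase is resolved
        assert np.all(np.diff(env[k:]) > 0)  # monotone growth to spike
        assert env[-1] > 1e3 * env[k]        # spans the small-to-spiking range


class TestRescue:
    def test_thresholds_nonincreasing_and_below_rest(self, params):
        delays = [50.0, 300.0, 800.0]
        exc = an.rescue_threshold_curve(params, delays, E_rev_mV=0.0,
                                        at_rest=True)
        assert np.all(np.diff(exc.threshold_nS) <= 1e-9)
        assert exc.threshold_nS[0] < exc.threshold_at_rest_nS
        inh = an.rescue_threshold_curve(params, delays, E_rev_mV=-65.0)
        assert np.all(np.diff(inh.threshold_nS) <= 1e-9)

    def test_upper_bracket_error(self, params):
        y_rest = resting_state(params)
        with pytest.raises(RuntimeError, match="bracket"):
            an.rescue_threshold(params, y_rest, hold_pA=0.0,
                                g_hi_nS=0.5)


class TestMinSustainedFrequency:
    def test_regular_train(self):
        st = np.arange(0.0, 1000.0, 25.0)
        assert an.min_sustained_frequency(st) == pytest.approx(40.0)

    def test_boundary_isi_unchanged(self):
        # one ISI at 1.4x the mean stays below the 1.5x rule threshold
        isis = np.array([25.0] * 20 + [35.9])
        st = np.concatenate([[0.0], np.cumsum(isis)])
        f = an.min_sustained_frequency(st)
        assert f == pytest.approx(1000.0 / isis.mean())

    def test_errors(self):
        with pytest.raises(ValueError):
            an.min_sustained_frequency([100.0])
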