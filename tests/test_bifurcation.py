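"""Continuation, Hopf detection, limit cycles and regime labels."""

import numpy as np
import pytest

from pvin import bifurcation as bf
from pvin import model_core as mc
from pvin.integrate import integrate, resting_state
from pvin.stimulus import step_protocol


class TestEquilibria:
    def test_residual_below_tolerance(self, params):
        st = bf.find_equilibrium(params, 0.2, 450.0)
        d = mc.rhs(st, 450.0, params, frozen_q=0.2)
        assert np.linalg.norm(d) < 1e-10

    def test_gates_on_steady_state_curves(self, params):
        st = bf.find_equilibrium(params, 0.1, 300.0)
        V = st[0]
        for i, g in enumerate(mc.GATES[:-1], start=1):
            assert st[i] == pytest.approx(
                mc.gate_steady_state(g, V, params), rel=1e-12)

    def test_matches_long_integration_at_rest(self, params):
        st = bf.find_equilibrium(params, float(resting_state(params)[5]),
                                 0.0, v_guess=-70.0)
        res = integrate(params, step_protocol(0.0, 1000.0))
        assert abs(st[0] - res.V[-1]) < 0.01

    def test_depolarized_quiescent_branch_at_450(self, params):
        # the post-IPSP quiescent state: depolarized yet silent
        st = bf.find_equilibrium(params, 0.2, 450.0)
        assert -50.0 < st[0] < -35.0
        ev = np.linalg.eigvals(bf.fast_jacobian(params, st, 450.0))
        assert np.all(ev.real < 0)

    def test_missing_equilibrium_raises(self, params):
        with pytest.raises(RuntimeError, match="no equilibrium"):
            bf.find_equilibrium(params, 0.2, 450.0, v_guess=-100.0,
                                v_window=2.0)


class TestContinuation:
    def test_branch_matches_closed_form(self, params, branch_450, rng):
        """The predictor-corrector branch agrees with the closed-form
        parametrisation q_eq(V) (independent oracle) everywhere."""
        idx = rng.choice(branch_450.values.size, size=20, replace=False)
        q_oracle = mc.equilibrium_q_of_V(branch_450.V[idx], 450.0, params)
        np.testing.assert_allclose(branch_450.values[idx], q_oracle,
                                   atol=1e-10)

    def test_stability_flags_match_eigenvalues(self, branch_450):
        for ev, flag in zip(branch_450.eigvals, branch_450.stable):
            assert flag == bool(np.all(ev.real < 0))

    def test_stable_above_hopf_unstable_below(self, params, branch_450,
                                              hopf_450):
        q = branch_450.values
        above = q > hopf_450.value + 0.002
        below = (q < hopf_450.value - 0.002) & (q > 0.0)
        assert branch_450.stable[above].all()
        assert not branch_450.stable[below].any()

    def test_weakly_repelling_branch(self, branch_450, hopf_450):
        """Below the Hopf the fixed points repel only weakly (small
        positive real parts), which is what prolongs the interruption."""
        q = branch_450.values
        sel = (q < hopf_450.value) & (q > 0.01)
        re = np.array([ev.real.max() for ev in branch_450.eigvals[sel]])
        assert np.all(re > 0.0)
        assert np.all(re < 0.1)   # per-ms rate << spike dynamics

    def test_continuation_in_applied_current(self, params):
        br = bf.continue_equilibria(params, 0.0, (0.0, 300.0),
                                    parameter="I_app", frozen_q=0.2)
        assert br.values.size > 50
        assert np.all(np.isfinite(br.V))
        # V increases with injected current along this branch
        order = np.argsort(br.values)
        assert br.V[order][-1] > br.V[order][0]


class TestHopf:
    def test_single_subcritical_hopf_at_450(self, params, branch_450):
        hopfs = bf.detect_hopf(branch_450, params, I_app_pA=450.0,
                               classify=True)
        assert len(hopfs) == 1
        assert hopfs[0].criticality == "subcritical"

    def test_pure_imaginary_pair_at_crossing(self, hopf_450):
        assert abs(hopf_450.eig_pair.real) < 1e-8
        assert hopf_450.eig_pair.imag > 0.1   # genuine oscillatory pair

    def test_simulation_brackets_hopf(self, params, hopf_450):
        """Frozen-q simulations started near the equilibrium decay just
        above the Hopf and grow just below it (bracket < 1e-3)."""
        def grows(q):
            eq = bf.find_equilibrium(params, q, 450.0)
            y0 = eq.copy()
            y0[0] += 0.1
            res = integrate(params, step_protocol(450.0, 3000.0),
                            frozen_q=q, y0=y0)
            if res.spike_times.size:
                return True
            d = np.abs(res.V - eq[0])
            return d[res.t > 2500.0].max() > d[(res.t > 100.0)
                                               & (res.t < 500.0)].max()

        dq = 5e-4
        assert grows(hopf_450.value - dq)
        assert not grows(hopf_450.value + dq)


class TestLimitCycles:
    def test_cycle_inside_bistable_window(self, params):
        cyc = bf.stable_limit_cycle(params, 0.1, 450.0)
        assert cyc is not None
        assert cyc["V_max"] > 0.0 > cyc["V_min"]

    def test_no_cycle_above_snpo(self, params):
        assert bf.stable_limit_cycle(params, 0.55, 450.0) is None

    def test_period_matches_spike_rate(self, params):
        cyc = bf.stable_limit_cycle(params, 0.1, 450.0)
        res = integrate(params, step_protocol(450.0, 800.0), frozen_q=0.1,
                        y0=np.array([-80.0, 0.0, 0.9, 0.0, 0.0, 0.1]))
        st = res.spike_times
        isi = np.diff(st[st > 400.0]).mean()
        assert abs(cyc["period_ms"] - isi) / isi < 0.005

    def test_unstable_cycle_small_near_hopf(self, params, hopf_450):
        out = bf.unstable_limit_cycle(params, hopf_450.value + 0.01, 450.0)
        assert out["exists"]
        assert out["amplitude_mV"] < 12.0

    def test_unstable_cycle_grows_toward_snpo(self, params, hopf_450):
        near_hopf = bf.unstable_limit_cycle(params, hopf_450.value + 0.01,
                                            450.0)
        mid_window = bf.unstable_limit_cycle(params, 0.30, 450.0)
        assert mid_window["exists"]
        assert mid_window["amplitude_mV"] > near_hopf["amplitude_mV"]

    def test_no_unstable_cycle_outside_window(self, params):
        out = bf.unstable_limit_cycle(params, 0.02, 450.0)
        assert not out["exists"]

    def test_limit_cycle_branch_container(self, params, hopf_450):
        br = bf.limit_cycle_branch(params, 450.0,
                                   q_stable=[0.1, 0.3, 0.6],
                                   q_unstable=[hopf_450.value + 0.02])
        df = br.to_frame()
        assert df.stable.sum() == 2          # q = 0.6 has no cycle
        assert (~df.stable).sum() == 1
        stable = df[df.stable]
        assert (stable.V_max > stable.V_min).all()
        assert np.isnan(df[~df.stable].period_ms).all()

    def test_ray_directions_agree(self, params):
        up = bf.unstable_limit_cycle(params, 0.2, 450.0, direction=+1)
        down = bf.unstable_limit_cycle(params, 0.2, 450.0, direction=-1)
        assert up["exists"] and down["exists"]
        # both rays hit the same basin boundary object: comparable size
        assert 0.3 < down["amplitude_mV"] / up["amplitude_mV"] < 3.0


class TestSNPO:
    def test_bisection_tolerance_and_dt_stability(self, params):
        s1 = bf.detect_snpo(params, 450.0, tol=1e-3)
        s2 = bf.detect_snpo(params, 450.0, tol=1e-3, dt=0.005)
        assert s1 is not None
        assert abs(s1 - s2) < 0.005

    def test_lower_current_shrinks_window(self, params):
        s450 = bf.detect_snpo(params, 450.0, tol=1e-3)
        s330 = bf.detect_snpo(params, 330.0, tol=1e-3)
        assert s330 < s450

    def test_none_when_no_cycle(self, params):
        assert bf.detect_snpo(params, 50.0) is None


class TestQNullcline:
    def test_matches_gate_steady_state(self, params):
        V = np.linspace(-100.0, 0.0, 50)
        np.testing.assert_array_equal(
            bf.q_nullcline(V, params),
            mc.gate_steady_state("q", V, params))
        assert bf.q_nullcline(np.array([-78.5]), params)[0] == 0.5
        assert np.all(np.diff(bf.q_nullcline(V, params)) < 0)


class TestRegimeClassifier:
    def test_labels_on_synthetic_trains(self):
        dur = 3000.0
        assert bf.classify_trace([], dur) == "quiescent"
        assert bf.classify_trace([600.0, 620.0, 640.0], dur) == "transient"
        tonic = np.arange(100.0, 2990.0, 20.0)
        assert bf.classify_trace(tonic, dur) == "tonic"
        burst = np.concatenate([np.arange(0, 200, 20.0),
                                np.arange(900, 1100, 20.0),
                                np.arange(1800, 2000, 20.0)])
        assert bf.classify_trace(burst, dur) == "elliptical_bursting"

    def test_trailing_silence_counts_as_gap(self):
        # one internal gap + long trailing silence: a slow burst cycle
        burst = np.concatenate([np.arange(0, 300, 15.0),
                                np.arange(1500, 1800, 15.0)])
        assert bf.classify_trace(burst, 3000.0) == "elliptical_bursting"

    def test_single_pause_tiebreak_is_tonic(self):
        train = np.concatenate([np.arange(0, 1000, 20.0),
                                np.arange(1400, 2990, 20.0)])
        assert bf.classify_trace(train, 3000.0) == "tonic"

    def test_scan_reproduces_known_cells(self, params):
        grid = bf.regime_scan(params, g_values=[0.0, 5.0],
                              I_values=[60.0, 450.0])
        df = grid.to_frame()
        assert df.loc[0.0, 450.0] == "tonic"
        assert df.loc[5.0, 450.0] == "tonic"
        assert df.loc[0.0, 60.0] == "quiescent"
        assert df.loc[5.0, 60.0] == "quiescent"

    def test_bursting_cell_high_gkv1(self, params):
        from pvin.integrate import resting_state as rs

        p10 = params.replace(g_Kv1=10.0)
        res = integrate(p10, step_protocol(330.0, 3000.0),
                        y0=rs(p10))
        assert bf.classify_trace(res.spike_times, 3000.0) == \
            "elliptical_bursting"
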