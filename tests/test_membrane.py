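"""Cell-scale model: variants, limit-cycle pacing, AP metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from fibrosim import membrane as mb


class TestVariants:
    def test_afib_scalings_match_published_reductions(self):
        m = mb.make_model("afib")
        s = m.conductance_scalings
        assert s["I_CaL"] == pytest.approx(0.3)
        assert s["I_Kur"] == pytest.approx(0.5)
        assert s["I_to"] == pytest.approx(0.5)
        assert "I_Na" not in s

    def test_fibrotic_composes_with_afib(self):
        # independent hand computation: the fibrotic changes are applied to
        # the AFib model, so I_CaL = 0.3 (afib) * 0.5 (fibrotic) = 0.15
        s = mb.make_model("fibrotic").conductance_scalings
        assert s["I_CaL"] == pytest.approx(0.3 * 0.5)
        assert s["I_Na"] == pytest.approx(0.6)
        assert s["I_K1"] == pytest.approx(0.5)

    def test_baseline_has_unit_scalings(self):
        v = mb.make_model("baseline").scaling_vector()
        assert np.all(v == 1.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown membrane variant"):
            mb.make_model("healthy")

    def test_scaling_vector_order_and_range(self):
        for name in ("baseline", "afib", "fibrotic"):
            v = mb.make_model(name).scaling_vector()
            assert v.shape == (5,)
            assert np.all((0 < v) & (v <= 1))


class TestMetrics:
    def test_trapezoid_pulse_apd_matches_analytic_crossing(self):
        # up in 1 ms, plateau 100 ms, down in 10 ms, level 0.9
        t = np.arange(0, 200.0, 0.05)
        v = np.full_like(t, -80.0)
        up = (t >= 5) & (t < 6)
        v[up] = -80 + 120 * (t[up] - 5)
        v[(t >= 6) & (t < 106)] = 40.0
        dn = (t >= 106) & (t < 116)
        v[dn] = 40 - 12 * (t[dn] - 106)
        m = mb.measure_ap_metrics(t, v, repol_level=0.9)
        # crossing of 40 - 0.9*120 = -68 happens 9 ms into the downstroke
        # (t = 115); the upstroke instant is t = 5
        assert m.apd == pytest.approx(110.0, abs=0.15)
        assert m.v_peak == pytest.approx(40.0)

    def test_exponential_repolarization_closed_form(self):
        tau = 50.0
        t = np.arange(0, 600.0, 0.01)
        v = -80.0 + 120.0 * np.exp(-t / tau)
        v[0] = -80.0   # instantaneous upstroke at t=0
        m = mb.measure_ap_metrics(t, v, repol_level=0.9)
        assert m.apd == pytest.approx(tau * np.log(1 / 0.1), rel=1e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(tau=hst.floats(10.0, 200.0), level=hst.floats(0.2, 0.95))
    def test_exponential_apd_closed_form_property(self, tau, level):
        """APD of an exponential repolarization equals tau*ln(1/(1-level))
        for any decay constant and repolarization level."""
        t = np.arange(0, 15 * tau, tau / 2000.0)
        v = -80.0 + 120.0 * np.exp(-t / tau)
        v[0] = -80.0
        m = mb.measure_ap_metrics(t, v, repol_level=level)
        # allow one sampling step of bias on top of interpolation error
        assert m.apd == pytest.approx(tau * np.log(1 / (1 - level)),
                                      rel=2e-3, abs=2 * tau / 2000.0)

    def test_unrepolarized_trace_raises(self):
        t = np.arange(0, 100.0, 0.05)
        v = np.where(t < 1, -80 + 100 * t, 20.0)
        with pytest.raises(ValueError, match="unrepolarized"):
            mb.measure_ap_metrics(t, v)

    def test_bad_repol_level_rejected(self):
        with pytest.raises(ValueError):
            mb.measure_ap_metrics(np.arange(4.0), np.zeros(4), repol_level=1.5)


class TestPacing:
    def test_zero_max_beats_rejected(self):
        with pytest.raises(ValueError):
            mb.pace_to_limit_cycle(mb.make_model("afib"), max_beats=0)

    def test_negative_bcl_rejected(self):
        with pytest.raises(ValueError):
            mb.pace_to_limit_cycle(mb.make_model("afib"), bcl=-1.0)

    def test_baseline_converges_and_matches_rk4_oracle(self):
        """Production Rush-Larsen integrator vs classical RK4 at fine dt."""
        model = mb.make_model("baseline")
        state, (t, v), info = mb.pace_to_limit_cycle(model, bcl=500.0)
        assert info["converged"]
        assert info["beats"] <= 200
        # integrate one further beat from the converged state with both
        # schemes: production RL at its default step vs RK4 at dt = 2 us
        t_rk, v_rk = mb.trace_final_beat_rk4(
            model, state.y.copy(), dt=0.002, stim_amp=info["stim_amp"])
        m_rk = mb.measure_ap_metrics(t_rk, v_rk, stim_amp=info["stim_amp"],
                                     stim_dur=2.0)
        y1 = state.y.copy()
        v_rl = mb._run_cell(y1, 0.005, int(500 / 0.005), np.array([0.0]),
                            2.0, info["stim_amp"],
                            model.scaling_vector(), 1)
        m_rl = mb.measure_ap_metrics(0.005 * np.arange(v_rl.size), v_rl,
                                     stim_amp=info["stim_amp"], stim_dur=2.0)
        assert abs(m_rl.apd - m_rk.apd) < 0.5
        assert m_rl.dvdt_max == pytest.approx(m_rk.dvdt_max, rel=0.05)

    def test_fibrotic_rest_more_depolarized_than_afib(self, limit_cycles):
        vr_f = limit_cycles["fibrotic"]["info"]["metrics"].v_rest
        vr_a = limit_cycles["afib"]["info"]["metrics"].v_rest
        assert vr_f > vr_a + 3.0

    def test_limit_cycle_beats_monotone_in_tol(self):
        model = mb.make_model("afib")
        beats = []
        for tol in (1.0, 0.1, 0.01):
            _, _, info = mb.pace_to_limit_cycle(model, tol=tol)
            beats.append(info["beats"])
        assert beats[0] <= beats[1] <= beats[2]


class TestTables:
    def test_table_kernel_matches_direct_kernel(self):
        """The dt-locked lookup-table path reproduces the direct-rate path."""
        from fibrosim import tissue as ts

        mesh = ts.sheet_mesh(2.0, 2.0, 0.4)
        tm = ts.TissueModel(mesh, solver=ts.SolverConfig(dt=0.025))
        S = tm.initial_states(paced=False)
        stim = ts.StimulusTrain(site=0, pulse_onsets=np.array([5.0]),
                                pulse_duration=2.0, amplitude=40.0,
                                nodes=np.arange(mesh.n_nodes))
        res = tm.run(S, [stim], duration=400.0)
        v_tab = res.vm[:, 0]
        y = mb.equilibrate(mb.make_model("afib"))
        v_dir = mb._run_cell(y, 0.025, int(400 / 0.025), np.array([5.0]),
                             2.0, 40.0, mb.make_model("afib").scaling_vector(),
                             40)
        t = res.times
        td = 0.025 * 40 * np.arange(v_dir.size)
        vi = np.interp(t, td, v_dir)
        # uniform stimulation of a uniform sheet = isolated cell behavior
        m_tab = mb.measure_ap_metrics(t, v_tab, stim_amp=0.0)
        m_dir = mb.measure_ap_metrics(t, vi, stim_amp=0.0)
        assert abs(m_tab.apd - m_dir.apd) < 2.0
        assert m_tab.v_rest == pytest.approx(m_dir.v_rest, abs=1.0)

    def test_gate_rate_formulas_are_singularity_free(self):
        # removable singularities of the published rate formulas must be
        # finite and continuous (the h/j branch switch at -40 mV is a real,
        # tiny discontinuity of the published model and is excluded)
        inf = np.empty(mb.N_GATE)
        tau = np.empty(mb.N_GATE)
        for v in (-47.13, -14.1, 3.3328, 19.9, -10.0, 7.9):
            mb.gate_rates(v, inf, tau)
            assert np.all(np.isfinite(inf)) and np.all(np.isfinite(tau))
            assert np.all(tau > 0)
            mb.gate_rates(v + 1e-7, inf, tau)
            inf2 = inf.copy()
            mb.gate_rates(v - 1e-7, inf, tau)
            assert np.allclose(inf, inf2, atol=1e-5)
        mb.gate_rates(-40.0, inf, tau)
        assert np.all(np.isfinite(inf)) and np.all(tau > 0)
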