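"""Rapid-pacing protocol and arrhythmia-outcome classification."""

import numpy as np
import pytest

from fibrosim import induction as ind
from fibrosim import membrane as mb
from fibrosim import tissue as ts


class TestPacingTrain:
    def test_interval_sequence(self):
        train = ind.build_pacing_train(np.array([0]), amplitude=60.0)
        intervals = np.diff(train.pulse_onsets)
        assert list(intervals) == [300, 280, 260, 240, 220,
                                   200, 200, 200, 200, 200, 200]

    def test_twelve_pulses_last_at_2500(self):
        train = ind.build_pacing_train(np.array([0]), amplitude=60.0)
        assert len(train.pulse_onsets) == 12
        assert train.pulse_onsets[0] == 0.0
        assert train.pulse_onsets[-1] == 2500.0

    def test_onsets_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ts.StimulusTrain(site=0, pulse_onsets=np.array([0.0, 0.0]),
                             pulse_duration=2.0, amplitude=1.0,
                             nodes=np.array([0]))


@pytest.fixture(scope="module")
def small_model():
    """Reduced-scale healthy sheet shared by the outcome tests."""
    mesh = ts.sheet_mesh(12.0, 12.0, 0.4)
    cond = ts.ConductivityConfig(
        sigma_l_healthy=0.409 / 9, sigma_t_healthy=0.0820 / 2.25,
        sigma_l_fibrotic=0.177 / 9, sigma_t_fibrotic=0.0221 / 2.25)
    tm = ts.TissueModel(mesh, cond=cond,
                        solver=ts.SolverConfig(dt=0.05))
    states = tm.initial_states()
    return tm, states


class TestOutcomes:
    def site(self, tm):
        c = np.array([1.5, 6.0, 0.0])
        return np.nonzero(np.linalg.norm(tm.mesh.pts - c, axis=1) <= 1.2)[0]

    def test_zero_amplitude_not_inducible(self, small_model):
        tm, states = small_model
        cfg = ind.InductionConfig(observe_ms=300.0, amplitude=0.0,
                                  quiet_ms=200.0)
        rec = ind.run_induction(tm, states, 0, self.site(tm), cfg)
        assert rec.outcome == "none"
        assert rec.sustained_ms == 0.0

    def test_homogeneous_sheet_waves_extinguish(self, small_model):
        """Planar waves from the train die out with no fibrotic substrate."""
        tm, states = small_model
        cfg = ind.InductionConfig(observe_ms=800.0, amplitude=60.0,
                                  quiet_ms=400.0)
        rec = ind.run_induction(tm, states, 0, self.site(tm), cfg)
        assert rec.outcome == "none"
        assert rec.rd_events == []

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="bad outcome"):
            ind.InducibilityRecord(model_id="x", site_id=0,
                                   outcome="spiral", sustained_ms=0.0)


class TestClassification:
    def test_spiral_classified_rd_on_simply_connected_sheet(self):
        """A rotor phase movie on a hole-free sheet must classify as RD."""
        mesh = ts.sheet_mesh(10.0, 10.0, 0.5)
        times = np.arange(0.0, 1000.0, 10.0)
        x, y = mesh.pts[:, 0], mesh.pts[:, 1]
        th = np.arctan2(y - 5, x - 5)
        r = np.hypot(x - 5, y - 5)
        vm = -70 + 35 * np.sin(th[None, :] - r[None, :]
                               - 2 * np.pi * times[:, None] / 150.0)
        res = ts.SimulationResult(
            times=times, vm=vm,
            activation_times=np.zeros(mesh.n_nodes),
            act_count=np.ones(mesh.n_nodes, np.int64) * 6,
            final_states=np.zeros((mesh.n_nodes, 21)),
            last_activation=float(times[-1]))
        outcome, events, ambiguous = ind.classify_arrhythmia(
            res, mesh, t_start=0.0)
        assert outcome == "rd"
        assert len(events) >= 1

    def test_wave_circulating_annulus_is_macroscopic_reentry(self):
        """Winding activation around a hole with no free-wall singularity."""
        mesh = annulus_mesh()
        times = np.arange(0.0, 1000.0, 10.0)
        x, y = mesh.pts[:, 0], mesh.pts[:, 1]
        th = np.arctan2(y, x)
        vm = -70 + 35 * np.sin(th[None, :]
                               - 2 * np.pi * times[:, None] / 180.0)
        res = ts.SimulationResult(
            times=times, vm=vm,
            activation_times=np.zeros(mesh.n_nodes),
            act_count=np.ones(mesh.n_nodes, np.int64) * 5,
            final_states=np.zeros((mesh.n_nodes, 21)),
            last_activation=float(times[-1]))
        outcome, events, ambiguous = ind.classify_arrhythmia(
            res, mesh, t_start=0.0)
        assert outcome == "macroscopic_reentry"
        assert events == []

    def test_annulus_winding_oracle(self):
        """Loop winding of the circulating wave is exactly +-1."""
        from fibrosim import rd

        mesh = annulus_mesh()
        th = np.arctan2(mesh.pts[:, 1], mesh.pts[:, 0])
        phase = np.angle(np.exp(1j * th))
        loops = mesh.boundary_loops()
        assert len(loops) == 2
        for loop in loops:
            assert abs(rd.loop_winding(phase, loop)) == 1

    def test_extinguished_activity_is_none(self, small_model):
        tm, states = small_model
        cfg = ind.InductionConfig(observe_ms=600.0, amplitude=60.0,
                                  quiet_ms=300.0)
        c = np.array([1.5, 6.0, 0.0])
        nodes = np.nonzero(np.linalg.norm(tm.mesh.pts - c, axis=1)
                           <= 1.2)[0]
        rec = ind.run_induction(tm, states, 0, nodes, cfg)
        assert rec.outcome == "none"


def annulus_mesh(r_in=3.0, r_out=6.0, n_th=48, n_r=7):
    """Ring geometry fixture: two boundary loops, one hole."""
    ths = np.linspace(0, 2 * np.pi, n_th, endpoint=False)
    rs = np.linspace(r_in, r_out, n_r)
    pts = np.array([[r * np.cos(t), r * np.sin(t), 0.0]
                    for r in rs for t in ths])
    tris = []
    for i in range(n_r - 1):
        for j in range(n_th):
            a = i * n_th + j
            b = i * n_th + (j + 1) % n_th
            c = (i + 1) * n_th + j
            d = (i + 1) * n_th + (j + 1) % n_th
            tris.append([a, b, c])
            tris.append([b, d, c])
    tris = np.array(tris)
    m = len(tris)
    return ts.BilayerMesh(
        pts=pts, tris=tris,
        fibers=np.tile([1.0, 0.0, 0.0], (m, 1)),
        fibrotic=np.zeros(m, bool), region=np.zeros(m, np.int16),
        layer=np.zeros(m, np.int8), meta={"geometry": "annulus"})


class TestAmplitudeMonotonicity:
    def test_substrate_inducible_at_amp_stays_inducible_at_2amp(self):
        """Capture, not charge, limits induction at these amplitudes."""
        from fibrosim import substrate as sub

        spec = sub.SubstrateSpec(geometry="sheet", dimensions=(20.0, 20.0),
                                 resolution_um=400.0, fibrosis_burden=0.13,
                                 correlation_mm=2.5, patchiness=0.0, seed=7)
        outcomes = {}
        for amp in (60.0, 120.0):
            mesh = sub.generate_substrate(spec)
            cond = ts.ConductivityConfig(
                sigma_l_healthy=0.409 / 9, sigma_t_healthy=0.0820 / 2.25,
                sigma_l_fibrotic=0.177 / 9, sigma_t_fibrotic=0.0221 / 2.25)
            tm = ts.TissueModel(mesh, cond=cond,
                                solver=ts.SolverConfig(dt=0.05))
            S = tm.initial_states()
            c = np.array([2.0, 10.0, 0.0])
            nodes = np.nonzero(np.linalg.norm(mesh.pts - c, axis=1)
                               <= 1.2)[0]
            cfg = ind.InductionConfig(observe_ms=1200.0, amplitude=amp,
                                      quiet_ms=400.0)
            outcomes[amp] = ind.run_induction(tm, S, 0, nodes, cfg).outcome
        assert outcomes[60.0] == "rd"
        assert outcomes[120.0] == "rd"


class TestTissueThreshold:
    def test_threshold_bisection_brackets_capture(self):
        mesh = ts.sheet_mesh(6.0, 6.0, 0.4)
        tm = ts.TissueModel(mesh, cond=ts.ConductivityConfig(scale=1 / 9),
                            solver=ts.SolverConfig(dt=0.05))
        states = tm.initial_states()
        c = np.array([1.0, 3.0, 0.0])
        nodes = np.nonzero(np.linalg.norm(mesh.pts - c, axis=1) <= 1.0)[0]
        thr = ind.find_tissue_threshold(tm, states, nodes)
        assert 1.0 < thr < 80.0
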