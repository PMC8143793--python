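"""Clinical rapid-pacing arrhythmia induction and outcome classification.

The protocol delivers 12 stimuli from a pacing site: two pulses separated by
a 300 ms coupling interval, then intervals ramping down by 20 ms to 200 ms,
the remaining intervals staying at 200 ms until the train totals 12 pulses
(interval sequence 300, 280, 260, 240, 220, 200 x6).  After the final
stimulus the tissue is observed; if self-sustaining activation persists for
the configured window the episode is classified as a reentrant driver (at
least one persistent phase singularity on the free wall) or as macroscopic
reentry (activation circulating a non-conductive obstacle — a boundary loop
such as the mitral rim or a PV ostium — with no free-wall singularity).
Macroscopic reentry is excluded from driver statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rd
from .tissue import BilayerMesh, StimulusTrain, TissueModel

#: inter-pulse intervals of the standard 12-stimulus train (ms)
TRAIN_INTERVALS = (300.0, 280.0, 260.0, 240.0, 220.0,
                   200.0, 200.0, 200.0, 200.0, 200.0, 200.0)


@dataclass(frozen=True)
class InductionConfig:
    """Protocol and classification settings.

    ``observe_ms`` is the post-pacing window activity must survive to count
    as sustained (5000 ms at full scale; reduced-scale runs shorten it).
    ``quiet_ms``: no upstroke anywhere for this long = extinguished.
    """

    observe_ms: float = 5000.0
    quiet_ms: float = 500.0
    pulse_ms: float = 2.0
    amplitude: float | None = None       # pA/pF; None = 2x tissue threshold
    frame_ms: float = 10.0               # Vm recording stride
    min_ps_lifespan_ms: float = 100.0    # about one rotation
    link_radius_mm: float = 2.0


def build_pacing_train(site_nodes: np.ndarray, amplitude: float,
                       site_id: int = 0, t0: float = 0.0,
                       pulse_ms: float = 2.0) -> StimulusTrain:
    """The standard 12-pulse ramp train starting at ``t0``."""
    onsets = t0 + np.concatenate([[0.0], np.cumsum(TRAIN_INTERVALS)])
    return StimulusTrain(site=site_id, pulse_onsets=onsets,
                         pulse_duration=pulse_ms, amplitude=amplitude,
                         nodes=np.asarray(site_nodes))


def find_tissue_threshold(model: TissueModel, states: np.ndarray,
                          site_nodes: np.ndarray, pulse_ms: float = 2.0,
                          t_test: float = 30.0) -> float:
    """Tissue capture threshold (pA/pF) by bisection of a single pulse.

    Capture = at least one node outside the stimulated set activates.
    Determined once per substrate (at the first pacing site) and reused.
    """
    outside = np.setdiff1d(np.arange(model.mesh.n_nodes), site_nodes)

    def fires(amp):
        s = states.copy()
        st = StimulusTrain(site=-1, pulse_onsets=np.array([1.0]),
                           pulse_duration=pulse_ms, amplitude=amp,
                           nodes=site_nodes)
        res = model.run(s, [st], duration=t_test)
        return bool((res.activation_times[outside] >= 0).any())

    lo, hi = 0.0, 40.0
    while not fires(hi):
        hi *= 2.0
        if hi > 2560.0:
            raise RuntimeError("tissue does not capture at any amplitude")
    for _ in range(6):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class InducibilityRecord:
    """Outcome of one (model, pacing site) induction attempt."""

    model_id: str
    site_id: int
    outcome: str                      # none | rd | macroscopic_reentry
    sustained_ms: float
    rd_events: list = field(default_factory=list)
    n_unique_rds: int = 0
    ambiguous: bool = False
    invalid: bool = False

    def __post_init__(self):
        if self.outcome not in ("none", "rd", "macroscopic_reentry"):
            raise ValueError(f"bad outcome {self.outcome!r}")


def run_induction(model: TissueModel, states0: np.ndarray, site_id: int,
                  site_nodes: np.ndarray, config: InductionConfig,
                  amplitude: float | None = None,
                  model_id: str = "model") -> InducibilityRecord:
    """Deliver the pacing train and classify what the tissue does next."""
    amp = amplitude if amplitude is not None else config.amplitude
    if amp is None:
        amp = 2.0 * find_tissue_threshold(model, states0, site_nodes,
                                          config.pulse_ms)
    states = states0.copy()
    train = build_pacing_train(site_nodes, amp, site_id,
                               pulse_ms=config.pulse_ms)
    t_train_end = float(train.pulse_onsets[-1] + config.pulse_ms)
    duration = t_train_end + config.observe_ms
    old_out = model.solver
    model.solver = _with_output(model.solver, config.frame_ms, duration)
    try:
        res = model.run(states, [train], duration=duration,
                        stop_if_quiet=config.quiet_ms)
    finally:
        model.solver = old_out
    if res.diverged:
        return InducibilityRecord(model_id=model_id, site_id=site_id,
                                  outcome="none", sustained_ms=0.0,
                                  invalid=True)
    sustained = max(0.0, res.last_activation - t_train_end)
    # activity counts as sustained when it was still alive inside the final
    # quiet window (the run then cannot have been stopped for quiescence)
    alive_to_end = res.last_activation > duration - config.quiet_ms
    if amp == 0.0 or not alive_to_end:
        return InducibilityRecord(model_id=model_id, site_id=site_id,
                                  outcome="none", sustained_ms=sustained)
    outcome, events, ambiguous = classify_arrhythmia(
        res, model.mesh, t_start=t_train_end, config=config)
    n_unique = rd.count_unique_morphologies(events) if events else 0
    return InducibilityRecord(model_id=model_id, site_id=site_id,
                              outcome=outcome, sustained_ms=sustained,
                              rd_events=events, n_unique_rds=n_unique,
                              ambiguous=ambiguous)


def _with_output(solver, frame_ms, duration):
    from dataclasses import replace
    return replace(solver, output_every=frame_ms, duration=duration)


def classify_arrhythmia(result, mesh: BilayerMesh, t_start: float,
                        config: InductionConfig = InductionConfig()):
    """Distinguish reentrant drivers from macroscopic (obstacle) reentry.

    Returns ``(outcome, rd_events, ambiguous)``.  A persistent free-wall
    phase singularity means a reentrant driver; a nonzero phase winding
    around a boundary loop with no free-wall singularity means macroscopic
    reentry.  If both are present the driver takes precedence and the
    ambiguity is flagged.
    """
    sel = result.times >= t_start
    if sel.sum() < 8:
        return "none", [], False
    times = result.times[sel]
    vm = result.vm[sel]
    phase = rd.compute_phase(times, vm)
    events = rd.detect_phase_singularities(
        phase, mesh, times, link_radius_mm=config.link_radius_mm,
        min_lifespan_ms=config.min_ps_lifespan_ms)
    loops = mesh.boundary_loops()
    mid_frames = range(len(times) // 2, len(times), max(1, len(times) // 8))
    macro = False
    for loop in loops:
        w = [rd.loop_winding(phase[f], loop) for f in mid_frames]
        if w and np.median(np.abs(w)) >= 1:
            macro = True
            break
    if events and macro:
        return "rd", events, True
    if events:
        return "rd", events, False
    if macro:
        return "macroscopic_reentry", [], False
    # sustained activity with neither signature: no organizing driver found
    return "macroscopic_reentry", [], True
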