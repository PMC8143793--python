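"""Phase-based reentrant-driver (rotor) detection and region-wise scoring.

Activation phase is obtained from the analytic signal (Hilbert transform) of
the sliding-mean-removed transmembrane voltage.  Phase singularities — points
where the phase winds by +-2pi around an element — are detected per frame by
summing wrapped phase differences around each triangle, linked over time
into trajectories, and reported as reentrant-driver events with chirality,
lifespan, mean position and anatomical region.  A brute-force winding-number
oracle (independent scalar implementation) backs the detector in tests.

The region-wise inducibility score IdS of a cohort is the number of
(model, pacing site) pairs whose rapid-pacing outcome was a reentrant
driver, grouped by the *site's* region, divided by the number of pacing
sites in that region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .tissue import BilayerMesh

QUIESCENT_PTP_MV = 5.0     # below this peak-to-peak swing a node has no phase


def compute_phase(times: np.ndarray, vm: np.ndarray,
                  window_ms: float = 500.0) -> np.ndarray:
    """Per-node activation phase in (-pi, pi] from the analytic signal.

    ``vm`` is (frames, nodes).  The sliding-window mean (default 500 ms) is
    removed before the Hilbert transform so slow baseline drift does not
    masquerade as rotation.  Quiescent nodes (peak-to-peak < 5 mV) are NaN.
    """
    vm = np.asarray(vm, float)
    if vm.ndim != 2 or vm.shape[0] < 8:
        raise ValueError("vm must be (frames, nodes) with >= 8 frames")
    dt = float(np.median(np.diff(times)))
    win = max(3, int(round(window_ms / dt)))
    base = uniform_filter1d(vm, size=win, axis=0, mode="nearest")
    x = vm - base
    phase = np.angle(hilbert(x, axis=0))
    quiet = (vm.max(axis=0) - vm.min(axis=0)) < QUIESCENT_PTP_MV
    phase[:, quiet] = np.nan
    return phase


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * a))


def element_charges(phase_frame: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Topological charge (+-1, else 0) of every element in one frame."""
    p0 = phase_frame[tris[:, 0]]
    p1 = phase_frame[tris[:, 1]]
    p2 = phase_frame[tris[:, 2]]
    w = _wrap(p1 - p0) + _wrap(p2 - p1) + _wrap(p0 - p2)
    charge = np.zeros(len(tris), np.int8)
    ok = ~(np.isnan(p0) | np.isnan(p1) | np.isnan(p2))
    charge[ok & (w > np.pi)] = 1
    charge[ok & (w < -np.pi)] = -1
    return charge


def winding_number_oracle(phase_frame: np.ndarray, tris: np.ndarray,
                          elem: int) -> int:
    """Scalar re-derivation of one element's charge (test oracle)."""
    idx = [int(tris[elem, k]) for k in (0, 1, 2)]
    vals = [phase_frame[i] for i in idx]
    if any(math.isnan(v) for v in vals):
        return 0
    total = 0.0
    for a, b in ((0, 1), (1, 2), (2, 0)):
        d = vals[b] - vals[a]
        # wrap into [-pi, pi]; exact +-pi stays put, matching the
        # analytic-signal convention of the production detector
        while d > math.pi:
            d -= 2.0 * math.pi
        while d < -math.pi:
            d += 2.0 * math.pi
        total += d
    return int(round(total / (2.0 * math.pi)))


@dataclass
class RDEvent:
    """One phase-singularity trajectory (a reentrant-driver candidate)."""

    times: np.ndarray                  # ms
    positions: np.ndarray              # (k, 3) mm
    chirality: int                     # +-1, constant along the trajectory
    region: int = 0
    morphology_id: int = -1

    @property
    def lifespan(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def detect_phase_singularities(phase: np.ndarray, mesh: BilayerMesh,
                               times: np.ndarray,
                               link_radius_mm: float = 2.0,
                               min_lifespan_ms: float = 100.0
                               ) -> list[RDEvent]:
    """Track phase singularities through time into RDEvent trajectories.

    Per frame, elements with winding +-2pi are singular; singular points are
    linked frame-to-frame by nearest neighbor within ``link_radius_mm``
    (scaled by the frame gap), and trajectories shorter than
    ``min_lifespan_ms`` (about one rotation) are discarded.
    """
    cen = mesh.centroids()
    open_tracks: list[dict] = []
    done: list[dict] = []
    for fi, t in enumerate(times):
        ch = element_charges(phase[fi], mesh.tris)
        idx = np.nonzero(ch)[0]
        pos = cen[idx]
        sgn = ch[idx]
        used = np.zeros(idx.size, bool)
        still_open = []
        for tr in open_tracks:
            if idx.size:
                d = np.linalg.norm(pos - tr["pos"][-1], axis=1)
                d[used | (sgn != tr["chir"])] = np.inf
                j = int(np.argmin(d))
                gap = max(1, fi - tr["last_frame"])
                if d[j] <= link_radius_mm * gap:
                    tr["pos"].append(pos[j])
                    tr["t"].append(t)
                    tr["last_frame"] = fi
                    used[j] = True
                    still_open.append(tr)
                    continue
            if fi - tr["last_frame"] > 2:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        for j in np.nonzero(~used)[0]:
            open_tracks.append({"pos": [pos[j]], "t": [t],
                                "chir": int(sgn[j]), "last_frame": fi})
    done.extend(open_tracks)
    events = []
    for tr in done:
        ts = np.array(tr["t"])
        if ts[-1] - ts[0] < min_lifespan_ms:
            continue
        events.append(RDEvent(times=ts, positions=np.array(tr["pos"]),
                              chirality=tr["chir"]))
    for ev in events:
        ev.region = _region_at(mesh, ev.mean_position)
    return events


def _region_at(mesh: BilayerMesh, point: np.ndarray) -> int:
    cen = mesh.centroids()
    return int(mesh.region[np.argmin(np.linalg.norm(cen - point, axis=1))])


def count_unique_morphologies(events: list[RDEvent],
                              merge_radius_mm: float = 10.0) -> int:
    """Single-linkage clustering of trajectory mean positions.

    Two drivers closer than ``merge_radius_mm`` are the same morphology;
    the count is the number of clusters.  Assigns ``morphology_id``s.
    """
    n = len(events)
    if n == 0:
        return 0
    pos = np.array([ev.mean_position for ev in events])
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) <= merge_radius_mm:
                parent[find(i)] = find(j)
    roots = {}
    for i, ev in enumerate(events):
        r = find(i)
        ev.morphology_id = roots.setdefault(r, len(roots))
    return len(roots)


def loop_winding(phase_frame: np.ndarray, loop_nodes: np.ndarray) -> int:
    """Net phase winding of one boundary loop (macroscopic-reentry test)."""
    vals = phase_frame[loop_nodes]
    if np.any(np.isnan(vals)):
        return 0
    d = _wrap(np.diff(np.concatenate([vals, vals[:1]])))
    return int(round(d.sum() / (2.0 * np.pi)))


# ---------------------------------------------------------------------------
# Region-wise inducibility score
# ---------------------------------------------------------------------------

@dataclass
class IdSTable:
    """Per-region inducibility scores for one cohort."""

    cohort: str
    numerator: dict = field(default_factory=dict)   # region -> RD count
    sites_per_region: dict = field(default_factory=dict)

    @property
    def ids(self) -> dict:
        return {r: self.numerator.get(r, 0) / c
                for r, c in self.sites_per_region.items() if c > 0}


def compute_ids(records, site_regions: dict, cohort: str = "") -> IdSTable:
    """IdS = RD inductions from a region's sites / sites in the region.

    ``records`` need attributes ``site_id`` and ``outcome``; macroscopic
    reentry and non-inducible outcomes do not count toward the numerator.
    """
    spr: dict = {}
    for s, r in site_regions.items():
        spr[r] = spr.get(r, 0) + 1
    num: dict = {}
    for rec in records:
        if rec.site_id not in site_regions:
            raise ValueError(f"pacing site {rec.site_id} has no region")
        if rec.outcome == "rd":
            r = site_regions[rec.site_id]
            num[r] = num.get(r, 0) + 1
    return IdSTable(cohort=cohort, numerator=num, sites_per_region=spr)
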