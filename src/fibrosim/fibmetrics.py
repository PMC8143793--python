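"""Fibrosis spatial-pattern metrics and the pro-RD classification.

Local fibrosis density (FD) is the area-weighted fibrotic fraction within a
geodesic neighborhood of each element; local fibrosis entropy (FE) is the
binary entropy of the fraction of discordant edge-adjacent element pairs in
that neighborhood (so FE measures boundary-zone interdigitation and is not a
deterministic function of FD).  Elements whose (FD, FE) fall on the positive
side of the published SVM-derived polynomial

    0.4096 FD^2 + 3.28 FD FE - 0.1036 FE^2 - 0.7112 FD - FE + 0.0429 > 0

(and with FD > 0.01, guarding the positive offset at zero density) are
flagged pro-RD.  The module also implements the quiescent resting-voltage
analysis: the cohort-pooled 95th percentile of equilibrium V_m defines the
abnormal-depolarization threshold, and each model reports the fraction of
its tissue above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .tissue import BilayerMesh


@dataclass
class FibrosisMetricsMap:
    """Per-element FD, FE and pro-RD flags."""

    fd: np.ndarray
    fe: np.ndarray
    pro_rd: np.ndarray
    radius_mm: float


def _neighborhoods(mesh: BilayerMesh, radius_mm: float):
    """Element index lists within geodesic (adjacency-graph) radius."""
    adj = mesh.element_adjacency().astype(float)
    cen = mesh.centroids()
    i, j = adj.nonzero()
    w = np.linalg.norm(cen[i] - cen[j], axis=1)
    g = sp.csr_matrix((w, (i, j)), shape=adj.shape)
    dist = dijkstra(g, directed=False, limit=radius_mm)
    return [np.nonzero(np.isfinite(dist[k]))[0] for k in range(len(cen))]


def _check_radius(mesh: BilayerMesh, radius_mm: float) -> None:
    h = float(np.sqrt(np.median(mesh.element_areas()) * 2.0))
    if radius_mm < 2.0 * h:
        raise ValueError(
            f"neighborhood radius {radius_mm} mm too small for mean edge "
            f"length {h:.3f} mm (need >= 2x)")


def local_density(mesh: BilayerMesh, labels: np.ndarray,
                  radius_mm: float = 2.5) -> np.ndarray:
    """FD: area-weighted fibrotic fraction within the geodesic radius."""
    _check_radius(mesh, radius_mm)
    areas = mesh.element_areas()
    fd = np.empty(mesh.n_elems)
    for k, nb in enumerate(_neighborhoods(mesh, radius_mm)):
        a = areas[nb]
        fd[k] = float(a[labels[nb]].sum() / a.sum())
    return fd


def local_entropy(mesh: BilayerMesh, labels: np.ndarray,
                  radius_mm: float = 2.5) -> np.ndarray:
    """FE: binary entropy of discordant adjacent-pair fraction."""
    _check_radius(mesh, radius_mm)
    adj = mesh.element_adjacency()
    i, j = adj.nonzero()
    keep = i < j
    pi, pj = i[keep], j[keep]
    discord = labels[pi] != labels[pj]
    fe = np.empty(mesh.n_elems)
    for k, nb in enumerate(_neighborhoods(mesh, radius_mm)):
        inside = np.zeros(mesh.n_elems, bool)
        inside[nb] = True
        sel = inside[pi] & inside[pj]
        n = int(sel.sum())
        if n == 0:
            fe[k] = 0.0
            continue
        q = float(discord[sel].sum()) / n
        fe[k] = _binary_entropy(q)
    return fe


def _binary_entropy(q: float) -> float:
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return float(-q * np.log2(q) - (1.0 - q) * np.log2(1.0 - q))


#: published classification polynomial coefficients
PRO_RD_COEFFS = dict(fd2=0.4096, fdfe=3.28, fe2=-0.1036,
                     fd=-0.7112, fe=-1.0, const=0.0429)
FD_GUARD = 0.01


def pro_rd_value(fd, fe):
    """The decision polynomial, evaluated exactly as printed."""
    return (0.4096 * fd ** 2 + 3.28 * fd * fe - 0.1036 * fe ** 2
            - 0.7112 * fd - fe + 0.0429)


def classify_pro_rd(fd, fe):
    """Pro-RD flag: positive polynomial value and FD above the guard."""
    fd = np.asarray(fd, float)
    fe = np.asarray(fe, float)
    if np.any((fd < 0) | (fd > 1) | (fe < 0) | (fe > 1)):
        raise ValueError("FD and FE must lie in [0, 1]")
    return (pro_rd_value(fd, fe) > 0.0) & (fd > FD_GUARD)


def compute_metrics(mesh: BilayerMesh, radius_mm: float = 2.5
                    ) -> FibrosisMetricsMap:
    fd = local_density(mesh, mesh.fibrotic, radius_mm)
    fe = local_entropy(mesh, mesh.fibrotic, radius_mm)
    return FibrosisMetricsMap(fd=fd, fe=fe,
                              pro_rd=classify_pro_rd(fd, fe),
                              radius_mm=radius_mm)


def region_pro_rd_burden(mesh: BilayerMesh, metrics: FibrosisMetricsMap
                         ) -> dict:
    """Area-weighted fraction of pro-RD tissue per region."""
    areas = mesh.element_areas()
    out = {}
    for r in np.unique(mesh.region):
        sel = mesh.region == r
        out[int(r)] = float(areas[sel & metrics.pro_rd].sum()
                            / areas[sel].sum())
    return out


# ---------------------------------------------------------------------------
# Quiescent resting-voltage (pro-trigger surrogate) analysis
# ---------------------------------------------------------------------------

@dataclass
class DepolarizationSummary:
    """Cohort-pooled threshold and per-model depolarized fractions."""

    threshold_mv: float
    fractions: dict                  # model id -> fraction of nodes above
    excluded: list                   # models still oscillating at the end


def quiescent_vm_analysis(final_vms: dict, percentile: float = 95.0,
                          still_active: dict | None = None
                          ) -> DepolarizationSummary:
    """Pooled-percentile threshold and per-model depolarized fraction.

    ``final_vms`` maps model id -> per-node equilibrium V_m after a
    stimulus-free settling run.  Models flagged in ``still_active`` are
    excluded from the pool and reported.  The percentile uses the linear
    interpolation convention; the fraction counts nodes strictly above.
    """
    still_active = still_active or {}
    excluded = [k for k, v in still_active.items() if v]
    keep = {k: np.asarray(v, float) for k, v in final_vms.items()
            if k not in excluded}
    if not keep:
        raise ValueError("no quiescent models to analyze")
    pooled = np.concatenate(list(keep.values()))
    thr = float(np.percentile(pooled, percentile))
    fracs = {k: float((v > thr).mean()) for k, v in keep.items()}
    return DepolarizationSummary(threshold_mv=thr, fractions=fracs,
                                 excluded=excluded)
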