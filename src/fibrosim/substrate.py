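"""Synthetic fibrotic substrates standing in for patient LGE-MRI meshes.

Patient-derived atrial geometries are not publicly available, so the virtual
cohort runs on synthetic surrogates that emulate the features the analysis
actually consumes:

* geometry — either a flat ``sheet`` or an ``la_surrogate``: an ellipsoidal
  shell with four pulmonary-vein ostia, an appendage bulge with an open tip,
  and a mitral rim, bilayer-constructed with a 100 um offset;
* fibrosis — a binary per-element pattern from a thresholded, graph-smoothed
  random field with controllable global burden, correlation length and
  patchiness (the cohort's density/entropy control knobs);
* regions — the five-region partition (floor, posterior, anterior+LAA, left
  and right PV areas, the PV areas grown to 15% of total surface each);
* pacing sites — 15 trigger-site surrogates (anterior/posterior aspects of
  each PV ostium, LAA base, mitral annulus, posterior wall, plus four
  distributed wall sites);
* fibers — rule-based unit vectors: circumferential around ostia and the
  mitral rim blending into oblique wall directions (uniform on sheets).

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .tissue import BilayerMesh, build_bilayer, check_manifold, sheet_mesh

REGION_FLOOR, REGION_POST, REGION_ANT, REGION_LPV, REGION_RPV = 1, 2, 3, 4, 5

# surrogate anatomical anchors, (longitude deg, colatitude deg from north)
_OSTIA = {
    "lspv": (125.0, 42.0),
    "lipv": (125.0, 78.0),
    "rspv": (235.0, 42.0),
    "ripv": (235.0, 78.0),
}
_OSTIUM_RADIUS_DEG = 11.0
_LAA_CENTER = (60.0, 55.0)
_LAA_RADIUS_DEG = 16.0
_LAA_TIP_RADIUS_DEG = 5.0


@dataclass(frozen=True)
class SubstrateSpec:
    """Everything needed to regenerate a substrate deterministically."""

    geometry: str = "sheet"              # sheet | la_surrogate
    dimensions: tuple = (20.0, 20.0)     # sheet (w, h) mm; LA radii scale
    resolution_um: float = 400.0
    fibrosis_burden: float = 0.15        # target global fraction
    correlation_mm: float = 2.5          # texture correlation length
    patchiness: float = 0.3              # fine-scale noise admixture [0, 1)
    fiber_angle_deg: float = 0.0         # sheet base fiber direction
    endo_epi_twist_deg: float = 0.0      # epi fiber rotation (bilayer)
    bilayer: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fibrosis_burden <= 1.0):
            raise ValueError("fibrosis_burden must be in [0, 1]")
        if self.geometry not in ("sheet", "la_surrogate"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.resolution_um <= 0:
            raise ValueError("resolution must be positive")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ellipsoid_point(lon, colat, radii):
    sl, cl = np.sin(lon), np.cos(lon)
    sc, cc = np.sin(colat), np.cos(colat)
    a, b, c = radii
    return np.stack([a * sc * cl, b * sc * sl, c * cc], axis=-1)


def _angdist_deg(lon1, colat1, lon2, colat2):
    """Great-circle distance in degrees on the parameter sphere."""
    l1, c1 = np.deg2rad(lon1), np.deg2rad(colat1)
    l2, c2 = np.deg2rad(lon2), np.deg2rad(colat2)
    cosd = (np.cos(c1) * np.cos(c2)
            + np.sin(c1) * np.sin(c2) * np.cos(l1 - l2))
    return np.rad2deg(np.arccos(np.clip(cosd, -1.0, 1.0)))


def la_surrogate_surface(spec: SubstrateSpec) -> BilayerMesh:
    """Single-layer LA-like ellipsoidal shell with ostia holes and LAA bulge.

    The shell spans colatitudes [0, 150 deg]; the open bottom edge is the
    mitral rim.  Triangles inside the four PV caps and the LAA tip cap are
    removed, leaving six boundary loops in total.
    """
    scale = spec.dimensions[0] / 20.0 if spec.dimensions else 1.0
    radii = (30.0 * scale, 25.0 * scale, 28.0 * scale)
    h = spec.resolution_um * 1e-3
    mean_r = float(np.mean(radii))
    n_colat = max(12, int(round(np.deg2rad(150.0) * mean_r / h)))
    n_lon = max(16, int(round(2.0 * np.pi * mean_r * 0.8 / h)))

    colat = np.linspace(150.0 / n_colat, 150.0, n_colat)   # skip pole row 0
    lon = np.linspace(0.0, 360.0, n_lon, endpoint=False)
    LON, COL = np.meshgrid(lon, colat, indexing="ij")
    lon_f, col_f = LON.ravel(), COL.ravel()

    # LAA bulge: radial displacement around the LAA center
    d_laa = _angdist_deg(lon_f, col_f, *_LAA_CENTER)
    bump = 1.0 + 0.25 * np.exp(-(d_laa / _LAA_RADIUS_DEG) ** 2)

    pts_grid = _ellipsoid_point(np.deg2rad(lon_f), np.deg2rad(col_f), radii)
    pts_grid *= bump[:, None]
    pole = np.array([[0.0, 0.0, radii[2]]])
    pts = np.vstack([pole, pts_grid])

    def gid(i, j):   # i: lon index, j: colat index
        return 1 + (i % n_lon) * n_colat + j

    tris = []
    for i in range(n_lon):
        tris.append((0, gid(i, 0), gid(i + 1, 0)))     # pole fan
        for j in range(n_colat - 1):
            a, b = gid(i, j), gid(i + 1, j)
            c, d = gid(i, j + 1), gid(i + 1, j + 1)
            tris.append((a, c, b))
            tris.append((b, c, d))
    tris = np.array(tris)

    # remove PV caps and the LAA tip
    cen = pts[tris].mean(axis=1)
    cen_n = cen / np.linalg.norm(cen / np.array(radii), axis=1)[:, None]
    clon = np.rad2deg(np.arctan2(cen_n[:, 1] / radii[1],
                                 cen_n[:, 0] / radii[0])) % 360.0
    ccol = np.rad2deg(np.arccos(np.clip(
        cen_n[:, 2] / radii[2] / np.linalg.norm(
            cen_n / np.array(radii), axis=1), -1, 1)))
    keep = np.ones(len(tris), bool)
    hole_centers = list(_OSTIA.values()) + [_LAA_CENTER]
    hole_radii = [_OSTIUM_RADIUS_DEG] * 4 + [_LAA_TIP_RADIUS_DEG]
    for (hl, hc), hr in zip(hole_centers, hole_radii):
        keep &= _angdist_deg(clon, ccol, hl, hc) > hr
    tris = tris[keep]

    used = np.unique(tris)
    remap = -np.ones(len(pts), int)
    remap[used] = np.arange(len(used))
    tris = remap[tris]
    pts = pts[used]

    fibers = np.tile([1.0, 0.0, 0.0], (len(tris), 1))
    mesh = BilayerMesh(
        pts=pts, tris=tris, fibers=fibers,
        fibrotic=np.zeros(len(tris), bool),
        region=np.zeros(len(tris), np.int16),
        layer=np.zeros(len(tris), np.int8),
        meta={"geometry": "la_surrogate", "radii": radii,
              "resolution_um": spec.resolution_um,
              "lonlat": (clon[keep], ccol[keep])})
    check_manifold(mesh)
    return mesh


def _surface_lonlat(mesh: BilayerMesh, n_elems: int | None = None):
    """Element-centroid surrogate coordinates (longitude, colatitude)."""
    radii = np.array(mesh.meta["radii"])
    cen = mesh.centroids() if n_elems is None else \
        mesh.centroids()[:n_elems]
    q = cen / radii
    lon = np.rad2deg(np.arctan2(q[:, 1], q[:, 0])) % 360.0
    colat = np.rad2deg(np.arccos(np.clip(
        q[:, 2] / np.linalg.norm(q, axis=1), -1, 1)))
    return lon, colat


def generate_geometry(spec: SubstrateSpec) -> BilayerMesh:
    """Build the requested surface, bilayer-constructed when asked."""
    if spec.geometry == "sheet":
        w, hgt = spec.dimensions
        mesh = sheet_mesh(w, hgt, spec.resolution_um * 1e-3,
                          spec.fiber_angle_deg)
    else:
        mesh = la_surrogate_surface(spec)
        # the smallest feature (LAA tip hole) must span at least one edge
        min_feature_mm = np.deg2rad(_LAA_TIP_RADIUS_DEG) * 30.0
        if spec.resolution_um * 1e-3 > min_feature_mm:
            raise ValueError("resolution too coarse for the PV/LAA features")
        generate_fibers(mesh, spec)
    if spec.bilayer:
        mesh = build_bilayer(mesh)
        if spec.endo_epi_twist_deg:
            _twist_epi_fibers(mesh, spec.endo_epi_twist_deg)
    mesh.meta["spec"] = spec
    return mesh


def _twist_epi_fibers(mesh: BilayerMesh, angle_deg: float) -> None:
    """Rotate epicardial fibers about the element normal."""
    epi = np.nonzero(mesh.layer == 1)[0]
    p = mesh.pts
    t = mesh.tris[epi]
    nrm = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
    nrm /= np.linalg.norm(nrm, axis=1)[:, None]
    f = mesh.fibers[epi]
    th = np.deg2rad(angle_deg)
    mesh.fibers[epi] = (f * np.cos(th)
                        + np.cross(nrm, f) * np.sin(th)
                        + nrm * (nrm * f).sum(1)[:, None] * (1 - np.cos(th)))


# ---------------------------------------------------------------------------
# Fibrosis patterns
# ---------------------------------------------------------------------------

def generate_fibrosis(mesh: BilayerMesh, spec: SubstrateSpec) -> np.ndarray:
    """Binary per-element fibrosis labels at the requested global burden.

    White noise per element is smoothed by graph diffusion on the element
    adjacency (iteration count set by the correlation length), optionally
    remixed with a fraction of fine-scale noise ("patchiness"), then
    thresholded at the area-weighted quantile that yields the target burden.
    Both layers of a bilayer mesh share one pattern.
    """
    m = mesh.n_elems
    endo = np.nonzero(mesh.layer == 0)[0]
    m0 = endo.size
    if m0 < 1:
        raise ValueError("mesh has no elements")
    target = spec.fibrosis_burden
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(m0)
    adj = mesh.element_adjacency()[endo][:, endo]
    deg = np.asarray(adj.sum(axis=1)).ravel()
    h = float(np.sqrt(np.median(mesh.element_areas()[endo]) * 2.0))
    n_iter = int(np.clip((spec.correlation_mm / max(h, 1e-6)) ** 2, 0, 400))
    for _ in range(n_iter):
        x = (x + adj @ x) / (1.0 + deg)
    if x.std() > 0:
        x = (x - x.mean()) / x.std()
    if spec.patchiness > 0:
        x = (1.0 - spec.patchiness) * x \
            + spec.patchiness * rng.standard_normal(m0)

    areas = mesh.element_areas()[endo]
    order = np.argsort(-x, kind="stable")     # most fibrosis-prone first
    csum = np.cumsum(areas[order])
    total = csum[-1]
    k = int(np.searchsorted(csum, target * total))
    labels0 = np.zeros(m0, bool)
    labels0[order[:min(k + (1 if target > 0 and k == 0 else 0), m0)]] = True
    if target >= 1.0:
        labels0[:] = True
    if target <= 0.0:
        labels0[:] = False

    labels = np.zeros(m, bool)
    labels[endo] = labels0
    if (mesh.layer == 1).any():
        labels[mesh.layer == 1] = labels0   # mirrored element order
    mesh.fibrotic = labels
    mesh.meta["achieved_burden"] = float(
        areas[labels0].sum() / areas.sum())
    mesh.meta["fibrosis_seed"] = spec.seed
    return labels


# ---------------------------------------------------------------------------
# Regions and pacing sites
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Per-element region ids and per-region areas (cm^2)."""

    region: np.ndarray
    areas_cm2: dict = field(default_factory=dict)


def assign_regions(mesh: BilayerMesh) -> RegionPartition:
    """Five-region LA partition; a sheet maps to the single region 0.

    PV regions are grown from the ostia rims until each holds 15% of the
    total surface; the remainder splits into floor / posterior / anterior
    (+LAA) by surrogate-coordinate cutoffs.
    """
    geom = mesh.meta.get("geometry")
    areas = mesh.element_areas()
    if geom == "sheet":
        mesh.region[:] = 0
        return RegionPartition(
            region=mesh.region,
            areas_cm2={0: float(areas.sum()) * 1e-2})
    if geom != "la_surrogate":
        raise ValueError("region partition requires a labeled geometry")

    endo = np.nonzero(mesh.layer == 0)[0]
    lon, colat = _surface_lonlat(mesh, None)
    lon, colat = lon[endo], colat[endo]
    a_endo = areas[endo]
    total = a_endo.sum()
    region = np.zeros(endo.size, np.int16)

    adj = mesh.element_adjacency()[endo][:, endo]
    cen = mesh.centroids()[endo]
    for rid, pair in ((REGION_LPV, ("lspv", "lipv")),
                      (REGION_RPV, ("rspv", "ripv"))):
        seeds = []
        for name in pair:
            hl, hc = _OSTIA[name]
            d = _angdist_deg(lon, colat, hl, hc)
            seeds.extend(np.argsort(d)[:8])       # rim elements
        grown = _region_grow(adj, cen, a_endo, np.array(seeds),
                             0.15 * total, region == 0)
        region[grown] = rid

    free = region == 0
    is_floor = colat > 120.0
    is_ant = (lon < 100.0) | (lon > 300.0)
    region[free & is_floor] = REGION_FLOOR
    region[free & ~is_floor & is_ant] = REGION_ANT
    region[free & ~is_floor & ~is_ant] = REGION_POST

    full = np.zeros(mesh.n_elems, np.int16)
    full[endo] = region
    if (mesh.layer == 1).any():
        full[mesh.layer == 1] = region
    mesh.region = full
    areas_cm2 = {int(r): float(areas[full == r].sum()) * 1e-2
                 for r in np.unique(full)}
    return RegionPartition(region=full, areas_cm2=areas_cm2)


def _region_grow(adj: sp.csr_matrix, centroids: np.ndarray,
                 areas: np.ndarray, seeds: np.ndarray,
                 target_area: float, allowed: np.ndarray) -> np.ndarray:
    """Geodesic accretion from seeds until the area target is met.

    Elements join in order of graph (geodesic centroid-to-centroid)
    distance from the seed set, which keeps the grown region compact and
    connected; deterministic.
    """
    import heapq

    m = areas.size
    dist = np.full(m, np.inf)
    heap = []
    for s in np.unique(seeds):
        if allowed[s]:
            dist[s] = 0.0
            heapq.heappush(heap, (0.0, int(s)))
    inside = np.zeros(m, bool)
    acc = 0.0
    visited = np.zeros(m, bool)
    while heap and acc < target_area:
        d, e = heapq.heappop(heap)
        if visited[e]:
            continue
        visited[e] = True
        inside[e] = True
        acc += areas[e]
        for k in range(adj.indptr[e], adj.indptr[e + 1]):
            nb = adj.indices[k]
            if visited[nb] or not allowed[nb]:
                continue
            nd = d + float(np.linalg.norm(centroids[e] - centroids[nb]))
            if nd < dist[nb]:
                dist[nb] = nd
                heapq.heappush(heap, (nd, int(nb)))
    return np.nonzero(inside)[0]


@dataclass(frozen=True)
class PacingSite:
    """A labeled stimulation node set."""

    site_id: int
    name: str
    nodes: np.ndarray
    center: np.ndarray


def place_pacing_sites(mesh: BilayerMesh,
                       radius_mm: float = 1.0) -> list[PacingSite]:
    """The 15 trigger-site surrogates on an la_surrogate mesh.

    Anterior/posterior aspects of each PV ostium (8), LAA base, mitral
    annulus, posterior wall, and four additional distributed wall sites.
    Each site is the set of nodes within ``radius_mm`` of its anchor.
    """
    if mesh.meta.get("geometry") != "la_surrogate":
        raise ValueError("pacing sites are defined on la_surrogate meshes")
    if not np.any(mesh.region > 0):
        raise ValueError("region partition must be assigned first")

    anchors = []
    for name, (hl, hc) in _OSTIA.items():
        anchors.append((f"{name}_ant", (hl - _OSTIUM_RADIUS_DEG - 3.0, hc)))
        anchors.append((f"{name}_post", (hl + _OSTIUM_RADIUS_DEG + 3.0, hc)))
    anchors += [
        ("laa_base", (_LAA_CENTER[0],
                      _LAA_CENTER[1] + _LAA_RADIUS_DEG + 2.0)),
        ("mitral_annulus", (0.0, 140.0)),
        ("posterior_wall", (180.0, 85.0)),
        ("posterior_left", (168.0, 110.0)),
        ("posterior_right", (192.0, 110.0)),
        ("anterior_wall", (20.0, 60.0)),
        ("anterior_roof", (330.0, 35.0)),
    ]
    radii = np.array(mesh.meta["radii"])
    endo_n = mesh.n_nodes // 2 if (mesh.layer == 1).any() else mesh.n_nodes
    sites = []
    taken = np.zeros(mesh.n_nodes, bool)
    for sid, (name, (al, ac)) in enumerate(anchors):
        p = _ellipsoid_point(np.deg2rad(al), np.deg2rad(ac), radii)
        d = np.linalg.norm(mesh.pts - p, axis=1)
        nodes = np.nonzero((d <= max(radius_mm, d[:endo_n].min() + 1e-9))
                           & ~taken)[0]
        if nodes.size == 0:
            nodes = np.array([int(np.argmin(d))])
        taken[nodes] = True
        sites.append(PacingSite(site_id=sid, name=name, nodes=nodes,
                                center=p))
    assert len(sites) == 15
    return sites


# ---------------------------------------------------------------------------
# Fibers
# ---------------------------------------------------------------------------

def generate_fibers(mesh: BilayerMesh, spec: SubstrateSpec) -> np.ndarray:
    """Rule-based smooth unit fiber field.

    Sheets: uniform direction at ``fiber_angle_deg``.  LA surrogate:
    circumferential (constant-colatitude) flow re-oriented to circulate
    around each PV ostium and the mitral rim, blended by inverse-square
    angular distance, projected into each element plane and normalized.
    """
    if mesh.meta.get("geometry") == "sheet":
        th = np.deg2rad(spec.fiber_angle_deg)
        mesh.fibers[:] = [np.cos(th), np.sin(th), 0.0]
        return mesh.fibers

    p = mesh.pts
    t = mesh.tris
    cen = mesh.centroids()
    nrm = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
    nrm /= np.linalg.norm(nrm, axis=1)[:, None]

    zhat = np.array([0.0, 0.0, 1.0])
    base = np.cross(zhat, cen)            # circumferential
    base /= np.maximum(np.linalg.norm(base, axis=1)[:, None], 1e-12)

    lon, colat = _surface_lonlat(mesh)
    radii = np.array(mesh.meta["radii"])
    vec = base * 1.0
    for hl, hc in list(_OSTIA.values()):
        c = _ellipsoid_point(np.deg2rad(hl), np.deg2rad(hc), radii)
        d = _angdist_deg(lon, colat, hl, hc)
        w = np.exp(-(d / (2.0 * _OSTIUM_RADIUS_DEG)) ** 2)
        circ = np.cross(c / np.linalg.norm(c), cen - c)
        circ /= np.maximum(np.linalg.norm(circ, axis=1)[:, None], 1e-12)
        sign = np.sign((circ * base).sum(1))[:, None]
        sign[sign == 0] = 1.0
        vec = (1 - w)[:, None] * vec + w[:, None] * circ * sign

    # project into element planes, normalize
    vec -= nrm * (vec * nrm).sum(1)[:, None]
    nv = np.linalg.norm(vec, axis=1)
    weak = nv < 1e-9
    if weak.any():                         # degenerate: fall back to an edge
        e = p[t[weak, 1]] - p[t[weak, 0]]
        vec[weak] = e / np.linalg.norm(e, axis=1)[:, None]
        nv = np.linalg.norm(vec, axis=1)
    mesh.fibers = vec / nv[:, None]
    return mesh.fibers


# ---------------------------------------------------------------------------
# One-call generator
# ---------------------------------------------------------------------------

def generate_substrate(spec: SubstrateSpec) -> BilayerMesh:
    """Geometry + fibers + fibrosis + regions in one deterministic call.

    Fibers are already set by :func:`generate_geometry` (including any
    endo/epi twist), so only labels and regions are added here.
    """
    mesh = generate_geometry(spec)
    generate_fibrosis(mesh, spec)
    assign_regions(mesh)
    return mesh
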