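"""Mesh, state and configuration I/O.

Meshes travel as CARP-style plain text: ``.pts`` (node count header, then
coordinates in um), ``.elem`` (count header, then ``Tr`` triangles with a
composite label tag, ``Ln`` lines for interlayer links) and ``.lon`` (one
fiber vector per element).  The composite element tag encodes
``fibrotic * 1000 + layer * 100 + region`` so a mesh round-trips through a
single tag column; a JSON sidecar carries generator metadata (seed, achieved
burden).  Legacy-ASCII VTK export is provided for visual audit, and full
membrane state snapshots go to HDF5.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .tissue import BilayerMesh

UM_PER_MM = 1000.0


def write_mesh(mesh: BilayerMesh, outdir, basename: str = "mesh") -> Path:
    """Write .pts/.elem/.lon plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = outdir / basename
    pts = mesh.pts * UM_PER_MM
    with open(f"{base}.pts", "w") as f:
        f.write(f"{len(pts)}\n")
        for p in pts:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    tags = (mesh.fibrotic.astype(int) * 1000 + mesh.layer.astype(int) * 100
            + mesh.region.astype(int))
    with open(f"{base}.elem", "w") as f:
        f.write(f"{mesh.n_elems + len(mesh.links)}\n")
        for t, tag in zip(mesh.tris, tags):
            f.write(f"Tr {t[0]} {t[1]} {t[2]} {tag}\n")
        for a, b in mesh.links:
            f.write(f"Ln {a} {b} 0\n")
    with open(f"{base}.lon", "w") as f:
        f.write("1\n")
        for v in mesh.fibers:
            f.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for _ in range(len(mesh.links)):
            f.write("0 0 0\n")
    meta = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in mesh.meta.items()
            if isinstance(v, (int, float, str, bool, list, tuple))}
    meta["format"] = "carp_text"
    with open(f"{base}.json", "w") as f:
        json.dump(meta, f, indent=1)
    return base


def _fail(path, lineno, msg):
    raise ValueError(f"{path}:{lineno}: {msg}")


def read_mesh(base) -> BilayerMesh:
    """Read a CARP-text mesh written by :func:`write_mesh`."""
    base = Path(str(base))
    pts_path = base.with_suffix(".pts")
    with open(pts_path) as f:
        try:
            n = int(f.readline().split()[0])
        except (ValueError, IndexError):
            _fail(pts_path, 1, "bad node-count header")
        pts = np.empty((n, 3))
        for i in range(n):
            parts = f.readline().split()
            if len(parts) != 3:
                _fail(pts_path, i + 2, "expected 3 coordinates")
            pts[i] = [float(x) for x in parts]
    pts /= UM_PER_MM

    elem_path = base.with_suffix(".elem")
    tris, tags, links = [], [], []
    with open(elem_path) as f:
        try:
            m = int(f.readline().split()[0])
        except (ValueError, IndexError):
            _fail(elem_path, 1, "bad element-count header")
        for i in range(m):
            parts = f.readline().split()
            if not parts:
                _fail(elem_path, i + 2, "truncated element list")
            kind = parts[0]
            if kind == "Tr":
                if len(parts) != 5:
                    _fail(elem_path, i + 2, "Tr needs 3 nodes + tag")
                tris.append([int(parts[1]), int(parts[2]), int(parts[3])])
                tags.append(int(parts[4]))
            elif kind == "Ln":
                links.append([int(parts[1]), int(parts[2])])
            else:
                _fail(elem_path, i + 2,
                      f"unsupported element type {kind!r} for surface "
                      "solvers")
    tris = np.array(tris, int)
    tags = np.array(tags, int)

    lon_path = base.with_suffix(".lon")
    with open(lon_path) as f:
        f.readline()
        vecs = []
        for i, line in enumerate(f):
            parts = line.split()
            if len(parts) != 3:
                _fail(lon_path, i + 2, "expected 3 components")
            vecs.append([float(x) for x in parts])
    n_total = len(tris) + len(links)
    if len(vecs) != n_total:
        _fail(lon_path, 1, f"fiber count {len(vecs)} != element count "
              f"{n_total}")
    fibers = np.array(vecs[:len(tris)])

    meta = {}
    sidecar = base.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return BilayerMesh(
        pts=pts, tris=tris, fibers=fibers,
        fibrotic=(tags // 1000) > 0,
        region=(tags % 100).astype(np.int16),
        layer=((tags // 100) % 10).astype(np.int8),
        links=np.array(links, int).reshape(-1, 2),
        meta=meta)


def write_vtk(mesh: BilayerMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> Path:
    """Legacy-ASCII VTK UNSTRUCTURED_GRID export (triangles only)."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("fibrosim surface\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.pts:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        m = mesh.n_elems
        f.write(f"CELLS {m} {4 * m}\n")
        for t in mesh.tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("5\n" * m)
        cell_data = {"region": mesh.region,
                     "fibrotic": mesh.fibrotic.astype(int),
                     **(cell_data or {})}
        f.write(f"CELL_DATA {m}\n")
        for name, arr in cell_data.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in np.asarray(arr, float):
                f.write(f"{v:.6g}\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, float):
                    f.write(f"{v:.6g}\n")
    return path


def read_vtk(path) -> BilayerMesh:
    """Read a legacy-ASCII VTK UNSTRUCTURED_GRID written by write_vtk."""
    lines = Path(path).read_text().splitlines()
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n = int(lines[i].split()[1])
    pts = np.array([[float(x) for x in lines[i + 1 + k].split()]
                    for k in range(n)])
    j = next(k for k, ln in enumerate(lines) if ln.startswith("CELLS"))
    m = int(lines[j].split()[1])
    tris = []
    for k in range(m):
        parts = lines[j + 1 + k].split()
        if parts[0] != "3":
            raise ValueError(f"{path}: only triangle cells are supported")
        tris.append([int(p) for p in parts[1:]])
    tris = np.array(tris, int)

    def cell_scalar(name):
        for k, ln in enumerate(lines):
            if ln.startswith(f"SCALARS {name} "):
                return np.array([float(v) for v in lines[k + 2:k + 2 + m]])
        return None

    region = cell_scalar("region")
    fib = cell_scalar("fibrotic")
    e01 = pts[tris[:, 1]] - pts[tris[:, 0]]
    fibers = e01 / np.linalg.norm(e01, axis=1)[:, None]
    return BilayerMesh(
        pts=pts, tris=tris, fibers=fibers,
        fibrotic=(fib > 0.5) if fib is not None
        else np.zeros(m, bool),
        region=region.astype(np.int16) if region is not None
        else np.zeros(m, np.int16),
        layer=np.zeros(m, np.int8), meta={"format": "vtk"})


def write_vtk_polylines(trajectories, path) -> Path:
    """Export trajectories (lists of (k, 3) positions) for visual audit."""
    path = Path(path)
    pts = [p for tr in trajectories for p in np.asarray(tr)]
    nl = "\n"
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0" + nl)
        f.write("fibrosim trajectories" + nl + "ASCII" + nl
                + "DATASET POLYDATA" + nl)
        f.write(f"POINTS {len(pts)} float" + nl)
        for p in pts:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" + nl)
        sizes = [len(np.asarray(tr)) for tr in trajectories]
        total = sum(s + 1 for s in sizes)
        f.write(f"LINES {len(sizes)} {total}" + nl)
        off = 0
        for sz in sizes:
            f.write(" ".join([str(sz)] + [str(off + k) for k in range(sz)])
                    + nl)
            off += sz
    return path


def save_states(path, states: np.ndarray, time_ms: float = 0.0,
                meta: dict | None = None) -> None:
    """Full membrane state snapshot to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("states", data=states)
        f.attrs["time_ms"] = time_ms
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_states(path) -> tuple[np.ndarray, float]:
    import h5py

    with h5py.File(path, "r") as f:
        return f["states"][...], float(f.attrs.get("time_ms", 0.0))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def load_config(path) -> dict:
    """YAML/JSON run configuration with field validation.

    Unknown or missing fields are reported by name; every random procedure
    must reference an explicit seed.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    out = {}
    from .cohort import CohortSpec
    from .induction import InductionConfig
    from .substrate import SubstrateSpec
    from .tissue import ConductivityConfig, SolverConfig

    sections = {"substrate": SubstrateSpec, "solver": SolverConfig,
                "conductivity": ConductivityConfig,
                "induction": InductionConfig, "cohort": CohortSpec}
    for key, val in raw.items():
        if key not in sections:
            raise ValueError(f"unknown config section {key!r}")
        cls = sections[key]
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(val) - names
        if bad:
            raise ValueError(
                f"unknown field(s) {sorted(bad)} in section {key!r}")
        if "dimensions" in val:
            val["dimensions"] = tuple(val["dimensions"])
        out[key] = cls(**val)
    return out


def dump_config(objs: dict, path) -> None:
    """Write the exact resolved configuration next to an output."""
    import yaml

    doc = {"schema_version": SCHEMA_VERSION}
    for key, obj in objs.items():
        d = dataclasses.asdict(obj)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
            elif isinstance(v, np.ndarray):
                d[k] = v.tolist()
        doc[key] = d
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
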