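"""Monodomain reaction-diffusion solver on triangulated atrial surfaces.

The tissue voltage obeys beta*C_m dV/dt = div(sigma grad V) - beta(I_ion -
I_stim).  Dividing through by beta*C_m turns the conductivity tensor into a
diffusivity tensor D = sigma / (beta C_m); we assemble a linear-finite-element
stiffness matrix with a per-element anisotropic D (longitudinal along the
fiber vector), lump the mass matrix, and advance with operator splitting:
a Rush-Larsen reaction step followed by explicit diffusion sub-steps (the
sub-step count is chosen from a Gershgorin bound so the diffusion update is
always stable, including through the stiff interlayer links of bilayer
meshes).

Units: mm, ms, mV; conductivities in S/m; C_m in uF/cm^2; beta in 1/um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from numba import njit

from . import membrane as mb

# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

REGION_NAMES = {0: "sheet", 1: "floor", 2: "posterior", 3: "anterior_laa",
                4: "lpv", 5: "rpv"}


@dataclass
class BilayerMesh:
    """Triangulated surface (optionally bilayer) with per-element labels.

    ``pts`` are node coordinates in mm.  For bilayer meshes the first half of
    the nodes is the endocardial shell, the second half the epicardial copy,
    and ``links`` pairs corresponding nodes across the 100 um gap.
    """

    pts: np.ndarray                    # (N, 3) mm
    tris: np.ndarray                   # (M, 3) int
    fibers: np.ndarray                 # (M, 3) unit vectors
    fibrotic: np.ndarray               # (M,) bool
    region: np.ndarray                 # (M,) int, see REGION_NAMES
    layer: np.ndarray                  # (M,) int8: 0 endo, 1 epi
    links: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.pts.shape[0]

    @property
    def n_elems(self) -> int:
        return self.tris.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.pts
        a, b, c = (p[self.tris[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def centroids(self) -> np.ndarray:
        return self.pts[self.tris].mean(axis=1)

    def node_areas(self) -> np.ndarray:
        """Lumped (one-third) nodal areas in mm^2."""
        areas = self.element_areas()
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.tris.ravel(),
                  np.repeat(areas / 3.0, 3))
        return out

    def edges(self) -> np.ndarray:
        e = np.vstack([self.tris[:, [0, 1]], self.tris[:, [1, 2]],
                       self.tris[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed node loops of boundary edges (holes and open rims)."""
        e = np.vstack([self.tris[:, [0, 1]], self.tris[:, [1, 2]],
                       self.tris[:, [2, 0]]])
        se = np.sort(e, axis=1)
        uniq, counts = np.unique(se, axis=0, return_counts=True)
        bed = uniq[counts == 1]
        nxt: dict[int, list[int]] = {}
        for a, b in bed:
            nxt.setdefault(int(a), []).append(int(b))
            nxt.setdefault(int(b), []).append(int(a))
        seen = set()
        loops = []
        for start in sorted(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nbrs = [n for n in nxt[cur] if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                if cur == start:
                    break
                loop.append(cur)
                seen.add(cur)
            if len(loop) >= 3:
                loops.append(np.array(loop))
        return loops

    def element_adjacency(self) -> sp.csr_matrix:
        """Element-to-element adjacency across shared edges (same layer)."""
        m = self.n_elems
        edge_map: dict[tuple, int] = {}
        rows, cols = [], []
        for ei in range(m):
            t = self.tris[ei]
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                key = (min(a, b), max(a, b))
                if key in edge_map:
                    ej = edge_map[key]
                    rows += [ei, ej]
                    cols += [ej, ei]
                else:
                    edge_map[key] = ei
        data = np.ones(len(rows), bool)
        return sp.csr_matrix((data, (rows, cols)), shape=(m, m))


def check_manifold(mesh: BilayerMesh) -> None:
    """Raise if an edge is shared by >2 triangles or orientation flips."""
    e = np.vstack([mesh.tris[:, [0, 1]], mesh.tris[:, [1, 2]],
                   mesh.tris[:, [2, 0]]])
    se = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(se, axis=0, return_inverse=True,
                                  return_counts=True)
    if counts.max(initial=0) > 2:
        raise ValueError("non-manifold surface: an edge is shared by more "
                         "than two triangles")
    # consistent orientation: a shared edge must appear once in each order
    order = e[:, 0] < e[:, 1]
    for k in np.nonzero(counts == 2)[0]:
        idx = np.nonzero(inv == k)[0]
        if order[idx[0]] == order[idx[1]]:
            raise ValueError("inconsistently oriented surface")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductivityConfig:
    """Monodomain conductivities (S/m).

    Healthy (AFib, non-fibrotic) tissue has a 5:1 anisotropy ratio;
    fibrotic tissue is slower with an exaggerated 8:1 ratio.  Interlayer
    links couple the two shells of a bilayer mesh.
    """

    sigma_l_healthy: float = 0.409
    sigma_t_healthy: float = 0.0820
    sigma_l_fibrotic: float = 0.177
    sigma_t_fibrotic: float = 0.0221
    sigma_interlayer: float = 0.8
    #: uniform scale on every conductivity; reduced-scale runs shrink the
    #: spatial wavelength by sqrt(scale) without touching membrane kinetics
    scale: float = 1.0

    def __post_init__(self):
        vals = (self.sigma_l_healthy, self.sigma_t_healthy,
                self.sigma_l_fibrotic, self.sigma_t_fibrotic,
                self.sigma_interlayer, self.scale)
        if any(v <= 0 for v in vals):
            raise ValueError("conductivities must be positive")
        if (self.sigma_l_healthy < self.sigma_t_healthy
                or self.sigma_l_fibrotic < self.sigma_t_fibrotic):
            raise ValueError("longitudinal conductivity must be >= "
                             "transverse within each tissue class")


@dataclass(frozen=True)
class SolverConfig:
    """Discretization and output control for the monodomain solver."""

    cm: float = 1.0            # uF/cm^2
    #: surface-to-volume ratio, 1/um.  Calibrated (not a measured constant)
    #: so that a planar wave in healthy tissue at 200 um resolution conducts
    #: at the effective longitudinal CV of 71.49 cm/s for sigma_L = 0.409
    #: S/m; the anisotropy ratio then fixes the transverse CV.
    beta: float = 0.198
    dt: float = 0.025          # ms, reaction step
    output_every: float = 1.0  # ms between recorded voltage frames
    duration: float = 100.0    # ms
    act_threshold: float = -10.0   # mV, upstroke crossing defines activation
    nernst_refresh: float = 1.0    # ms between Nernst-potential refreshes
    vm_bounds: tuple = (-120.0, 80.0)

    def __post_init__(self):
        if self.dt > 0.05:
            raise ValueError("dt must be <= 0.05 ms")
        if min(self.cm, self.beta, self.dt, self.output_every,
               self.duration) <= 0:
            raise ValueError("solver parameters must be positive")


def diffusivity(sigma_s_per_m: float, solver: SolverConfig) -> float:
    """Convert a conductivity (S/m) to a diffusivity in mm^2/ms."""
    beta_per_m = solver.beta * 1e6
    cm_f_per_m2 = solver.cm * 1e-2
    return sigma_s_per_m / (beta_per_m * cm_f_per_m2) * 1e3


@dataclass(frozen=True)
class StimulusTrain:
    """A train of rectangular current pulses delivered to a node set."""

    site: int
    pulse_onsets: np.ndarray      # ms
    pulse_duration: float         # ms
    amplitude: float              # pA/pF
    nodes: np.ndarray             # node indices

    def __post_init__(self):
        on = np.asarray(self.pulse_onsets, float)
        if on.size > 1 and not np.all(np.diff(on) > 0):
            raise ValueError("pulse onsets must be strictly increasing")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_diffusion(mesh: BilayerMesh, cond: ConductivityConfig,
                       solver: SolverConfig) -> tuple[sp.csr_matrix, float]:
    """Mass-lumped diffusion operator L (1/ms) with row sums ~ 0.

    Per-element tensor D = D_T I + (D_L - D_T) f f^T with f the unit fiber
    vector projected into the element plane; fibrotic elements use the
    fibrotic conductivity pair.  Interlayer links contribute a pairwise
    exchange D_link * A_node / offset^2 consistent with a 1D conductor of
    the node's lumped (Voronoi) cross-section.  Returns (L, gershgorin)
    where gershgorin bounds the operator's spectral radius for explicit
    stability control.
    """
    pts, tris = mesh.pts, mesh.tris
    n = mesh.n_nodes
    dl_h = diffusivity(cond.sigma_l_healthy * cond.scale, solver)
    dt_h = diffusivity(cond.sigma_t_healthy * cond.scale, solver)
    dl_f = diffusivity(cond.sigma_l_fibrotic * cond.scale, solver)
    dt_f = diffusivity(cond.sigma_t_fibrotic * cond.scale, solver)
    d_link = diffusivity(cond.sigma_interlayer * cond.scale, solver)

    p0 = pts[tris[:, 0]]
    e01 = pts[tris[:, 1]] - p0
    e02 = pts[tris[:, 2]] - p0
    nrm = np.cross(e01, e02)
    areas2 = np.linalg.norm(nrm, axis=1)          # 2*area
    bad = np.nonzero(areas2 < 1e-12)[0]
    if bad.size:
        raise ValueError(f"degenerate element {bad[0]}: zero area")
    fnorm = np.linalg.norm(mesh.fibers, axis=1)
    bad = np.nonzero(fnorm < 1e-9)[0]
    if bad.size:
        raise ValueError(f"element {bad[0]} has a zero-length fiber vector")

    # local orthonormal frame per element
    u1 = e01 / np.linalg.norm(e01, axis=1)[:, None]
    nhat = nrm / areas2[:, None]
    u2 = np.cross(nhat, u1)
    # 2D vertex coordinates
    x2 = np.einsum("ij,ij->i", e01, u1)
    x3 = np.einsum("ij,ij->i", e02, u1)
    y3 = np.einsum("ij,ij->i", e02, u2)
    area = 0.5 * areas2
    # fiber in local frame (projected, renormalized)
    f1 = np.einsum("ij,ij->i", mesh.fibers, u1)
    f2 = np.einsum("ij,ij->i", mesh.fibers, u2)
    fl = np.hypot(f1, f2)
    bad = np.nonzero(fl < 1e-9)[0]
    if bad.size:
        raise ValueError(f"element {bad[0]}: fiber is normal to the "
                         "element plane")
    f1, f2 = f1 / fl, f2 / fl

    dl = np.where(mesh.fibrotic, dl_f, dl_h)
    dtt = np.where(mesh.fibrotic, dt_f, dt_h)
    dxx = dtt + (dl - dtt) * f1 * f1
    dxy = (dl - dtt) * f1 * f2
    dyy = dtt + (dl - dtt) * f2 * f2

    # linear shape-function gradients; vertices (0,0), (x2,0), (x3,y3)
    inv2a = 1.0 / areas2
    gx = np.stack([-y3, y3, np.zeros_like(y3)], axis=1) * inv2a[:, None]
    gy = np.stack([x3 - x2, -x3, x2], axis=1) * inv2a[:, None]

    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    ke = np.empty((len(tris), 9))
    for i in range(3):
        for j in range(3):
            ke[:, 3 * i + j] = area * (
                gx[:, i] * (dxx * gx[:, j] + dxy * gy[:, j])
                + gy[:, i] * (dxy * gx[:, j] + dyy * gy[:, j]))
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    node_area = mesh.node_areas()
    if mesh.links.size:
        li, lj = mesh.links[:, 0], mesh.links[:, 1]
        ell = np.linalg.norm(pts[li] - pts[lj], axis=1)
        a_pair = 0.5 * (node_area[li] + node_area[lj])
        g = d_link * a_pair / ell ** 2
        lk = sp.coo_matrix(
            (np.concatenate([g, g, -g, -g]),
             (np.concatenate([li, lj, li, lj]),
              np.concatenate([li, lj, lj, li]))), shape=(n, n)).tocsr()
        K = K + lk

    minv = sp.diags(1.0 / np.maximum(node_area, 1e-30))
    L = (-(minv @ K)).tocsr()
    gersh = float(np.abs(L.diagonal()).max())
    return L, gersh


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _advance(S, variant, scal, Ld, Li, Lp, dt, n_sub, n_steps, t0,
             st_on, st_off, st_amp, st_ptr, st_idx,
             tab_inf, tab_rl, tab_fac, tab_rlv, erl_fca, erl_u,
             rec_every, rec_buf, rec_fill, act_thr,
             first_act, act_count, last_act,
             nernst_every, ena, ek, eca, istim):
    """Advance the coupled reaction-diffusion system ``n_steps`` steps.

    The reaction update is a fused, table-driven Rush-Larsen step of the
    atrial ionic model; it must stay formula-identical to
    ``membrane._currents_core`` (guarded by the table-vs-direct kernel
    equivalence test).  Returns (frames_recorded,
    global_last_activation_time, vmax, vmin).
    """
    n = S.shape[0]
    dt_sub = dt / n_sub
    n_rec = rec_fill
    glast = last_act
    vlo = 1e30
    vhi = -1e30
    vtmp = np.empty(n)
    nv = tab_inf.shape[0]
    for s in range(n_steps):
        t = t0 + s * dt
        if s % nernst_every == 0:
            mb.refresh_nernst(S, ena, ek, eca)
        # stimulus currents
        for i in range(istim.shape[0]):
            istim[i] = 0.0
        for q in range(st_on.shape[0]):
            if st_on[q] <= t < st_off[q]:
                for k in range(st_ptr[q], st_ptr[q + 1]):
                    istim[st_idx[k]] += st_amp[q]
        # reaction (fused Rush-Larsen step, one node at a time)
        for i in range(n):
            V = S[i, 0]
            vi = (V + 120.0) * 50.0 + 0.5
            if vi < 0.0:
                vi = 0.0
            k = int(vi)
            if k > nv - 1:
                k = nv - 1
            vb = variant[i]
            s0 = scal[vb, 0]
            s1 = scal[vb, 1]
            s2 = scal[vb, 2]
            s3 = scal[vb, 3]
            s4 = scal[vb, 4]
            f0 = tab_fac[k, 0]
            f1 = tab_fac[k, 1]
            f2 = tab_fac[k, 2]
            f3 = tab_fac[k, 3]
            f4 = tab_fac[k, 4]
            f5 = tab_fac[k, 5]
            m_ = S[i, 1]
            h_ = S[i, 2]
            j_ = S[i, 3]
            oa = S[i, 4]
            oi = S[i, 5]
            ua = S[i, 6]
            ui = S[i, 7]
            xr = S[i, 8]
            xs = S[i, 9]
            d_ = S[i, 10]
            fg = S[i, 11]
            fca = S[i, 12]
            u_ = S[i, 13]
            v_ = S[i, 14]
            w_ = S[i, 15]
            nai = S[i, 16]
            ki = S[i, 17]
            cai = S[i, 18]
            caup = S[i, 19]
            carel = S[i, 20]
            ena_i = ena[i]
            ek_i = ek[i]
            eca_i = eca[i]
            ina = mb.CM * mb.G_NA * s0 * m_ * m_ * m_ * h_ * j_ * (V - ena_i)
            ik1 = mb.CM * mb.G_K1 * s1 * f1 * (V - ek_i)
            ito = mb.CM * mb.G_TO * s2 * oa * oa * oa * oi * (V - ek_i)
            ikur = mb.CM * f0 * s3 * ua * ua * ua * ui * (V - ek_i)
            ikr = mb.CM * mb.G_KR * xr * f2 * (V - ek_i)
            iks = mb.CM * mb.G_KS * xs * xs * (V - ek_i)
            ical = mb.CM * mb.G_CAL * s4 * d_ * fg * fca * (V - 65.0)
            rn = mb.KM_NA_I / nai
            inak = (mb.CM * mb.I_NAK_MAX * f3 * (mb.K_O / (mb.K_O + mb.KM_K_O))
                    / (1.0 + rn * math.sqrt(rn)))
            inaca = (mb.CM * mb.I_NACA_MAX
                     * (f4 * nai * nai * nai * mb.CA_O
                        - f5 * mb.NA_O ** 3 * cai)
                     / ((mb.KM_NA ** 3 + mb.NA_O ** 3) * (mb.KM_CA + mb.CA_O)
                        * (1.0 + mb.K_SAT * f5)))
            ibna = mb.CM * mb.G_B_NA * (V - ena_i)
            ibca = mb.CM * mb.G_B_CA * (V - eca_i)
            ipca = mb.CM * mb.I_PCA_MAX * cai / (0.0005 + cai)
            irel = mb.K_REL * u_ * u_ * v_ * w_ * (carel - cai)
            itr = (caup - carel) / mb.TAU_TR
            iup = mb.I_UP_MAX / (1.0 + mb.K_UP / cai)
            iupleak = mb.I_UP_MAX * caup / mb.CA_UP_MAX
            fn = 1e3 * (1e-15 * mb.V_REL * irel
                        - 1e-15 / (2.0 * mb.F) * (0.5 * ical - 0.2 * inaca))
            arg = -(fn - 3.4175e-13) / 13.67e-16
            if arg > 45.0:
                u_inf = 0.0
            elif arg < -45.0:
                u_inf = 1.0
            else:
                u_inf = 1.0 / (1.0 + math.exp(arg))
            bv = arg - 200.0
            if bv > 45.0:
                v_inf = 1.0
            elif bv < -45.0:
                v_inf = 0.0
            else:
                v_inf = 1.0 - 1.0 / (1.0 + math.exp(bv))
            fca_inf = 1.0 / (1.0 + cai / 0.00035)
            S[i, 1] = tab_inf[k, 0] + (m_ - tab_inf[k, 0]) * tab_rl[k, 0]
            S[i, 2] = tab_inf[k, 1] + (h_ - tab_inf[k, 1]) * tab_rl[k, 1]
            S[i, 3] = tab_inf[k, 2] + (j_ - tab_inf[k, 2]) * tab_rl[k, 2]
            S[i, 4] = tab_inf[k, 3] + (oa - tab_inf[k, 3]) * tab_rl[k, 3]
            S[i, 5] = tab_inf[k, 4] + (oi - tab_inf[k, 4]) * tab_rl[k, 4]
            S[i, 6] = tab_inf[k, 5] + (ua - tab_inf[k, 5]) * tab_rl[k, 5]
            S[i, 7] = tab_inf[k, 6] + (ui - tab_inf[k, 6]) * tab_rl[k, 6]
            S[i, 8] = tab_inf[k, 7] + (xr - tab_inf[k, 7]) * tab_rl[k, 7]
            S[i, 9] = tab_inf[k, 8] + (xs - tab_inf[k, 8]) * tab_rl[k, 8]
            S[i, 10] = tab_inf[k, 9] + (d_ - tab_inf[k, 9]) * tab_rl[k, 9]
            S[i, 11] = tab_inf[k, 10] + (fg - tab_inf[k, 10]) * tab_rl[k, 10]
            S[i, 15] = tab_inf[k, 11] + (w_ - tab_inf[k, 11]) * tab_rl[k, 11]
            S[i, 12] = fca_inf + (fca - fca_inf) * erl_fca
            S[i, 13] = u_inf + (u_ - u_inf) * erl_u
            S[i, 14] = v_inf + (v_ - v_inf) * tab_rlv[
                int(u_inf * 1024.0 + 0.5)]
            S[i, 16] = nai + dt * ((-3.0 * inak - 3.0 * inaca - ibna - ina)
                                   / (mb.F * mb.V_I))
            S[i, 17] = ki + dt * ((2.0 * inak - ik1 - ito - ikur - ikr - iks)
                                  / (mb.F * mb.V_I))
            b1 = ((2.0 * inaca - ipca - ical - ibca)
                  / (2.0 * mb.F * mb.V_I)
                  + (mb.V_UP * (iupleak - iup) + irel * mb.V_REL) / mb.V_I)
            ct = cai + mb.KM_TRPN
            cd = cai + mb.KM_CMDN
            b2 = (1.0 + mb.TRPN_MAX * mb.KM_TRPN / (ct * ct)
                  + mb.CMDN_MAX * mb.KM_CMDN / (cd * cd))
            S[i, 18] = cai + dt * (b1 / b2)
            S[i, 19] = caup + dt * (iup - iupleak
                                    - itr * mb.V_REL / mb.V_UP)
            cr = carel + mb.KM_CSQN
            S[i, 20] = carel + dt * ((itr - irel)
                                     / (1.0 + mb.CSQN_MAX * mb.KM_CSQN
                                        / (cr * cr)))
            iion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak
                    + inaca + ibna + ibca + ipca) / mb.CM
            vnew = V + dt * (-iion + istim[i])
            S[i, 0] = vnew
            if V < act_thr and vnew >= act_thr:
                if first_act[i] < 0.0:
                    first_act[i] = t + dt
                act_count[i] += 1
                glast = t + dt
        # diffusion (explicit, sub-stepped)
        for _ in range(n_sub):
            for i in range(n):
                acc = 0.0
                for k in range(Lp[i], Lp[i + 1]):
                    acc += Ld[k] * S[Li[k], 0]
                vtmp[i] = S[i, 0] + dt_sub * acc
            for i in range(n):
                vprev = S[i, 0]
                S[i, 0] = vtmp[i]
                if vprev < act_thr and vtmp[i] >= act_thr:
                    if first_act[i] < 0.0:
                        first_act[i] = t + dt
                    act_count[i] += 1
                    glast = t + dt
        # record
        if (s + 1) % rec_every == 0 and n_rec < rec_buf.shape[0]:
            for i in range(n):
                v = S[i, 0]
                rec_buf[n_rec, i] = v
                if v > vhi:
                    vhi = v
                if v < vlo:
                    vlo = v
            n_rec += 1
    return n_rec, glast, vhi, vlo


@dataclass
class SimulationResult:
    """Voltage frames, activation bookkeeping and final membrane states."""

    times: np.ndarray            # ms, recorded frame times
    vm: np.ndarray               # (frames, nodes) mV
    activation_times: np.ndarray  # first crossing of threshold, -1 if none
    act_count: np.ndarray        # upstrokes per node
    final_states: np.ndarray     # (nodes, 21)
    last_activation: float       # ms, most recent upstroke anywhere
    diverged: bool = False


class TissueModel:
    """A mesh + membrane assignment + assembled operator, ready to run."""

    def __init__(self, mesh: BilayerMesh,
                 cond: ConductivityConfig | None = None,
                 solver: SolverConfig | None = None,
                 healthy_variant: str = "afib",
                 fibrotic_variant: str = "fibrotic"):
        self.mesh = mesh
        self.cond = cond or ConductivityConfig()
        self.solver = solver or SolverConfig()
        self.healthy_variant = healthy_variant
        self.fibrotic_variant = fibrotic_variant
        self.L, self.gersh = assemble_diffusion(mesh, self.cond, self.solver)
        # per-node variant: fibrotic if any adjacent element is fibrotic
        n = mesh.n_nodes
        node_fib = np.zeros(n, bool)
        node_fib[np.unique(mesh.tris[mesh.fibrotic])] = True
        self.node_fibrotic = node_fib
        self.variant = node_fib.astype(np.int64)   # 0 healthy, 1 fibrotic
        self.scal = np.vstack([
            mb.make_model(healthy_variant).scaling_vector(),
            mb.make_model(fibrotic_variant).scaling_vector()])
        self._tables = None

    def initial_states(self, paced: bool = True,
                       bcl: float = 500.0) -> np.ndarray:
        """Per-node state vectors from the variants' limit cycles.

        With ``paced=False`` the variants' quiescent equilibria are used.
        """
        if paced:
            ya = mb.limit_cycle_state(self.healthy_variant, bcl=bcl)
            yf = mb.limit_cycle_state(self.fibrotic_variant, bcl=bcl)
        else:
            ya = mb.equilibrate(mb.make_model(self.healthy_variant))
            yf = mb.equilibrate(mb.make_model(self.fibrotic_variant))
        S = np.where(self.variant[:, None] == 1, yf[None, :], ya[None, :])
        return np.ascontiguousarray(S)

    def run(self, states: np.ndarray, stimuli: list[StimulusTrain],
            duration: float | None = None,
            stop_if_quiet: float | None = None,
            chunk_ms: float = 50.0) -> SimulationResult:
        """Advance the tissue, optionally stopping once activity dies out.

        ``stop_if_quiet``: end early when no node has had an upstroke for
        this many ms (activity extinguished).  The state array is updated
        in place.  Deterministic for identical inputs.
        """
        sol = self.solver
        duration = sol.duration if duration is None else duration
        dt = sol.dt
        if self._tables is None or self._tables[0] != dt:
            ti, tr, tf, trlv = mb.build_tables(dt)
            self._tables = (dt, ti, tr, tf, trlv,
                            float(np.exp(-dt / 2.0)),
                            float(np.exp(-dt / 8.0)))
        _, ti, tr, tf, trlv, erl_fca, erl_u = self._tables
        n_sub = max(1, int(np.ceil(dt * self.gersh / 1.6)))
        dt_sub = dt / n_sub

        st_on, st_off, st_amp, st_ptr, st_idx = _pack_stimuli(stimuli)
        n = states.shape[0]
        rec_every = max(1, int(round(sol.output_every / dt)))
        n_steps_total = int(round(duration / dt))
        n_frames = n_steps_total // rec_every + 1
        rec_buf = np.empty((n_frames, n))
        ena = np.empty(n)
        ek = np.empty(n)
        eca = np.empty(n)
        istim = np.zeros(n)
        first_act = np.full(n, -1.0)
        act_count = np.zeros(n, np.int64)
        nernst_every = max(1, int(round(sol.nernst_refresh / dt)))

        chunk_steps = max(1, int(round(chunk_ms / dt)))
        done = 0
        n_rec = 0
        glast = -1.0
        diverged = False
        while done < n_steps_total:
            todo = min(chunk_steps, n_steps_total - done)
            n_rec, glast, vhi, vlo = _advance(
                states, self.variant, self.scal,
                self.L.data, self.L.indices, self.L.indptr,
                dt, n_sub, todo, done * dt,
                st_on, st_off, st_amp, st_ptr, st_idx,
                ti, tr, tf, trlv, erl_fca, erl_u,
                rec_every, rec_buf, n_rec, sol.act_threshold,
                first_act, act_count, glast,
                nernst_every, ena, ek, eca, istim)
            done += todo
            t_now = done * dt
            if not (sol.vm_bounds[0] < states[:, 0].min()
                    and states[:, 0].max() < sol.vm_bounds[1]):
                diverged = True
                break
            if (stop_if_quiet is not None
                    and t_now > st_off.max(initial=0.0)
                    and t_now - max(glast, st_off.max(initial=0.0))
                    >= stop_if_quiet):
                break
        times = dt * rec_every * (1 + np.arange(n_rec))
        return SimulationResult(
            times=times, vm=rec_buf[:n_rec],
            activation_times=first_act, act_count=act_count,
            final_states=states, last_activation=glast, diverged=diverged)


def _pack_stimuli(stimuli: list[StimulusTrain]):
    """Flatten stimulus trains into pulse windows + a CSR node table."""
    on, off, amp, ptr, idx = [], [], [], [0], []
    for st in stimuli:
        for o in np.asarray(st.pulse_onsets, float):
            on.append(o)
            off.append(o + st.pulse_duration)
            amp.append(st.amplitude)
            idx.extend(int(i) for i in st.nodes)
            ptr.append(len(idx))
    return (np.array(on, float), np.array(off, float),
            np.array(amp, float), np.array(ptr, np.int64),
            np.array(idx, np.int64))


# ---------------------------------------------------------------------------
# Geometry builders and measurements
# ---------------------------------------------------------------------------

def sheet_mesh(width_mm: float, height_mm: float, h_mm: float,
               fiber_angle_deg: float = 0.0) -> BilayerMesh:
    """Regular triangulated sheet in the z=0 plane, single layer."""
    nx = int(round(width_mm / h_mm)) + 1
    ny = int(round(height_mm / h_mm)) + 1
    xs = np.linspace(0, width_mm, nx)
    ys = np.linspace(0, height_mm, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            tris.append((a, b, a + 1))
            tris.append((b, b + 1, a + 1))
    tris = np.array(tris)
    th = np.deg2rad(fiber_angle_deg)
    fibers = np.tile([np.cos(th), np.sin(th), 0.0], (len(tris), 1))
    return BilayerMesh(
        pts=pts, tris=tris, fibers=fibers,
        fibrotic=np.zeros(len(tris), bool),
        region=np.zeros(len(tris), np.int16),
        layer=np.zeros(len(tris), np.int8),
        meta={"geometry": "sheet", "shape": (nx, ny), "h": h_mm})


def build_bilayer(surface: BilayerMesh, offset_um: float = 100.0
                  ) -> BilayerMesh:
    """Duplicate a single-layer surface into nested endo/epi shells.

    Epicardial nodes are the endocardial ones moved outward by ``offset_um``
    along the (area-weighted) vertex normal; each node pair becomes a 1D
    interlayer link; fibers, fibrosis and region labels are copied.
    """
    check_manifold(surface)
    n = surface.n_nodes
    p = surface.pts
    t = surface.tris
    fn = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
    vn = np.zeros((n, 3))
    np.add.at(vn, t.ravel(), np.repeat(fn, 3, axis=0))
    norm = np.linalg.norm(vn, axis=1)
    if norm.min() < 1e-12:
        raise ValueError("cannot compute a vertex normal (degenerate fan)")
    vn /= norm[:, None]
    off = offset_um * 1e-3
    pts2 = np.vstack([p, p + off * vn])
    tris2 = np.vstack([t, t[:, ::-1] + n])   # epi mirrored to keep outward
    rep = lambda a: np.concatenate([a, a])
    links = np.column_stack([np.arange(n), np.arange(n) + n])
    return BilayerMesh(
        pts=pts2, tris=tris2, fibers=rep(surface.fibers),
        fibrotic=rep(surface.fibrotic), region=rep(surface.region),
        layer=np.concatenate([np.zeros(len(t), np.int8),
                              np.ones(len(t), np.int8)]),
        links=links,
        meta={**surface.meta, "bilayer": True, "offset_um": offset_um})


def planar_wave_stimulus(mesh: BilayerMesh, axis: int = 0,
                         onset: float = 0.0, amplitude: float = 60.0,
                         duration: float = 2.0,
                         depth_mm: float = 0.5) -> StimulusTrain:
    """Stimulate the low-coordinate edge strip to launch a planar wave."""
    lo = mesh.pts[:, axis].min()
    nodes = np.nonzero(mesh.pts[:, axis] <= lo + depth_mm)[0]
    return StimulusTrain(site=-1, pulse_onsets=np.array([onset]),
                         pulse_duration=duration, amplitude=amplitude,
                         nodes=nodes)


def measure_cv(result: SimulationResult, mesh: BilayerMesh,
               axis: int = 0) -> float:
    """Planar-wave conduction velocity (cm/s) between the 25% and 75%
    stations along ``axis``.

    Returns NaN (a "propagation failure" outcome, not an exception) if
    either station was never activated — decremental conduction is a
    legitimate result.
    """
    x = mesh.pts[:, axis]
    lo, hi = x.min(), x.max()
    at = result.activation_times
    sts = []
    for frac in (0.25, 0.75):
        target = lo + frac * (hi - lo)
        sel = np.abs(x - target) < 0.5 * (hi - lo) * 0.02 + 1e-9
        if not sel.any():
            sel = np.abs(x - target) <= np.abs(x - target).min() + 1e-9
        ts = at[sel]
        if np.any(ts < 0):
            return float("nan")
        sts.append((target, float(ts.mean())))
    (x1, t1), (x2, t2) = sts
    if t2 == t1:
        return float("nan")
    return float((x2 - x1) / (t2 - t1) * 100.0)   # mm/ms -> cm/s
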