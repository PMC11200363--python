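"""Linear elastodynamics of the vessel wall (plane strain, P2 triangles).

The wall strip is discretized with quadratic (six-node) triangles built on
the geometric mesh, which resolves the bending of the 0.5 mm wall with very
few elements through the thickness.  Time integration is implicit Newmark
with average acceleration (gamma = 1/2, beta = 1/4): unconditionally stable
and, for undamped linear systems, energy-conserving.  No structural damping
is applied.  The temporal-bone backing acts through a unilateral penalty:
stiff springs on the wall's medial surface wherever bone is present (i.e.
everywhere except the dehiscence patch), active in compression only.

Supports: the wall end cross-sections (inlet/outlet sections) are fixed.
The lateral lumen wall is rigid and carries no solid mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import MaterialSet
from .meshing import Mesh


def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """First and second Lame parameters from Young's modulus and Poisson ratio.

    lambda = nu E / ((1 + nu)(1 - 2 nu)),  mu = E / (2 (1 + nu)).
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must be in [0, 0.5); nu >= 1/2 is the "
                         "incompressible limit")
    lam = nu * E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def contact_penalty_traction(u_normal: np.ndarray, gap: float, k: float):
    """Penalty contact traction magnitude for normal displacement u_n.

    Penetration is ``u_n - gap`` where positive; the returned traction
    k * max(0, penetration) opposes the penetration.  Zero where the wall
    has separated (and, by construction of the contact node set, over the
    dehiscence patch where no bone backs the wall).
    """
    if k <= 0:
        raise ValueError("penalty stiffness must be positive")
    if gap < 0:
        raise ValueError("gap must be non-negative")
    return k * np.maximum(0.0, np.asarray(u_normal, dtype=float) - gap)


# -- P2 quadrature ----------------------------------------------------------

# degree-2 rule (3 interior points) for the stiffness, degree-4 (6 points)
# for the mass matrix
_QP3 = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW3 = np.array([1 / 3, 1 / 3, 1 / 3])
_A6, _B6 = 0.445948490915965, 0.091576213509771
_QP6 = np.array([[_A6, _A6], [1 - 2 * _A6, _A6], [_A6, 1 - 2 * _A6],
                 [_B6, _B6], [1 - 2 * _B6, _B6], [_B6, 1 - 2 * _B6]])
_QW6 = np.array([0.223381589678011] * 3 + [0.109951743655322] * 3)


def _p2_shape(xi, eta):
    l1 = 1.0 - xi - eta
    N = np.array([l1 * (2 * l1 - 1), xi * (2 * xi - 1), eta * (2 * eta - 1),
                  4 * l1 * xi, 4 * xi * eta, 4 * eta * l1])
    dN = np.array([
        [1 - 4 * l1, 1 - 4 * l1],
        [4 * xi - 1, 0.0],
        [0.0, 4 * eta - 1],
        [4 * (l1 - xi), -4 * xi],
        [4 * eta, 4 * xi],
        [-4 * eta, 4 * (l1 - eta)],
    ])
    return N, dN


@dataclass
class SolidField:
    """Displacement state on the P2 wall nodes."""

    u: np.ndarray   # (n2,) dof vector [ux..., uy...] (m)
    v: np.ndarray   # velocity (m/s)
    a: np.ndarray   # acceleration (m/s^2)
    t: float = 0.0

    def copy(self) -> "SolidField":
        return SolidField(self.u.copy(), self.v.copy(), self.a.copy(), self.t)


class SolidSolver:
    """P2 plane-strain elastodynamics on one mesh region."""

    def __init__(self, mesh: Mesh, materials: MaterialSet, region: str = "wall",
                 fixed_markers: tuple[str, ...] = ("wall_end",),
                 contact_markers: tuple[str, ...] = ("medial",),
                 penalty_stiffness: float = 0.0,
                 modulus: float | None = None, density: float | None = None,
                 poisson: float | None = None, subdivide: int = 0):
        self.mesh = mesh
        self.mat = materials
        self.rho = density if density is not None else materials.vessel_density
        E = modulus if modulus is not None else materials.vessel_modulus
        nu = poisson if poisson is not None else materials.vessel_poisson
        self.lam, self.mu = lame_parameters(E, nu)
        self.penalty_k = penalty_stiffness
        self.subdivide = subdivide

        tris_g = mesh.region_tris(region)
        verts = np.unique(tris_g)
        self.verts = verts                        # global vertex ids
        g2l = -np.ones(mesh.num_nodes, dtype=np.int64)
        g2l[verts] = np.arange(len(verts))
        self.g2l = g2l
        tris = g2l[tris_g]
        pts_v = [mesh.points[v].copy() for v in verts]

        # map from the geometric mesh's edges (global node pairs) to the
        # solver's local sub-edges; internal subdivision refines the strip
        # beyond the geometric mesh (e.g. to keep >= 2 element rows through
        # a thin wall) without touching the shared discretization
        sub_edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for tri in tris_g:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (int(min(a, b)), int(max(a, b)))
                if key not in sub_edges:
                    sub_edges[key] = [(int(g2l[key[0]]), int(g2l[key[1]]))]
        for _ in range(subdivide):
            mid: dict[tuple[int, int], int] = {}

            def midpoint(a, b):
                k = (min(a, b), max(a, b))
                if k not in mid:
                    mid[k] = len(pts_v)
                    pts_v.append(0.5 * (pts_v[a] + pts_v[b]))
                return mid[k]

            new_tris = []
            for a, b, c in tris:
                ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
                new_tris.extend([(a, ab, ca), (ab, b, bc),
                                 (ca, bc, c), (ab, bc, ca)])
            tris = np.asarray(new_tris, dtype=np.int64)
            for key, segs in sub_edges.items():
                sub_edges[key] = [pair for (la, lb) in segs
                                  for pair in ((la, midpoint(la, lb)),
                                               (midpoint(la, lb), lb))]
        self._sub_edges = sub_edges
        self.n_verts = len(pts_v)

        # assign P2 midside node ids on the (possibly subdivided) strip
        edge_mid: dict[tuple[int, int], int] = {}
        next_id = self.n_verts
        conn = np.empty((len(tris), 6), dtype=np.int64)
        for e, tri in enumerate(tris):
            conn[e, :3] = tri
            for k, (a, b) in enumerate(((0, 1), (1, 2), (2, 0))):
                key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
                if key not in edge_mid:
                    edge_mid[key] = next_id
                    next_id += 1
                conn[e, 3 + k] = edge_mid[key]
        self.conn = conn
        self.n_nodes = next_id
        self.edge_mid = edge_mid
        pts = np.empty((next_id, 2))
        pts[:self.n_verts] = np.asarray(pts_v)
        for (a, b), m in edge_mid.items():
            pts[m] = 0.5 * (pts[a] + pts[b])
        self.pts = pts
        self.ndof = 2 * next_id

        self._assemble_matrices()
        self._setup_boundaries(fixed_markers, contact_markers)
        self._factor_cache: dict = {}

    # -- assembly ----------------------------------------------------------
    def _assemble_matrices(self) -> None:
        lam, mu, rho = self.lam, self.mu, self.rho
        D = np.array([[lam + 2 * mu, lam, 0.0],
                      [lam, lam + 2 * mu, 0.0],
                      [0.0, 0.0, mu]])
        n = self.n_nodes
        conn = self.conn
        x = self.pts[conn[:, :3], 0]
        y = self.pts[conn[:, :3], 1]
        j11 = x[:, 1] - x[:, 0]; j12 = y[:, 1] - y[:, 0]
        j21 = x[:, 2] - x[:, 0]; j22 = y[:, 2] - y[:, 0]
        detj = j11 * j22 - j12 * j21
        if np.any(detj <= 0):
            raise ValueError("inverted wall elements")
        inv = np.stack([np.stack([j22, -j12], -1), np.stack([-j21, j11], -1)], 1)
        inv /= detj[:, None, None]

        ne = len(conn)
        Ke = np.zeros((ne, 12, 12))
        Me = np.zeros((ne, 12, 12))
        for qp, qw, mass in ((_QP3, _QW3, False), (_QP6, _QW6, True)):
            for (xi, eta), w in zip(qp, qw):
                N, dN = _p2_shape(xi, eta)
                # physical gradients: (ne, 6, 2)
                g = np.einsum("exy,ny->enx", inv, dN)
                B = np.zeros((ne, 3, 12))
                B[:, 0, :6] = g[:, :, 0]
                B[:, 1, 6:] = g[:, :, 1]
                B[:, 2, :6] = g[:, :, 1]
                B[:, 2, 6:] = g[:, :, 0]
                if mass:
                    NN = np.outer(N, N)
                    Me[:, :6, :6] += (w * 0.5 * rho) * detj[:, None, None] * NN
                    Me[:, 6:, 6:] += (w * 0.5 * rho) * detj[:, None, None] * NN
                else:
                    Ke += (w * 0.5) * detj[:, None, None] * np.einsum(
                        "eki,kl,elj->eij", B, D, B)

        dof = np.concatenate([conn, conn + n], axis=1)  # (ne, 12)
        rows = np.repeat(dof[:, :, None], 12, axis=2).ravel()
        cols = np.repeat(dof[:, None, :], 12, axis=1).ravel()
        self.K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                               shape=(self.ndof, self.ndof)).tocsr()
        self.M = sp.coo_matrix((Me.ravel(), (rows, cols)),
                               shape=(self.ndof, self.ndof)).tocsr()

    def _edge_triples(self, a_g: int, b_g: int):
        """Local P2 triples (a, mid, b) of the sub-edges of a mesh edge."""
        key = (int(min(a_g, b_g)), int(max(a_g, b_g)))
        segs = self._sub_edges.get(key)
        if segs is None:
            return []
        out = []
        for la, lb in segs:
            m = self.edge_mid.get((min(la, lb), max(la, lb)))
            if m is not None:
                out.append((int(la), int(m), int(lb)))
        return out

    def edge_midside_samples(self, edges_g: np.ndarray):
        """Sampling nodes along mesh edges: (P2 midside ids, sub-edge lengths)."""
        mids, lengths = [], []
        for a_g, b_g in edges_g:
            for a, m, b in self._edge_triples(int(a_g), int(b_g)):
                mids.append(m)
                lengths.append(float(np.hypot(*(self.pts[b] - self.pts[a]))))
        return np.asarray(mids, dtype=np.int64), np.asarray(lengths)

    def _setup_boundaries(self, fixed_markers, contact_markers) -> None:
        # adjacency for orienting boundary normals
        edge_elem: dict[tuple[int, int], int] = {}
        for e, tri in enumerate(self.conn[:, :3]):
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                edge_elem[(min(a, b), max(a, b))] = e

        fixed = set()
        for mk in fixed_markers:
            for a_g, b_g in self.mesh.marker_edges(mk):
                for tr in self._edge_triples(a_g, b_g):
                    fixed.update(tr)
        self.fixed_nodes = np.array(sorted(fixed), dtype=np.int64)
        fdof = np.concatenate([self.fixed_nodes, self.fixed_nodes + self.n_nodes]) \
            if len(fixed) else np.array([], dtype=np.int64)
        self.free = np.setdiff1d(np.arange(self.ndof), fdof)

        # contact nodes: lumped tributary lengths and outward normals
        weights = np.zeros(self.n_nodes)
        normals = np.zeros((self.n_nodes, 2))
        cn = set()
        for mk in contact_markers:
            for a_g, b_g in self.mesh.marker_edges(mk):
                for a, m, b in self._edge_triples(a_g, b_g):
                    pa, pb = self.pts[a], self.pts[b]
                    d = pb - pa
                    length = float(np.hypot(*d))
                    nrm = np.array([d[1], -d[0]]) / length
                    elem = edge_elem[(min(a, b), max(a, b))]
                    cen = self.pts[self.conn[elem, :3]].mean(axis=0)
                    if np.dot(nrm, cen - 0.5 * (pa + pb)) > 0:
                        nrm = -nrm
                    for node, wgt in ((a, length / 6), (m, 2 * length / 3),
                                      (b, length / 6)):
                        weights[node] += wgt
                        normals[node] += wgt * nrm
                        cn.add(node)
        cn = np.array(sorted(cn - set(self.fixed_nodes.tolist()))
                      if cn else [], dtype=np.int64)
        self.contact_nodes = cn
        if len(cn):
            nrm = normals[cn]
            nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
            self.contact_normals = nrm
            self.contact_weights = weights[cn]
        else:
            self.contact_normals = np.zeros((0, 2))
            self.contact_weights = np.zeros(0)

    def _contact_matrix(self, active: np.ndarray) -> sp.csr_matrix:
        """Penalty spring stiffness k * w_i * (n n^T) for active contact nodes."""
        if self.penalty_k <= 0 or not np.any(active):
            return sp.csr_matrix((self.ndof, self.ndof))
        idx = self.contact_nodes[active]
        nrm = self.contact_normals[active]
        wgt = self.contact_weights[active] * self.penalty_k
        n = self.n_nodes
        rows, cols, data = [], [], []
        for (i, (nx, ny), w) in zip(idx, nrm, wgt):
            for (r, vr) in ((i, nx), (i + n, ny)):
                for (c, vc) in ((i, nx), (i + n, ny)):
                    rows.append(r); cols.append(c); data.append(w * vr * vc)
        return sp.coo_matrix((data, (rows, cols)),
                             shape=(self.ndof, self.ndof)).tocsr()

    def contact_penetration(self, u: np.ndarray) -> np.ndarray:
        """Outward-normal displacement of the contact nodes (gap = 0)."""
        n = self.n_nodes
        un = (u[self.contact_nodes] * self.contact_normals[:, 0]
              + u[self.contact_nodes + n] * self.contact_normals[:, 1])
        return un

    # -- loads -------------------------------------------------------------
    def edge_load_vector(self, edges_g: np.ndarray,
                         tractions: np.ndarray) -> np.ndarray:
        """Consistent nodal forces for constant traction per mesh edge.

        ``edges_g``: (E, 2) global mesh node pairs; ``tractions``: (E, 2) Pa.
        """
        F = np.zeros(self.ndof)
        n = self.n_nodes
        for (a_g, b_g), tr in zip(edges_g, tractions):
            for a, m, b in self._edge_triples(int(a_g), int(b_g)):
                length = float(np.hypot(*(self.pts[b] - self.pts[a])))
                for node, w in ((a, length / 6), (m, 2 * length / 3),
                                (b, length / 6)):
                    F[node] += w * tr[0]
                    F[node + n] += w * tr[1]
        return F

    # -- solvers -----------------------------------------------------------
    def zero_state(self) -> SolidField:
        return SolidField(np.zeros(self.ndof), np.zeros(self.ndof),
                          np.zeros(self.ndof), 0.0)

    def _factorized(self, key, matrix_fn):
        if key not in self._factor_cache:
            A = matrix_fn()[self.free][:, self.free].tocsc()
            self._factor_cache[key] = spla.splu(A)
        return self._factor_cache[key]

    def static_solve(self, F: np.ndarray, contact: bool = False,
                     prescribed: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> np.ndarray:
        """Quasi-static displacement under nodal load F.

        ``prescribed`` optionally pins extra dofs (indices, values) beyond
        the fixed supports, e.g. for patch tests.
        """
        u = np.zeros(self.ndof)
        free = self.free
        if prescribed is not None:
            idx, vals = prescribed
            u[idx] = vals
            free = np.setdiff1d(free, idx)
        active = np.zeros(len(self.contact_nodes), dtype=bool)
        for _ in range(6):
            A = self.K + self._contact_matrix(active) if (
                contact and self.penalty_k > 0) else self.K
            rhs = F - A.dot(u)
            u_f = spla.spsolve(A[free][:, free].tocsc(), rhs[free])
            u[free] = u[free] + u_f
            if not contact or self.penalty_k <= 0 or len(self.contact_nodes) == 0:
                return u
            new_active = self.contact_penetration(u) > 0
            if np.array_equal(new_active, active):
                return u
            active = new_active
        return u

    def initialize_state(self, u0: np.ndarray | None = None,
                         v0: np.ndarray | None = None,
                         F: np.ndarray | None = None) -> SolidField:
        """State with the consistent initial acceleration M a = F - K u."""
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        v = np.zeros(self.ndof) if v0 is None else v0.copy()
        rhs = (np.zeros(self.ndof) if F is None else F) - self.K.dot(u)
        a = np.zeros(self.ndof)
        lu = self._factorized(("massinv",), lambda: self.M.copy())
        a[self.free] = lu.solve(rhs[self.free])
        return SolidField(u, v, a, 0.0)

    def newmark_step(self, state: SolidField, F: np.ndarray, dt: float,
                     contact: bool = True, gamma: float = 0.5,
                     active_set: np.ndarray | None = None) -> SolidField:
        """One implicit Newmark step under load F.

        ``gamma = 0.5`` is the energy-conserving average-acceleration rule;
        ``gamma > 0.5`` (with beta = (gamma + 1/2)^2 / 4) adds algorithmic
        dissipation that damps only modes near the step Nyquist frequency,
        leaving the resolved band essentially untouched.

        Contact is resolved by an active-set loop on the penalty springs;
        passing ``active_set`` instead freezes the springs for the step,
        which keeps the step linear inside FSI subiterations (the caller
        updates the set once per accepted step).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if gamma < 0.5:
            raise ValueError("gamma < 1/2 is not unconditionally stable")
        beta = 0.25 * (gamma + 0.5) ** 2
        c0 = 1.0 / (beta * dt * dt)
        c1 = 1.0 / (beta * dt)
        c2 = 1.0 / (2.0 * beta) - 1.0
        pred = self.M.dot(c0 * state.u + c1 * state.v + c2 * state.a)
        rhs_full = F + pred
        u = state.u.copy()
        use_contact = contact and self.penalty_k > 0 and len(self.contact_nodes)
        if not use_contact:
            active = np.zeros(0, dtype=bool)
        elif active_set is not None:
            active = active_set
        else:
            active = self.contact_penetration(state.u) > 0
        for _ in range(6):
            lu = self._factorized(("newmark", dt, gamma,
                                   tuple(np.flatnonzero(active))),
                                  lambda: self.K + self._contact_matrix(active)
                                  + c0 * self.M)
            u = np.zeros(self.ndof)
            u[self.free] = lu.solve(rhs_full[self.free])
            if not use_contact or active_set is not None:
                break
            new_active = self.contact_penetration(u) > 0
            if np.array_equal(new_active, active):
                break
            active = new_active
        a_new = c0 * (u - state.u) - c1 * state.v - c2 * state.a
        v_new = state.v + dt * ((1.0 - gamma) * state.a + gamma * a_new)
        return SolidField(u, v_new, a_new, state.t + dt)

    # -- derived -----------------------------------------------------------
    def energy(self, state: SolidField) -> float:
        """Kinetic + strain + contact-spring energy."""
        e = 0.5 * state.v @ self.M.dot(state.v) + 0.5 * state.u @ self.K.dot(state.u)
        if self.penalty_k > 0 and len(self.contact_nodes):
            pen = self.contact_penetration(state.u)
            e += 0.5 * self.penalty_k * np.sum(self.contact_weights * pen ** 2)
        return float(e)

    def displacement_at_vertices(self, state: SolidField,
                                 global_ids: np.ndarray) -> np.ndarray:
        """(len(ids), 2) displacement at geometric mesh vertices."""
        loc = self.g2l[global_ids]
        n = self.n_nodes
        return np.stack([state.u[loc], state.u[loc + n]], axis=1)

    def velocity_at_vertices(self, state: SolidField,
                             global_ids: np.ndarray) -> np.ndarray:
        loc = self.g2l[global_ids]
        n = self.n_nodes
        return np.stack([state.v[loc], state.v[loc + n]], axis=1)

    def first_structural_mode(self, n_modes: int = 6,
                              with_contact_springs: bool = True):
        """Lowest constrained eigenfrequency (Hz) and mass-normalized shape.

        Contact springs (bilateral, as a linearization of the bone backing)
        are included by default, matching the operating configuration.
        """
        A = self.K
        if with_contact_springs and self.penalty_k > 0 and len(self.contact_nodes):
            A = A + self._contact_matrix(np.ones(len(self.contact_nodes), bool))
        Af = (A[self.free][:, self.free]).tocsc()
        Mf = (self.M[self.free][:, self.free]).tocsc()
        vals, vecs = spla.eigsh(Af, k=min(n_modes, Af.shape[0] - 2), M=Mf,
                                sigma=0.0, which="LM")
        vals = np.real(vals)
        pos = vals > 1.0e-6 * vals.max()
        lam1 = float(vals[pos].min())
        i1 = int(np.flatnonzero(vals == vals[pos].min())[0])
        shape = np.zeros(self.ndof)
        phi = np.real(vecs[:, i1])
        phi /= np.sqrt(phi @ Mf.dot(phi))
        shape[self.free] = phi
        return float(np.sqrt(lam1) / (2.0 * np.pi)), shape
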