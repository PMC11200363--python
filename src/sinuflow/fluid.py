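"""Transient incompressible Navier-Stokes solver for the lumen.

Linear (P1) velocity and pressure on triangles with SUPG/PSPG
stabilization, implicit backward-Euler time stepping and Picard
linearization of the convective term.  Boundary conditions: prescribed
pulsatile mass flow (parabolic profile) at the inlet, zero-traction
("do-nothing", hence zero mean pressure) at the outlet, and no-slip equal
to the wall velocity on the lateral wall and the lumen-wall interface.
Wall motion enters in arbitrary Lagrangian-Eulerian fashion as the
interface velocity only; the interior mesh is held fixed, which is accurate
for the micrometre-scale wall displacements of this problem.

The momentum residual uses the full symmetric stress
mu (grad v + grad v^T) - p I, matching the solid-side traction exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import MaterialSet
from .geometry import VesselGeometry
from .meshing import Mesh
from .waveform import InletWaveform, sample_waveform, ramp_factor  # noqa: F401


@dataclass
class FluidField:
    """Velocity-pressure state on the lumen nodes (local numbering)."""

    u: np.ndarray          # (n, 2) m/s
    p: np.ndarray          # (n,) Pa
    t: float = 0.0         # s
    residuals: tuple = ()  # Picard residual history of the last solve

    def copy(self) -> "FluidField":
        return FluidField(self.u.copy(), self.p.copy(), self.t, self.residuals)


def reynolds_number_from(rho: float, v: float, d: float, mu: float) -> float:
    """Re = rho v d / mu."""
    return rho * v * d / mu


class FluidSolver:
    """Stabilized P1-P1 incompressible flow solver on the lumen region."""

    def __init__(self, mesh: Mesh, materials: MaterialSet,
                 geometry: VesselGeometry | None = None,
                 inlet: str = "inlet", outlet: str = "outlet",
                 noslip: tuple[str, ...] = ("lateral",),
                 interface: str = "interface",
                 picard_tol: float = 1.0e-3, picard_max_iter: int = 25):
        self.mesh = mesh
        self.mat = materials
        self.geom = geometry
        self.rho = materials.fluid_density
        self.mu = materials.fluid_viscosity
        self.picard_tol = picard_tol
        self.picard_max_iter = picard_max_iter
        #: velocity scale (m/s) used as a floor in relative residuals, so
        #: near-rest states do not chase solver noise; set by the caller
        self.u_ref = 0.0

        tris = mesh.region_tris("lumen")
        nodes = np.unique(tris)
        self.nodes = nodes                       # global ids of lumen nodes
        self.n = len(nodes)
        g2l = -np.ones(mesh.num_nodes, dtype=np.int64)
        g2l[nodes] = np.arange(self.n)
        self.g2l = g2l
        self.tris = g2l[tris]                    # (M, 3) local
        self.pts = mesh.points[nodes]

        self._precompute_geometry()
        self._precompute_constant_blocks()

        def local_marker_nodes(name):
            g = mesh.marker_nodes(name)
            g = g[g2l[g] >= 0]
            return g2l[g]

        self.inlet_nodes = local_marker_nodes(inlet)
        self.interface_nodes = local_marker_nodes(interface)
        wall = np.concatenate([local_marker_nodes(m) for m in noslip])
        self.wall_nodes = np.setdiff1d(wall, self.inlet_nodes)
        # interface nodes shared with the inlet/outlet sections follow the
        # wall prescription (they are clamped in the solid anyway)
        self.interface_nodes = np.setdiff1d(self.interface_nodes, self.inlet_nodes)

        self._edge_cache: dict[str, tuple] = {}
        self._last_operator: tuple | None = None
        self._setup_inlet_profile()
        self._setup_sparsity()

    # -- precomputation ----------------------------------------------------
    def _precompute_geometry(self) -> None:
        p = self.pts
        t = self.tris
        x = p[t, 0]                              # (M, 3)
        y = p[t, 1]
        self.area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                           - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
        if np.any(self.area <= 0):
            raise ValueError("inverted lumen elements")
        a2 = 2.0 * self.area
        self.bg = np.stack([(y[:, 1] - y[:, 2]) / a2,
                            (y[:, 2] - y[:, 0]) / a2,
                            (y[:, 0] - y[:, 1]) / a2], axis=1)
        self.cg = np.stack([(x[:, 2] - x[:, 1]) / a2,
                            (x[:, 0] - x[:, 2]) / a2,
                            (x[:, 1] - x[:, 0]) / a2], axis=1)
        edges = np.stack([np.hypot(x[:, 1] - x[:, 0], y[:, 1] - y[:, 0]),
                          np.hypot(x[:, 2] - x[:, 1], y[:, 2] - y[:, 1]),
                          np.hypot(x[:, 0] - x[:, 2], y[:, 0] - y[:, 2])], axis=1)
        self.h_alt = 2.0 * self.area / edges.max(axis=1)   # min altitude
        self.h_elem = np.sqrt(2.0 * self.area)
        rows = np.repeat(self.tris[:, :, None], 3, axis=2)
        cols = np.repeat(self.tris[:, None, :], 3, axis=1)
        self._rows = rows.ravel()
        self._cols = cols.ravel()

    def _precompute_constant_blocks(self) -> None:
        mu, A = self.mu, self.area[:, None, None]
        b = self.bg
        c = self.cg
        bb = b[:, :, None] * b[:, None, :]
        cc = c[:, :, None] * c[:, None, :]
        bc = b[:, :, None] * c[:, None, :]   # b_i c_j
        cb = c[:, :, None] * b[:, None, :]   # c_i b_j
        self.Kxx = (mu * A * (2.0 * bb + cc)).ravel()
        self.Kyy = (mu * A * (2.0 * cc + bb)).ravel()
        self.Kxy = (mu * A * cb).ravel()     # row wx, col uy
        self.Kyx = (mu * A * bc).ravel()
        ident = np.full((len(self.area), 3, 3), 1.0)
        ident += np.eye(3)[None]
        self.Mgal = (self.rho * self.area[:, None, None] / 12.0 * ident).ravel()
        ones = np.ones((len(self.area), 3, 3))
        self.Gx = (-self.area[:, None, None] / 3.0 * b[:, :, None] * ones).ravel()
        self.Gy = (-self.area[:, None, None] / 3.0 * c[:, :, None] * ones).ravel()
        self.Dx = (self.area[:, None, None] / 3.0 * b[:, None, :] * ones).ravel()
        self.Dy = (self.area[:, None, None] / 3.0 * c[:, None, :] * ones).ravel()

    def _setup_inlet_profile(self) -> None:
        """Unit-flux parabolic inlet profile (scaled per step by Q/rho)."""
        if len(self.inlet_nodes) == 0:
            self._inlet_unit = np.zeros((0, 2))
            return
        mesh = self.mesh
        xi = mesh.node_n[self.nodes[self.inlet_nodes]]
        lo, hi = xi.min(), xi.max()
        halfw = 0.5 * (hi - lo)
        center = 0.5 * (hi + lo)
        prof = 1.0 - ((xi - center) / halfw) ** 2
        prof = np.clip(prof, 0.0, None)
        flux = np.trapezoid(prof[np.argsort(xi)], np.sort(xi))
        prof /= flux                              # unit volumetric flux
        if self.geom is not None:
            direction = self.geom.tangent(np.array([0.0]))[0]
        else:
            direction = np.array([1.0, 0.0])
        self._inlet_unit = prof[:, None] * direction[None, :]

    # -- assembly ----------------------------------------------------------
    def _assemble(self, a_vel: np.ndarray, dt: float | None):
        """System matrix and mass-like operator for Picard velocity a_vel."""
        rho, A = self.rho, self.area
        t = self.tris
        ax = a_vel[t, 0]
        ay = a_vel[t, 1]
        # Galerkin convection: C[i,j] = rho (m_i^x b_j + m_i^y c_j)
        mx = A[:, None] / 12.0 * (ax + ax.sum(axis=1, keepdims=True))
        my = A[:, None] / 12.0 * (ay + ay.sum(axis=1, keepdims=True))
        Cv = rho * (mx[:, :, None] * self.bg[:, None, :]
                    + my[:, :, None] * self.cg[:, None, :])

        axm = ax.mean(axis=1)
        aym = ay.mean(axis=1)
        speed = np.hypot(axm, aym)
        nu = self.mu / rho
        h = self.h_elem
        inv_dt2 = (2.0 / dt) ** 2 if dt else 0.0
        tau = 1.0 / np.sqrt(inv_dt2 + (2.0 * speed / h) ** 2
                            + (4.0 * nu / h ** 2) ** 2)
        adg = axm[:, None] * self.bg + aym[:, None] * self.cg   # a . grad phi_i

        tA = tau * A
        Ssupg = (rho * tA)[:, None, None] * adg[:, :, None] * adg[:, None, :]
        Spx = tA[:, None, None] * adg[:, :, None] * self.bg[:, None, :]
        Spy = tA[:, None, None] * adg[:, :, None] * self.cg[:, None, :]
        Ppp = (tA / rho)[:, None, None] * (
            self.bg[:, :, None] * self.bg[:, None, :]
            + self.cg[:, :, None] * self.cg[:, None, :])
        Pux = tA[:, None, None] * self.bg[:, :, None] * adg[:, None, :]
        Puy = tA[:, None, None] * self.cg[:, :, None] * adg[:, None, :]

        # mass-like terms (x 1/dt in the system; also build the rhs)
        ones3 = np.ones((len(A), 3, 3)) / 3.0
        Msupg = (rho * tA)[:, None, None] * adg[:, :, None] * ones3
        Mpx = tA[:, None, None] * self.bg[:, :, None] * ones3
        Mpy = tA[:, None, None] * self.cg[:, :, None] * ones3

        # flat value arrays in the fixed block order of _setup_sparsity
        conv = Cv.ravel()
        sys_data = np.concatenate([
            conv + Ssupg.ravel() + self.Kxx,
            self.Kxy,
            self.Kyx,
            conv + Ssupg.ravel() + self.Kyy,
            self.Gx + Spx.ravel(),
            self.Gy + Spy.ravel(),
            self.Dx + Pux.ravel(),
            self.Dy + Puy.ravel(),
            Ppp.ravel(),
        ])
        msupg = self.Mgal + Msupg.ravel()
        mass_data = np.concatenate([msupg, msupg, Mpx.ravel(), Mpy.ravel()])
        return sys_data, mass_data

    def _dirichlet(self, t: float, q_vol: float,
                   interface_velocity: np.ndarray | None):
        """Constrained velocity dofs and their values."""
        n = self.n
        idx = []
        val = []
        inl = self.inlet_nodes
        uin = q_vol * self._inlet_unit
        idx.append(inl); val.append(uin[:, 0])
        idx.append(inl + n); val.append(uin[:, 1])
        w = self.wall_nodes
        idx.append(w); val.append(np.zeros(len(w)))
        idx.append(w + n); val.append(np.zeros(len(w)))
        itf = self.interface_nodes
        if interface_velocity is None:
            vi = np.zeros((len(itf), 2))
        else:
            vi = interface_velocity
        idx.append(itf); val.append(vi[:, 0])
        idx.append(itf + n); val.append(vi[:, 1])
        return np.concatenate(idx), np.concatenate(val)

    def _setup_sparsity(self) -> None:
        """Precompute the CSC structure of the stabilized system.

        The sparsity pattern and the constrained-dof set are fixed over the
        whole run, so each iteration only refills the value array (via a
        precomputed scatter map) before factorization.
        """
        n = self.n
        n3 = 3 * n
        r, c = self._rows, self._cols
        sys_rc = [(0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (1, 2),
                  (2, 0), (2, 1), (2, 2)]
        mass_rc = [(0, 0), (1, 1), (2, 0), (2, 1)]
        rows = np.concatenate([r + ro * n for ro, _ in sys_rc + mass_rc])
        cols = np.concatenate([c + co * n for _, co in sys_rc + mass_rc])

        dir_idx = self._dirichlet(0.0, 0.0, None)[0]
        is_dir = np.zeros(n3, dtype=bool)
        is_dir[dir_idx] = True
        self._dir_idx_sorted = np.sort(dir_idx)
        keep = ~is_dir[rows]
        self._sys_keep = keep
        rows_f = np.concatenate([rows[keep], self._dir_idx_sorted])
        cols_f = np.concatenate([cols[keep], self._dir_idx_sorted])
        order = np.lexsort((rows_f, cols_f))   # column-major for CSC
        rs, cs = rows_f[order], cols_f[order]
        new_col = np.concatenate([[True], np.diff(cs) != 0])
        new_ent = new_col | np.concatenate([[True], np.diff(rs) != 0])
        slot = np.cumsum(new_ent) - 1
        nnz = int(slot[-1]) + 1
        inverse = np.empty(len(order), dtype=np.int64)
        inverse[order] = slot
        self._csc_inverse = inverse
        self._csc_indices = rs[new_ent]
        indptr = np.zeros(n3 + 1, dtype=np.int64)
        uniq_slots_per_col = np.bincount(cs[new_ent].astype(np.int64),
                                         minlength=n3)
        indptr[1:] = np.cumsum(uniq_slots_per_col)
        self._csc_indptr = indptr
        self._csc_nnz = nnz

        # mass operator structure (for the time-derivative rhs)
        m_rows = np.concatenate([r + ro * n for ro, _ in mass_rc])
        m_cols = np.concatenate([c + co * n for _, co in mass_rc])
        m_order = np.lexsort((m_cols, m_rows))  # row-major for CSR
        mrs, mcs = m_rows[m_order], m_cols[m_order]
        m_new = np.concatenate([[True], (np.diff(mrs) != 0)
                                | (np.diff(mcs) != 0)])
        m_slot = np.cumsum(m_new) - 1
        m_inverse = np.empty(len(m_order), dtype=np.int64)
        m_inverse[m_order] = m_slot
        self._m_inverse = m_inverse
        self._m_indices = mcs[m_new]
        m_indptr = np.zeros(n3 + 1, dtype=np.int64)
        m_indptr[1:] = np.cumsum(np.bincount(mrs[m_new].astype(np.int64),
                                             minlength=n3))
        self._m_indptr = m_indptr
        self._m_nnz = int(m_slot[-1]) + 1

    def _solve_linear(self, sys_data, mass_data, dt, u_old_vec,
                      dir_idx, dir_val):
        n3 = 3 * self.n
        data = sys_data if not dt else np.concatenate([sys_data,
                                                       mass_data / dt])
        if not dt:
            data = np.concatenate([sys_data, 0.0 * mass_data])
        data_f = np.concatenate([data[self._sys_keep],
                                 np.ones(len(self._dir_idx_sorted))])
        vals = np.bincount(self._csc_inverse, weights=data_f,
                           minlength=self._csc_nnz)
        Asys = sp.csc_matrix((vals, self._csc_indices, self._csc_indptr),
                             shape=(n3, n3))
        rhs = np.zeros(n3)
        if dt:
            mvals = np.bincount(self._m_inverse, weights=mass_data,
                                minlength=self._m_nnz)
            Mop = sp.csr_matrix((mvals, self._m_indices, self._m_indptr),
                                shape=(n3, n3))
            rhs = Mop.dot(u_old_vec) / dt
        rhs[dir_idx] = dir_val
        lu = spla.splu(Asys)
        self._last_operator = (lu, rhs.copy())
        return lu.solve(rhs)

    # -- public stepping ---------------------------------------------------
    def step_frozen(self, dt: float, q_vol: float,
                    interface_velocity: np.ndarray | None,
                    t_old: float) -> FluidField:
        """Re-solve the last factorized step operator with new boundary data.

        Valid within the FSI subiterations of one time step, where only the
        interface velocity values change: the system matrix (including the
        Picard convection field) and the time-derivative load are reused,
        so the cost is a single back-substitution.  The linearization lag
        this introduces is bounded by the interface convergence tolerance.
        """
        lu, rhs_base = self._last_operator
        dir_idx, dir_val = self._dirichlet(t_old + dt, q_vol,
                                           interface_velocity)
        rhs = rhs_base.copy()
        rhs[dir_idx] = dir_val
        sol = lu.solve(rhs)
        u = np.stack([sol[:self.n], sol[self.n:2 * self.n]], axis=1)
        return FluidField(u=u, p=sol[2 * self.n:], t=t_old + dt,
                          residuals=())

    def step(self, state: FluidField, dt: float, q_vol: float,
             interface_velocity: np.ndarray | None = None,
             initial_guess: "FluidField | None" = None,
             tol: float | None = None) -> FluidField:
        """Advance one implicit step.

        Parameters
        ----------
        q_vol : float
            Volumetric inlet flux per unit depth (m^2/s) at the new time
            level (mass flow divided by the blood density).
        interface_velocity : array (len(interface_nodes), 2), optional
            Wall velocity transferred from the solid (ALE no-slip value).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        tol = self.picard_tol if tol is None else tol
        u_old_vec = np.concatenate([state.u[:, 0], state.u[:, 1],
                                    np.zeros(self.n)])
        dir_idx, dir_val = self._dirichlet(state.t + dt, q_vol, interface_velocity)
        a = (initial_guess.u if initial_guess is not None else state.u).copy()
        residuals = []
        sol = None
        for _ in range(self.picard_max_iter):
            sys_data, mass_data = self._assemble(a, dt)
            sol = self._solve_linear(sys_data, mass_data, dt, u_old_vec,
                                     dir_idx, dir_val)
            u_new = np.stack([sol[:self.n], sol[self.n:2 * self.n]], axis=1)
            denom = max(np.linalg.norm(u_new),
                        0.02 * self.u_ref * np.sqrt(2.0 * self.n), 1.0e-14)
            res = np.linalg.norm(u_new - a) / denom
            residuals.append(res)
            if res < tol:
                a = u_new
                break
            # damped update when the iteration oscillates (limit cycles of
            # the convective fixed point on well-resolved shear layers)
            if len(residuals) >= 2 and res > 0.8 * residuals[-2]:
                a = 0.5 * u_new + 0.5 * a
            else:
                a = u_new
            if len(residuals) >= 3 and res > 5.0 and res > 10 * residuals[0]:
                raise RuntimeError(
                    f"Picard iteration diverged: residuals {residuals[-3:]}")
        else:
            if residuals[-1] > 10 * tol and residuals[-1] > residuals[0]:
                raise RuntimeError(
                    f"Picard iteration diverged: residuals {residuals[-3:]}")
        return FluidField(u=a, p=sol[2 * self.n:], t=state.t + dt,
                          residuals=tuple(residuals))

    def steady_solve(self, q_vol: float, max_iter: int = 60,
                     tol: float | None = None, relax: float = 1.0) -> FluidField:
        """Steady flow at fixed inlet flux (rigid walls)."""
        tol = tol or self.picard_tol
        dir_idx, dir_val = self._dirichlet(0.0, q_vol, None)
        a = np.zeros((self.n, 2))
        sol = None
        residuals = []
        for _ in range(max_iter):
            sys_data, mass_data = self._assemble(a, None)
            sol = self._solve_linear(sys_data, mass_data, None, None,
                                     dir_idx, dir_val)
            u_new = np.stack([sol[:self.n], sol[self.n:2 * self.n]], axis=1)
            u_new = relax * u_new + (1.0 - relax) * a
            res = np.linalg.norm(u_new - a) / max(np.linalg.norm(u_new), 1e-14)
            residuals.append(res)
            a = u_new
            if res < tol:
                break
        return FluidField(u=a, p=sol[2 * self.n:], t=0.0,
                          residuals=tuple(residuals))

    def zero_state(self) -> FluidField:
        return FluidField(u=np.zeros((self.n, 2)), p=np.zeros(self.n), t=0.0)

    # -- derived quantities -------------------------------------------------
    def _marker_edge_geometry(self, marker: str):
        """Per-edge (local nodes, length, outward normal, adjacent element)."""
        if marker in self._edge_cache:
            return self._edge_cache[marker]
        mesh = self.mesh
        edges_g = mesh.marker_edges(marker)
        tri_lookup = {}
        for ei, tri in enumerate(self.tris):
            for k in range(3):
                key = (int(min(tri[k], tri[(k + 1) % 3])),
                       int(max(tri[k], tri[(k + 1) % 3])))
                tri_lookup[key] = ei
        loc_edges, lengths, normals, elems = [], [], [], []
        for a_g, b_g in edges_g:
            a, b = self.g2l[a_g], self.g2l[b_g]
            if a < 0 or b < 0:
                continue
            key = (int(min(a, b)), int(max(a, b)))
            if key not in tri_lookup:
                continue
            ei = tri_lookup[key]
            pa, pb = self.pts[a], self.pts[b]
            d = pb - pa
            length = float(np.hypot(*d))
            nrm = np.array([d[1], -d[0]]) / length
            centroid = self.pts[self.tris[ei]].mean(axis=0)
            if np.dot(nrm, centroid - 0.5 * (pa + pb)) > 0:
                nrm = -nrm
            loc_edges.append((a, b))
            lengths.append(length)
            normals.append(nrm)
            elems.append(ei)
        out = (np.asarray(loc_edges, dtype=np.int64),
               np.asarray(lengths), np.asarray(normals),
               np.asarray(elems, dtype=np.int64))
        self._edge_cache[marker] = out
        return out

    def flux_through(self, state: FluidField, marker: str) -> float:
        """Outward volumetric flux per unit depth through a marked boundary."""
        edges, lengths, normals, _ = self._marker_edge_geometry(marker)
        if len(edges) == 0:
            return 0.0
        u_mid = 0.5 * (state.u[edges[:, 0]] + state.u[edges[:, 1]])
        return float(np.sum(lengths * np.sum(u_mid * normals, axis=1)))

    def traction_on(self, state: FluidField, marker: str = "interface"):
        """Fluid stress vector sigma . n on marked edges (n outward of lumen).

        Returns (edges_local, lengths, normals, traction (E,2)).
        """
        edges, lengths, normals, elems = self._marker_edge_geometry(marker)
        ux = state.u[self.tris[elems], 0]
        uy = state.u[self.tris[elems], 1]
        b = self.bg[elems]
        c = self.cg[elems]
        dudx = np.sum(b * ux, axis=1)
        dudy = np.sum(c * ux, axis=1)
        dvdx = np.sum(b * uy, axis=1)
        dvdy = np.sum(c * uy, axis=1)
        p_mid = 0.5 * (state.p[edges[:, 0]] + state.p[edges[:, 1]])
        sxx = -p_mid + 2.0 * self.mu * dudx
        syy = -p_mid + 2.0 * self.mu * dvdy
        sxy = self.mu * (dudy + dvdx)
        tx = sxx * normals[:, 0] + sxy * normals[:, 1]
        ty = sxy * normals[:, 0] + syy * normals[:, 1]
        return edges, lengths, normals, np.stack([tx, ty], axis=1)

    def pressure_on(self, state: FluidField, marker: str = "interface"):
        """Edge-midpoint pressure on marked edges: (edges, lengths, p_mid)."""
        edges, lengths, _, _ = self._marker_edge_geometry(marker)
        p_mid = 0.5 * (state.p[edges[:, 0]] + state.p[edges[:, 1]])
        return edges, lengths, p_mid

    def _advective_crossing(self, state: FluidField) -> np.ndarray:
        """Per-element advective crossing time h_dir / |u|.

        The element length scale is measured along the local flow
        direction (the largest edge projection onto the mean velocity),
        which is the physically relevant convective scale on stretched
        boundary-layer cells.
        """
        t = self.tris
        um = state.u[t].mean(axis=1)                 # (M, 2)
        speed = np.hypot(um[:, 0], um[:, 1])
        p = self.pts
        crossing = np.full(len(t), np.inf)
        moving = speed > 0
        if np.any(moving):
            uhat = um[moving] / speed[moving, None]
            proj = np.zeros(int(moving.sum()))
            for a, b in ((0, 1), (1, 2), (2, 0)):
                e = p[t[moving, b]] - p[t[moving, a]]
                proj = np.maximum(proj, np.abs(np.sum(e * uhat, axis=1)))
            crossing[moving] = proj / speed[moving]
        return crossing

    def cfl_timestep(self, state: FluidField, period: float,
                     safety: float = 0.8) -> float:
        """Automatic time step: CFL < 1, clamped to [T/2000, T/100]."""
        dt = safety * float(np.min(self._advective_crossing(state)))
        return float(np.clip(dt, period / 2000.0, period / 100.0))

    def cfl_number(self, state: FluidField, dt: float) -> float:
        """Largest dt / (advective crossing time) over the elements."""
        return float(dt / np.min(self._advective_crossing(state)))

    def max_speed(self, state: FluidField) -> float:
        return float(np.max(np.hypot(state.u[:, 0], state.u[:, 1])))

    def reynolds_number(self, state: FluidField) -> float:
        """Re = rho v_max D / mu with D the channel width at the maximum."""
        speeds = np.hypot(state.u[:, 0], state.u[:, 1])
        i = int(np.argmax(speeds))
        v = float(speeds[i])
        if v == 0.0:
            return 0.0
        if self.geom is not None and self.mesh.node_s is not None:
            s = self.mesh.node_s[self.nodes[i]]
            d = float(self.geom.width(np.array([s]))[0])
        else:
            d = float(self.pts[:, 1].max() - self.pts[:, 1].min())
        return reynolds_number_from(self.rho, v, d, self.mu)

    def divergence_norm(self, state: FluidField) -> float:
        """Element-wise L2 norm of div(u), for diagnostics."""
        ux = state.u[self.tris, 0]
        uy = state.u[self.tris, 1]
        div = np.sum(self.bg * ux, axis=1) + np.sum(self.cg * uy, axis=1)
        return float(np.sqrt(np.sum(div ** 2 * self.area)))
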