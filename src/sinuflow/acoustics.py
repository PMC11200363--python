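"""One-way acoustic-structure coupling: Helmholtz solve in the air cell.

The vibration of the vessel wall over the dehiscence (SSWD) patch is the
only sound source: its normal displacement history from the FSI run is
Fourier-analysed over the last cardiac cycle, and the complex amplitude at
the analysis frequency drives a frequency-domain Helmholtz problem in the
air cavity (adiabatic air, no viscosity or heat exchange).  The temporal
bone surfaces and the tympanum are impedance (Robin) boundaries
n.grad p = -(i omega rho / Z) p; the tympanum is additionally the receiver
where the sound pressure level is evaluated.

Time convention e^{+i omega t}; SPL = 20 log10(|p| / 20 uPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import MaterialSet
from .meshing import Mesh

P_REF = 20.0e-6  # Pa, SPL reference pressure


@dataclass
class AcousticField:
    """Complex pressure amplitude on the air-cavity nodes at one frequency."""

    p: np.ndarray            # complex (n,)
    frequency: float         # Hz
    nodes: np.ndarray        # global mesh ids of the local nodes
    residual: float = 0.0    # relative discrete residual of the solve

    def spl(self) -> np.ndarray:
        return spl_from_pressure(self.p)


def spl_from_pressure(p) -> np.ndarray:
    """SPL in dB re 20 uPa of complex amplitude(s); |p| = 0 clamps to 0 dB."""
    mag = np.abs(np.asarray(p, dtype=complex))
    tiny = mag < P_REF
    if np.any(tiny & (mag == 0.0)):
        warnings.warn("zero acoustic pressure clamped to 0 dB re 20 uPa")
    return 20.0 * np.log10(np.maximum(mag, P_REF) / P_REF)


def extract_sswd_source(history: np.ndarray, normals: np.ndarray, dt: float,
                        frequency: float, period: float):
    """Complex normal-displacement amplitude at one frequency by DFT.

    Parameters
    ----------
    history : (n_steps, n_nodes, 2)
        Displacement samples over (at least) the last cardiac cycle at
        uniform spacing ``dt``; the trailing integer number of periods is
        used.
    normals : (n_nodes, 2)
        Outward (into-air) unit normals per node.
    frequency : float
        Requested analysis frequency; snapped to the nearest harmonic of
        1/period resolvable on the window.

    Returns
    -------
    amplitudes : complex (n_nodes,), actual_frequency : float
    """
    n_cycle = int(round(period / dt))
    if history.shape[0] < n_cycle:
        raise ValueError("displacement history is shorter than one cycle")
    window = history[-n_cycle:]
    u_n = np.einsum("tnk,nk->tn", window, normals)
    m = int(round(frequency * period))
    m = max(1, min(m, n_cycle // 2 - 1 if n_cycle > 3 else 1))
    j = np.arange(n_cycle)
    phase = np.exp(-2.0j * np.pi * m * j / n_cycle)
    amp = (2.0 / n_cycle) * phase @ u_n
    return amp, m / period


def dominant_harmonic(history: np.ndarray, normals: np.ndarray,
                      weights: np.ndarray, dt: float, period: float) -> float:
    """Frequency (Hz) of the strongest harmonic of the SSWD normal motion."""
    n_cycle = int(round(period / dt))
    if history.shape[0] < n_cycle:
        raise ValueError("displacement history is shorter than one cycle")
    u_n = np.einsum("tnk,nk->tn", history[-n_cycle:], normals)
    spec = np.fft.rfft(u_n, axis=0)
    power = np.abs(spec[1:]) @ weights  # skip the mean
    m = 1 + int(np.argmax(power))
    return m / period


class AcousticSolver:
    """P1 Helmholtz solver on the air region with impedance boundaries."""

    def __init__(self, mesh: Mesh, materials: MaterialSet,
                 region: str = "air", source_marker: str = "sswd",
                 impedance_markers: tuple[str, ...] = ("bone_air",),
                 receiver_marker: str = "tympanum",
                 receiver_impedance: float | None = None):
        self.mesh = mesh
        self.mat = materials
        self.rho = materials.air_density
        self.c0 = materials.sound_speed
        self.source_marker = source_marker
        tris_g = mesh.region_tris(region)
        nodes = np.unique(tris_g)
        self.nodes = nodes
        g2l = -np.ones(mesh.num_nodes, dtype=np.int64)
        g2l[nodes] = np.arange(len(nodes))
        self.g2l = g2l
        self.tris = g2l[tris_g]
        self.pts = mesh.points[nodes]
        self.n = len(nodes)
        self._assemble()
        self._imp = [(mk, materials.impedance) for mk in impedance_markers]
        self._imp.append((receiver_marker,
                          receiver_impedance if receiver_impedance is not None
                          else materials.impedance))
        self._boundary_mass = {mk: self._edge_mass(mk) for mk, _ in self._imp}

    def _assemble(self) -> None:
        p = self.pts
        t = self.tris
        x, y = p[t, 0], p[t, 1]
        area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                      - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
        a2 = 2.0 * area
        b = np.stack([(y[:, 1] - y[:, 2]) / a2, (y[:, 2] - y[:, 0]) / a2,
                      (y[:, 0] - y[:, 1]) / a2], axis=1)
        c = np.stack([(x[:, 2] - x[:, 1]) / a2, (x[:, 0] - x[:, 2]) / a2,
                      (x[:, 1] - x[:, 0]) / a2], axis=1)
        Ke = area[:, None, None] * (b[:, :, None] * b[:, None, :]
                                    + c[:, :, None] * c[:, None, :])
        ident = np.full((len(area), 3, 3), 1.0) + np.eye(3)[None]
        Me = area[:, None, None] / 12.0 * ident
        rows = np.repeat(t[:, :, None], 3, axis=2).ravel()
        cols = np.repeat(t[:, None, :], 3, axis=1).ravel()
        self.K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                               shape=(self.n, self.n)).tocsr()
        self.M = sp.coo_matrix((Me.ravel(), (rows, cols)),
                               shape=(self.n, self.n)).tocsr()

    def _edge_mass(self, marker: str) -> sp.csr_matrix:
        """Boundary mass matrix int phi_i phi_j over marked edges."""
        rows, cols, data = [], [], []
        for a_g, b_g in self.mesh.marker_edges(marker):
            a, b = self.g2l[a_g], self.g2l[b_g]
            if a < 0 or b < 0:
                continue
            length = float(np.hypot(*(self.pts[b] - self.pts[a])))
            for (i, j, v) in ((a, a, length / 3), (b, b, length / 3),
                              (a, b, length / 6), (b, a, length / 6)):
                rows.append(i); cols.append(j); data.append(v)
        return sp.coo_matrix((data, (rows, cols)),
                             shape=(self.n, self.n)).tocsr()

    def source_nodes(self) -> np.ndarray:
        """Global mesh ids of the SSWD source boundary nodes."""
        g = self.mesh.marker_nodes(self.source_marker)
        return g[self.g2l[g] >= 0]

    def solve(self, frequency: float, source_amplitude: np.ndarray,
              source_nodes_global: np.ndarray | None = None) -> AcousticField:
        """Helmholtz solve with normal-acceleration source on the SSWD patch.

        ``source_amplitude``: complex normal displacement per source node
        (outward into the air); the Neumann datum is rho omega^2 u_n.
        """
        if frequency <= 0:
            raise ValueError("frequency must be positive")
        omega = 2.0 * np.pi * frequency
        k = omega / self.c0
        A = (self.K - k * k * self.M).astype(complex)
        for mk, z in self._imp:
            A = A + (1.0j * omega * self.rho / z) * self._boundary_mass[mk]

        if source_nodes_global is None:
            source_nodes_global = self.source_nodes()
        amp = np.zeros(self.n, dtype=complex)
        amp[self.g2l[source_nodes_global]] = source_amplitude
        rhs = self.rho * omega * omega * \
            self._edge_mass(self.source_marker).dot(amp)

        p = spla.spsolve(A.tocsc(), rhs)
        denom = max(float(np.linalg.norm(rhs)), 1.0e-300)
        res = float(np.linalg.norm(A.dot(p) - rhs)) / denom
        if res > 1.0e-3:
            est = abs(A.diagonal()).max() / max(abs(A.diagonal()).min(), 1e-300)
            warnings.warn(f"Helmholtz residual {res:.2e} above 1e-3 "
                          f"(possible resonance; diagonal ratio {est:.1e})")
        return AcousticField(p=p, frequency=frequency, nodes=self.nodes,
                             residual=res)

    def spl_at(self, field: AcousticField, marker: str) -> np.ndarray:
        """Per-node SPL (dB) on a marked boundary of the air region."""
        g = self.mesh.marker_nodes(marker)
        g = g[self.g2l[g] >= 0]
        return spl_from_pressure(field.p[self.g2l[g]])

    def spl_edge_average(self, field: AcousticField, marker: str) -> float:
        """Edge-length weighted average SPL over a marked boundary."""
        vals, weights = [], []
        for a_g, b_g in self.mesh.marker_edges(marker):
            a, b = self.g2l[a_g], self.g2l[b_g]
            if a < 0 or b < 0:
                continue
            length = float(np.hypot(*(self.pts[b] - self.pts[a])))
            p_mid = 0.5 * (field.p[a] + field.p[b])
            vals.append(float(spl_from_pressure(p_mid)))
            weights.append(length)
        from .metrics import area_weighted_average
        return area_weighted_average(np.array(vals), np.array(weights))
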