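"""Conforming triangulation of the lumen / wall / bone / air regions.

The geometry is parametric in centerline coordinates (s, n), so the mesh is
a mapped structured grid: a shared set of arclength columns crosses every
region, and each region stacks its own rows on top of the previous one
(lumen -> wall -> bone or dehiscence notch -> air cell).  Interface nodes
are therefore shared *by identity* between regions, uniform midpoint
refinement nests exactly, and generation is fully deterministic.

Two boundary-layer rows (heights h/4 and h/2) line both lumen walls; the
in-plane spacing is h/sqrt(2) so that every element circumdiameter stays
below the requested h and the minimum triangle angle stays above 15 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import VesselGeometry

REGIONS = ("lumen", "wall", "bone", "air")

#: boundary / interface edge markers used by the solvers
MARKERS = ("inlet", "outlet", "lateral", "interface", "wall_end",
           "medial", "sswd", "bone_air", "bone_outer", "tympanum")

MAX_TRIANGLES = 600_000


@dataclass
class Mesh:
    """Tagged triangulated multi-region mesh (coordinates in metres)."""

    points: np.ndarray            # (N, 2)
    triangles: np.ndarray         # (M, 3) node indices, ccw
    tri_region: np.ndarray        # (M,) region ids
    regions: dict[str, int]
    edges: np.ndarray             # (E, 2) marked boundary/interface edges
    edge_marker: np.ndarray       # (E,)
    markers: dict[str, int]
    h: float
    n_layers: int = 0
    node_s: np.ndarray | None = None   # arclength coordinate per node
    node_n: np.ndarray | None = None   # normal offset per node

    # -- queries -----------------------------------------------------------
    @property
    def num_nodes(self) -> int:
        return len(self.points)

    def region_tris(self, name: str) -> np.ndarray:
        return self.triangles[self.tri_region == self.regions[name]]

    def marker_edges(self, name: str) -> np.ndarray:
        return self.edges[self.edge_marker == self.markers[name]]

    def marker_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.marker_edges(name))

    def tri_areas(self, tris: np.ndarray | None = None) -> np.ndarray:
        t = self.triangles if tris is None else tris
        p = self.points
        v1 = p[t[:, 1]] - p[t[:, 0]]
        v2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.points[edges[:, 1]] - self.points[edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def region_area(self, name: str) -> float:
        return float(np.sum(self.tri_areas(self.region_tris(name))))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _build_columns(geom: VesselGeometry, delta: float) -> np.ndarray:
    """Arclength columns: every geometric breakpoint is a column, and each
    breakpoint interval is subdivided to a local spacing of at most
    ``delta / (max medial stretch)``.

    On the junction bend the medial regions are geometrically stretched by
    the factor 1 + n/R, so columns are packed more densely there to keep
    physical element sizes below the target.
    """
    n_top = geom.half_width + geom.div_depth + geom.wall_thickness
    n_cav = geom.cavity_ceiling + geom.cavity_height if geom.cavity_enabled else n_top
    bps = geom.breakpoints()
    h = delta * math.sqrt(2.0)
    # smallest row height adjacent to a sloped wall: first boundary-layer row
    # (h/4) or, on very coarse meshes without layers, an interior row
    dn_ref = min(h / 4.0, float(np.min(geom.width(bps))) / 3.0)
    cols = [0.0]
    for b0, b1 in zip(bps[:-1], bps[1:]):
        n_here = n_top
        if geom.cavity_enabled and b1 > geom.cavity_start and b0 < geom.cavity_end:
            n_here = n_cav
        probe = np.linspace(b0, b1, 16)
        stretch = float(np.max(geom.stretch(probe, np.full(16, n_here))))
        # wall-profile slope bounds the column spacing: with the shorter
        # quad diagonal, shear up to ~2 row heights keeps angles > 15 deg
        slope = max(float(np.max(np.abs(np.gradient(geom.w_lat(probe), probe)))),
                    float(np.max(np.abs(np.gradient(geom.w_med(probe), probe)))),
                    1.0e-9)
        d_local = min(delta / max(stretch, 1.0), 2.0 * dn_ref / slope)
        m = max(1, int(math.ceil((b1 - b0) / d_local)))
        cols.extend(np.linspace(b0, b1, m + 1)[1:].tolist())
    return np.asarray(cols)


def _lumen_offsets(geom: VesselGeometry, s_cols: np.ndarray, h: float,
                   delta: float, n_layers: int) -> np.ndarray:
    """Per-column offset rows across the lumen, boundary layers at both walls."""
    w_lat = geom.w_lat(s_cols)
    w_med = geom.w_med(s_cols)
    widths = w_lat + w_med
    # cumulative boundary-layer heights: h/4, then h/2 (n_layers=2)
    bl = np.array([h / 4.0 * (2.0 ** (j + 1) - 1.0) for j in range(n_layers)])
    bl_total = bl[-1] if n_layers else 0.0
    if np.min(widths) < 2.0 * bl_total + delta:
        bl = np.array([])
        bl_total = 0.0
    span_max = np.max(widths) - 2.0 * bl_total
    k_int = max(2, int(math.ceil(span_max / delta)))
    rows = []
    for i in range(len(s_cols)):
        lo, hi = -w_lat[i], w_med[i]
        inner0, inner1 = lo + bl_total, hi - bl_total
        col = np.concatenate([
            [lo], lo + bl,
            np.linspace(inner0, inner1, k_int + 1)[1:-1],
            hi - bl[::-1], [hi],
        ])
        rows.append(col)
    return np.asarray(rows)  # (ncols, n_rows)


def _strip_rows(thickness: float, delta: float) -> int:
    return max(1, int(math.ceil(thickness / delta)))


def generate_mesh(geom: VesselGeometry, h_max: float,
                  n_layers: int = 2) -> Mesh:
    """Triangulate all regions of a vessel geometry.

    Parameters
    ----------
    h_max : float
        Maximum element circumdiameter in metres.
    n_layers : int
        Structured boundary-layer rows along both lumen walls (first-row
        height ``h_max/4``).
    """
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    delta = h_max / math.sqrt(2.0)
    s_cols = _build_columns(geom, delta)
    nc = len(s_cols)

    lumen_off = _lumen_offsets(geom, s_cols, h_max, delta, n_layers)
    wall_rows = _strip_rows(geom.wall_thickness, delta)
    bone_rows = _strip_rows(geom.bone_thickness, delta)
    air_rows = _strip_rows(geom.cavity_height, delta) if geom.cavity_enabled else 0

    est = 2 * nc * (lumen_off.shape[1] + wall_rows + bone_rows + air_rows)
    if est > MAX_TRIANGLES:
        raise ValueError(
            f"h_max={h_max:g} m implies ~{est} triangles (cap {MAX_TRIANGLES})")

    eps = 1.0e-12
    in_cavity = np.zeros(nc, bool)
    in_sswd = np.zeros(nc, bool)
    if geom.cavity_enabled:
        in_cavity = (s_cols >= geom.cavity_start - eps) & (s_cols <= geom.cavity_end + eps)
        in_sswd = (s_cols >= geom.sswd_start - eps) & (s_cols <= geom.sswd_end + eps)
        in_tymp = (s_cols >= geom.tympanum_start - eps) & (s_cols <= geom.tympanum_end + eps)
    else:
        in_tymp = np.zeros(nc, bool)

    yc = geom.cavity_ceiling
    w_med = geom.w_med(s_cols)
    wall_top = w_med + geom.wall_thickness

    # -- node stacks per column -------------------------------------------
    pts_s: list[float] = []
    pts_n: list[float] = []
    col_lumen: list[np.ndarray] = []
    col_wall: list[np.ndarray] = []
    col_mid: list[np.ndarray | None] = []   # bone strip or dehiscence notch
    col_air: list[np.ndarray | None] = []

    def add_nodes(s_val, offs):
        start = len(pts_s)
        pts_s.extend([s_val] * len(offs))
        pts_n.extend(offs.tolist())
        return np.arange(start, start + len(offs))

    for i in range(nc):
        s_val = s_cols[i]
        lum = add_nodes(s_val, lumen_off[i])
        col_lumen.append(lum)
        wall_off = np.linspace(w_med[i], wall_top[i], wall_rows + 1)[1:]
        wal = np.concatenate([[lum[-1]], add_nodes(s_val, wall_off)])
        col_wall.append(wal)
        if in_cavity[i]:
            mid_off = np.linspace(wall_top[i], yc, bone_rows + 1)[1:]
            mid = np.concatenate([[wal[-1]], add_nodes(s_val, mid_off)])
            col_mid.append(mid)
            air_off = np.linspace(yc, yc + geom.cavity_height, air_rows + 1)[1:]
            air = np.concatenate([[mid[-1]], add_nodes(s_val, air_off)])
            col_air.append(air)
        else:
            col_mid.append(None)
            col_air.append(None)

    node_s = np.asarray(pts_s)
    node_n = np.asarray(pts_n)
    points = geom.map_to_xy(node_s, node_n)

    # -- cells -------------------------------------------------------------
    regions = {name: k for k, name in enumerate(REGIONS)}
    markers = {name: k for k, name in enumerate(MARKERS)}
    tris: list[tuple[int, int, int]] = []
    tri_region: list[int] = []
    edges: list[tuple[int, int]] = []
    edge_marker: list[int] = []

    def emit_strip(ca, cb, region, parity):
        """Triangulate the quad strip between node columns ca and cb.

        For sheared quads (rows following a sloped wall) the shorter
        diagonal is chosen, which keeps the triangles well-shaped; square
        quads alternate diagonals by parity.
        """
        rid = regions[region]
        for j in range(len(ca) - 1):
            a, b = ca[j], ca[j + 1]
            c, d = cb[j], cb[j + 1]
            # quad: a (col i, row j), b (col i, row j+1), c/d (col i+1)
            d_ad = np.hypot(*(points[d] - points[a]))
            d_cb = np.hypot(*(points[b] - points[c]))
            if abs(d_ad - d_cb) > 1.0e-9 * (d_ad + d_cb):
                use_ad = d_ad < d_cb
            else:
                use_ad = (parity + j) % 2 == 0
            if use_ad:
                tris.extend([(a, c, d), (a, d, b)])
            else:
                tris.extend([(a, c, b), (b, c, d)])
            tri_region.extend([rid, rid])

    def mark_span(col, j0, j1, marker):
        mid = markers[marker]
        for j in range(j0, j1):
            edges.append((col[j], col[j + 1]))
            edge_marker.append(mid)

    for i in range(nc - 1):
        emit_strip(col_lumen[i], col_lumen[i + 1], "lumen", i)
        emit_strip(col_wall[i], col_wall[i + 1], "wall", i)
        strip_cav = in_cavity[i] and in_cavity[i + 1]
        strip_sswd = in_sswd[i] and in_sswd[i + 1]
        if strip_cav:
            emit_strip(col_mid[i], col_mid[i + 1], "air" if strip_sswd else "bone", i)
            emit_strip(col_air[i], col_air[i + 1], "air", i)

        # horizontal boundary/interface edges of this strip
        lum_a, lum_b = col_lumen[i], col_lumen[i + 1]
        edges.append((lum_a[0], lum_b[0])); edge_marker.append(markers["lateral"])
        edges.append((lum_a[-1], lum_b[-1])); edge_marker.append(markers["interface"])
        wall_a, wall_b = col_wall[i], col_wall[i + 1]
        top_marker = "sswd" if strip_sswd else "medial"
        edges.append((wall_a[-1], wall_b[-1])); edge_marker.append(markers[top_marker])
        if strip_cav:
            if not strip_sswd:  # bone top faces air
                edges.append((col_mid[i][-1], col_mid[i + 1][-1]))
                edge_marker.append(markers["bone_air"])
            edges.append((col_air[i][-1], col_air[i + 1][-1]))
            edge_marker.append(markers["tympanum" if (in_tymp[i] and in_tymp[i + 1])
                                       else "bone_air"])

    # vertical edges: lumen inlet/outlet, wall ends, cavity sides, notch sides
    mark_span(col_lumen[0], 0, len(col_lumen[0]) - 1, "inlet")
    mark_span(col_lumen[-1], 0, len(col_lumen[-1]) - 1, "outlet")
    mark_span(col_wall[0], 0, len(col_wall[0]) - 1, "wall_end")
    mark_span(col_wall[-1], 0, len(col_wall[-1]) - 1, "wall_end")
    for i in range(nc):
        if col_mid[i] is None:
            continue
        left_cav = i > 0 and col_mid[i - 1] is not None
        right_cav = i + 1 < nc and col_mid[i + 1] is not None
        if not left_cav or not right_cav:  # cavity footprint end faces
            mark_span(col_mid[i], 0, len(col_mid[i]) - 1, "bone_outer")
            mark_span(col_air[i], 0, len(col_air[i]) - 1, "bone_air")
        else:
            left_sswd = in_sswd[i - 1] and in_sswd[i]
            right_sswd = in_sswd[i] and in_sswd[i + 1]
            if left_sswd != right_sswd:  # vertical bone face of the notch
                mark_span(col_mid[i], 0, len(col_mid[i]) - 1, "bone_air")

    mesh = Mesh(
        points=points,
        triangles=np.asarray(tris, dtype=np.int64),
        tri_region=np.asarray(tri_region, dtype=np.int32),
        regions=regions,
        edges=np.asarray(edges, dtype=np.int64),
        edge_marker=np.asarray(edge_marker, dtype=np.int32),
        markers=markers,
        h=h_max,
        n_layers=n_layers,
        node_s=node_s,
        node_n=node_n,
    )
    areas = mesh.tri_areas()
    if np.any(areas <= 0):
        raise ValueError("geometry self-intersection: inverted elements produced")
    min_angle = mesh_quality(mesh)["min_angle_deg"]
    if min_angle <= 15.0:
        raise ValueError(
            f"h_max={h_max:g} m is too coarse for this geometry: minimum "
            f"triangle angle {min_angle:.1f} deg (must exceed 15 deg); "
            "reduce h_max")
    return mesh


def rectangle_mesh(width: float, height: float, nx: int, ny: int,
                   region: str = "lumen",
                   marker_names: tuple[str, str, str, str] =
                   ("inlet", "outlet", "lateral", "interface")) -> Mesh:
    """Structured triangulation of [0,width] x [0,height].

    ``marker_names`` tags the (left, right, bottom, top) boundaries; names
    may be arbitrary.  Used for verification oracles and unit tests.
    """
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    points = np.stack([xx.ravel(), yy.ravel()], axis=-1)

    def nid(i, j):
        return i * (ny + 1) + j

    tris, edges, marks = [], [], []
    names = list(dict.fromkeys(list(marker_names)))
    markers = {nm: k for k, nm in enumerate(names)}
    left, right, bottom, top = (markers[m] for m in marker_names)
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i, j + 1), nid(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris.extend([(a, b, d), (a, d, c)])
            else:
                tris.extend([(a, b, c), (b, d, c)])
    for j in range(ny):
        edges.append((nid(0, j), nid(0, j + 1))); marks.append(left)
        edges.append((nid(nx, j), nid(nx, j + 1))); marks.append(right)
    for i in range(nx):
        edges.append((nid(i, 0), nid(i + 1, 0))); marks.append(bottom)
        edges.append((nid(i, ny), nid(i + 1, ny))); marks.append(top)
    tris = np.asarray(tris, dtype=np.int64)
    return Mesh(
        points=points, triangles=tris,
        tri_region=np.zeros(len(tris), dtype=np.int32),
        regions={region: 0},
        edges=np.asarray(edges, dtype=np.int64),
        edge_marker=np.asarray(marks, dtype=np.int32),
        markers=markers,
        h=max(width / nx, height / ny) * math.sqrt(2.0),
        node_s=points[:, 0].copy(), node_n=points[:, 1].copy(),
    )


# ---------------------------------------------------------------------------
# refinement and quality
# ---------------------------------------------------------------------------

def refine_mesh(mesh: Mesh) -> Mesh:
    """Uniform midpoint refinement: each triangle splits into four.

    Midpoint nodes are created once per unique edge, so region interfaces
    stay conforming bit-exactly, areas are preserved, and markers are
    inherited by the two half-edges.
    """
    t = mesh.triangles
    pairs = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    pairs = np.sort(pairs, axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    n0 = mesh.num_nodes
    mid_ids = n0 + np.arange(len(uniq))
    mid_pts = 0.5 * (mesh.points[uniq[:, 0]] + mesh.points[uniq[:, 1]])
    points = np.vstack([mesh.points, mid_pts])

    m01 = mid_ids[inverse[: len(t)]]
    m12 = mid_ids[inverse[len(t): 2 * len(t)]]
    m20 = mid_ids[inverse[2 * len(t):]]
    tris = np.concatenate([
        np.stack([t[:, 0], m01, m20], axis=1),
        np.stack([m01, t[:, 1], m12], axis=1),
        np.stack([m20, m12, t[:, 2]], axis=1),
        np.stack([m01, m12, m20], axis=1),
    ])
    tri_region = np.tile(mesh.tri_region, 4)

    # split marked edges, looking up the shared midpoint ids
    lut = {(int(a), int(b)): int(m) for (a, b), m in zip(uniq, mid_ids)}
    new_edges, new_marks = [], []
    for (a, b), mk in zip(mesh.edges, mesh.edge_marker):
        key = (int(min(a, b)), int(max(a, b)))
        m = lut[key]
        new_edges.extend([(a, m), (m, b)])
        new_marks.extend([mk, mk])

    node_s = node_n = None
    if mesh.node_s is not None:
        node_s = np.concatenate([mesh.node_s,
                                 0.5 * (mesh.node_s[uniq[:, 0]] + mesh.node_s[uniq[:, 1]])])
        node_n = np.concatenate([mesh.node_n,
                                 0.5 * (mesh.node_n[uniq[:, 0]] + mesh.node_n[uniq[:, 1]])])
    return Mesh(
        points=points, triangles=tris, tri_region=tri_region,
        regions=dict(mesh.regions),
        edges=np.asarray(new_edges, dtype=np.int64),
        edge_marker=np.asarray(new_marks, dtype=np.int32),
        markers=dict(mesh.markers),
        h=mesh.h / 2.0, n_layers=mesh.n_layers,
        node_s=node_s, node_n=node_n,
    )


def mesh_quality(mesh: Mesh) -> dict:
    """Angle and aspect-ratio statistics plus per-region element counts."""
    p = mesh.points
    t = mesh.triangles
    v = [p[t[:, (k + 1) % 3]] - p[t[:, k]] for k in range(3)]
    lengths = np.stack([np.hypot(e[:, 0], e[:, 1]) for e in v], axis=1)
    angles = np.empty_like(lengths)
    for k in range(3):
        e1 = v[k]
        e2 = -v[(k + 2) % 3]
        cosang = np.sum(e1 * e2, axis=1) / (lengths[:, k] * lengths[:, (k + 2) % 3])
        angles[:, k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    aspect = lengths.max(axis=1) / lengths.min(axis=1)
    hist, bin_edges = np.histogram(aspect, bins=[1, 1.5, 2, 3, 4, 6, np.inf])
    counts = {name: int(np.sum(mesh.tri_region == rid))
              for name, rid in mesh.regions.items() if np.any(mesh.tri_region == rid)}
    return {
        "min_angle_deg": float(angles.min()),
        "max_angle_deg": float(angles.max()),
        "max_aspect": float(aspect.max()),
        "aspect_histogram": {f"<{b}": int(c) for b, c in zip(bin_edges[1:], hist)},
        "region_counts": counts,
        "num_nodes": mesh.num_nodes,
        "num_triangles": len(t),
        "max_circumdiameter": float(np.max(
            lengths.prod(axis=1) / (2.0 * mesh.tri_areas()))),
    }


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def write_vtk(mesh: Mesh, path, point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured-grid writer (region id as cell data)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsinuflow mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.num_nodes} double\n")
        for x, y in mesh.points:
            fh.write(f"{x:.12g} {y:.12g} 0\n")
        m = len(mesh.triangles)
        fh.write(f"CELLS {m} {4 * m}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("5\n" * m)
        fh.write(f"CELL_DATA {m}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.tri_region) + "\n")
        if cell_data:
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.num_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        fh.write(f"{row[0]:.9g} {row[1]:.9g} 0\n")


def write_msh(mesh: Mesh, path) -> None:
    """Gmsh MSH 2.2 ASCII writer; regions and markers become physical groups.

    Marker groups use ids offset by 100 to keep them disjoint from regions.
    """
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n")
        names = [(2, rid + 1, nm) for nm, rid in mesh.regions.items()]
        names += [(1, mid + 101, nm) for nm, mid in mesh.markers.items()]
        fh.write(f"{len(names)}\n")
        for dim, tag, nm in names:
            fh.write(f'{dim} {tag} "{nm}"\n')
        fh.write("$EndPhysicalNames\n$Nodes\n")
        fh.write(f"{mesh.num_nodes}\n")
        for i, (x, y) in enumerate(mesh.points, start=1):
            fh.write(f"{i} {x:.12g} {y:.12g} 0\n")
        fh.write("$EndNodes\n$Elements\n")
        fh.write(f"{len(mesh.edges) + len(mesh.triangles)}\n")
        eid = 1
        for (a, b), mk in zip(mesh.edges, mesh.edge_marker):
            fh.write(f"{eid} 1 2 {mk + 101} {mk + 101} {a + 1} {b + 1}\n")
            eid += 1
        for tri, rid in zip(mesh.triangles, mesh.tri_region):
            fh.write(f"{eid} 2 2 {rid + 1} {rid + 1} "
                     f"{tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
            eid += 1
        fh.write("$EndElements\n")


def read_msh(path) -> Mesh:
    """Read back a MSH 2.2 file written by :func:`write_msh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def seek(tag):
        nonlocal i
        while lines[i].strip() != tag:
            i += 1
        i += 1

    seek("$PhysicalNames")
    n_names = int(lines[i]); i += 1
    regions, markers = {}, {}
    for _ in range(n_names):
        dim, tag, nm = lines[i].split(maxsplit=2); i += 1
        nm = nm.strip('"')
        if int(dim) == 2:
            regions[nm] = int(tag) - 1
        else:
            markers[nm] = int(tag) - 101
    seek("$Nodes")
    n_nodes = int(lines[i]); i += 1
    pts = np.empty((n_nodes, 2))
    for k in range(n_nodes):
        parts = lines[i].split(); i += 1
        pts[k] = (float(parts[1]), float(parts[2]))
    seek("$Elements")
    n_elem = int(lines[i]); i += 1
    tris, tri_region, edges, edge_marker = [], [], [], []
    for _ in range(n_elem):
        parts = lines[i].split(); i += 1
        etype = int(parts[1]); phys = int(parts[3])
        nodes = [int(v) - 1 for v in parts[5:]]
        if etype == 1:
            edges.append(nodes); edge_marker.append(phys - 101)
        elif etype == 2:
            tris.append(nodes); tri_region.append(phys - 1)
    return Mesh(
        points=pts,
        triangles=np.asarray(tris, dtype=np.int64),
        tri_region=np.asarray(tri_region, dtype=np.int32),
        regions=regions,
        edges=np.asarray(edges, dtype=np.int64),
        edge_marker=np.asarray(edge_marker, dtype=np.int32),
        markers=markers,
        h=float("nan"),
    )
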