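"""Parametric 2D sinus geometry: curved channel, stenosis, stent, morphometrics.

The vessel is described by an analytic centerline (straight transverse-sinus
segment, circular junction bend, straight sigmoid-sinus segment) and two
half-width profiles: the rigid lateral wall at offset ``-w_lat(s)`` and the
elastic medial wall at ``+w_med(s)``.  An arachnoid-granulation stenosis is a
smooth cosine indentation of the lateral wall (single- or multi-lobed); the
sigmoid-sinus diverticulum is a cosine bulge of the medial wall at the
junction.  On the medial side sit, in order, the 0.5 mm elastic wall strip,
the temporal-bone strip, and the air cell (TBAC); over the wall-dehiscence
(SSWD) patch the bone is absent and the wall faces air directly.

All public quantities are SI (metres); configuration input is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ScenarioConfig, GeometryParams

MM = 1.0e-3


def rate_from_measures(throat: float, nominal: float) -> float:
    """Residual-lumen rate in percent: 100 x throat measure / nominal measure.

    In 2D the lumen measure of a cross-section is its width.
    """
    if nominal <= 0:
        raise ValueError("nominal lumen measure must be positive")
    if throat <= 0:
        raise ValueError("degenerate (zero-width) throat")
    return 100.0 * throat / nominal


@dataclass(frozen=True)
class VesselGeometry:
    """Immutable analytic description of one scenario geometry (SI units)."""

    ts_length: float
    bend_radius: float
    bend_angle: float  # radians
    ss_length: float
    half_width: float
    wall_thickness: float
    bone_thickness: float
    # stenosis (indentation of the lateral wall)
    sten_start: float
    sten_end: float
    sten_depth: float
    sten_lobes: int
    sten_relief: float
    sten_position: str
    # diverticulum (bulge of the medial wall)
    div_center: float
    div_depth: float
    div_extent: float
    # dehiscence / cavity layout
    sswd_start: float
    sswd_end: float
    cavity_enabled: bool
    cavity_start: float
    cavity_end: float
    cavity_height: float
    tympanum_start: float
    tympanum_end: float
    stented: bool = False

    # -- centerline -------------------------------------------------------
    @property
    def arc_length(self) -> float:
        return self.bend_radius * self.bend_angle

    @property
    def total_length(self) -> float:
        return self.ts_length + self.arc_length + self.ss_length

    @property
    def cavity_ceiling(self) -> float:
        """Offset of the bone-air interface under the cavity (constant)."""
        return self.half_width + self.wall_thickness + self.bone_thickness

    def tangent_angle(self, s):
        s = np.asarray(s, dtype=float)
        l1, la = self.ts_length, self.arc_length
        th = np.where(s <= l1, 0.0,
                      np.where(s <= l1 + la, -(s - l1) / self.bend_radius,
                               -self.bend_angle))
        return th

    def curvature(self, s):
        s = np.asarray(s, dtype=float)
        l1, la = self.ts_length, self.arc_length
        on_arc = (s > l1) & (s < l1 + la)
        return np.where(on_arc, -1.0 / self.bend_radius, 0.0)

    def centerline_point(self, s):
        s = np.asarray(s, dtype=float)
        l1, la, r = self.ts_length, self.arc_length, self.bend_radius
        x = np.empty_like(s)
        y = np.empty_like(s)
        seg1 = s <= l1
        x[seg1], y[seg1] = s[seg1], 0.0
        if self.bend_angle > 0:
            seg2 = (s > l1) & (s <= l1 + la)
            phi = (s[seg2] - l1) / r
            x[seg2] = l1 + r * np.sin(phi)
            y[seg2] = -r + r * np.cos(phi)
            seg3 = s > l1 + la
            phi_e = self.bend_angle
            xe, ye = l1 + r * np.sin(phi_e), -r + r * np.cos(phi_e)
            te = np.array([np.cos(phi_e), -np.sin(phi_e)])
            x[seg3] = xe + (s[seg3] - l1 - la) * te[0]
            y[seg3] = ye + (s[seg3] - l1 - la) * te[1]
        else:
            rest = ~seg1
            x[rest], y[rest] = s[rest], 0.0
        return np.stack([x, y], axis=-1)

    def tangent(self, s):
        th = self.tangent_angle(s)
        return np.stack([np.cos(th), np.sin(th)], axis=-1)

    def normal(self, s):
        """Left (medial) unit normal."""
        th = self.tangent_angle(s)
        return np.stack([-np.sin(th), np.cos(th)], axis=-1)

    def map_to_xy(self, s, n):
        """Map centerline coordinates (s, offset n) to the plane."""
        s = np.asarray(s, dtype=float)
        n = np.asarray(n, dtype=float)
        return self.centerline_point(s) + n[..., None] * self.normal(s)

    def stretch(self, s, n):
        """Metric factor |d(map)/ds| for a level line of constant n."""
        return 1.0 - np.asarray(n) * self.curvature(s)

    # -- wall profiles ----------------------------------------------------
    def stenosis_profile(self, s):
        """Indentation depth of the lateral wall at arclength s (>= 0)."""
        s = np.asarray(s, dtype=float)
        d = np.zeros_like(s)
        if self.sten_depth <= 0:
            return d
        s0, s1 = self.sten_start, self.sten_end
        length = s1 - s0
        inside = (s >= s0) & (s <= s1)
        xi = (s - s0) / length  # 0..1 across the extent
        env = np.where(inside, np.cos(np.pi * (xi - 0.5)) ** 2, 0.0)
        if self.sten_lobes == 1:
            d = self.sten_depth * env
        else:
            lobe_len = length / self.sten_lobes
            lobes = np.zeros_like(s)
            for i in range(self.sten_lobes):
                ci = s0 + (i + 0.5) * lobe_len
                xi_l = (s - ci) / lobe_len
                in_l = np.abs(xi_l) <= 0.5
                lobes = np.maximum(lobes, np.where(in_l, np.cos(np.pi * xi_l) ** 2, 0.0))
            d = self.sten_depth * np.maximum(lobes, self.sten_relief * env)
        return d

    def diverticulum_profile(self, s):
        s = np.asarray(s, dtype=float)
        if self.div_depth <= 0:
            return np.zeros_like(s)
        xi = (s - self.div_center) / self.div_extent
        inside = np.abs(xi) <= 0.5
        return np.where(inside, self.div_depth * np.cos(np.pi * xi) ** 2, 0.0)

    def w_lat(self, s):
        return self.half_width - self.stenosis_profile(s)

    def w_med(self, s):
        return self.half_width + self.diverticulum_profile(s)

    def width(self, s):
        return self.w_lat(s) + self.w_med(s)

    def lobe_centers(self) -> np.ndarray:
        length = self.sten_end - self.sten_start
        if length <= 0:
            return np.array([])
        k = self.sten_lobes
        return self.sten_start + (np.arange(k) + 0.5) * length / k

    def breakpoints(self) -> np.ndarray:
        """Arclengths the mesh generator must honour exactly."""
        pts = [0.0, self.total_length, self.sten_start, self.sten_end]
        pts += list(self.lobe_centers())
        if self.div_depth > 0:
            pts += [self.div_center - self.div_extent / 2,
                    self.div_center + self.div_extent / 2]
        if self.cavity_enabled:
            pts += [self.cavity_start, self.cavity_end,
                    self.sswd_start, self.sswd_end,
                    self.tympanum_start, self.tympanum_end]
        pts = np.unique(np.clip(np.array(pts), 0.0, self.total_length))
        return pts

    # -- derived measures --------------------------------------------------
    def throat_width(self) -> float:
        if self.sten_end <= self.sten_start:
            return float(self.width(np.array([self.total_length / 2]))[0])
        s = np.unique(np.concatenate([
            np.linspace(self.sten_start, self.sten_end, 2001),
            self.lobe_centers()]))
        return float(np.min(self.width(s)))

    def boundary_tags(self, n_samples: int = 4000) -> dict[str, float]:
        """Arclengths of the tagged pieces of the lumen boundary loop."""
        s = np.linspace(0.0, self.total_length, n_samples)

        def curve_len(offset_fn, sign):
            n = sign * offset_fn(s)
            dn = np.gradient(n, s)
            j = self.stretch(s, n)
            return float(np.trapezoid(np.hypot(j, dn), s))

        return {
            "inlet": float(self.width(np.array([0.0]))[0]),
            "outlet": float(self.width(np.array([self.total_length]))[0]),
            "lateral": curve_len(self.w_lat, -1.0),
            "interface": curve_len(self.w_med, +1.0),
        }

    def medial_arclength(self, s0: float, s1: float, offset: float | None = None,
                         n_samples: int = 800) -> float:
        """Physical arclength of the wall medial surface between s0 and s1."""
        if offset is None:
            offset = self.wall_thickness
        s = np.linspace(s0, s1, n_samples)
        n = self.w_med(s) + offset
        dn = np.gradient(n, s)
        return float(np.trapezoid(np.hypot(self.stretch(s, n), dn), s))

    def air_area(self) -> float:
        """Physical area of the air cell, including the dehiscence notch."""
        if not self.cavity_enabled:
            return 0.0
        s = np.linspace(self.cavity_start, self.cavity_end, 2000)
        yc, top = self.cavity_ceiling, self.cavity_ceiling + self.cavity_height
        in_sswd = (s >= self.sswd_start) & (s <= self.sswd_end)
        n_bot = np.where(in_sswd, self.w_med(s) + self.wall_thickness, yc)
        k = self.curvature(s)
        integrand = (top - n_bot) - 0.5 * k * (top ** 2 - n_bot ** 2)
        return float(np.trapezoid(integrand, s))


def build_geometry(config: ScenarioConfig | GeometryParams,
                   stented: bool | None = None) -> VesselGeometry:
    """Construct the analytic geometry for a scenario.

    If the config is marked ``stented`` (or ``stented=True`` is passed), the
    virtual stent is applied, restoring the nominal lumen over the stenosis
    extent.
    """
    if isinstance(config, ScenarioConfig):
        config.validate()
        g = config.geometry
        if stented is None:
            stented = config.stented
    else:
        config.validate()
        g = config
        stented = bool(stented)

    b = g.half_width * MM
    sten = g.stenosis
    if sten.center is None:
        if sten.position == "middle":
            center = g.ts_length / 2.0
        else:
            # extends from the middle segment into the proximal TS
            # ("proximal" in the flow-referenced venous sense: toward the
            # heart, i.e. toward the TS-SS junction), so the stenosis
            # discharges its jet close to the junction
            center = g.ts_length / 2.0 + sten.length / 2.0
    else:
        center = sten.center
    s0 = (center - sten.length / 2.0) * MM
    s1 = (center + sten.length / 2.0) * MM
    total = g.total_length * MM
    margin = g.end_margin * MM
    if sten.rate < 100.0 and (s0 < margin or s1 > total - margin):
        raise ValueError("stenosis extent overlaps the inlet/outlet sections")
    depth = 2.0 * b * (1.0 - sten.rate / 100.0)

    div = g.diverticulum
    import math
    bend_angle = math.radians(g.bend_angle_deg)
    if div is not None and div.depth > 0:
        dc = (g.ts_length + g.bend_radius * bend_angle / 2.0) * MM \
            if div.center is None else div.center * MM
        dd, de = div.depth * MM, div.extent * MM
    else:
        dc, dd, de = 0.0, 0.0, 1.0

    geom = VesselGeometry(
        ts_length=g.ts_length * MM,
        bend_radius=g.bend_radius * MM,
        bend_angle=bend_angle,
        ss_length=g.ss_length * MM,
        half_width=b,
        wall_thickness=g.wall_thickness * MM,
        bone_thickness=g.bone_thickness * MM,
        sten_start=s0, sten_end=s1,
        sten_depth=0.0 if stented else depth,
        sten_lobes=sten.n_lobes, sten_relief=sten.lobe_relief,
        sten_position=sten.position,
        div_center=dc, div_depth=dd, div_extent=de,
        sswd_start=(g.sswd_center - g.sswd_length / 2.0) * MM,
        sswd_end=(g.sswd_center + g.sswd_length / 2.0) * MM,
        cavity_enabled=g.cavity_enabled,
        cavity_start=g.cavity_start * MM, cavity_end=g.cavity_end * MM,
        cavity_height=g.cavity_height * MM,
        tympanum_start=(g.tympanum_center - g.tympanum_length / 2.0) * MM,
        tympanum_end=(g.tympanum_center + g.tympanum_length / 2.0) * MM,
        stented=stented,
    )
    if np.any(geom.w_lat(np.linspace(0, geom.total_length, 4001)) <= 0):
        raise ValueError("stenosis closes the lumen: half-width must stay positive")
    return geom


def apply_virtual_stent(geom: VesselGeometry) -> VesselGeometry:
    """Restore the nominal lumen over the stenosis extent (idempotent).

    Only the lateral-wall profile inside the recorded stenosis extent
    changes; every other boundary point is untouched.
    """
    return replace(geom, sten_depth=0.0, stented=True)


def stenosis_rate(geom: VesselGeometry) -> float:
    """Residual-lumen rate (%): most-stenosed width over nominal width."""
    return rate_from_measures(geom.throat_width(), 2.0 * geom.half_width)


def morphometrics(geom: VesselGeometry) -> dict:
    """Geometric summary record (mm / mm^2), analogous to a cohort table row."""
    w_in = float(geom.width(np.array([0.0]))[0])
    w_out = float(geom.width(np.array([geom.total_length]))[0])
    rec = {
        "inlet_width_mm": w_in / MM,
        "outlet_width_mm": w_out / MM,
        "stenosis_rate_pct": stenosis_rate(geom),
        "stenosis_position": geom.sten_position,
        "stenosis_length_mm": (geom.sten_end - geom.sten_start) / MM,
        "stented": geom.stented,
        "sswd_length_mm": geom.medial_arclength(geom.sswd_start, geom.sswd_end) / MM,
        "air_cavity_area_mm2": geom.air_area() / MM ** 2,
        "tympanum_length_mm": (geom.tympanum_end - geom.tympanum_start) / MM,
        "diverticulum_depth_mm": geom.div_depth / MM,
    }
    return rec


def export_boundary_csv(geom: VesselGeometry, path, ds: float = 2.0e-4) -> None:
    """Write the tagged lumen boundary polylines as CSV (tag, x, y in metres)."""
    import csv

    n_pts = max(3, int(np.ceil(geom.total_length / ds)) + 1)
    s = np.linspace(0.0, geom.total_length, n_pts)
    rows = []
    lat = geom.map_to_xy(s, -geom.w_lat(s))
    med = geom.map_to_xy(s, geom.w_med(s))
    for x, y in lat:
        rows.append(("lateral", x, y))
    for x, y in med:
        rows.append(("interface", x, y))
    for tag, si in (("inlet", 0.0), ("outlet", geom.total_length)):
        wl = float(geom.w_lat(np.array([si]))[0])
        wm = float(geom.w_med(np.array([si]))[0])
        for n in np.linspace(-wl, wm, 9):
            x, y = geom.map_to_xy(np.array([si]), np.array([n]))[0]
            rows.append((tag, x, y))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tag", "x_m", "y_m"])
        w.writerows(rows)
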