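"""Scenario configuration: parametric description of one synthetic sinus model.

A :class:`ScenarioConfig` fully determines a simulation scenario: the
idealized 2D geometry of the transverse sinus (TS) -> sigmoid sinus (SS)
channel with its stenosis, diverticulum, wall-dehiscence (SSWD) patch and
temporal-bone air cell (TBAC), the material constants, the pulsatile inlet
waveform and the solver settings.  Configs round-trip through YAML and four
presets (``group1_pre/post``, ``group2_pre/post``) emulate the two stenosis
classes of the study cohort: a short intrinsic stenosis in the middle of the
TS (group 1) versus a long multi-lobed stenosis extending from the middle
segment into the proximal TS (group 2).

Geometry fields are in millimetres; materials are SI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

STENOSIS_POSITIONS = ("middle", "middle_and_proximal")


@dataclass
class StenosisSpec:
    """Transverse-sinus stenosis: a smooth cosine indentation of one wall.

    ``rate`` is the residual-lumen convention: 100 x (most-stenosed lumen
    measure / nominal lumen measure), so ``rate=100`` is no stenosis.  A
    multi-lobed profile (``n_lobes > 1``) represents compression by multiple
    continuous arachnoid granulations; ``lobe_relief`` is the fraction of the
    full indentation depth retained between adjacent lobes.
    """

    position: str = "middle"
    length: float = 6.0  # mm, arclength extent of the indentation
    rate: float = 65.0  # percent, residual lumen fraction x 100
    center: float | None = None  # mm along the centerline; None -> positional default
    n_lobes: int = 1
    lobe_relief: float = 0.5

    def validate(self) -> None:
        if self.position not in STENOSIS_POSITIONS:
            raise ValueError(f"unknown stenosis position {self.position!r}")
        if self.position == "middle" and not (5.0 <= self.length <= 7.0):
            raise ValueError(
                f"a 'middle' stenosis must be 5-7 mm long, got {self.length} mm")
        if self.position == "middle_and_proximal" and not self.length > 10.0:
            raise ValueError(
                "a 'middle_and_proximal' stenosis must be longer than 10 mm, "
                f"got {self.length} mm")
        if not (0.0 < self.rate <= 100.0):
            raise ValueError(f"stenosis rate must be in (0, 100], got {self.rate}")
        if self.rate < 100.0 and self.rate <= 50.0:
            raise ValueError(
                "one-sided indentation supports residual rates > 50% only "
                f"(got {self.rate}%); the moderate-stenosis band is 57.93-67.62%")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if not (0.0 <= self.lobe_relief < 1.0):
            raise ValueError("lobe_relief must be in [0, 1)")


@dataclass
class DiverticulumSpec:
    """Sigmoid-sinus diverticulum: outward bulge of the medial wall at the
    TS-SS junction.  ``center=None`` places it at mid-bend."""

    depth: float = 1.0  # mm
    extent: float = 8.0  # mm
    center: float | None = None  # mm arclength; None -> mid-bend

    def validate(self) -> None:
        if self.depth < 0 or self.extent <= 0:
            raise ValueError("diverticulum depth must be >= 0 and extent > 0")


@dataclass
class GeometryParams:
    """Planar channel layout: straight TS, circular junction bend, straight SS.

    The medial side (positive offset from the centerline) carries the elastic
    wall strip, the temporal-bone backing and the air cell; the lateral lumen
    wall is rigid.  All lengths in mm.
    """

    ts_length: float = 40.0
    bend_radius: float = 8.0
    bend_angle_deg: float = 90.0
    ss_length: float = 22.0
    half_width: float = 3.5
    wall_thickness: float = 0.5
    bone_thickness: float = 1.5
    stenosis: StenosisSpec = field(default_factory=StenosisSpec)
    diverticulum: DiverticulumSpec | None = field(default_factory=DiverticulumSpec)
    # the dehiscence patch sits on the outer (medial) wall of the proximal
    # sigmoid sinus just distal to the junction bend, where the flow flung
    # off the sharp turn impinges; the air cell and tympanum lie above
    sswd_center: float = 57.0
    sswd_length: float = 5.0
    cavity_enabled: bool = True
    cavity_start: float = 53.5
    cavity_end: float = 67.5
    cavity_height: float = 12.0
    tympanum_center: float = 57.0
    tympanum_length: float = 4.0
    end_margin: float = 2.0  # mm kept free of stenosis at inlet/outlet sections

    @property
    def total_length(self) -> float:
        import math

        return self.ts_length + self.bend_radius * math.radians(self.bend_angle_deg) \
            + self.ss_length

    def validate(self) -> None:
        for name in ("ts_length", "ss_length", "half_width", "wall_thickness",
                     "bone_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bend_angle_deg < 0 or (self.bend_angle_deg > 0 and self.bend_radius <= 0):
            raise ValueError("bend radius must be positive for a nonzero bend angle")
        self.stenosis.validate()
        if self.diverticulum is not None:
            self.diverticulum.validate()
            if self.diverticulum.depth >= self.bone_thickness:
                raise ValueError(
                    "diverticulum depth must stay below the bone-region thickness "
                    f"({self.diverticulum.depth} >= {self.bone_thickness} mm)")
        if self.cavity_enabled:
            s0 = self.sswd_center - self.sswd_length / 2
            s1 = self.sswd_center + self.sswd_length / 2
            if not (self.cavity_start < s0 and s1 < self.cavity_end):
                raise ValueError("SSWD patch must lie strictly inside the air-cavity "
                                 "contact zone")
            t0 = self.tympanum_center - self.tympanum_length / 2
            t1 = self.tympanum_center + self.tympanum_length / 2
            if not (self.cavity_start <= t0 and t1 <= self.cavity_end):
                raise ValueError("tympanum segment must lie on the air-cavity boundary")
            if self.cavity_end > self.total_length:
                raise ValueError("air cavity extends past the outlet")


@dataclass
class MaterialSet:
    """Blood, vessel wall, temporal bone and air constants (SI units)."""

    fluid_density: float = 1050.0  # kg/m^3
    fluid_viscosity: float = 3.5e-3  # Pa s
    vessel_density: float = 1050.0  # kg/m^3
    vessel_modulus: float = 1.26e6  # Pa
    vessel_poisson: float = 0.3
    bone_density: float = 2000.0  # kg/m^3
    bone_modulus: float = 1.2e10  # Pa
    bone_poisson: float = 0.3
    air_density: float = 1.139  # kg/m^3
    sound_speed: float = 340.0  # m/s
    impedance: float = 5.57e6  # Pa s/m, bone-air interface

    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            if getattr(self, f_.name) <= 0:
                raise ValueError(f"{f_.name} must be strictly positive")
        for nu in (self.vessel_poisson, self.bone_poisson):
            if not (0 <= nu < 0.5):
                raise ValueError("Poisson ratio must be in [0, 0.5)")

    def vessel_lame(self) -> tuple[float, float]:
        from .solid import lame_parameters

        return lame_parameters(self.vessel_modulus, self.vessel_poisson)

    def bone_lame(self) -> tuple[float, float]:
        from .solid import lame_parameters

        return lame_parameters(self.bone_modulus, self.bone_poisson)


@dataclass
class WaveformParams:
    """Pulsatile inlet mass flow per unit out-of-plane depth.

    Q(t) = mean * (1 + a1 sin(2 pi t/T + phi1) + a2 sin(4 pi t/T + phi2)),
    strictly positive.  The default mean corresponds to a 0.22 m/s mean
    inlet velocity in a 7 mm channel, calibrated so the peak Reynolds
    number in a stenosed scenario lands in the 1000-1500 band, below the
    laminar limit of 2300.
    """

    period: float = 0.8  # s, cardiac cycle
    mean_mass_flow: float = 1.617  # kg/(s m): rho_f * 0.22 m/s * 7 mm
    a1: float = 0.3
    a2: float = 0.1
    phi1: float = 0.0
    phi2: float = 0.0

    def validate(self) -> None:
        if self.period <= 0 or self.mean_mass_flow <= 0:
            raise ValueError("period and mean_mass_flow must be positive")
        if abs(self.a1) + abs(self.a2) >= 1.0:
            raise ValueError("harmonic amplitudes allow flow reversal")


@dataclass
class SolverParams:
    """Discretization and coupling settings."""

    h_max: float = 0.8  # mm, maximum element circumdiameter
    n_layers: int = 2  # boundary-layer rows along the lumen walls
    cycles: int = 4  # cardiac cycles simulated; metrics use the last one
    ramp_fraction: float = 0.25  # of the first cycle, smooth inflow ramp
    fsi_tol: float = 1.0e-3  # interface residual threshold
    fsi_max_iter: int = 50  # subiteration cap per step
    picard_tol: float = 1.0e-3
    picard_max_iter: int = 25
    cfl_safety: float = 0.8
    penalty_stiffness: float = 1.0e10  # Pa/m, wall-bone contact
    newmark_gamma: float = 0.8  # > 0.5 damps only near-Nyquist wall ringing
    acoustic_frequency: str = "dominant"  # or "fundamental" / "first_mode"
    tympanum_impedance: float | None = None  # Pa s/m; None -> bone impedance
    record_fields: bool = False

    def validate(self) -> None:
        if self.h_max <= 0 or self.cycles < 1 or self.n_layers < 0:
            raise ValueError("invalid solver sizes")
        if self.acoustic_frequency not in ("fundamental", "dominant",
                                           "first_mode"):
            raise ValueError("acoustic_frequency must be 'fundamental', "
                             "'dominant' or 'first_mode'")


@dataclass
class ScenarioConfig:
    name: str = "scenario"
    stented: bool = False
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: MaterialSet = field(default_factory=MaterialSet)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    solver: SolverParams = field(default_factory=SolverParams)

    def validate(self) -> "ScenarioConfig":
        self.geometry.validate()
        self.materials.validate()
        self.waveform.validate()
        self.solver.validate()
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        geo = dict(d.pop("geometry", {}))
        sten = geo.pop("stenosis", None)
        div = geo.pop("diverticulum", None)
        geometry = GeometryParams(**geo)
        if sten is not None:
            geometry.stenosis = StenosisSpec(**sten)
        geometry.diverticulum = DiverticulumSpec(**div) if div is not None else None
        cfg = cls(
            name=d.pop("name", "scenario"),
            stented=d.pop("stented", False),
            geometry=geometry,
            materials=MaterialSet(**d.pop("materials", {})),
            waveform=WaveformParams(**d.pop("waveform", {})),
            solver=SolverParams(**d.pop("solver", {})),
        )
        if d:
            raise ValueError(f"unknown config sections: {sorted(d)}")
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "ScenarioConfig":
        """Deep-ish copy with top-level field overrides."""
        d = self.to_dict()
        d.update(kw)
        return ScenarioConfig.from_dict(d)


# -- presets ---------------------------------------------------------------

#: residual-lumen rates (%) of the two cohort groups; each preset uses the
#: group mean of the reported per-patient rates.
GROUP1_RATE = (65.11 + 57.93 + 60.94) / 3.0
GROUP2_RATE = (67.62 + 62.43 + 62.34) / 3.0

PRESET_NAMES = ("group1_pre", "group1_post", "group2_pre", "group2_post")


def preset(name: str) -> ScenarioConfig:
    """Return one of the four bundled scenario presets.

    ``group1``: single-lobe 6 mm stenosis in the middle of the TS.
    ``group2``: three-lobe 12 mm stenosis from the middle into the proximal
    TS.  ``*_post`` are the virtually stented counterparts.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    group, phase = name.split("_")
    if group == "group1":
        sten = StenosisSpec(position="middle", length=6.0, rate=GROUP1_RATE, n_lobes=1)
    else:
        sten = StenosisSpec(position="middle_and_proximal", length=12.0,
                            rate=GROUP2_RATE, n_lobes=3)
    cfg = ScenarioConfig(name=name, stented=(phase == "post"),
                         geometry=GeometryParams(stenosis=sten))
    return cfg.validate()
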