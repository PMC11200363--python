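import numpy as np
import pytest

from sinuflow.config import (ScenarioConfig, GeometryParams, StenosisSpec,
                             DiverticulumSpec, MaterialSet, SolverParams,
                             WaveformParams)
from sinuflow.geometry import build_geometry
from sinuflow.meshing import generate_mesh, rectangle_mesh


@pytest.fixture(scope="session")
def materials():
    return MaterialSet()


@pytest.fixture(scope="session")
def straight_geom():
    """Uniform straight channel, 2 mm wide, 10 mm long, no cavity."""
    geo = GeometryParams(ts_length=8.0, bend_angle_deg=0.0, ss_length=2.0,
                         half_width=1.0, stenosis=StenosisSpec(rate=100.0),
                         diverticulum=None, cavity_enabled=False)
    return build_geometry(geo, stented=False)


def tiny_scenario(rate: float = 100.0, n_lobes: int = 1,
                  h_max: float = 2.0, cycles: int = 1) -> ScenarioConfig:
    """Small full scenario (straight, with cavity) for fast coupled runs."""
    sten = StenosisSpec(position="middle", length=5.0, rate=rate,
                        n_lobes=n_lobes)
    geo = GeometryParams(
        ts_length=16.0, bend_angle_deg=0.0, bend_radius=8.0, ss_length=14.0,
        half_width=3.5, stenosis=sten, diverticulum=None,
        sswd_center=22.0, sswd_length=5.0,
        cavity_enabled=True, cavity_start=18.0, cavity_end=27.0,
        cavity_height=6.0, tympanum_center=22.0, tympanum_length=3.0)
    cfg = ScenarioConfig(
        name=f"tiny_{rate:g}", geometry=geo,
        solver=SolverParams(h_max=h_max, cycles=cycles),
        waveform=WaveformParams())
    return cfg.validate()


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_scenario()


@pytest.fixture(scope="session")
def strip_mesh():
    """Clamped-strip solid test mesh: 20 x 1 mm, markers as in the wall."""
    return rectangle_mesh(20.0e-3, 1.0e-3, 80, 4, region="wall",
                          marker_names=("wall_end", "wall_end",
                                        "interface", "medial"))


@pytest.fixture(scope="session")
def scenario_mesh():
    """Coarse mesh of the default group-2 geometry (all four regions)."""
    from sinuflow.config import preset

    geom = build_geometry(preset("group2_pre"))
    return geom, generate_mesh(geom, 2.0e-3)
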