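import numpy as np
import pytest

from sinuflow.config import GeometryParams, StenosisSpec, preset
from sinuflow.geometry import (build_geometry, apply_virtual_stent,
                               stenosis_rate, morphometrics,
                               rate_from_measures, export_boundary_csv, MM)


def geom_with(rate=62.0, position="middle", length=6.0, n_lobes=1, **kw):
    sten = StenosisSpec(position=position, length=length, rate=rate,
                        n_lobes=n_lobes)
    return build_geometry(GeometryParams(stenosis=sten, **kw), stented=False)


class TestRateDefinition:
    def test_rate_is_residual_lumen_quotient(self):
        # 3 mm throat in a 6 mm nominal lumen is a 50% residual rate
        assert rate_from_measures(3.0, 6.0) == pytest.approx(50.0)

    def test_zero_throat_rejected(self):
        with pytest.raises(ValueError, match="throat"):
            rate_from_measures(0.0, 6.0)


class TestBuildGeometry:
    @pytest.mark.parametrize("rate", [62.0, 57.93, 67.62, 100.0])
    def test_realized_throat_matches_spec_rate(self, rate):
        g = geom_with(rate=rate)
        assert stenosis_rate(g) == pytest.approx(rate, rel=0.005)

    def test_uniform_channel_constant_width(self):
        g = geom_with(rate=100.0, diverticulum=None)
        s = np.linspace(0, g.total_length, 500)
        assert np.allclose(g.width(s), 2 * g.half_width)

    def test_multilobe_long_stenosis_extends_proximally(self):
        g = geom_with(rate=64.0, position="middle_and_proximal",
                      length=12.0, n_lobes=3)
        assert g.sten_end - g.sten_start == pytest.approx(12.0 * MM)
        # narrowed interval runs from the middle segment into the proximal
        # (junction-ward, flow-referenced) third of the TS
        assert g.sten_start == pytest.approx(g.ts_length / 2.0)
        assert g.sten_end > 2.0 * g.ts_length / 3.0
        assert g.sten_end < g.ts_length
        assert stenosis_rate(g) == pytest.approx(64.0, rel=0.005)

    def test_stenosis_overlapping_end_sections_rejected(self):
        with pytest.raises(ValueError, match="inlet/outlet"):
            geom_with(rate=62.0, position="middle", length=6.0,
                      ts_length=6.0, bend_angle_deg=0.0, ss_length=40.0,
                      cavity_enabled=False, diverticulum=None)

    def test_group_presets_inside_reported_rate_band(self):
        for name in ("group1_pre", "group2_pre"):
            g = build_geometry(preset(name))
            assert 57.93 <= stenosis_rate(g) <= 67.62


class TestVirtualStent:
    def test_stenting_restores_nominal_rate(self):
        g = apply_virtual_stent(geom_with(rate=60.0))
        assert stenosis_rate(g) == pytest.approx(100.0)

    def test_idempotent_and_identity_on_uniform(self):
        g = geom_with(rate=60.0)
        once = apply_virtual_stent(g)
        assert apply_virtual_stent(once) == once
        uniform = geom_with(rate=100.0)
        assert apply_virtual_stent(uniform).width(np.array([0.01]))[0] == \
            uniform.width(np.array([0.01]))[0]

    def test_boundary_changes_only_inside_stenosis_extent(self):
        g = geom_with(rate=60.0)
        st = apply_virtual_stent(g)
        s = np.linspace(0, g.total_length, 2000)
        lat_pre = g.map_to_xy(s, -g.w_lat(s))
        lat_post = st.map_to_xy(s, -st.w_lat(s))
        moved = np.any(lat_pre != lat_post, axis=1)
        inside = (s >= g.sten_start) & (s <= g.sten_end)
        assert np.all(inside[moved])
        med_pre = g.map_to_xy(s, g.w_med(s))
        med_post = st.map_to_xy(s, st.w_med(s))
        assert np.array_equal(med_pre, med_post)


class TestMorphometrics:
    def test_uniform_channel_symmetric_ends(self):
        rec = morphometrics(geom_with(rate=100.0))
        assert rec["inlet_width_mm"] == pytest.approx(rec["outlet_width_mm"])

    def test_stented_reports_full_rate(self):
        rec = morphometrics(apply_virtual_stent(geom_with(rate=58.0)))
        assert rec["stenosis_rate_pct"] == pytest.approx(100.0)
        assert rec["stented"]

    def test_sswd_length_scales_with_config(self):
        # without the diverticulum bulge the medial surface is a constant
        # offset curve, so the patch arclength is proportional to its extent
        rec1 = morphometrics(build_geometry(
            GeometryParams(sswd_center=58.0, sswd_length=4.0,
                           diverticulum=None), stented=False))
        rec2 = morphometrics(build_geometry(
            GeometryParams(sswd_center=58.0, sswd_length=8.0,
                           diverticulum=None), stented=False))
        assert rec2["sswd_length_mm"] == pytest.approx(
            2 * rec1["sswd_length_mm"], rel=1e-6)


def test_boundary_tags_partition_lumen_boundary():
    g = build_geometry(preset("group1_pre"))
    tags = g.boundary_tags()
    # straight-channel comparison: tag arclengths must reassemble the
    # perimeter of the lumen loop computed independently
    total = sum(tags.values())
    s = np.linspace(0, g.total_length, 8000)
    lat = g.map_to_xy(s, -g.w_lat(s))
    med = g.map_to_xy(s, g.w_med(s))
    perim = (np.sum(np.hypot(*np.diff(lat, axis=0).T))
             + np.sum(np.hypot(*np.diff(med, axis=0).T))
             + tags["inlet"] + tags["outlet"])
    assert total == pytest.approx(perim, rel=1e-4)


def test_boundary_export_csv(tmp_path):
    g = geom_with(rate=62.0)
    path = tmp_path / "boundary.csv"
    export_boundary_csv(g, path)
    rows = path.read_text().strip().splitlines()
    assert rows[0] == "tag,x_m,y_m"
    tags = {r.split(",")[0] for r in rows[1:]}
    assert tags == {"lateral", "interface", "inlet", "outlet"}
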