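import numpy as np
import pytest

from sinuflow.config import GeometryParams, StenosisSpec, MaterialSet
from sinuflow.geometry import build_geometry
from sinuflow.meshing import generate_mesh, refine_mesh
from sinuflow.fluid import FluidSolver, reynolds_number_from
from sinuflow.waveform import InletWaveform, sample_waveform, ramp_factor


@pytest.fixture(scope="module")
def channel(straight_geom, materials):
    mesh = generate_mesh(straight_geom, 2.0e-4)
    return FluidSolver(mesh, materials, straight_geom)


class TestWaveform:
    def test_periodicity_exact(self):
        w = InletWaveform()
        t = np.linspace(0, 0.8, 101)
        assert np.allclose(sample_waveform(w, t), sample_waveform(w, t + 0.8),
                           rtol=0, atol=1e-15)

    def test_cycle_average_is_mean(self):
        w = InletWaveform(mean=1.1025, a1=0.3, a2=0.1, phi1=0.4, phi2=1.1)
        t = np.linspace(0, 0.8, 200001)
        avg = np.trapezoid(w.sample(t), t) / 0.8
        assert avg == pytest.approx(w.mean, rel=1e-6)

    def test_strictly_positive(self):
        assert InletWaveform().trough() > 0

    def test_ramp_monotone_smooth(self):
        ts = np.linspace(0, 0.2, 50)
        vals = [ramp_factor(t, 0.2) for t in ts]
        assert vals[0] == 0.0 and vals[-1] == 1.0
        assert np.all(np.diff(vals) >= 0)
        assert ramp_factor(5.0, 0.2) == 1.0


class TestSteadyChannel:
    def test_poiseuille_centerline_to_mean_ratio(self, channel):
        mat = channel.mat
        q = 100 * mat.fluid_viscosity / mat.fluid_density
        st = channel.steady_solve(q)
        svals = channel.mesh.node_s[channel.nodes]
        sel = svals == svals[np.argmin(np.abs(svals - 5e-3))]
        vmax = np.max(np.hypot(st.u[sel, 0], st.u[sel, 1]))
        assert vmax / (q / 2e-3) == pytest.approx(1.5, rel=0.02)

    def test_mass_conserved_to_below_one_percent(self, channel):
        q = 100 * channel.mat.fluid_viscosity / channel.mat.fluid_density
        st = channel.steady_solve(q)
        fin = channel.flux_through(st, "inlet")
        fout = channel.flux_through(st, "outlet")
        assert fin == pytest.approx(-q, rel=0.01)  # inward = negative outward
        assert abs(fin + fout) / abs(fin) < 0.01

    def test_zero_inflow_zero_field(self, channel):
        st = channel.step(channel.zero_state(), 1e-3, 0.0)
        assert np.max(np.abs(st.u)) < 1e-12
        assert np.max(np.abs(st.p)) < 1e-9

    def test_grid_convergence_of_poiseuille_error(self, straight_geom,
                                                  materials):
        q = 100 * materials.fluid_viscosity / materials.fluid_density
        w = 2e-3
        errs = []
        mesh = generate_mesh(straight_geom, 4.0e-4)
        for _ in range(3):
            fs = FluidSolver(mesh, materials, straight_geom)
            st = fs.steady_solve(q)
            y = fs.mesh.node_n[fs.nodes]
            u_exact = 1.5 * (q / w) * (1.0 - (y / 1e-3) ** 2)
            interior = (fs.mesh.node_s[fs.nodes] > 2e-3) & \
                (fs.mesh.node_s[fs.nodes] < 8e-3)
            err = np.sqrt(np.mean(
                (st.u[interior, 0] - u_exact[interior]) ** 2))
            errs.append(err / (q / w))
            mesh = refine_mesh(mesh)
        assert errs[1] < errs[0] and errs[2] < errs[1]
        # at least first-order observed convergence over the sweep
        assert errs[2] < errs[0] / 2


class TestStenosisPressureDrop:
    def test_pressure_drop_monotone_in_rate(self, materials):
        drops = []
        for rate in (100.0, 85.0, 70.0, 55.0):
            geo = GeometryParams(
                ts_length=16.0, bend_angle_deg=0.0, ss_length=4.0,
                half_width=1.75,
                stenosis=StenosisSpec(position="middle", length=5.0, rate=rate),
                diverticulum=None, cavity_enabled=False)
            g = build_geometry(geo, stented=False)
            fs = FluidSolver(generate_mesh(g, 4e-4), materials, g)
            q = 150 * materials.fluid_viscosity / materials.fluid_density
            st = fs.steady_solve(q, relax=0.8, max_iter=100)
            drops.append(np.mean(st.p[fs.inlet_nodes]))
        assert np.all(np.diff(drops) > 0), drops


class TestTimeStepAndScales:
    def test_cfl_dt_halves_when_speed_doubles(self, channel):
        st = channel.steady_solve(
            100 * channel.mat.fluid_viscosity / channel.mat.fluid_density)
        st2 = st.copy()
        st2.u = 2 * st.u
        # period chosen so the clamp interval contains both steps
        d1 = channel.cfl_timestep(st, period=0.1)
        d2 = channel.cfl_timestep(st2, period=0.1)
        assert d2 == pytest.approx(d1 / 2)

    def test_zero_velocity_clamps_to_upper_bound(self, channel):
        dt = channel.cfl_timestep(channel.zero_state(), period=0.8)
        assert dt == pytest.approx(0.8 / 100.0)

    def test_stepping_with_returned_dt_keeps_cfl_below_one(self, channel):
        q = 100 * channel.mat.fluid_viscosity / channel.mat.fluid_density
        st = channel.steady_solve(q)
        dt = channel.cfl_timestep(st, period=0.1)
        st2 = channel.step(st, dt, q)
        assert channel.cfl_number(st2, dt) < 1.0

    def test_reynolds_direct_formula(self):
        assert reynolds_number_from(1050.0, 0.5, 0.005, 0.0035) == \
            pytest.approx(750.0)

    def test_reynolds_zero_and_linear_scaling(self, channel):
        assert channel.reynolds_number(channel.zero_state()) == 0.0
        q = 100 * channel.mat.fluid_viscosity / channel.mat.fluid_density
        st = channel.steady_solve(q)
        re1 = channel.reynolds_number(st)
        st.u *= 3.0
        assert channel.reynolds_number(st) == pytest.approx(3 * re1)

    def test_preset_peak_reynolds_laminar(self, materials):
        # peak waveform flow through the nominal channel stays laminar
        w = InletWaveform()
        q_peak = w.peak() / materials.fluid_density
        re = reynolds_number_from(materials.fluid_density, q_peak / 7e-3,
                                  7e-3, materials.fluid_viscosity)
        assert re < 2300
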