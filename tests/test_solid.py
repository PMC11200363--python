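import numpy as np
import pytest

from sinuflow.meshing import rectangle_mesh
from sinuflow.solid import SolidSolver, lame_parameters, contact_penalty_traction


@pytest.fixture(scope="module")
def strip(strip_mesh, materials):
    return SolidSolver(strip_mesh, materials, fixed_markers=("wall_end",),
                       contact_markers=())


def bottom_load(solver, mesh, p):
    edges = mesh.marker_edges("interface")
    return solver.edge_load_vector(edges, np.tile([0.0, p], (len(edges), 1)))


class TestLameParameters:
    @pytest.mark.parametrize("E,nu,lam,mu", [
        # hand evaluation with the vessel constants
        (1.26e6, 0.3, 0.3 * 1.26e6 / (1.3 * 0.4), 1.26e6 / 2.6),
        # degenerate nu = 0
        (2.0e6, 0.0, 0.0, 1.0e6),
        # hand evaluation with the temporal-bone constants
        (1.2e10, 0.3, 0.3 * 1.2e10 / (1.3 * 0.4), 1.2e10 / 2.6),
    ])
    def test_hand_values(self, E, nu, lam, mu):
        lam_c, mu_c = lame_parameters(E, nu)
        assert lam_c == pytest.approx(lam, rel=1e-14)
        assert mu_c == pytest.approx(mu, rel=1e-14)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            lame_parameters(1e6, 0.5)
        with pytest.raises(ValueError):
            lame_parameters(-1.0, 0.3)


class TestStatics:
    def test_clamped_strip_deflection_vs_beam_theory(self, strip, strip_mesh,
                                                     materials):
        u = strip.static_solve(bottom_load(strip, strip_mesh, 100.0))
        e_eff = materials.vessel_modulus / (1 - materials.vessel_poisson ** 2)
        w_eb = 100.0 * (20e-3) ** 4 / (384 * e_eff * (1e-3) ** 3 / 12)
        assert strip.n_nodes * 2 == strip.ndof
        assert u[strip.n_nodes:].max() == pytest.approx(w_eb, rel=0.05)

    def test_linearity_in_load(self, strip, strip_mesh):
        F = bottom_load(strip, strip_mesh, 100.0)
        u1 = strip.static_solve(F)
        u2 = strip.static_solve(2 * F)
        assert np.allclose(u2, 2 * u1, rtol=1e-12, atol=1e-18)

    def test_patch_test_uniform_strain_exact(self, materials):
        mesh = rectangle_mesh(4e-3, 2e-3, 6, 3, region="wall",
                              marker_names=("a", "b", "c", "d"))
        ss = SolidSolver(mesh, materials, fixed_markers=(), contact_markers=())
        grad = np.array([[1e-4, 2e-4], [-3e-4, 5e-5]])
        idx, vals = [], []
        for name in mesh.markers:
            for ag, bg in mesh.marker_edges(name):
                for node in ss._edge_triples(int(ag), int(bg))[0]:
                    x, y = ss.pts[node]
                    idx += [node, node + ss.n_nodes]
                    vals += [grad[0] @ (x, y), grad[1] @ (x, y)]
        idx = np.asarray(idx)
        vals = np.asarray(vals)
        idx, first = np.unique(idx, return_index=True)
        u = ss.static_solve(np.zeros(ss.ndof), prescribed=(idx, vals[first]))
        exact = np.concatenate([ss.pts @ grad[0], ss.pts @ grad[1]])
        assert np.max(np.abs(u - exact)) < 1e-16


class TestNewmark:
    def test_zero_load_zero_state_stays_zero(self, strip):
        st = strip.newmark_step(strip.zero_state(), np.zeros(strip.ndof), 1e-4)
        assert np.all(st.u == 0) and np.all(st.v == 0)

    def test_undamped_energy_conservation(self, strip, strip_mesh):
        u0 = strip.static_solve(bottom_load(strip, strip_mesh, 100.0))
        state = strip.initialize_state(u0=u0)
        e0 = strip.energy(state)
        f1, _ = strip.first_structural_mode(with_contact_springs=False)
        dt = 1.0 / (20 * f1)
        for _ in range(100):
            state = strip.newmark_step(state, np.zeros(strip.ndof), dt)
        assert abs(strip.energy(state) - e0) / e0 < 1e-3

    def test_gamma_above_half_dissipates(self, strip, strip_mesh):
        u0 = strip.static_solve(bottom_load(strip, strip_mesh, 100.0))
        state = strip.initialize_state(u0=u0)
        e0 = strip.energy(state)
        f1, _ = strip.first_structural_mode(with_contact_springs=False)
        dt = 1.0 / (4 * f1)  # near-Nyquist stepping of the first mode
        for _ in range(60):
            state = strip.newmark_step(state, np.zeros(strip.ndof), dt,
                                       gamma=0.6)
        assert strip.energy(state) < 0.9 * e0
        with pytest.raises(ValueError):
            strip.newmark_step(state, np.zeros(strip.ndof), dt, gamma=0.4)


class TestEigen:
    def test_first_mode_vs_beam_theory(self, strip, materials):
        f1, shape = strip.first_structural_mode(with_contact_springs=False)
        e_eff = materials.vessel_modulus / (1 - materials.vessel_poisson ** 2)
        L, t = 20e-3, 1e-3
        f_eb = (4.730 ** 2 / (2 * np.pi * L ** 2)) * np.sqrt(
            e_eff * t ** 3 / 12 / (materials.vessel_density * t))
        assert f1 == pytest.approx(f_eb, rel=0.05)
        assert shape.shape == (strip.ndof,)

    def test_quadrupling_modulus_doubles_frequency(self, strip_mesh,
                                                   materials):
        s1 = SolidSolver(strip_mesh, materials, fixed_markers=("wall_end",),
                         contact_markers=())
        s4 = SolidSolver(strip_mesh, materials, fixed_markers=("wall_end",),
                         contact_markers=(),
                         modulus=4 * materials.vessel_modulus)
        f1 = s1.first_structural_mode()[0]
        f4 = s4.first_structural_mode()[0]
        assert f4 == pytest.approx(2 * f1, rel=1e-6)

    def test_contact_springs_raise_frequency(self, strip_mesh, materials):
        free = SolidSolver(strip_mesh, materials, fixed_markers=("wall_end",),
                           contact_markers=("medial",), penalty_stiffness=0.0)
        sprung = SolidSolver(strip_mesh, materials,
                             fixed_markers=("wall_end",),
                             contact_markers=("medial",),
                             penalty_stiffness=1e8)
        f_free = free.first_structural_mode(with_contact_springs=False)[0]
        f_sprung = sprung.first_structural_mode(with_contact_springs=True)[0]
        assert f_sprung > f_free * 1.01


class TestContact:
    def test_traction_operator_definition(self):
        assert contact_penalty_traction(0.0, 0.0, 1e10) == 0.0
        assert contact_penalty_traction(2e-8, 0.0, 1e10) == pytest.approx(200.0)
        assert contact_penalty_traction(-1e-8, 0.0, 1e10) == 0.0  # separated
        assert contact_penalty_traction(3e-8, 2e-8, 1e10) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            contact_penalty_traction(0.0, 0.0, -1.0)

    def test_stiffer_penalty_reduces_penetration(self, strip_mesh, materials):
        pens = []
        for k in (1e8, 1e9):
            ss = SolidSolver(strip_mesh, materials,
                             fixed_markers=("wall_end",),
                             contact_markers=("medial",),
                             penalty_stiffness=k)
            F = bottom_load(ss, strip_mesh, 200.0)
            u = ss.static_solve(F, contact=True)
            pens.append(np.max(ss.contact_penetration(u)))
        assert pens[0] > 0
        assert pens[1] < pens[0] / 5.0

    def test_displacement_decreases_with_modulus(self, strip_mesh, materials):
        # 3-point stiffness sweep at fixed load
        maxu = []
        for scale in (1.0, 2.0, 4.0):
            ss = SolidSolver(strip_mesh, materials,
                             fixed_markers=("wall_end",), contact_markers=(),
                             modulus=scale * materials.vessel_modulus)
            u = ss.static_solve(bottom_load(ss, strip_mesh, 100.0))
            maxu.append(np.abs(u).max())
        assert maxu[0] > maxu[1] > maxu[2]
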