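import numpy as np
import pytest

from sinuflow.meshing import rectangle_mesh, refine_mesh
from sinuflow.acoustics import (AcousticSolver, extract_sswd_source,
                                dominant_harmonic, spl_from_pressure, P_REF)


@pytest.fixture(scope="module")
def tube(materials):
    """Quasi-1D duct: piston (sswd) at x=0, impedance receiver at x=L."""
    mesh = rectangle_mesh(0.1, 0.004, 60, 3, region="air",
                          marker_names=("sswd", "tympanum", "hard", "hard2"))
    return AcousticSolver(mesh, materials, impedance_markers=(),
                          receiver_marker="tympanum")


def tube_exact(materials, L, f, u0, x):
    rho, c, z = (materials.air_density, materials.sound_speed,
                 materials.impedance)
    w = 2 * np.pi * f
    k = w / c
    m = np.array([
        [1j * k, -1j * k],
        [(-1j * k + 1j * w * rho / z) * np.exp(-1j * k * L),
         (1j * k + 1j * w * rho / z) * np.exp(1j * k * L)]])
    a, b = np.linalg.solve(m, [rho * w * w * u0, 0.0])
    return a * np.exp(-1j * k * x) + b * np.exp(1j * k * x)


class TestSourceExtraction:
    T = 0.8

    def history(self, signal):
        h = np.zeros((len(signal), 1, 2))
        h[:, 0, 1] = signal
        return h

    def test_pure_sinusoid_amplitude_and_phase(self):
        dt = self.T / 400
        t = np.arange(800) * dt
        f1 = 5.0
        amp, fa = extract_sswd_source(self.history(2.5e-6 * np.sin(2 * np.pi * f1 * t)),
                                      np.array([[0.0, 1.0]]), dt, f1, self.T)
        assert fa == pytest.approx(f1)
        assert abs(amp[0]) == pytest.approx(2.5e-6, rel=1e-9)
        assert np.degrees(np.angle(amp[0])) == pytest.approx(-90.0, abs=1e-6)

    def test_zero_motion_zero_source(self):
        dt = self.T / 100
        amp, _ = extract_sswd_source(self.history(np.zeros(100)),
                                     np.array([[0.0, 1.0]]), dt, 2.5, self.T)
        assert np.all(amp == 0)

    def test_two_harmonics_isolated_by_orthogonality(self):
        dt = self.T / 512
        t = np.arange(512) * dt
        sig = 3e-6 * np.sin(2 * np.pi * 2.5 * t) \
            + 7e-6 * np.cos(2 * np.pi * 7.5 * t)
        amp, fa = extract_sswd_source(self.history(sig), np.array([[0.0, 1.0]]),
                                      dt, 2.5, self.T)
        assert fa == pytest.approx(2.5)
        assert abs(amp[0]) == pytest.approx(3e-6, rel=1e-9)

    def test_short_history_rejected(self):
        dt = self.T / 100
        with pytest.raises(ValueError, match="shorter than one cycle"):
            extract_sswd_source(self.history(np.zeros(40)),
                                np.array([[0.0, 1.0]]), dt, 2.5, self.T)

    def test_dominant_harmonic_found(self):
        dt = self.T / 256
        t = np.arange(256) * dt
        sig = 1e-7 * np.sin(2 * np.pi * 1.25 * t) \
            + 5e-6 * np.sin(2 * np.pi * 3.75 * t)
        f = dominant_harmonic(self.history(sig), np.array([[0.0, 1.0]]),
                              np.array([1.0]), dt, self.T)
        assert f == pytest.approx(3.75)


class TestHelmholtz:
    def test_impedance_tube_standing_wave(self, tube, materials):
        src = tube.source_nodes()
        field = tube.solve(1000.0, np.full(len(src), 1e-6, dtype=complex), src)
        p_exact = tube_exact(materials, 0.1, 1000.0, 1e-6, tube.pts[:, 0])
        err = np.max(np.abs(np.abs(field.p) - np.abs(p_exact)))
        assert err / np.max(np.abs(p_exact)) < 0.01
        assert field.residual < 1e-3

    def test_zero_source_zero_field(self, tube):
        src = tube.source_nodes()
        field = tube.solve(1000.0, np.zeros(len(src), dtype=complex), src)
        assert np.max(np.abs(field.p)) == 0.0

    def test_doubling_source_raises_spl_6dB(self, tube):
        src = tube.source_nodes()
        f1 = tube.solve(800.0, np.full(len(src), 1e-6, dtype=complex), src)
        f2 = tube.solve(800.0, np.full(len(src), 2e-6, dtype=complex), src)
        dspl = f2.spl() - f1.spl()
        assert np.allclose(dspl, 20 * np.log10(2.0), atol=1e-9)

    def test_refinement_invariance_of_receiver_spl(self, materials):
        mesh = rectangle_mesh(0.05, 0.004, 40, 3, region="air",
                              marker_names=("sswd", "tympanum", "h1", "h2"))
        spls = []
        for _ in range(2):
            sol = AcousticSolver(mesh, materials, impedance_markers=(),
                                 receiver_marker="tympanum")
            src = sol.source_nodes()
            fld = sol.solve(500.0, np.full(len(src), 1e-6, dtype=complex), src)
            spls.append(sol.spl_edge_average(fld, "tympanum"))
            mesh = refine_mesh(mesh)
        assert abs(spls[1] - spls[0]) / abs(spls[1]) < 0.05


class TestSPL:
    def test_reference_pressure_zero_dB(self):
        assert spl_from_pressure(P_REF) == pytest.approx(0.0)

    def test_80dB_example(self):
        assert spl_from_pressure(0.2) == pytest.approx(80.0, abs=1e-9)

    def test_zero_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = spl_from_pressure(np.array([0.0, 0.2]))
        assert out[0] == 0.0 and out[1] == pytest.approx(80.0)

    def test_uniform_field_uniform_spl(self, tube):
        src = tube.source_nodes()
        field = tube.solve(100.0, np.full(len(src), 1e-6, dtype=complex), src)
        spl = tube.spl_at(field, "tympanum")
        assert np.ptp(spl) < 1e-4
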