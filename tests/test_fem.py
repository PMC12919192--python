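"""Viscoelastic FEM: assembly identities, analytic oracles, solver contracts."""

import numpy as np
import pytest
import scipy.sparse as sp

from cellstretch import (
    ConfigurationError,
    InvalidParameterError,
    LoadingProgram,
    Material,
    SimulationEngine,
    apply_substrate_strain,
    assemble_operators,
    make_sine_waveform,
    step,
)
from cellstretch.fem import FieldHistory, ViscoelasticStepper
from cellstretch.meshing import box_mesh


def _uniform_materials(E, eta, nu):
    return {k: Material(k, E, eta, nu) for k in ("membrane", "cytoplasm", "nucleus")}


class TestAssembly:
    def test_unit_cube_hooke_uniaxial(self):
        """With nu=0, a unit axial strain produces a unit axial stress (E=1)."""
        m = box_mesh((1, 1, 1), (1, 1, 1))
        K, D = assemble_operators(m, _uniform_materials(1.0, 0.0, 0.0))
        # Affine displacement u_x = x -> strain eps_xx = 1 everywhere.
        u = np.zeros((m.n_vertices, 3))
        u[:, 0] = m.vertices[:, 0]
        f = K @ u.ravel()
        # Reaction on the x=1 face equals stress * area = E * 1 * 1.
        face = m.vertices[:, 0] > 0.5
        fx = f.reshape(-1, 3)[face, 0].sum()
        assert fx == pytest.approx(1.0, rel=1e-12)
        assert D.nnz == 0 or abs(D).max() == 0

    def test_damping_proportionality(self):
        """eta = 2 E makes D exactly 2 K (stiffness-proportional damping)."""
        m = box_mesh((1, 1, 1), (2, 2, 2))
        K, D = assemble_operators(m, _uniform_materials(1.0, 2.0, 0.3))
        assert abs(D - 2.0 * K).max() < 1e-12

    def test_operators_symmetric_psd(self, ci_mesh):
        mats = _uniform_materials(4000.0, 5430.0, 0.45)
        K, D = assemble_operators(ci_mesh, mats, mats["membrane"], 0.01)
        assert abs(K - K.T).max() < 1e-6 * abs(K).max()
        assert abs(D - D.T).max() < 1e-6 * abs(D).max()
        rng = np.random.default_rng(0)
        for _ in range(3):
            v = rng.standard_normal(K.shape[0])
            assert v @ (K @ v) >= -1e-9 * abs(K).max() * v @ v
            assert v @ (D @ v) >= -1e-9 * abs(D).max() * v @ v

    def test_missing_material_rejected(self):
        m = box_mesh((1, 1, 1), (1, 1, 1))
        with pytest.raises(ConfigurationError, match="cytoplasm"):
            assemble_operators(m, {"nucleus": Material("nucleus", 1.0, 0.0)})


class TestSubstrateStrain:
    def test_zero_strain_zero_displacement(self, ci_mesh):
        dofs, vals = apply_substrate_strain(ci_mesh, 0.0)
        assert np.all(vals == 0.0)
        assert len(dofs) == 3 * len(ci_mesh.basal_nodes)

    def test_equibiaxial_linear_map(self):
        m = box_mesh((10.0, 5.0, 1.0), (1, 1, 1))  # has a basal node at (10, 5, 0)
        dofs, vals = apply_substrate_strain(m, 0.1, "equibiaxial")
        u = dict(zip(dofs, vals))
        node = int(
            np.flatnonzero(np.all(m.vertices == np.array([10.0, 5.0, 0.0]), axis=1))[0]
        )
        assert u[3 * node] == pytest.approx(1.0)
        assert u[3 * node + 1] == pytest.approx(0.5)
        assert u[3 * node + 2] == 0.0

    def test_anisotropic_zero_ratio(self):
        m = box_mesh((10.0, 5.0, 1.0), (1, 1, 1))
        dofs, vals = apply_substrate_strain(m, 0.1, "anisotropic", y_to_x_ratio=0.0)
        u = dict(zip(dofs, vals))
        node = int(
            np.flatnonzero(np.all(m.vertices == np.array([10.0, 5.0, 0.0]), axis=1))[0]
        )
        assert (u[3 * node], u[3 * node + 1]) == (pytest.approx(1.0), 0.0)

    def test_excessive_strain_rejected(self, ci_mesh):
        with pytest.raises(InvalidParameterError):
            apply_substrate_strain(ci_mesh, 0.6)


class TestStep:
    def test_pure_elastic_equals_static_solution(self):
        m = box_mesh((1, 1, 1), (2, 2, 2))
        K, D = assemble_operators(m, _uniform_materials(1000.0, 0.0, 0.3))
        cons = apply_substrate_strain(m, 0.05, boundary_mode="basal")
        u1 = step(K, D, np.zeros(K.shape[0]), cons, dt=0.1)
        # With eta = 0 there is no history: a second step from u1 is identical.
        u2 = step(K, D, u1, cons, dt=0.1)
        assert np.allclose(u1, u2, atol=1e-12)

    def test_scalar_kelvin_voigt_creep(self):
        """1-DOF K=k, D=d under constant force: u(t) = (F/k)(1 - e^{-kt/d})."""
        k, d, F = 2.0, 6.0, 3.0
        dt = (d / k) / 2000
        st = ViscoelasticStepper(
            sp.csr_matrix(np.array([[k]])), sp.csr_matrix(np.array([[d]])),
            dt, np.array([], dtype=int),
        )
        u = np.zeros(1)
        worst = 0.0
        for n in range(1, 3001):
            u = st.step(u, np.array([]), f_ext=np.array([F]))
            worst = max(worst, abs(u[0] - F / k * (1 - np.exp(-n * dt * k / d))))
        assert worst / (F / k) < 1e-3

    def test_step_size_limit_refused(self):
        m = box_mesh((1, 1, 1), (1, 1, 1))
        K, D = assemble_operators(m, _uniform_materials(1.0, 1.0, 0.0))
        cons = apply_substrate_strain(m, 0.01)
        with pytest.raises(InvalidParameterError, match="T/50"):
            step(K, D, np.zeros(K.shape[0]), cons, dt=0.5, period=10.0)


class TestPatch:
    def test_homogeneous_block_patch(self):
        """Affine boundary displacement reproduces the exact uniform strain:
        eps_xx = applied eps and eps_zz = -2 nu/(1-nu) eps at every step."""
        nu = 0.45
        m = box_mesh((2, 2, 1), (3, 3, 2))
        eng = SimulationEngine(m, _uniform_materials(4000.0, 5430.0, nu),
                               with_membrane=False)
        h = eng.run(
            LoadingProgram(make_sine_waveform(0.075, 0.1), n_cycles=1,
                           boundary_mode="affine_all")
        )
        eps = h.strain_series()
        applied = h.applied_strain[:, None]
        assert np.abs(eps[:, :, 0] - applied).max() < 1e-6
        assert np.abs(eps[:, :, 1] - applied).max() < 1e-6
        assert np.abs(eps[:, :, 2] + 2 * nu / (1 - nu) * applied).max() < 1e-6

    def test_fields_zero_at_start_and_with_zero_constraints(self, run_cell):
        h, _ = run_cell()
        assert np.all(h.displacements[0] == 0.0)
        assert np.abs(h.strain_series()[0]).max() == 0.0


class TestKelvinVoigtOracle:
    def test_sinusoidal_stress_amplitude_and_phase(self):
        """Steady-state |sigma| = sqrt(E^2 + (w eta)^2) eps0 with phase lead
        arctan(w eta / E), within 1% at 200 steps per cycle."""
        E, eta, eps0, f0, spc = 100.0, 50.0, 0.01, 0.5, 200
        omega = 2 * np.pi * f0
        cube = box_mesh((1, 1, 1), (1, 1, 1))
        times = np.arange(3 * spc + 1) * (1 / f0 / spc)
        epst = eps0 * np.sin(omega * times)
        U = np.zeros((len(times), cube.n_vertices, 3))
        U[:, :, 0] = epst[:, None] * cube.vertices[None, :, 0]
        h = FieldHistory(
            cube, times, U, epst,
            LoadingProgram(make_sine_waveform(eps0, f0), 3, spc),
            _uniform_materials(E, eta, 0.0),
        )
        sig = h.stress_series()[:, 0, 0]
        sel = times >= 2 / f0
        M = np.column_stack([np.sin(omega * times[sel]), np.cos(omega * times[sel])])
        coef, *_ = np.linalg.lstsq(M, sig[sel], rcond=None)
        amp, phase = np.hypot(*coef), np.arctan2(coef[1], coef[0])
        assert amp == pytest.approx(np.sqrt(E**2 + (omega * eta) ** 2) * eps0, rel=0.01)
        assert phase == pytest.approx(np.arctan(omega * eta / E), rel=0.01)


class TestSimulationProperties:
    def test_linearity_in_amplitude(self, run_cell):
        """Doubling eps_max doubles every strain component at every step."""
        _, s1 = run_cell(eps=0.025)
        _, s2 = run_cell(eps=0.05)
        for a, b in [
            (s1.mean_eps_xx, s2.mean_eps_xx),
            (s1.mean_eps_yy, s2.mean_eps_yy),
            (s1.mean_eps_zz, s2.mean_eps_zz),
        ]:
            scale = np.abs(b).max()
            assert np.abs(2 * a - b).max() < 1e-6 * scale

    def test_elastic_limit_frequency_independent(self, ci_mesh):
        """With all eta = 0 the response depends only on the loading phase."""
        eng = SimulationEngine(ci_mesh, _uniform_materials(4000.0, 0.0, 0.45))
        hists = [
            eng.run(LoadingProgram(make_sine_waveform(0.075, f), n_cycles=1))
            for f in (0.1, 1.0)
        ]
        d = np.abs(hists[0].displacements - hists[1].displacements).max()
        assert d < 1e-9 * np.abs(hists[0].displacements).max()

    def test_energy_dissipation_positive(self, engine, run_cell):
        """Work done by the substrate constraints over the final cycle is
        strictly positive when eta > 0 (viscous dissipation)."""
        h, _ = run_cell()
        K, D = engine.K, engine.D
        dofs, _ = apply_substrate_strain(h.mesh, 0.01)
        dt = h.program.dt
        U = h.displacements.reshape(len(h.times), -1)
        work = 0.0
        for n in range(len(h.times) - 51, len(h.times)):
            R = K @ U[n] + D @ ((U[n] - U[n - 1]) / dt)
            work += R[dofs] @ (U[n] - U[n - 1])[dofs]
        assert work > 0

    def test_peak_sequence_monotone_after_cycle_two(self, run_cell):
        """Per-cycle peak nuclear strain approaches its limit monotonically
        after the initial transient."""
        from cellstretch import per_cycle_peaks

        _, s = run_cell(freq=1.0)
        peaks = per_cycle_peaks(s).peak_x
        gaps = np.abs(peaks - peaks[-1])
        assert np.all(np.diff(gaps[1:]) <= 1e-9)

    def test_generalized_alpha_consistent_with_backward_euler(self, ci_mesh):
        eng = SimulationEngine(ci_mesh)
        runs = {}
        for scheme in ("backward_euler", "generalized_alpha"):
            runs[scheme] = eng.run(
                LoadingProgram(
                    make_sine_waveform(0.075, 0.1), n_cycles=1,
                    steps_per_cycle=100, scheme=scheme,
                )
            )
        a = runs["backward_euler"].displacements[-1]
        b = runs["generalized_alpha"].displacements[-1]
        assert np.abs(a - b).max() < 0.05 * np.abs(a).max()

    def test_run_simulation_wrapper(self):
        """run_simulation meshes, assembles and advances in one call."""
        import warnings

        from cellstretch import CellGeometry, MeshSizing, run_simulation
        from cellstretch.errors import InvalidParameterError as IPE

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = CellGeometry(cell_semi_axes=(6.0, 4.0, 3.0),
                             nucleus_semi_axes=(2.0, 1.5, 1.0),
                             nucleus_center=(0.0, 0.0, 1.3))
        prog = LoadingProgram(make_sine_waveform(0.05, 0.1), n_cycles=1)
        h = run_simulation(g, MeshSizing(2.0, 1.4, 0.8), program=prog)
        assert len(h.times) == 51
        assert np.all(h.displacements[0] == 0.0)
        assert np.abs(h.strain_series()).max() < 0.5
        with pytest.raises(IPE):
            run_simulation(g, MeshSizing(2.0, 1.4, 0.8))

    def test_singular_system_reported(self):
        """An exactly singular constrained operator (here: zero stiffness and
        damping, no constraints) raises a solver error naming the cause."""
        from cellstretch.errors import SolverError

        Z = sp.csr_matrix((3, 3))
        with pytest.raises(SolverError, match="singular"):
            ViscoelasticStepper(Z, Z, 0.1, np.array([], dtype=int))
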