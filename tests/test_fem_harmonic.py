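"""Pressure loads, sectioning, modal-superposition FRF and power."""

import numpy as np
import pytest
import scipy.linalg as sla
import trimesh

from bladderkit import fem
from bladderkit.fem.core import ConstrainedSystem, DOF_PER_NODE, ModalResult

ZETA = 0.325


def single_mode_modal(omega_n: float) -> ModalResult:
    """A 1-DOF 'structure' expressed as a modal basis (unit modal mass)."""
    import scipy.sparse as sp
    system = ConstrainedSystem(K=sp.eye(6).tocsr() * omega_n**2,
                               M=sp.eye(6).tocsr(),
                               free_dofs=np.arange(6), n_dof_full=6)
    shapes = np.zeros((6, 1))
    shapes[0, 0] = 1.0
    return ModalResult(frequencies_hz=np.array([omega_n / (2 * np.pi)]),
                       shapes=shapes, system=system)


def unit_point_load(n_nodes: int = 1) -> fem.HarmonicLoad:
    forces = np.zeros((n_nodes, 3))
    forces[0, 0] = 1.0
    return fem.HarmonicLoad(theta_deg=0.0, amplitude=1.0,
                            loaded_faces=np.array([0]),
                            nodal_forces=forces, projected_area=1.0)


def one_node_points() -> fem.RepresentativePoints:
    return fem.RepresentativePoints(node_ids=np.array([0]), labels=["p0"],
                                    coords=np.zeros((1, 3)))


class TestSingleModeFRF:
    omega_n = 2 * np.pi * 200.0

    def test_matches_damped_oscillator_closed_form(self):
        """|U| = |F| / sqrt((wn^2-w^2)^2 + (2 zeta wn w)^2) to 1e-9."""
        modal = single_mode_modal(self.omega_n)
        freqs = np.linspace(0.0, 350.0, 141)
        resp = fem.harmonic_response(modal, unit_point_load(), freqs, ZETA,
                                     one_node_points(), coverage_margin=0.5)
        w = 2 * np.pi * freqs
        exact = 1.0 / np.sqrt((self.omega_n**2 - w**2) ** 2
                              + (2 * ZETA * self.omega_n * w) ** 2)
        np.testing.assert_allclose(resp.magnitude[0], exact, rtol=1e-9)

    def test_displacement_peak_at_damped_resonance(self):
        """Amplitude peak sits at wn * sqrt(1 - 2 zeta^2)."""
        modal = single_mode_modal(self.omega_n)
        f_peak_exact = 200.0 * np.sqrt(1 - 2 * ZETA**2)
        freqs = np.linspace(100.0, 200.0, 20001)
        resp = fem.harmonic_response(modal, unit_point_load(), freqs, ZETA,
                                     one_node_points(), coverage_margin=0.5)
        f_peak = freqs[np.argmax(resp.magnitude[0])]
        assert f_peak == pytest.approx(f_peak_exact, abs=0.01)

    def test_zero_frequency_is_static_solution(self):
        modal = single_mode_modal(self.omega_n)
        resp = fem.harmonic_response(modal, unit_point_load(), np.array([0.0]),
                                     ZETA, one_node_points(), coverage_margin=0.0)
        assert resp.magnitude[0, 0] == pytest.approx(1.0 / self.omega_n**2,
                                                     rel=1e-12)

    def test_power_peaks_at_velocity_resonance(self):
        """P = w^2 |U|^2 / 2 peaks at w = wn for a single mode."""
        modal = single_mode_modal(self.omega_n)
        freqs = np.linspace(150.0, 250.0, 20001)
        resp = fem.harmonic_response(modal, unit_point_load(), freqs, ZETA,
                                     one_node_points(), coverage_margin=0.5)
        P = fem.compute_power(resp)
        assert freqs[np.argmax(P[0])] == pytest.approx(200.0, abs=0.01)

    def test_power_quadratic_in_displacement(self):
        modal = single_mode_modal(self.omega_n)
        freqs = np.array([100.0])
        r1 = fem.harmonic_response(modal, unit_point_load(), freqs, ZETA,
                                   one_node_points(), coverage_margin=0.5)
        load2 = unit_point_load()
        load2.nodal_forces *= 2.0
        r2 = fem.harmonic_response(modal, load2, freqs, ZETA,
                                   one_node_points(), coverage_margin=0.5)
        assert fem.compute_power(r2)[0, 0] == pytest.approx(
            4.0 * fem.compute_power(r1)[0, 0], rel=1e-12)

    def test_coverage_guard(self):
        modal = single_mode_modal(self.omega_n)
        with pytest.raises(ValueError, match="coverage"):
            fem.harmonic_response(modal, unit_point_load(),
                                  np.array([500.0]), ZETA, one_node_points(),
                                  coverage_margin=1.2)


class TestOracleEquivalence:
    def test_frf_matches_direct_full_system_solve(self):
        """Modal superposition (full basis) vs direct complex solve, <= 500 DOF.

        With a uniform modal damping ratio the equivalent viscous damping is
        C = M Phi diag(2 zeta wn) Phi^T M over the complete modal basis, and
        the direct solve of (K - w^2 M + i w C) U = F must agree.
        """
        from conftest import make_plate_mesh, plate_bending_system

        mesh = make_plate_mesh(0.1, 6)          # 49 nodes
        system = plate_bending_system(mesh, 0.1, 2.0e9, 0.3, 1e-3, 1500.0)
        nfree = system.K.shape[0]
        assert nfree <= 500
        Kd = system.K.toarray()
        Md = system.M.toarray()
        w2, Phi = sla.eigh(Kd, Md)              # complete basis
        wn = np.sqrt(np.clip(w2, 0, None))
        shapes = system.expand(Phi)
        modal = fem.ModalResult(frequencies_hz=wn / (2 * np.pi),
                                shapes=shapes, system=system)

        F_free = np.zeros(nfree)
        F_free[nfree // 2] = 1.0
        F_full = system.expand(F_free)
        n_nodes = shapes.shape[0] // DOF_PER_NODE
        load = fem.HarmonicLoad(
            theta_deg=0.0, amplitude=1.0, loaded_faces=np.array([0]),
            nodal_forces=np.zeros((n_nodes, 3)), projected_area=1.0)
        # route the arbitrary DOF force through the load vector by hand
        object.__setattr__(load, "as_dof_vector", lambda: F_full)

        pts = fem.RepresentativePoints(
            node_ids=np.arange(n_nodes), labels=[str(i) for i in range(n_nodes)],
            coords=np.asarray(mesh.vertices))
        freqs = np.arange(25.0, 751.0, 25.0)
        resp = fem.harmonic_response(modal, load, freqs, ZETA, pts,
                                     coverage_margin=0.0)

        C = Md @ Phi @ np.diag(2 * ZETA * wn) @ Phi.T @ Md
        U_direct = np.zeros((n_nodes, len(freqs), 3), dtype=complex)
        for i, f in enumerate(freqs):
            w = 2 * np.pi * f
            A = Kd - w**2 * Md + 1j * w * C
            u = np.linalg.solve(A, F_free)
            full = system.expand(u)
            U_direct[:, i, :] = full.reshape(n_nodes, DOF_PER_NODE)[:, :3]

        mag_modal = resp.magnitude
        mag_direct = np.linalg.norm(np.abs(U_direct), axis=2)
        scale = mag_direct.max()
        err = np.abs(mag_modal - mag_direct) / scale
        assert err.max() < 0.01


class TestPressureLoad:
    def test_unit_pressure_relation(self, horned_mesh):
        model = fem.FemModel.from_mesh_mm(horned_mesh)
        for th in (0.0, 45.0, 90.0, 135.0):
            load = fem.build_pressure_load(model, th, amplitude=1.0)
            total = np.linalg.norm(load.total_force)
            assert total / load.projected_area == pytest.approx(1.0, abs=1e-9)

    def test_sphere_projected_area(self):
        r_mm = 10.0
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=r_mm)
        model = fem.FemModel.from_mesh_mm(sphere)
        load = fem.build_pressure_load(model, 30.0)
        r_m = r_mm * 1e-3
        assert load.projected_area == pytest.approx(np.pi * r_m**2, rel=0.01)

    def test_opposite_angles_mirror(self, hornless_mesh):
        model = fem.FemModel.from_mesh_mm(hornless_mesh)
        la = fem.build_pressure_load(model, 90.0)
        lb = fem.build_pressure_load(model, 270.0)
        assert np.linalg.norm(la.total_force) == pytest.approx(
            np.linalg.norm(lb.total_force), rel=0.01)
        # forces point along opposite propagation directions
        ca = la.total_force / np.linalg.norm(la.total_force)
        cb = lb.total_force / np.linalg.norm(lb.total_force)
        assert ca @ cb == pytest.approx(-1.0, abs=1e-6)

    def test_invalid_inputs(self, hornless_mesh):
        model = fem.FemModel.from_mesh_mm(hornless_mesh)
        with pytest.raises(ValueError):
            fem.build_pressure_load(model, 380.0)
        with pytest.raises(ValueError):
            fem.build_pressure_load(model, 0.0, amplitude=0.0)


class TestSectioning:
    def test_sixteen_nonempty_sections(self, horned_mesh, hornless_mesh):
        for mesh in (horned_mesh, hornless_mesh):
            labels = fem.section_mesh(mesh)
            assert set(np.unique(labels)) == set(range(16))

    def test_azimuth_to_sector_mapping(self, hornless_mesh):
        labels = fem.section_mesh(hornless_mesh)
        centroids = hornless_mesh.triangles_center - hornless_mesh.centroid
        az = np.degrees(np.arctan2(centroids[:, 1], centroids[:, 0])) % 360
        np.testing.assert_array_equal(labels, (az // 22.5).astype(int))

    def test_rotation_shifts_sectors_cyclically(self, hornless_mesh):
        from scipy.spatial.transform import Rotation
        base = fem.section_mesh(hornless_mesh)
        m = hornless_mesh.copy()
        R = Rotation.from_euler("z", 22.5, degrees=True).as_matrix()
        m.vertices = (R @ (m.vertices - hornless_mesh.centroid).T).T
        rotated = fem.section_mesh(m)
        np.testing.assert_array_equal(rotated, (base + 1) % 16)


class TestRepresentativePoints:
    def test_hornless_count_48(self, hornless_mesh):
        sections = fem.section_mesh(hornless_mesh)
        pts = fem.select_representative_points(hornless_mesh, sections)
        assert len(pts.node_ids) == 48

    def test_horned_count_50(self, horned_mesh):
        sections = fem.section_mesh(horned_mesh)
        pts = fem.select_representative_points(horned_mesh, sections)
        assert len(pts.node_ids) == 50
        assert pts.labels[-2:] == ["horn_left", "horn_right"]

    def test_ids_are_valid_nodes(self, horned_mesh):
        sections = fem.section_mesh(horned_mesh)
        pts = fem.select_representative_points(horned_mesh, sections)
        assert pts.node_ids.min() >= 0
        assert pts.node_ids.max() < len(horned_mesh.vertices)


class TestCompareStates:
    def _responses(self, scale=1.0):
        modal = single_mode_modal(2 * np.pi * 200.0)
        pts = one_node_points()
        grid = fem.response_grid(750.0, 25.0)
        out = {}
        for th in (0.0, 90.0):
            load = unit_point_load()
            load.nodal_forces *= scale
            out[th] = fem.harmonic_response(modal, load, grid, ZETA, pts,
                                            coverage_margin=0.0)
        return out

    def test_identical_models_zero_difference(self):
        cmp = fem.compare_states(self._responses(), self._responses())
        assert np.allclose(cmp["difference"], 0.0)

    def test_load_scaling_quadruples_power(self):
        c1 = fem.compare_states(self._responses(), self._responses(2.0))
        np.testing.assert_allclose(c1["power_b"], 4.0 * c1["power_a"],
                                   rtol=1e-12)

    def test_angle_mismatch_rejected(self):
        a = self._responses()
        b = {0.0: a[0.0]}
        with pytest.raises(ValueError):
            fem.compare_states(a, b)
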