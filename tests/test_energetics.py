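import numpy as np
import pytest

import solvshell as sv
from solvshell.energetics import _fibonacci_sphere, dihedral_angle
from solvshell.structure import RadialDistribution, ShellPartition
from solvshell.trajectory_io import Topology


def _rdf_from_g(g, dr=0.05):
    g = np.asarray(g, dtype=float)
    edges = np.linspace(0, len(g) * dr, len(g) + 1)
    return RadialDistribution(bin_edges=edges, g=g, rho=0.03,
                              cumulative_cn=np.zeros(len(g) + 1), n_frames=1)


class TestPMF:
    def test_unit_correlation_is_zero_free_energy(self):
        pmf = sv.pmf_from_rdf(_rdf_from_g(np.ones(50)), T=298.15)
        np.testing.assert_allclose(pmf.w, 0.0, atol=1e-15)

    def test_hand_evaluated_value_at_g_two(self):
        pmf = sv.pmf_from_rdf(_rdf_from_g([2.0]), T=298.15)
        assert pmf.w[0] == pytest.approx(-1.7182, abs=1e-3)

    def test_zero_density_masked_not_infinite(self):
        pmf = sv.pmf_from_rdf(_rdf_from_g([0.0, 1.0, 2.0]), T=300.0)
        assert np.isnan(pmf.w[0]) and np.isfinite(pmf.w[1:]).all()

    def test_round_trip_to_machine_precision(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0.05, 15.0, size=80)
        pmf = sv.pmf_from_rdf(_rdf_from_g(g), T=298.15)
        np.testing.assert_allclose(sv.rdf_from_pmf(pmf), g, rtol=1e-12)

    def test_well_depths_per_shell(self):
        r = np.arange(0.025, 6.0, 0.05)
        g = 1.0 + 13.0 * np.exp(-((r - 2.2) / 0.2) ** 2)
        pmf = sv.pmf_from_rdf(_rdf_from_g(g), T=298.15)
        wells = pmf.wells(ShellPartition([3.2], [False]))
        pos, depth = wells[0]
        assert pos == pytest.approx(2.2, abs=0.06)
        assert depth == pytest.approx(-8.314 * 298.15 * np.log(14.0) / 1000,
                                      abs=0.05)


def _single_atom_topology(radius=1.5):
    return Topology(elements=["C"], names=["C1"], roles=["ring_C_alpha"],
                    vdw_radius=np.array([radius]), polarity=["hydrophobic"])


def _two_atom_topology(radius=1.5):
    return Topology(elements=["C", "N"], names=["C1", "N1"],
                    roles=["ring_C_alpha", "ring_N"],
                    vdw_radius=np.array([radius, radius]),
                    polarity=["hydrophobic", "hydrophilic"])


def two_sphere_sasa_analytic(r1, r2, d):
    """Closed-form accessible area (nm²) of two fused spheres (radii incl. probe)."""
    if d >= r1 + r2:
        return (4 * np.pi * (r1**2 + r2**2)) / 100.0
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    a1 = 4 * np.pi * r1**2 - 2 * np.pi * r1 * h1
    a2 = 4 * np.pi * r2**2 - 2 * np.pi * r2 * h2
    return (a1 + a2) / 100.0


class TestSASA:
    def test_single_sphere_analytic_area(self):
        res = sv.compute_sasa(np.zeros((1, 3)), _single_atom_topology(),
                              probe_radius=1.4, n_points=960)
        analytic = 4 * np.pi * 2.9**2 / 100.0
        assert res.total == pytest.approx(analytic, rel=0.02)

    def test_coincident_spheres_add_nothing(self):
        topo = _two_atom_topology()
        res = sv.compute_sasa(np.zeros((2, 3)), topo, probe_radius=1.4,
                              n_points=960)
        single = sv.compute_sasa(np.zeros((1, 3)), _single_atom_topology(),
                                 probe_radius=1.4, n_points=960)
        assert res.total == pytest.approx(single.total, rel=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0])
    def test_fused_two_sphere_closed_form(self, d):
        topo = _two_atom_topology()
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        res = sv.compute_sasa(coords, topo, probe_radius=1.4, n_points=960)
        assert res.total == pytest.approx(two_sphere_sasa_analytic(2.9, 2.9, d),
                                          rel=0.02)

    def test_decomposition_sums_exactly(self, scaffold):
        topo, coords = scaffold
        res = sv.compute_sasa(coords, topo)
        assert res.hydrophobic + res.hydrophilic == pytest.approx(res.total,
                                                                  abs=1e-10)
        assert np.all(res.per_atom >= 0)

    def test_missing_radius_names_atom(self):
        topo = Topology(elements=["C", "X"], names=["C1", "X1"],
                        roles=["ring_C_alpha", "ring_C_beta"],
                        vdw_radius=np.array([1.7, np.nan]),
                        polarity=["hydrophobic", "hydrophobic"])
        with pytest.raises(ValueError, match="X1"):
            sv.compute_sasa(np.zeros((2, 3)), topo)

    def test_rigid_motion_invariance(self, scaffold):
        # the fixed lab-frame sample lattice leaves O(1/√n_points) residual
        # orientation dependence, ≲1% of the total for 960 points
        topo, coords = scaffold
        traj, _ = sv.generate_rigid_body_trajectory(scaffold, 4, seed=6)
        base = sv.compute_sasa(coords, topo)
        for f in range(4):
            moved = sv.compute_sasa(traj.coordinates[f], topo)
            assert moved.total == pytest.approx(base.total, rel=0.01)

    def test_time_average_of_static_equals_single_frame(self, scaffold):
        topo, coords = scaffold
        traj = sv.Trajectory(np.repeat(coords[None], 3, axis=0), dt=1.0)
        avg = sv.time_averaged_sasa(traj, topo)
        single = sv.compute_sasa(coords, topo)
        assert avg.total == pytest.approx(single.total, abs=1e-12)
        assert avg.hydrophobic + avg.hydrophilic == pytest.approx(avg.total,
                                                                  abs=1e-10)


class TestRMSF:
    def test_rigid_body_fluctuations_vanish(self, scaffold):
        traj, topo = sv.generate_rigid_body_trajectory(scaffold, 40, seed=2)
        prof = sv.compute_rmsf(sv.kabsch_align(traj, topo), topo)
        assert prof.rmsf.max() < 1e-6

    def test_isotropic_jitter_recovers_sigma_root_three(self, scaffold):
        sigma = 0.1
        traj, topo = sv.generate_rigid_body_trajectory(scaffold, 2000, seed=3,
                                                       jitter=sigma)
        prof = sv.compute_rmsf(sv.kabsch_align(traj, topo), topo)
        expected = sigma * np.sqrt(3.0)
        assert np.mean(prof.rmsf) == pytest.approx(expected, rel=0.05)

    def test_default_selection_excludes_hydrogens_and_metal(self, scaffold):
        traj, topo = sv.generate_rigid_body_trajectory(scaffold, 5, seed=4)
        prof = sv.compute_rmsf(sv.kabsch_align(traj, topo), topo)
        roles = [topo.roles[i] for i in prof.atom_ids]
        assert "metal" not in roles and "ring_H" not in roles
        assert set(roles) <= {"ring_N", "ring_C_alpha", "ring_C_beta",
                              "ring_C_meso"}

    def test_added_global_motion_changes_nothing(self, scaffold):
        from scipy.spatial.transform import Rotation

        sigma = 0.05
        traj, topo = sv.generate_rigid_body_trajectory(scaffold, 100, seed=5,
                                                       jitter=sigma)
        p1 = sv.compute_rmsf(sv.kabsch_align(traj, topo), topo)
        rng = np.random.default_rng(0)
        moved = traj.coordinates.copy()
        R = Rotation.random(random_state=rng).as_matrix()
        moved = moved @ R.T + np.array([5.0, -3.0, 1.0])
        p2 = sv.compute_rmsf(sv.kabsch_align(sv.Trajectory(moved, dt=1.0), topo),
                             topo)
        np.testing.assert_allclose(p1.rmsf, p2.rmsf, atol=1e-6)


class TestDihedral:
    def test_cis_planar_is_zero(self):
        ang = dihedral_angle([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0])
        assert ang == pytest.approx(0.0, abs=1e-10)

    def test_trans_planar_is_180(self):
        ang = dihedral_angle([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0])
        assert abs(ang) == pytest.approx(180.0, abs=1e-10)

    def test_right_handed_quarter_twist_sign(self):
        # independent construction: sign from the triple product (n1 × n2)·b2
        p1, p2, p3, p4 = (np.array(p, float) for p in
                          ([1, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 1]))
        ang = dihedral_angle(p1, p2, p3, p4)
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        mag = np.degrees(np.arccos(
            np.clip(n1 @ n2 / np.linalg.norm(n1) / np.linalg.norm(n2), -1, 1)))
        sign = np.sign(np.cross(n1, n2) @ b2)
        assert ang == pytest.approx(sign * mag, abs=1e-10)
        assert abs(ang) == pytest.approx(90.0, abs=1e-10)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


class TestTorsionDistribution:
    def test_planar_scaffold_proper_torsion_at_zero(self, scaffold):
        topo, coords = scaffold
        traj = sv.Trajectory(np.repeat(coords[None], 10, axis=0), dt=1.0)
        td = sv.torsion_distribution(traj, topo.torsion_quadruples["proper"],
                                     bin_width=5.0)
        nonzero = np.nonzero(td.average)[0]
        assert len(nonzero) == 1
        lo = td.bin_edges[nonzero[0]]
        assert lo <= 0 < td.bin_edges[nonzero[0] + 1]

    def test_four_impropers_identical_by_symmetry(self, scaffold):
        topo, coords = scaffold
        traj = sv.Trajectory(np.repeat(coords[None], 5, axis=0), dt=1.0)
        td = sv.torsion_distribution(traj, topo.torsion_quadruples["improper"])
        for q in range(1, td.per_quadruple.shape[0]):
            hist_folded = td.per_quadruple[q]
            np.testing.assert_allclose(
                sorted(hist_folded[hist_folded > 0]),
                sorted(td.per_quadruple[0][td.per_quadruple[0] > 0]))

    def test_width_grows_with_jitter_and_mean_near_zero(self, scaffold):
        topo, _ = scaffold
        widths = []
        for sigma in (0.02, 0.08):
            traj, _ = sv.generate_rigid_body_trajectory(scaffold, 400, seed=8,
                                                        jitter=sigma)
            td = sv.torsion_distribution(traj, topo.torsion_quadruples["proper"],
                                         bin_width=2.0)
            mean = float(np.sum(td.angles * td.average))
            var = float(np.sum((td.angles - mean) ** 2 * td.average))
            widths.append(np.sqrt(var))
            assert abs(mean) < 3 * np.sqrt(var / 400) + 2.0
        assert widths[1] > widths[0]

    def test_running_average_preserves_mass(self, scaffold):
        topo, coords = scaffold
        traj, _ = sv.generate_rigid_body_trajectory(scaffold, 50, seed=9,
                                                    jitter=0.05)
        td = sv.torsion_distribution(
            traj, topo.torsion_quadruples["proper"]
            + topo.torsion_quadruples["improper"])
        assert td.average.sum() == pytest.approx(1.0, abs=1e-12)
        assert td.running_average.sum() == pytest.approx(1.0, abs=1e-9)
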