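import numpy as np
import pytest

import solvshell as sv
from conftest import brute_force_pair_histogram
from solvshell.structure import RadialDistribution


def _make_rdf(g, dr=0.05, rho=0.03):
    g = np.asarray(g, dtype=float)
    edges = np.linspace(0, len(g) * dr, len(g) + 1)
    shell_vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    cn = np.concatenate([[0.0], np.cumsum(g * rho * shell_vol)])
    return RadialDistribution(bin_edges=edges, g=g, rho=rho, cumulative_cn=cn,
                              n_frames=1)


class TestRDF:
    def test_matches_brute_force_bit_exact(self):
        traj, topo = sv.generate_ideal_gas_box(50, 12.0, 3, seed=7)
        rdf = sv.compute_rdf(traj, topo, "other", "other", r_max=6.0, dr=0.05)
        edges = rdf.bin_edges
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
        idx = np.arange(50)
        for f in range(3):
            counts += brute_force_pair_histogram(traj.coordinates[f], idx, idx,
                                                 12.0, edges)
        shell_vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        g_oracle = counts / (3 * 50 * rdf.rho * shell_vol)
        np.testing.assert_array_equal(rdf.g, g_oracle)

    def test_single_axial_water_occupies_single_bin(self, scaffold):
        shells = sv.ShellSpec([(1.93, 2.67)], [1], placement_radius=[2.2])
        traj, topo = sv.generate_shell_snapshot(scaffold, shells, seed=1,
                                                hydrogens=False)
        rdf = sv.compute_rdf(traj, topo, "metal", "water_O", r_max=4.0, dr=0.05,
                             rho=0.03299)
        occupied = np.nonzero(rdf.g)[0]
        assert len(occupied) == 1
        assert rdf.bin_edges[occupied[0]] == pytest.approx(2.20)
        assert sv.integrate_coordination(rdf, 2.67) == 1.0

    def test_ideal_gas_unit_pair_correlation(self):
        traj, topo = sv.generate_ideal_gas_box(300, 15.0, 40, seed=8)
        rdf = sv.compute_rdf(traj, topo, "other", "other", r_max=7.0, dr=0.1)
        # 3σ band from the raw bin counts
        shell_vol = 4 / 3 * np.pi * np.diff(rdf.bin_edges**3)
        expected_counts = rdf.n_frames * 300 * rdf.rho * shell_vol
        mask = rdf.r > 1.0
        sigma = 1.0 / np.sqrt(expected_counts[mask])
        assert np.all(np.abs(rdf.g[mask] - 1.0) < 3.5 * sigma + 0.01)

    def test_r_max_beyond_half_box_rejected(self):
        traj, topo = sv.generate_ideal_gas_box(10, 10.0, 1, seed=0)
        with pytest.raises(ValueError, match="half the box"):
            sv.compute_rdf(traj, topo, "other", "other", r_max=6.0)

    def test_empty_selection_rejected(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        with pytest.raises(ValueError, match="empty"):
            sv.compute_rdf(traj, topo, "metal", "other", r_max=3.0)


class TestCoordinationIntegral:
    def test_two_axial_waters_integrate_to_two(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        rdf = sv.compute_rdf(traj, topo, "metal", "water_O", r_max=4.0, dr=0.05,
                             rho=0.03299)
        assert sv.integrate_coordination(rdf, 2.38) == 2.0

    def test_zero_below_first_occupied_bin(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        rdf = sv.compute_rdf(traj, topo, "metal", "water_O", r_max=4.0, dr=0.05,
                             rho=0.03299)
        assert sv.integrate_coordination(rdf, 1.5) == 0.0

    def test_ideal_gas_closed_form(self):
        n, box = 400, 16.0
        traj, topo = sv.generate_ideal_gas_box(n, box, 30, seed=9)
        rdf = sv.compute_rdf(traj, topo, "other", "other", r_max=7.0, dr=0.05)
        r_c = 5.0
        expected = 4 / 3 * np.pi * r_c**3 * (n / box**3) * (n - 1) / n
        assert sv.integrate_coordination(rdf, r_c) == pytest.approx(expected,
                                                                    rel=0.03)

    def test_cut_outside_grid_rejected(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        rdf = sv.compute_rdf(traj, topo, "metal", "water_O", r_max=4.0,
                             rho=0.03299)
        with pytest.raises(ValueError):
            sv.integrate_coordination(rdf, 5.0)


class TestShellBoundaries:
    def test_separated_peaks_boundary_at_gap_midpoint(self):
        r = np.arange(0.025, 6.0, 0.05)
        g = np.exp(-((r - 2.2) / 0.15) ** 2) * 10 + np.exp(-((r - 4.2) / 0.15) ** 2) * 3
        g[g < 1e-3] = 0.0
        part = sv.detect_shell_boundaries(_make_rdf(g), n_shells=1)
        assert part.boundaries[0] == pytest.approx(3.2, abs=0.15)
        assert part.zero_minimum[0] is True

    def test_monotone_profile_rejected(self):
        g = np.linspace(0, 2, 100)
        with pytest.raises(ValueError):
            sv.detect_shell_boundaries(_make_rdf(g), n_shells=1)

    def test_overlapping_tails_nonzero_minimum(self):
        r = np.arange(0.025, 6.0, 0.05)
        g = np.exp(-((r - 2.2) / 0.5) ** 2) * 10 + np.exp(-((r - 4.2) / 0.5) ** 2) * 6
        part = sv.detect_shell_boundaries(_make_rdf(g), n_shells=1)
        # analytic saddle of the two Gaussians lies between the peaks
        assert 2.8 < part.boundaries[0] < 3.8
        assert part.zero_minimum[0] is False

    def test_flat_noisy_profile_has_no_shells(self):
        rng = np.random.default_rng(0)
        g = 1.0 + rng.normal(scale=0.03, size=150)
        with pytest.raises(ValueError, match="boundaries"):
            sv.detect_shell_boundaries(_make_rdf(g), n_shells=1)


class TestADF:
    def test_octahedron_angle_ratio_12_to_3(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        adf = sv.compute_adf(traj, topo, r_cut=2.67, bin_width=2.0)
        assert adf.n_angles == 15
        near_90 = adf.counts[np.abs(adf.angles - 90.0) < 3.0].sum()
        near_180 = adf.counts[adf.angles > 176.0].sum()
        assert (near_90, near_180) == (12, 3)

    def test_square_pyramid_ratio_8_to_2(self, square_pyramid_snapshot):
        traj, topo = square_pyramid_snapshot
        adf = sv.compute_adf(traj, topo, r_cut=2.67, bin_width=2.0)
        assert adf.n_angles == 10
        near_90 = adf.counts[np.abs(adf.angles - 90.0) < 3.0].sum()
        near_180 = adf.counts[adf.angles > 176.0].sum()
        assert (near_90, near_180) == (8, 2)

    def test_jittered_octahedron_peaks_near_90_and_177(self, scaffold):
        shells = sv.ShellSpec([(1.4, 3.0)], [2], jitter=0.12,
                              placement_radius=[2.2])
        rng_frames = []
        for s in range(60):
            t, topo = sv.generate_shell_snapshot(scaffold, shells, seed=100 + s,
                                                 hydrogens=False)
            rng_frames.append(t.coordinates[0])
        traj = sv.Trajectory(np.stack(rng_frames), dt=1.0)
        adf = sv.compute_adf(traj, topo, r_cut=3.0, bin_width=2.0)
        lo = adf.frequency[(adf.angles > 60) & (adf.angles < 120)]
        peak_lo = adf.angles[(adf.angles > 60) & (adf.angles < 120)][np.argmax(lo)]
        hi = adf.frequency[adf.angles > 150]
        peak_hi = adf.angles[adf.angles > 150][np.argmax(hi)]
        assert abs(peak_lo - 90) <= 4
        assert peak_hi >= 172

    def test_invariant_under_global_rotation(self, octahedral_snapshot):
        from scipy.spatial.transform import Rotation

        traj, topo = octahedral_snapshot
        R = Rotation.from_euler("zyx", [30, 40, 50], degrees=True).as_matrix()
        rot = sv.Trajectory(traj.coordinates @ R.T, dt=traj.dt)
        a1 = sv.compute_adf(traj, topo, r_cut=2.67)
        a2 = sv.compute_adf(rot, topo, r_cut=2.67)
        np.testing.assert_array_equal(a1.counts, a2.counts)


class TestCND:
    def test_static_octahedron_is_pure_six(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        static = sv.repeat_snapshot(traj, 100)
        cnd = sv.compute_cnd(static, topo, r_cut=2.67)
        assert cnd.p(6) == 1.0

    def test_exchange_splits_five_and_six(self, scaffold):
        shells = sv.ShellSpec([(1.93, 2.67), (3.27, 5.03)], [0, 0])
        spec = sv.ExchangeSpec(rate=1.0, n_ligands=2, duration=30.0, dt=0.05,
                               seed=13)
        traj, topo, log = sv.generate_exchange_trajectory(scaffold, spec, shells)
        cnd = sv.compute_cnd(traj, topo, r_cut=2.67)
        # 4 N plus 0..2 first-shell waters
        assert cnd.p(4) + cnd.p(5) + cnd.p(6) == pytest.approx(1.0)
        assert cnd.p(5) > 0
        # recount from the generator's own series
        first_shell = (log.shell_series == 0).sum(axis=1) + 4
        vals, cts = np.unique(first_shell, return_counts=True)
        for v, c in zip(vals, cts):
            assert cnd.p(int(v)) == pytest.approx(c / len(first_shell))

    def test_vanishing_cutoff_gives_zero_coordination(self, octahedral_snapshot):
        traj, topo = octahedral_snapshot
        cnd = sv.compute_cnd(traj, topo, r_cut=1e-6)
        assert cnd.p(0) == 1.0

    def test_mean_equals_coordination_integral(self):
        # same counting through two routes: per-frame CND mean vs cumulative n(r)
        traj, topo = sv.generate_ideal_gas_box(60, 14.0, 10, seed=5)
        rdf = sv.compute_rdf(traj, topo, None, None, r_max=6.0, dr=0.05,
                             center_indices=[0], target_indices=np.arange(60))
        r_cut = 5.0
        from solvshell.trajectory_io import minimum_image_distance

        counts = [
            int(np.sum(minimum_image_distance(traj.coordinates[f][0],
                                              traj.coordinates[f][1:], 14.0)
                       < r_cut))
            for f in range(10)
        ]
        assert np.mean(counts) == pytest.approx(
            sv.integrate_coordination(rdf, r_cut), abs=1e-10)


class TestNHCND:
    def test_metal_oriented_hydrogens_never_bond(self, scaffold):
        shells = sv.ShellSpec([(1.93, 2.67)], [2], placement_radius=[2.2])
        traj, topo = sv.generate_shell_snapshot(scaffold, shells, seed=3,
                                                hydrogen_mode="away")
        cnd = sv.compute_nh_cnd(sv.repeat_snapshot(traj, 20), topo)
        assert cnd.p(0) == 1.0

    def test_constructed_close_hydrogen_counts_once(self, scaffold):
        topo0, base = scaffold
        n1 = topo0.ring_n_indices[0]
        h = base[n1] + np.array([0.0, 0.0, 1.9])
        o = h + np.array([0.0, 0.0, 0.957])
        coords = np.vstack([base, o[None], h[None]])
        topo = sv.Topology(
            elements=list(topo0.elements) + ["O", "H"],
            names=list(topo0.names) + ["OW1", "HW11"],
            roles=list(topo0.roles) + ["water_O", "water_H"],
            water_parent={len(base) + 1: len(base)},
        )
        traj = sv.Trajectory(coords[None], dt=1.0)
        cnd = sv.compute_nh_cnd(traj, topo, h_bond_cutoff=2.5)
        assert cnd.p(1) == 1.0

    def test_matches_brute_force_recount(self, scaffold):
        shells = sv.ShellSpec([(1.93, 2.67), (3.0, 4.5)], [2, 4], jitter=0.1)
        traj, topo = sv.generate_shell_snapshot(scaffold, shells, seed=17,
                                                hydrogen_mode="random")
        static = sv.repeat_snapshot(traj, 10)
        cnd = sv.compute_nh_cnd(static, topo, h_bond_cutoff=3.5)
        ring_n = topo.ring_n_indices
        water_h = topo.indices_with_role("water_H")
        frame = traj.coordinates[0]
        count = sum(
            1 for h in water_h
            if any(np.linalg.norm(frame[h] - frame[n]) < 3.5 for n in ring_n)
        )
        assert cnd.p(count) == 1.0
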