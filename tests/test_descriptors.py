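"""Descriptor calculations checked against analytic values, high-density
oracles, and hand-enumerated toys."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggkin import descriptors as D
from aggkin import synthgen
from aggkin.trajio import Trajectory

from conftest import ca_chain_trajectory, make_atom


def rotation_z(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th), 0],
                     [np.sin(th), np.cos(th), 0],
                     [0, 0, 1.0]])


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        _, rmsd = D.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        pts = np.random.default_rng(1).normal(size=(8, 3)) * 3
        moved = pts @ rotation_z(37).T + np.array([1.0, 2.0, 3.0])
        _, rmsd = D.kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_align_vectors(self):
        # independent oracle: scipy's orthogonal Procrustes solution
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 3)) * 2
        mob = ref + rng.normal(scale=0.3, size=(4, 3))
        _, rmsd = D.kabsch_superpose(mob, ref)
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        aligned = rot.apply(mob - mob.mean(0)) + ref.mean(0)
        oracle = np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean())
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_no_sampled_rotation_beats_the_solution(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        ref = rng.normal(size=(5, 3)) * 2
        mob = ref + rng.normal(scale=0.5, size=(5, 3))
        _, rmsd = D.kabsch_superpose(mob, ref)
        mc = mob - mob.mean(0)
        rc = ref - ref.mean(0)
        for rot in Rotation.random(2000, random_state=4):
            cand = np.sqrt(((rot.apply(mc) - rc) ** 2).sum(axis=1).mean())
            assert cand >= rmsd - 1e-3

    def test_reflection_excluded(self):
        # a mirrored copy must NOT superpose to zero: proper rotations only
        pts = np.random.default_rng(5).normal(size=(6, 3)) * 2
        mirrored = pts.copy()
        mirrored[:, 0] *= -1
        _, rmsd = D.kabsch_superpose(mirrored, pts)
        assert rmsd > 0.1

    def test_input_validation(self):
        pts = np.zeros((4, 3))
        with pytest.raises(ValueError):
            D.kabsch_superpose(pts, np.zeros((5, 3)))
        with pytest.raises(ValueError, match="weights"):
            D.kabsch_superpose(pts, pts, weights=np.zeros(4))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, static_trajectory):
        series = D.rmsd_series(static_trajectory)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_uniform_translation_removed(self):
        base = np.random.default_rng(0).normal(size=(5, 3))
        shifted = base + np.array([1.0, 0, 0])
        traj = ca_chain_trajectory([base, shifted])
        series = D.rmsd_series(traj)
        assert series[1] == pytest.approx(0.0, abs=1e-9)

    def test_three_frame_toy_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        frames = [rng.normal(size=(4, 3)) * 2 for _ in range(3)]
        traj = ca_chain_trajectory(frames)
        series = D.rmsd_series(traj)
        for f in range(3):
            aligned, _ = D.kabsch_superpose(frames[f], frames[0])
            direct = np.sqrt(((aligned - frames[0]) ** 2).sum(axis=1).mean())
            assert series[f] == pytest.approx(direct, abs=1e-12)

    def test_rigid_motion_invariance(self, helix_trajectory):
        series = D.rmsd_series(helix_trajectory)
        R = rotation_z(63.0)
        moved = Trajectory(
            topology=helix_trajectory.topology,
            coordinates=helix_trajectory.coordinates @ R.T + 5.0,
            times=helix_trajectory.times,
        )
        np.testing.assert_allclose(D.rmsd_series(moved), series, atol=1e-6)


class TestRmsf:
    def test_static_trajectory_zero(self, static_trajectory):
        rmsf = D.rmsf_per_residue(static_trajectory)
        np.testing.assert_allclose(rmsf.to_numpy(), 0.0, atol=1e-9)

    def test_isotropic_gaussian_expectation(self):
        # 3-D isotropic jitter of scale sigma has E[RMSF] = sigma * sqrt(3)
        sigma = 0.5
        n_res, n_frames = 30, 5000
        spec = synthgen.TrajectorySpec(n_residues=n_res, n_frames=n_frames,
                                       sigma_profile=sigma, seed=42)
        traj = synthgen.synth_trajectory(spec)
        rmsf = D.rmsf_per_residue(traj, superpose=False,
                                  use_last_window=False)
        per_res = rmsf.to_numpy()
        se = per_res.std(ddof=1) / np.sqrt(n_res)
        assert abs(per_res.mean() - sigma * np.sqrt(3)) < 3 * se

    def test_two_frame_displacement_hand_value(self):
        # one atom moves 2 A between two frames: mean position sits 1 A from
        # each, so that residue's RMSF is exactly 1
        base = np.array([[0.0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0]])
        moved = base.copy()
        moved[2, 0] += 2.0
        traj = ca_chain_trajectory([base, moved])
        rmsf = D.rmsf_per_residue(traj, superpose=False,
                                  use_last_window=False)
        assert rmsf.loc[3] == pytest.approx(1.0, abs=1e-12)
        assert rmsf.loc[1] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_duplicate_atoms_per_residue(self):
        topo = [make_atom(1, "CA", "C", "GLY", 1),
                make_atom(2, "CA", "C", "GLY", 1)]
        traj = Trajectory(topology=topo,
                          coordinates=np.zeros((3, 2, 3)))
        with pytest.raises(ValueError, match="one atom per residue"):
            D.rmsf_per_residue(traj, selection=np.array([0, 1]))


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        traj = ca_chain_trajectory(np.zeros((1, 3)))
        assert D.radius_of_gyration(traj)[0] == 0.0

    def test_two_equal_masses_two_angstrom(self):
        traj = ca_chain_trajectory(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert D.radius_of_gyration(traj)[0] == pytest.approx(1.0, abs=1e-12)

    def test_random_atoms_match_direct_formula(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(10, 3)) * 3
        elements = rng.choice(["C", "N", "O", "S"], size=10)
        topo = [make_atom(i + 1, el, el, "GLY", i + 1)
                for i, el in enumerate(elements)]
        traj = Trajectory(topology=topo, coordinates=coords[None])
        m = traj.masses
        com = (m[:, None] * coords).sum(0) / m.sum()
        direct = np.sqrt((m * ((coords - com) ** 2).sum(1)).sum() / m.sum())
        assert D.radius_of_gyration(traj)[0] == pytest.approx(direct,
                                                              abs=1e-12)


class TestSasa:
    def test_isolated_carbon_analytic_sphere(self):
        area = D.shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.70]),
                                    probe_radius=1.4, sphere_points=960)
        analytic = 4 * np.pi * 3.1 ** 2
        assert area[0] == pytest.approx(analytic, rel=0.01)

    def test_fully_enclosed_atom_zero(self):
        # cage of large neighbours on a sphere around the central atom
        mesh = D._golden_spiral(60)
        coords = np.vstack([[0.0, 0, 0], 2.0 * mesh])
        radii = np.array([1.5] + [2.0] * 60)
        area = D.shrake_rupley_sasa(coords, radii, subset=np.array([0]))
        assert area[0] == 0.0

    def test_two_spheres_match_high_density_mesh_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        radii = np.array([1.70, 1.70])
        ours = D.shrake_rupley_sasa(coords, radii, sphere_points=960)
        oracle = D.shrake_rupley_sasa(coords, radii, sphere_points=100_000)
        np.testing.assert_allclose(ours, oracle, rtol=0.005)

    def test_mesh_convergence_doubling_points(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(5, 3)) * 1.5
        radii = np.full(5, 1.6)
        a1 = D.shrake_rupley_sasa(coords, radii, sphere_points=960)
        a2 = D.shrake_rupley_sasa(coords, radii, sphere_points=1920)
        assert np.all(np.abs(a1 - a2) <= 0.01 * np.maximum(a2, 1.0))

    def test_cross_check_against_biotite(self):
        # independent established implementation on the same radii
        import biotite.structure as struc

        rng = np.random.default_rng(9)
        coords = rng.normal(size=(6, 3)) * 2
        radii = np.full(6, 1.7)
        arr = struc.AtomArray(6)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 6)
        arr.res_id = np.arange(1, 7)
        arr.res_name = np.array(["GLY"] * 6)
        arr.atom_name = np.array(["CA"] * 6)
        arr.chain_id = np.array(["A"] * 6)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                         vdw_radii=radii)
        ours = D.shrake_rupley_sasa(coords.astype(np.float32).astype(float),
                                    radii, sphere_points=5000)
        np.testing.assert_allclose(ours, ref, rtol=0.03, atol=0.5)

    def test_nonpolar_is_carbon_subset_additivity(self):
        # toy molecule with C and N atoms: nonpolar = sum of per-carbon areas
        topo = [make_atom(1, "C1", "C", "UNK", 1),
                make_atom(2, "N1", "N", "UNK", 1),
                make_atom(3, "C2", "C", "UNK", 2),
                make_atom(4, "O1", "O", "UNK", 2),
                make_atom(5, "C3", "C", "UNK", 3)]
        coords = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0],
                           [1, 1, 1.5]])
        traj = Trajectory(topology=topo, coordinates=coords[None])
        per_atom = D.shrake_rupley_sasa(coords, traj.vdw_radii)
        carbon = traj.elements == "C"
        assert D.nonpolar_sasa(traj) == pytest.approx(per_atom[carbon].sum(),
                                                      rel=1e-9)
        assert D.total_sasa(traj) == pytest.approx(per_atom.sum(), rel=1e-9)

    def test_structure_without_carbon_has_zero_nonpolar_sasa(self):
        topo = [make_atom(1, "N", "N", "UNK", 1)]
        traj = Trajectory(topology=topo, coordinates=np.zeros((1, 1, 3)))
        assert D.nonpolar_sasa(traj) == 0.0

    def test_hydrogens_excluded_from_subset_and_occluders(self):
        topo = [make_atom(1, "C1", "C", "UNK", 1),
                make_atom(2, "H1", "H", "UNK", 1)]
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        traj = Trajectory(topology=topo, coordinates=coords[None])
        isolated = 4 * np.pi * (1.70 + 1.4) ** 2
        assert D.total_sasa(traj) == pytest.approx(isolated, rel=0.01)


class TestDeltaSasa:
    def test_static_trajectory_zero(self, static_trajectory):
        region = D.APRRegion("r_2-4", 2, 4)
        cfg = D.DescriptorConfig(baseline_frames=5, sphere_points=240)
        assert D.delta_sasa_region([static_trajectory], region, cfg) == \
            pytest.approx(0.0, abs=1e-9)

    def test_step_signal_recovers_difference(self):
        # region SASA steps when a blocking atom departs mid-trajectory
        near = np.array([[0.0, 0, 0], [2.2, 0, 0]])
        far = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        frames = [near] * 10 + [far] * 10
        traj = ca_chain_trajectory(frames)
        region = D.APRRegion("r_1-1", 1, 1)
        cfg = D.DescriptorConfig(baseline_frames=10,
                                 last_window_fraction=0.5,
                                 sphere_points=2000)
        delta = D.delta_sasa_region([traj], region, cfg)
        radii = np.array([1.70, 1.70])
        blocked = D.shrake_rupley_sasa(near, radii, subset=np.array([0]),
                                       sphere_points=2000)[0]
        free = D.shrake_rupley_sasa(far, radii, subset=np.array([0]),
                                    sphere_points=2000)[0]
        assert delta == pytest.approx(free - blocked, abs=1e-9)

    def test_too_few_frames_rejected(self, helix_trajectory):
        cfg = D.DescriptorConfig(baseline_frames=1000)
        with pytest.raises(ValueError, match="baseline"):
            D.delta_sasa_region([helix_trajectory],
                                D.APRRegion("r_1-2", 1, 2), cfg)


def _hbond_trajectory(n_o_dist, angle_deg=0.0, with_h=True):
    """Donor N (res 1), its H, acceptor O (res 2) at a chosen geometry."""
    topo = [make_atom(1, "N", "N", "GLY", 1)]
    coords = [[0.0, 0.0, 0.0]]
    if with_h:
        topo.append(make_atom(2, "H", "H", "GLY", 1))
        th = np.deg2rad(angle_deg)
        coords.append([1.0 * np.cos(th), 1.0 * np.sin(th), 0.0])
    topo.append(make_atom(len(topo) + 1, "O", "O", "GLY", 2))
    coords.append([n_o_dist, 0.0, 0.0])
    return Trajectory(topology=topo,
                      coordinates=np.asarray(coords)[None])


class TestHydrogenBonds:
    def test_collinear_pair_counts(self):
        counts = D.hydrogen_bond_count(_hbond_trajectory(2.9, 0.0))
        assert counts.tolist() == [1]

    def test_distance_fail(self):
        counts = D.hydrogen_bond_count(_hbond_trajectory(3.8, 0.0))
        assert counts.tolist() == [0]

    def test_angle_fail(self):
        counts = D.hydrogen_bond_count(_hbond_trajectory(2.9, 45.0))
        assert counts.tolist() == [0]

    def test_no_hydrogens_falls_back_to_distance(self):
        traj = _hbond_trajectory(2.9, with_h=False)
        with pytest.warns(UserWarning, match="no hydrogens"):
            counts = D.hydrogen_bond_count(traj)
        assert counts.tolist() == [1]


def _salt_bridge_traj(n_frames_near, n_frames_far, dist_near=3.0,
                      dist_far=5.0):
    """ASP OD1 (res 1) vs LYS NZ (res 2), alternating distance."""
    topo = [make_atom(1, "OD1", "O", "ASP", 1),
            make_atom(2, "NZ", "N", "LYS", 2)]
    frames = ([[[0, 0, 0], [dist_near, 0, 0]]] * n_frames_near
              + [[[0, 0, 0], [dist_far, 0, 0]]] * n_frames_far)
    return Trajectory(topology=topo, coordinates=np.asarray(frames, float))


class TestSaltBridges:
    def test_always_within_cutoff_is_100pct(self):
        cfg = D.DescriptorConfig(last_window_fraction=0.999)
        table, avg = D.salt_bridge_occurrence([_salt_bridge_traj(10, 0)], cfg)
        assert avg == pytest.approx(100.0)
        assert table.occurrence_pct.tolist() == [100.0]

    def test_never_within_cutoff_excluded_from_universe(self):
        cfg = D.DescriptorConfig(last_window_fraction=0.999)
        with pytest.warns(UserWarning, match="empty salt-bridge universe"):
            table, avg = D.salt_bridge_occurrence(
                [_salt_bridge_traj(0, 10)], cfg)
        assert avg == 0.0
        assert table.empty

    def test_half_window_occupancy_is_50pct(self):
        # analysed window = last 500 of 1000 frames; the pair sits within
        # the cutoff in 250 of those -> occurrence 50%
        topo = _salt_bridge_traj(1, 0).topology
        frames = ([[[0, 0, 0], [5.0, 0, 0]]] * 500
                  + [[[0, 0, 0], [3.0, 0, 0]]] * 250
                  + [[[0, 0, 0], [5.0, 0, 0]]] * 250)
        traj = Trajectory(topology=topo,
                          coordinates=np.asarray(frames, float))
        cfg = D.DescriptorConfig(last_window_fraction=0.5)
        _, avg = D.salt_bridge_occurrence([traj], cfg)
        assert avg == pytest.approx(50.0)

    def test_replicate_averaging(self):
        cfg = D.DescriptorConfig(last_window_fraction=0.999)
        with pytest.warns(UserWarning):
            _, avg = D.salt_bridge_occurrence(
                [_salt_bridge_traj(10, 0), _salt_bridge_traj(0, 10)], cfg)
        assert avg == pytest.approx(50.0)


class TestNativeContacts:
    def test_reference_against_itself_is_one(self, helix_trajectory):
        q = D.native_contact_fraction(helix_trajectory)
        assert q[0] == pytest.approx(1.0)
        assert np.all((q >= 0) & (q <= 1))

    def test_scattered_frame_is_zero(self):
        ref = np.arange(5)[:, None] * np.array([6.0, 0, 0])
        scattered = np.arange(5)[:, None] * np.array([60.0, 0, 0])
        traj = ca_chain_trajectory([ref, scattered])
        q = D.native_contact_fraction(traj)
        assert q.tolist() == [1.0, 0.0]

    def test_hand_enumerated_five_residue_chain(self):
        # CA chain spaced 6 A: contacts (1,2),(2,3),(3,4),(4,5); breaking the
        # last one leaves Q = 3/4
        ref = np.arange(5)[:, None] * np.array([6.0, 0, 0])
        broken = ref.copy()
        broken[4, 0] = 40.0
        traj = ca_chain_trajectory([ref, broken])
        q = D.native_contact_fraction(traj)
        assert q[1] == pytest.approx(0.75)

    def test_empty_contact_set_rejected(self):
        ref = np.arange(4)[:, None] * np.array([20.0, 0, 0])
        traj = ca_chain_trajectory([ref])
        with pytest.raises(ValueError, match="contact"):
            D.native_contact_fraction(traj)


class TestNetCharge:
    def test_half_titration(self):
        site = D.PkaSite(1, "ASP1", pka=4.0, site_class="acid")
        assert D.net_charge([site], pH=4.0) == pytest.approx(-0.5)

    def test_base_far_below_pka_fully_charged(self):
        site = D.PkaSite(1, "LYS1", pka=10.0, site_class="base")
        assert D.net_charge([site], pH=3.0) == pytest.approx(1.0, abs=1e-3)

    def test_mixed_sites_direct_formula(self):
        sites = [D.PkaSite(i, f"ASP{i}", 4.0, "acid") for i in range(3)] + \
                [D.PkaSite(i + 3, f"LYS{i}", 10.0, "base") for i in range(2)]
        expected = -3 / (1 + 10 ** (4.0 - 7.0)) + 2 / (1 + 10 ** (7.0 - 10.0))
        assert D.net_charge(sites, 7.0) == pytest.approx(expected, abs=1e-12)

    def test_empty_sites_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert D.net_charge([], 7.0) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.lists(
        st.tuples(st.floats(1.0, 13.0), st.sampled_from(["acid", "base"])),
        min_size=1, max_size=8),
        st.floats(0.5, 13.0), st.floats(0.1, 1.0))
    def test_monotonically_nonincreasing_in_ph(self, site_specs, ph, dph):
        sites = [D.PkaSite(i + 1, f"S{i}", pka, cls)
                 for i, (pka, cls) in enumerate(site_specs)]
        hi = min(ph + dph, 13.5)
        assert D.net_charge(sites, ph) >= D.net_charge(sites, hi) - 1e-12


class TestBuildFeatureTable:
    @staticmethod
    def _regions():
        return (D.APRRegion("r_2-3", 2, 3), D.APRRegion("r_5-6", 5, 6))

    def test_two_conditions_internal_consistency(self):
        cfg = D.DescriptorConfig(baseline_frames=3, sphere_points=120)
        reps = {
            1: [synthgen.synth_trajectory(synthgen.TrajectorySpec(
                n_residues=8, n_frames=12, sigma_profile=0.2, seed=1))],
            2: [synthgen.synth_trajectory(synthgen.TrajectorySpec(
                n_residues=8, n_frames=12, sigma_profile=0.4, seed=2))],
        }
        pka = {1: [D.PkaSite(1, "A", 4.0, "acid")],
               2: [D.PkaSite(1, "A", 4.0, "acid")]}
        ph = {1: 5.5, 2: 7.0}
        with pytest.warns(UserWarning):  # no salt-bridge partners present
            table, prov = D.build_feature_table(
                reps, pka, ph, regions=self._regions(), config=cfg)
        region_cols = [r.name for r in self._regions()]
        assert table.shape == (2, 12)  # 17 with 2 regions instead of 7
        assert np.isfinite(table[region_cols].to_numpy()).all()
        np.testing.assert_allclose(table["sum_aprsasa"],
                                   table[region_cols].sum(axis=1), atol=1e-6)
        assert prov["conditions"][1]["n_replicates"] == 1

    def test_default_regions_sum_consistency(self):
        # residues spanning the canonical windows so all seven are present
        cfg = D.DescriptorConfig(baseline_frames=2, sphere_points=60)
        spec = synthgen.TrajectorySpec(n_residues=442, n_frames=4,
                                       sigma_profile=0.05, seed=3)
        traj = synthgen.synth_trajectory(spec)
        with pytest.warns(UserWarning):
            table, _ = D.build_feature_table(
                {1: [traj]}, {1: []}, {1: 7.0}, config=cfg)
        region_cols = [r.name for r in D.DEFAULT_APR_REGIONS]
        assert table.loc[1, "sum_aprsasa"] == pytest.approx(
            table.loc[1, region_cols].sum(), abs=1e-6)

    def test_static_condition_zero_dynamics(self, static_trajectory):
        cfg = D.DescriptorConfig(baseline_frames=3, sphere_points=120)
        with pytest.warns(UserWarning):
            table, _ = D.build_feature_table(
                {1: [static_trajectory]}, {1: []}, {1: 7.0},
                regions=self._regions(), config=cfg)
        assert table.loc[1, "mean RMSD"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[1, "r_2-3"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[1, "average native contact"] == pytest.approx(1.0)

    def test_planted_temperature_profile_is_monotone_in_rmsf(self):
        cfg = D.DescriptorConfig(baseline_frames=3, sphere_points=60)
        reps = {}
        for cid, temp in enumerate([277.0, 296.0, 318.0, 338.0], start=1):
            spec = synthgen.TrajectorySpec(
                n_residues=10, n_frames=60, sigma_profile=0.3,
                temperature=temp, seed=cid)
            reps[cid] = [synthgen.synth_trajectory(spec)]
        ph = dict.fromkeys(reps, 7.0)
        with pytest.warns(UserWarning):
            table, _ = D.build_feature_table(
                reps, {}, ph, regions=self._regions(), config=cfg)
        rmsf = table["mean RMSF"].to_numpy()
        assert np.all(np.diff(rmsf) > 0)
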