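"""Geometric observables: cutoff rules, round-trips, rigid invariance, PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cphmc.geometry import (
    bending_angle,
    bent_occupancy,
    gate_rg,
    hbond_present,
    hydration_number,
    kabsch_rotation,
    pca_ca,
    saltbridge_min_distance,
    sodium_binding_probability,
    sodium_bound,
    superpose_kabsch,
    water_density_map,
    write_opendx,
)
from cphmc.structure import SelectionSpec, StructureFrame
from cphmc.synth import gen_gate_fixture, gen_helix, gen_pca_trajectory


def frame_from_atoms(atoms):
    """atoms: list of (name, resname, resid, xyz)."""
    return StructureFrame(
        names=np.array([a[0] for a in atoms], dtype=object),
        resnames=np.array([a[1] for a in atoms], dtype=object),
        resids=np.array([a[2] for a in atoms]),
        chains=np.array(["A"] * len(atoms), dtype=object),
        elements=np.array([a[0][0] for a in atoms], dtype=object),
        xyz=np.array([a[3] for a in atoms], dtype=float),
    )


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return R, t


class TestGateRg:
    def test_two_atoms_two_angstroms_apart(self):
        fr = frame_from_atoms([("CB", "VAL", 75, (0, 0, 0)), ("CB", "ILE", 134, (2, 0, 0))])
        sel = SelectionSpec(resids=(75, 134), sidechain_heavy=True)
        assert gate_rg(fr, sel) == pytest.approx(1.0, abs=1e-12)

    def test_constructed_fixture_exact(self):
        fix, _ = gen_gate_fixture(target_rg=5.5, shell_waters=0)
        assert gate_rg(fix) == pytest.approx(5.5, abs=1e-9)

    def test_empty_selection_errors(self):
        fr = frame_from_atoms([("CB", "VAL", 75, (0, 0, 0))])
        with pytest.raises(ValueError, match="no atoms"):
            gate_rg(fr, SelectionSpec(resids=(999,), sidechain_heavy=True))

    def test_backbone_and_hydrogens_excluded(self):
        fr = frame_from_atoms([
            ("CB", "VAL", 75, (0, 0, 0)), ("CB", "ILE", 134, (2, 0, 0)),
            ("CA", "VAL", 75, (50, 0, 0)), ("HB1", "VAL", 75, (-50, 0, 0)),
        ])
        sel = SelectionSpec(resids=(75, 134), sidechain_heavy=True)
        assert gate_rg(fr, sel) == pytest.approx(1.0, abs=1e-12)

    def test_mass_weighted_variant(self):
        fr = frame_from_atoms([("CB", "VAL", 75, (0, 0, 0)), ("SD", "MET", 157, (2, 0, 0))])
        sel = SelectionSpec(resids=(75, 157), sidechain_heavy=True)
        rg = gate_rg(fr, sel, mass_weighted=True, masses=np.array([12.0, 32.0]))
        # centre sits at 2*32/44 from the carbon
        com = 2 * 32 / 44
        expected = np.sqrt((12 * com**2 + 32 * (2 - com) ** 2) / 44)
        assert rg == pytest.approx(expected, abs=1e-12)


class TestHydration:
    @staticmethod
    def asp_with_waters(dists):
        atoms = [("OD1", "ASP", 164, (0, 0, 0)), ("OD2", "ASP", 164, (0, 50, 0))]
        for i, d in enumerate(dists):
            atoms.append(("O", "HOH", 400 + i, (d, 0, 0)))
        return frame_from_atoms(atoms)

    def test_strict_cutoff_counting(self):
        fr = self.asp_with_waters([3.0, 3.4, 3.6])
        assert hydration_number(fr, 164) == 2

    def test_boundary_excluded(self):
        fr = self.asp_with_waters([3.5])
        assert hydration_number(fr, 164) == 0

    def test_no_waters(self):
        fr = self.asp_with_waters([])
        assert hydration_number(fr, 164) == 0

    def test_missing_carboxylate_errors(self):
        fr = frame_from_atoms([("CB", "ALA", 10, (0, 0, 0))])
        with pytest.raises(ValueError, match="carboxylate"):
            hydration_number(fr, 10)

    def test_fixture_shell_count(self):
        fix, man = gen_gate_fixture(target_rg=4.6, shell_waters=5)
        assert hydration_number(fix, 164) == 5

    def test_water_dialects_recognized(self):
        for resname in ("HOH", "TIP3", "WAT", "SOL"):
            fr = frame_from_atoms([("OD1", "ASP", 164, (0, 0, 0)),
                                   ("OD2", "ASP", 164, (0, 50, 0)),
                                   ("O", resname, 1, (3.0, 0, 0))])
            assert hydration_number(fr, 164) == 1, resname


class TestSodiumBound:
    @staticmethod
    def scene(na_pos):
        atoms = [
            ("OD1", "ASP", 163, (0, 0, 0)), ("OD2", "ASP", 163, (-1.2, 0.8, 0)),
            ("OD1", "ASP", 164, (20, 0, 0)), ("OD2", "ASP", 164, (21, 0.8, 0)),
            ("O", "THR", 132, (0, 20, 0)), ("NA", "NA", 500, na_pos),
        ]
        return frame_from_atoms(atoms)

    def test_below_cutoff_bound(self):
        flags = sodium_bound(self.scene((2.9, 0, 0)))
        assert flags["Asp163"] and flags["any"]
        assert not flags["Asp164"] and not flags["Thr132"]

    def test_boundary_not_bound(self):
        # 3.0 Å exactly: strict rule excludes
        flags = sodium_bound(self.scene((3.0, 0, 0)))
        assert not flags["Asp163"]

    def test_backbone_oxygen_target(self):
        flags = sodium_bound(self.scene((0, 17.2, 0)))
        assert flags["Thr132"] and not flags["Asp163"] and not flags["Asp164"]

    def test_no_sodium_all_false(self):
        atoms = [("OD1", "ASP", 163, (0, 0, 0)), ("OD2", "ASP", 163, (1, 0, 0)),
                 ("OD1", "ASP", 164, (20, 0, 0)), ("OD2", "ASP", 164, (21, 0, 0)),
                 ("O", "THR", 132, (0, 20, 0))]
        flags = sodium_bound(frame_from_atoms(atoms))
        assert not flags["any"]

    def test_unknown_target_spec_errors(self):
        with pytest.raises(ValueError, match="resid"):
            sodium_bound(self.scene((0, 0, 0)), targets={"X": 163})

    def test_probability_by_frame_counting(self):
        frames = [self.scene((2.9, 0, 0)), self.scene((10, 0, 0)),
                  self.scene((2.5, 0, 0)), self.scene((50, 0, 0))]
        probs = sodium_binding_probability(frames)
        assert probs["Asp163"] == pytest.approx(0.5)
        assert probs["any"] == pytest.approx(0.5)


class TestSaltBridge:
    def test_min_rule(self):
        fr = frame_from_atoms([("NZ", "LYS", 300, (0, 0, 0)),
                               ("OD1", "ASP", 163, (2.7, 0, 0)),
                               ("OD2", "ASP", 163, (3.5, 0, 0))])
        assert saltbridge_min_distance(fr) == pytest.approx(2.7)

    def test_tie(self):
        fr = frame_from_atoms([("NZ", "LYS", 300, (0, 0, 0)),
                               ("OD1", "ASP", 163, (3.0, 0, 0)),
                               ("OD2", "ASP", 163, (0, 3.0, 0))])
        assert saltbridge_min_distance(fr) == pytest.approx(3.0)

    def test_missing_atoms_named(self):
        fr = frame_from_atoms([("OD1", "ASP", 163, (0, 0, 0)),
                               ("OD2", "ASP", 163, (1, 0, 0))])
        with pytest.raises(ValueError, match="NZ"):
            saltbridge_min_distance(fr)

    def test_bound_fixture_separates_lysine(self):
        """A scene built with the lysine rotated away (sodium in place) has a
        longer salt-bridge distance than the tight unbound scene."""
        bound, _ = gen_gate_fixture(ion_distances={"Asp163": 2.9}, lys_nz_distance=5.5)
        unbound, _ = gen_gate_fixture(lys_nz_distance=2.8)
        assert saltbridge_min_distance(bound) > saltbridge_min_distance(unbound)


class TestBendingAngle:
    def test_collinear_is_zero(self):
        fr = frame_from_atoms([("CA", "ALA", 152, (0, 0, 0)),
                               ("CA", "ASP", 163, (0, 0, 5)),
                               ("CA", "ALA", 174, (0, 0, 10))])
        assert bending_angle(fr) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_construction(self):
        fr = frame_from_atoms([("CA", "ALA", 152, (5, 0, 0)),
                               ("CA", "ASP", 163, (0, 0, 0)),
                               ("CA", "ALA", 174, (0, 5, 0))])
        assert bending_angle(fr) == pytest.approx(90.0, abs=1e-9)

    def test_coincident_points_error(self):
        fr = frame_from_atoms([("CA", "ALA", 152, (0, 0, 0)),
                               ("CA", "ASP", 163, (0, 0, 0)),
                               ("CA", "ALA", 174, (0, 5, 0))])
        with pytest.raises(ValueError, match="coincident"):
            bending_angle(fr)

    @pytest.mark.parametrize("angle", [0.0, 34.0, 90.0])
    def test_planted_helix_bend_recovered(self, angle):
        frames, _ = gen_helix(bend_angle=angle)
        assert bending_angle(frames[0]) == pytest.approx(angle, abs=2.0)

    def test_missing_ca_errors(self):
        fr = frame_from_atoms([("CA", "ALA", 152, (0, 0, 0))])
        with pytest.raises(ValueError, match="163"):
            bending_angle(fr)


class TestBentOccupancy:
    def test_all_straight(self):
        assert bent_occupancy([10.0] * 5) == 0.0

    def test_strict_cutoff(self):
        # 28 deg exactly is excluded by the strict rule
        assert bent_occupancy([20.0, 30.0, 40.0, 28.0]) == pytest.approx(0.5)

    def test_complement_sums_to_one(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 60, 500)
        frac = bent_occupancy(angles)
        straight = np.mean(angles <= 28.0)
        assert frac + straight == pytest.approx(1.0, abs=1e-15)

    def test_bimodal_series_recovers_mass(self):
        rng = np.random.default_rng(4)
        n = 2000
        bent = rng.random(n) < 0.30
        angles = np.where(bent, rng.normal(34, 3, n), rng.normal(8, 4, n))
        frac = bent_occupancy(angles)
        assert frac == pytest.approx(0.30, abs=4 * np.sqrt(0.3 * 0.7 / n) + 0.02)

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            bent_occupancy([])


class TestHBond:
    @staticmethod
    def scene(d, h_angle_deg=None):
        atoms = [("N", "THR", 132, (0.0, 0.0, 0.0)),
                 ("OD1", "ASP", 163, (d, 0.0, 0.0)),
                 ("OD2", "ASP", 163, (d + 3, 0.0, 0.0))]
        if h_angle_deg is not None:
            # place H at 1 Å from N such that the N-H...O angle is as given
            theta = np.radians(180.0 - h_angle_deg)
            h = np.array([np.cos(theta), np.sin(theta), 0.0])
            atoms.append(("H", "THR", 132, tuple(h)))
        return frame_from_atoms(atoms)

    def test_close_and_linear_true(self):
        assert hbond_present(self.scene(2.9, h_angle_deg=165.0))

    def test_distance_fails(self):
        assert not hbond_present(self.scene(4.0, h_angle_deg=165.0))

    def test_angle_fails(self):
        assert not hbond_present(self.scene(2.9, h_angle_deg=120.0))

    def test_heavy_atom_only_mode(self):
        assert hbond_present(self.scene(2.9))
        assert not hbond_present(self.scene(3.6))

    def test_missing_acceptor_errors(self):
        fr = frame_from_atoms([("N", "THR", 132, (0, 0, 0))])
        with pytest.raises(ValueError, match="acceptor"):
            hbond_present(fr)


class TestWaterDensity:
    @staticmethod
    def water_frame(positions):
        atoms = [("O", "HOH", i + 1, p) for i, p in enumerate(positions)]
        return frame_from_atoms(atoms) if atoms else StructureFrame(
            names=np.array([], dtype=object), resnames=np.array([], dtype=object),
            resids=np.array([], dtype=int), chains=np.array([], dtype=object),
            elements=np.array([], dtype=object), xyz=np.zeros((0, 3)))

    def test_no_waters_all_zero(self):
        d = water_density_map([self.water_frame([])], grid_spacing=1.0,
                              bounds=((0, 4), (0, 4), (0, 4)))
        assert np.all(d.grid == 0.0)

    def test_single_voxel_conservation(self):
        frames = [self.water_frame([(0.5, 0.5, 0.5)] * 7) for _ in range(3)]
        d = water_density_map(frames, grid_spacing=1.0, bounds=((0, 2), (0, 2), (0, 2)))
        # all mass in one voxel
        assert np.count_nonzero(d.grid) == 1
        total = d.grid.sum() * d.voxel_volume * d.bulk_density * d.n_frames
        assert total == pytest.approx(21)
        assert d.grid.max() == pytest.approx(7 / (1.0 * d.bulk_density), rel=1e-12)

    def test_uniform_bulk_water_reads_one(self):
        """Waters drawn uniformly at bulk number density give voxel values
        averaging 1.0 in bulk units."""
        rng = np.random.default_rng(8)
        box = 12.0
        n_per_frame = int(round(0.0334 * box**3))
        frames = [self.water_frame(list(rng.uniform(0, box, (n_per_frame, 3))))
                  for _ in range(20)]
        d = water_density_map(frames, grid_spacing=3.0,
                              bounds=((0, box), (0, box), (0, box)))
        assert d.grid.mean() == pytest.approx(1.0, abs=0.05)

    def test_count_conservation_random(self):
        rng = np.random.default_rng(9)
        frames = [self.water_frame(list(rng.uniform(0, 10, (50, 3)))) for _ in range(4)]
        d = water_density_map(frames, grid_spacing=2.0, bounds=((0, 10), (0, 10), (0, 10)))
        recovered = d.grid.sum() * d.voxel_volume * d.bulk_density * d.n_frames
        assert recovered == pytest.approx(d.n_observations, rel=1e-12)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            water_density_map([self.water_frame([])], grid_spacing=0.0)

    def test_opendx_writer_round_trippable_text(self, tmp_path):
        frames = [self.water_frame([(0.5, 0.5, 0.5)])]
        d = water_density_map(frames, grid_spacing=1.0, bounds=((0, 2), (0, 2), (0, 2)))
        path = tmp_path / "map.dx"
        write_opendx(d, path)
        text = path.read_text()
        assert "gridpositions counts 2 2 2" in text
        values = []
        for line in text.splitlines():
            parts = line.split()
            if parts and all(p.replace(".", "").replace("e", "").replace("-", "")
                             .replace("+", "").isdigit() for p in parts):
                values += [float(p) for p in parts]
        assert len(values) == 8


class TestSuperposition:
    def test_identical_frames_zero_rmsd(self):
        frames, _ = gen_helix(bend_angle=0.0)
        aligned, rmsd = superpose_kabsch([frames[0]], frames[0])
        assert rmsd[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(5)
        frames, _ = gen_helix(bend_angle=20.0)
        R, t = random_rigid(rng)
        moved = frames[0].transformed(R, t)
        _, rmsd = superpose_kabsch([moved], frames[0])
        assert rmsd[0] == pytest.approx(0.0, abs=1e-8)

    def test_single_atom_displacement_closed_form(self):
        """Moving one of N atoms by 1 Å gives RMSD 1/sqrt(N) (upper bound:
        superposition can only reduce it)."""
        frames, _ = gen_helix(n_res=20, bend_angle=0.0, bend_residue=161,
                              start_resid=152)
        ref = frames[0]
        n = ref.n_atoms
        moved = ref.transformed(np.eye(3), np.zeros(3))
        moved.xyz[0] += np.array([1.0, 0.0, 0.0])
        _, rmsd = superpose_kabsch([moved], ref)
        assert rmsd[0] <= 1.0 / np.sqrt(n) + 1e-9
        assert rmsd[0] > 0.5 / np.sqrt(n)

    def test_mismatched_atom_counts_error(self):
        a, _ = gen_helix(n_res=10, bend_angle=0.0, bend_residue=157, start_resid=152)
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_rotation(a[0].xyz[:5], a[0].xyz)


class TestRigidInvariance:
    def test_observables_invariant_under_rigid_transforms(self):
        """Distance/angle observables are unchanged by 100 random global
        rotations + translations."""
        fix, _ = gen_gate_fixture(target_rg=4.6, shell_waters=3,
                                  ion_distances={"Asp163": 2.9}, lys_nz_distance=3.2)
        helix, _ = gen_helix(bend_angle=34.0)
        rng = np.random.default_rng(17)
        rg0 = gate_rg(fix)
        hyd0 = hydration_number(fix, 164)
        na0 = sodium_bound(fix)
        sb0 = saltbridge_min_distance(fix)
        bend0 = bending_angle(helix[0])
        for _ in range(100):
            R, t = random_rigid(rng)
            f2 = fix.transformed(R, t)
            h2 = helix[0].transformed(R, t)
            assert gate_rg(f2) == pytest.approx(rg0, abs=1e-9)
            assert hydration_number(f2, 164) == hyd0
            assert sodium_bound(f2) == na0
            assert saltbridge_min_distance(f2) == pytest.approx(sb0, abs=1e-9)
            assert bending_angle(h2) == pytest.approx(bend0, abs=1e-7)


class TestBruteForceOracle:
    def test_agreement_with_naive_pairwise_distances(self):
        """gate_rg / hydration_number / sodium_bound against a naive
        double-loop oracle on a randomized scene."""
        rng = np.random.default_rng(19)
        fix, _ = gen_gate_fixture(target_rg=5.0, shell_waters=4,
                                  ion_distances={"Asp164": 2.5})
        jittered = fix.transformed(np.eye(3), np.zeros(3))
        jittered.xyz += rng.normal(0, 0.3, jittered.xyz.shape)
        fr = jittered

        # naive Rg over gate sidechain atoms
        sel = [i for i in range(fr.n_atoms)
               if fr.resids[i] in (75, 134, 157, 160, 161)
               and fr.names[i] not in ("N", "CA", "C", "O", "OXT")
               and not str(fr.names[i]).startswith("H")]
        pts = fr.xyz[sel]
        centroid = pts.mean(axis=0)
        rg_naive = np.sqrt(sum(np.sum((p - centroid) ** 2) for p in pts) / len(pts))
        assert gate_rg(fr) == pytest.approx(rg_naive, abs=1e-12)

        # naive hydration count
        ox = [fr.xyz[i] for i in range(fr.n_atoms)
              if fr.resids[i] == 164 and fr.names[i] in ("OD1", "OD2")]
        count = 0
        for i in range(fr.n_atoms):
            if fr.resnames[i] == "HOH" and str(fr.names[i]).startswith("O"):
                if min(np.linalg.norm(fr.xyz[i] - o) for o in ox) < 3.5:
                    count += 1
        assert hydration_number(fr, 164) == count

        # naive sodium flag
        na = [fr.xyz[i] for i in range(fr.n_atoms) if fr.resnames[i] == "NA"]
        t164 = [fr.xyz[i] for i in range(fr.n_atoms)
                if fr.resids[i] == 164 and fr.names[i] in ("OD1", "OD2")]
        naive_bound = any(np.linalg.norm(n - o) < 3.0 for n in na for o in t164)
        assert sodium_bound(fr)["Asp164"] == naive_bound


class TestPCA:
    def test_single_mode_full_fraction(self):
        traj, _ = gen_pca_trajectory(n_atoms=10, mode_variances=(2.0,), n_frames=50,
                                     background_variance=0.0, seed=6)
        res = pca_ca(traj, align=False)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_modes_known_ratio(self):
        """Planted variances 3:1 with no background -> fractions 0.75/0.25
        (up to sampling error of the mode amplitudes)."""
        traj, _ = gen_pca_trajectory(n_atoms=20, mode_variances=(3.0, 1.0),
                                     n_frames=4000, background_variance=0.0, seed=7)
        res = pca_ca(traj, align=False)
        assert res.variance_fractions[0] == pytest.approx(0.75, abs=0.02)
        assert res.variance_fractions[1] == pytest.approx(0.25, abs=0.02)

    def test_planted_dominant_fraction_recovered(self):
        """First-mode fraction ~0.32 planted over an isotropic background."""
        traj, man = gen_pca_trajectory(n_atoms=30, mode_variances=(16.0,),
                                       n_frames=1200, background_variance=0.3914,
                                       seed=8)
        assert man["expected_fractions"][0] == pytest.approx(0.32, abs=0.005)
        res = pca_ca(traj, align=False)
        assert res.variance_fractions[0] == pytest.approx(
            man["expected_fractions"][0], abs=0.02)

    def test_spectral_contract(self):
        traj, _ = gen_pca_trajectory(n_atoms=8, mode_variances=(2.0, 1.0),
                                     n_frames=200, background_variance=0.1, seed=9)
        res = pca_ca(traj, align=False)
        assert np.all(res.eigenvalues >= 0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        gram = res.modes @ res.modes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-9)

    def test_reconstruction_round_trip(self):
        traj, _ = gen_pca_trajectory(n_atoms=8, mode_variances=(2.0, 0.5),
                                     n_frames=100, background_variance=0.05, seed=10)
        res = pca_ca(traj, align=False)
        X = np.stack([fr.xyz.ravel() for fr in traj])
        centred = X - X.mean(axis=0)
        np.testing.assert_allclose(res.reconstruct(), centred, atol=1e-8)

    def test_alignment_does_not_break_on_rotated_frames(self):
        """Frames given in arbitrary rigid poses still yield a dominant
        planted mode after iterative mean alignment."""
        traj, _ = gen_pca_trajectory(n_atoms=15, mode_variances=(9.0,), n_frames=80,
                                     background_variance=0.01, seed=11)
        rng = np.random.default_rng(12)
        posed = []
        for fr in traj:
            R, t = random_rigid(rng)
            posed.append(fr.transformed(R, t))
        res = pca_ca(posed, align=True)
        assert res.variance_fractions[0] > 0.9

    def test_too_few_frames_error(self):
        traj, _ = gen_pca_trajectory(n_atoms=5, mode_variances=(1.0,), n_frames=2, seed=13)
        with pytest.raises(ValueError, match="3 frames"):
            pca_ca(traj)

    def test_zero_variance_error(self):
        traj, _ = gen_pca_trajectory(n_atoms=5, mode_variances=(0.0,), n_frames=10,
                                     background_variance=0.0, seed=14)
        with pytest.raises(ValueError, match="degenerate"):
            pca_ca(traj, align=False)
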