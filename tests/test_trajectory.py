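"""Superposition, RMSF, H-bond and close-contact occupancy statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from kunitzchar.simulate import make_trajectory, toy_structure
from kunitzchar.trajectory import (
    Trajectory,
    close_contacts,
    hbond_occupancy,
    occupancy_class,
    read_multimodel_pdb,
    rmsf,
    superpose_frames,
    write_multimodel_pdb,
)


def quaternion_superpose_rmsd(ref, mob):
    """Oracle: optimal-rotation RMSD via the quaternion (Kearsley) method."""
    ref0 = ref - ref.mean(axis=0)
    mob0 = mob - mob.mean(axis=0)
    R = mob0.T @ ref0
    key = np.array(
        [
            [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1],
             R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
            [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2],
             R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
            [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0],
             -R[0, 0] + R[1, 1] - R[2, 2], R[1, 2] + R[2, 1]],
            [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0],
             R[1, 2] + R[2, 1], -R[0, 0] - R[1, 1] + R[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    msd = (np.sum(ref0 ** 2) + np.sum(mob0 ** 2) - 2 * lam) / ref.shape[0]
    return np.sqrt(max(msd, 0.0))


def atoms_frame(n, chain="A", name="CA"):
    return pd.DataFrame(
        {"name": [name] * n, "element": [name[0]] * n,
         "resid": np.arange(1, n + 1), "resname": ["GLY"] * n,
         "chain": [chain] * n}
    )


class TestSuperpose:
    def test_identity_frame_zero_rmsd(self, rng):
        xyz = rng.normal(0, 3, (1, 8, 3))
        traj = Trajectory(np.repeat(xyz, 3, axis=0), atoms_frame(8))
        aligned, rmsd = superpose_frames(traj)
        np.testing.assert_allclose(rmsd, 0, atol=1e-12)
        np.testing.assert_allclose(aligned.coords, traj.coords, atol=1e-12)

    def test_pure_rotation_removed(self, rng):
        ref = rng.normal(0, 3, (10, 3))
        rot = Rotation.from_euler("xyz", [0.4, -1.0, 2.2])
        moved = rot.apply(ref) + np.array([5.0, -2.0, 1.0])
        traj = Trajectory(np.stack([ref, moved]), atoms_frame(10))
        _, rmsd = superpose_frames(traj)
        np.testing.assert_allclose(rmsd, 0, atol=1e-9)

    def test_rmsd_matches_quaternion_oracle(self, rng):
        for _ in range(10):
            ref = rng.normal(0, 2, (10, 3))
            mob = rng.normal(0, 2, (10, 3))
            traj = Trajectory(np.stack([ref, mob]), atoms_frame(10))
            _, rmsd = superpose_frames(traj)
            assert rmsd[1] == pytest.approx(
                quaternion_superpose_rmsd(ref, mob), abs=1e-8
            )

    def test_too_few_atoms_rejected(self, rng):
        traj = Trajectory(rng.normal(0, 1, (2, 2, 3)), atoms_frame(2))
        with pytest.raises(ValueError):
            superpose_frames(traj)


class TestRmsf:
    def test_static_trajectory_zero_rmsf(self):
        ref = toy_structure(8)
        traj = Trajectory(np.repeat(ref.coords, 50, axis=0), ref.atoms)
        assert np.allclose(rmsf(traj).values(), 0.0)

    def test_amplitude_ordering_preserved(self):
        ref = toy_structure(10)
        amp = np.full(10, 0.2)
        amp[4:7] = 0.8  # mobile canonical-loop-like stretch
        traj, _ = make_trajectory(ref, amp, n_frames=2000, seed=9)
        vals = rmsf(traj).values()
        assert vals[[4, 5, 6]].min() > vals[[0, 1, 2, 7, 8, 9]].max()

    def test_invariant_under_uniform_rigid_motion(self):
        ref = toy_structure(8)
        traj, _ = make_trajectory(ref, np.full(8, 0.4), n_frames=300, seed=10)
        rot = Rotation.from_euler("zyx", [1.0, 0.3, -0.7])
        moved = Trajectory(rot.apply(
            traj.coords.reshape(-1, 3)).reshape(traj.coords.shape) + 11.0,
            traj.atoms)
        a1, _ = superpose_frames(traj, selection=traj.select(name="CA"))
        a2, _ = superpose_frames(moved, selection=moved.select(name="CA"))
        np.testing.assert_allclose(rmsf(a1).values(), rmsf(a2).values(),
                                   atol=1e-9)

    def test_empty_window_rejected(self):
        ref = toy_structure(4)
        with pytest.raises(ValueError):
            ref.window(5, 5)


def brute_force_hbond(traj, d_cut):
    """Per-frame double loop over donor/acceptor pairs (heavy-atom mode)."""
    from kunitzchar.trajectory import _donor_acceptor_indices

    donors, acceptors = _donor_acceptor_indices(traj.atoms, False)
    counts = {}
    for f in range(traj.n_frames):
        for di in donors:
            for aj in acceptors:
                d = np.linalg.norm(traj.coords[f, di] - traj.coords[f, aj])
                if d <= d_cut:
                    counts[(di, aj)] = counts.get((di, aj), 0) + 1
    return {k: v / traj.n_frames for k, v in counts.items()}


class TestHbonds:
    def _two_chain_traj(self, n_frames, present_frames, dist=2.9):
        ref = toy_structure(3, chains=2)
        coords = np.repeat(ref.coords, n_frames, axis=0)
        atoms = ref.atoms
        di = atoms[(atoms.chain == "A") & (atoms.resid == 2) &
                   (atoms.name == "N")].index[0]
        ai = atoms[(atoms.chain == "B") & (atoms.resid == 2) &
                   (atoms.name == "O")].index[0]
        for f in range(n_frames):
            d = dist if f < present_frames else 8.0
            coords[f, ai] = coords[f, di] + np.array([0, 0, d])
        return Trajectory(coords, atoms), di, ai

    def test_permanent_bond_full_occupancy_strong(self):
        traj, di, ai = self._two_chain_traj(40, 40)
        rep = hbond_occupancy(traj, intermolecular=True)
        row = rep.iloc[0]
        assert row["occupancy"] == 1.0
        assert row["class"] == "strong"

    def test_850_of_1000_frames_gives_085(self):
        traj, _, _ = self._two_chain_traj(1000, 850)
        rep = hbond_occupancy(traj, intermolecular=True)
        assert rep.iloc[0]["occupancy"] == 0.85
        assert rep.iloc[0]["class"] == "strong"

    def test_occupancy_classes(self):
        assert occupancy_class(0.9) == "strong"
        assert occupancy_class(0.5) == "reported"
        assert occupancy_class(0.1) == "below"

    def test_matches_brute_force_oracle(self, rng):
        ref = toy_structure(4, chains=2)
        traj, _ = make_trajectory(ref, np.full(4, 1.5), n_frames=60, seed=13)
        rep = hbond_occupancy(traj, d_cut=4.5, intermolecular=False)
        oracle = brute_force_hbond(traj, 4.5)
        atoms = traj.atoms
        got = {}
        for _, row in rep.iterrows():
            got[(row["donor"], row["acceptor"])] = row["occupancy"]
        for (di, aj), occ in oracle.items():
            if atoms.at[di, "chain"] == atoms.at[aj, "chain"] and \
                    atoms.at[di, "resid"] == atoms.at[aj, "resid"]:
                continue
            key = (
                f"{atoms.at[di, 'chain']}:{atoms.at[di, 'resid']}:GLY:{atoms.at[di, 'name']}",
                f"{atoms.at[aj, 'chain']}:{atoms.at[aj, 'resid']}:GLY:{atoms.at[aj, 'name']}",
            )
            assert got.get(key, 0.0) == occ

    def test_mean_bonds_per_frame_equals_sum_of_occupancies(self, rng):
        ref = toy_structure(4, chains=2)
        traj, _ = make_trajectory(ref, np.full(4, 1.0), n_frames=50, seed=14)
        rep = hbond_occupancy(traj, d_cut=4.5, intermolecular=True)
        oracle = brute_force_hbond(traj, 4.5)
        atoms = traj.atoms
        inter = sum(
            occ for (di, aj), occ in oracle.items()
            if atoms.at[di, "chain"] != atoms.at[aj, "chain"]
        )
        assert rep["occupancy"].sum() == pytest.approx(inter)


def brute_force_contacts(traj, cutoff):
    atoms = traj.atoms
    keys = list(zip(atoms["chain"], atoms["resid"]))
    occ = {}
    for f in range(traj.n_frames):
        seen = set()
        for i in range(traj.n_atoms):
            for j in range(traj.n_atoms):
                if keys[i] >= keys[j]:
                    continue
                d = np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                if d < cutoff:
                    seen.add((keys[i], keys[j]))
        for pair in seen:
            occ[pair] = occ.get(pair, 0) + 1
    return {k: v / traj.n_frames for k, v in occ.items()}


class TestContacts:
    def test_threshold_is_strict(self):
        atoms = atoms_frame(2, chain="A")
        atoms.loc[1, "chain"] = "B"
        near = Trajectory(np.array([[[0, 0, 0], [3.9, 0, 0]]]), atoms)
        far = Trajectory(np.array([[[0, 0, 0], [4.1, 0, 0]]]), atoms)
        assert len(close_contacts(near, 4.0)) == 1
        assert len(close_contacts(far, 4.0)) == 0

    def test_designed_interface_recovered(self):
        # residues 3-8 of chain B pulled within contact range of chain A
        ref = toy_structure(10, chains=2, chain_offset=20.0)
        coords = ref.coords.copy()
        atoms = ref.atoms
        target = set()
        for r in range(3, 9):
            sel = ((atoms.chain == "B") & (atoms.resid == r)).to_numpy()
            coords[0, sel, 2] -= 17.0  # bring to 3 Å from chain A
            target.add(r)
        traj = Trajectory(coords, atoms)
        rep = close_contacts(traj, cutoff=4.0)
        got = set(rep["resid_b"])
        assert got == target

    def test_occupancy_bounds_and_oracle(self, rng):
        ref = toy_structure(3, chains=2)
        traj, _ = make_trajectory(ref, np.full(3, 1.0), n_frames=40, seed=15)
        rep = close_contacts(traj, cutoff=5.5, intermolecular=False)
        assert ((rep["occupancy"] > 0) & (rep["occupancy"] <= 1)).all()
        oracle = brute_force_contacts(traj, 5.5)
        got = {
            ((row["chain_a"], row["resid_a"]), (row["chain_b"], row["resid_b"])):
            row["occupancy"] for _, row in rep.iterrows()
        }
        assert got == oracle

    def test_single_chain_intermolecular_rejected(self):
        ref = toy_structure(4)
        with pytest.raises(ValueError):
            close_contacts(ref, intermolecular=True)


class TestPdbIO:
    def test_round_trip(self, tmp_path, rng):
        ref = toy_structure(5, chains=2)
        traj, _ = make_trajectory(ref, np.full(5, 0.3), n_frames=4, seed=16)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 4
        assert back.n_atoms == traj.n_atoms
        np.testing.assert_allclose(back.coords, traj.coords, atol=1.5e-3)
        pd.testing.assert_frame_equal(back.atoms, traj.atoms)

    def test_reader_agrees_with_biopython(self, tmp_path):
        from Bio.PDB import PDBParser

        ref = toy_structure(3)
        traj, _ = make_trajectory(ref, np.full(3, 0.2), n_frames=2, seed=17)
        path = tmp_path / "x.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("x", str(path))
        models = list(structure)
        assert len(models) == 2
        bio_coords = np.array(
            [[atom.coord for atom in model.get_atoms()] for model in models]
        )
        np.testing.assert_allclose(back.coords, bio_coords, atol=1e-3)
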