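"""Trajectory observables against brute-force and independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from quenchbind.errors import ValidationError
from quenchbind.synthetic import TrajSimSpec, simulate_trajectory
from quenchbind.trajectory import (
    Atom,
    Trajectory,
    atom_masses,
    hbond_count,
    ligand_residue_distance,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
)


def _toy(coords, atoms=None, **kw):
    coords = np.asarray(coords, dtype=float)
    if atoms is None:
        atoms = tuple(
            Atom(name="CA", element="C", resname="ALA", resid=i + 1)
            for i in range(coords.shape[1])
        )
    return Trajectory(coords=coords, atoms=atoms, **kw)


def _grid_search_rmsd(a, b):
    """Independent superposition oracle: coarse Euler-angle grid search
    followed by simplex refinement, never touching the Kabsch/SVD path."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt((((b @ R.T) - a) ** 2).sum(axis=1).mean())

    grid = np.linspace(-np.pi, np.pi, 16, endpoint=False)
    best = min(
        ((rmsd_of((x, y, z)), (x, y, z)) for x in grid for y in grid for z in grid),
        key=lambda t: t[0],
    )
    res = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12})
    return min(best[0], res.fun)


class TestRMSD:
    def test_identical_frame_gives_zero(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=3, n_atoms=10))
        assert rmsd_series(traj).max() == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_copy_gives_zero(self):
        traj = simulate_trajectory(
            TrajSimSpec(n_frames=6, n_atoms=25, rigid_motion=True, seed=2)
        )
        assert rmsd_series(traj).max() < 1e-9

    def test_four_atom_toy_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(4, 3)) * 2
        b = rng.normal(size=(4, 3)) * 2
        traj = _toy([a, b])
        ours = rmsd_series(traj)[1]
        oracle = _grid_search_rmsd(a, b)
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_chiral_set_is_not_matched_by_a_reflection(self):
        # mirror image of a chiral 5-point set: a proper rotation cannot
        # reach RMSD 0, and our value must agree with MDAnalysis.
        from MDAnalysis.analysis import rms

        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3))
        b = a.copy()
        b[:, 0] *= -1
        traj = _toy([a, b])
        ours = rmsd_series(traj)[1]
        assert ours > 0.1
        theirs = rms.rmsd(b, a, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_too_few_atoms_rejected(self):
        traj = _toy(np.zeros((2, 2, 3)))
        with pytest.raises(ValidationError):
            rmsd_series(traj, selection="all")


class TestRMSF:
    def test_static_trajectory_has_zero_fluctuation(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=5, n_atoms=12))
        assert max(rmsf_per_residue(traj).values()) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        sigma = 0.25
        traj = simulate_trajectory(
            TrajSimSpec(n_frames=600, n_atoms=100, jitter_sd=sigma, seed=4)
        )
        vals = np.array(list(rmsf_per_residue(traj).values()))
        assert vals.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_doubling_jitter_on_one_residue_doubles_its_rmsf(self):
        # a non-collinear base structure: collinear references leave the
        # superposition rotation about the axis undetermined
        from quenchbind.synthetic import _base_structure

        rng = np.random.default_rng(6)
        n_atoms, n_frames, sigma = 30, 800, 0.2
        base = _base_structure(n_atoms)
        coords = base + rng.normal(0, sigma, size=(n_frames, n_atoms, 3))
        coords[:, 5, :] = base[5] + rng.normal(0, 2 * sigma, size=(n_frames, 3))
        traj = _toy(coords)
        rmsf = rmsf_per_residue(traj)
        others = np.mean([v for (c, r), v in rmsf.items() if r != 6])
        assert rmsf[("A", 6)] / others == pytest.approx(2.0, rel=0.1)

    def test_empty_window_rejected(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=5, n_atoms=10))
        with pytest.raises(ValidationError):
            rmsf_per_residue(traj, window=(4, 4))


class TestRadiusOfGyration:
    SQUARE = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)

    def test_unit_square_gives_sqrt_two(self):
        traj = _toy(self.SQUARE[None])
        rg = radius_of_gyration(traj, mass_weighted=False)
        assert rg[0] == pytest.approx(np.sqrt(2), abs=1e-14)

    def test_invariant_under_rigid_motion(self):
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        moved = rot.apply(self.SQUARE) + np.array([5.0, -3.0, 11.0])
        traj = _toy(np.stack([self.SQUARE, moved]))
        rg = radius_of_gyration(traj, mass_weighted=False)
        assert rg[1] == pytest.approx(rg[0], abs=1e-12)

    def test_homogeneous_under_scaling(self):
        traj = _toy(np.stack([self.SQUARE, 3.5 * self.SQUARE]))
        rg = radius_of_gyration(traj, mass_weighted=False)
        assert rg[1] == pytest.approx(3.5 * rg[0], rel=1e-12)

    def test_coincident_atoms_give_zero_not_an_error(self):
        traj = _toy(np.zeros((1, 4, 3)))
        assert radius_of_gyration(traj)[0] == 0.0

    def test_mass_weighting_shifts_toward_heavy_atoms(self):
        atoms = (
            Atom("O", "O", "HOH", 1), Atom("H1", "H", "HOH", 1),
            Atom("H2", "H", "HOH", 1),
        )
        coords = np.array([[[0, 0, 0], [3, 0, 0], [-3, 0, 0]]], float)
        traj = _toy(coords, atoms=atoms)
        weighted = radius_of_gyration(traj, mass_weighted=True)[0]
        unweighted = radius_of_gyration(traj, mass_weighted=False)[0]
        assert weighted < unweighted


class TestLigandResidueDistance:
    ATOMS = (
        Atom("C1", "C", "DFX", 900, is_ligand=True),
        Atom("O1", "O", "DFX", 900, is_ligand=True),
        Atom("CA", "C", "ASP", 32),
        Atom("CB", "C", "ASP", 32),
        Atom("CA", "C", "GLY", 33),
    )

    def test_three_frame_toy_matches_pair_enumeration(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(-5, 5, size=(3, 5, 3))
        traj = _toy(coords, atoms=self.ATOMS)
        res = ligand_residue_distance(traj, residue=32)
        for f in range(3):
            expected = min(
                np.linalg.norm(coords[f, i] - coords[f, j])
                for i in (0, 1)
                for j in (2, 3)
            )
            assert res.per_frame[f] == pytest.approx(expected, abs=1e-12)
        assert res.mean == pytest.approx(res.per_frame.mean())
        assert res.minimum == pytest.approx(res.per_frame.min())
        assert res.minimum <= res.mean

    def test_coincident_atoms_give_zero_minimum(self):
        coords = np.zeros((1, 5, 3))
        coords[0, 2] = [0, 0, 0]  # same as ligand atom 0
        coords[0, 3] = [4, 0, 0]
        coords[0, 4] = [8, 0, 0]
        traj = _toy(coords, atoms=self.ATOMS)
        assert ligand_residue_distance(traj, residue=32).minimum == 0.0

    def test_two_single_atoms_report_their_separation(self):
        atoms = (
            Atom("C1", "C", "DFX", 900, is_ligand=True),
            Atom("CA", "C", "ASP", 32),
        )
        coords = np.tile(np.array([[[0, 0, 0], [0, 0, 4.2]]], float), (4, 1, 1))
        traj = _toy(coords, atoms=atoms)
        res = ligand_residue_distance(traj, residue=32)
        assert res.mean == pytest.approx(4.2)
        assert res.minimum == pytest.approx(4.2)

    def test_unknown_residue_lists_available_ids(self):
        traj = _toy(np.zeros((1, 5, 3)), atoms=self.ATOMS)
        with pytest.raises(ValidationError, match="available residues"):
            ligand_residue_distance(traj, residue=215)


class TestHBonds:
    @staticmethod
    def _water_pair(oo_distance, angle_deg):
        """Donor water O-H pointing at an acceptor O, with the given
        H...O distance and D-H...A angle."""
        atoms = (
            Atom("O", "O", "HOH", 1),
            Atom("H1", "H", "HOH", 1),
            Atom("O", "O", "HOH", 2),
        )
        theta = np.deg2rad(180.0 - angle_deg)
        h = np.array([0.96, 0.0, 0.0])
        acc = h + oo_distance * np.array([np.cos(theta), np.sin(theta), 0.0])
        coords = np.array([[[0, 0, 0], h, acc]])
        return Trajectory(coords=coords, atoms=atoms)

    def test_linear_canonical_bond_counts_one(self):
        traj = self._water_pair(1.9, 180.0)
        n = hbond_count(traj, donors=lambda a: a.resid == 1 and a.element == "O",
                        acceptors=lambda a: a.resid == 2)
        assert list(n) == [1]

    def test_bent_geometry_fails_the_angle_cutoff(self):
        traj = self._water_pair(1.9, 90.0)
        n = hbond_count(traj, donors=lambda a: a.resid == 1 and a.element == "O",
                        acceptors=lambda a: a.resid == 2, angle_min=120.0)
        assert list(n) == [0]

    def test_long_contact_fails_the_distance_cutoff(self):
        traj = self._water_pair(4.0, 180.0)
        n = hbond_count(traj, donors=lambda a: a.resid == 1 and a.element == "O",
                        acceptors=lambda a: a.resid == 2, d_max=3.5)
        assert list(n) == [0]

    def test_random_toy_matches_triple_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        atoms, pos = [], []
        for i in range(5):  # 5 donors, each with one H, on a wide grid
            o = np.array([6.0 * i, 0.0, 0.0])
            atoms += [Atom("O", "O", "DON", i + 1), Atom("H", "H", "DON", i + 1)]
            pos += [o, o + [0.96, 0, 0]]
        for i in range(5):  # 5 acceptors scattered nearby
            atoms.append(Atom("O", "O", "ACC", 100 + i))
            pos.append(rng.uniform([-2, -3, -3], [26, 3, 3]))
        coords = np.array([pos, (np.array(pos) + rng.normal(0, 0.3, (15, 3)))])
        traj = Trajectory(coords=coords, atoms=tuple(atoms))

        counts = hbond_count(
            traj, donors=lambda a: a.resname == "DON" and a.element == "O",
            acceptors=lambda a: a.resname == "ACC",
            d_max=3.5, angle_min=120.0,
        )
        for f in range(2):
            expected = 0
            for d in range(0, 10, 2):  # donor O at even index, its H next
                h = d + 1
                for a in range(10, 15):
                    ha = coords[f, a] - coords[f, h]
                    hd = coords[f, d] - coords[f, h]
                    dist = np.linalg.norm(ha)
                    cosang = hd @ ha / (np.linalg.norm(hd) * dist)
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if dist <= 3.5 and ang >= 120.0:
                        expected += 1
            assert counts[f] == expected

    def test_donor_without_hydrogen_is_an_error(self):
        atoms = (Atom("O", "O", "HOH", 1), Atom("O", "O", "HOH", 2))
        traj = Trajectory(coords=np.zeros((1, 2, 3)) + [[0, 0, 0], [3, 0, 0]],
                          atoms=atoms)
        with pytest.raises(ValidationError, match="HOH1:O"):
            hbond_count(traj, donors=lambda a: a.resid == 1,
                        acceptors=lambda a: a.resid == 2)


def test_unknown_element_falls_back_to_carbon_mass_with_warning():
    atoms = [Atom("X1", "Xx", "UNK", 1), Atom("O", "O", "HOH", 2)]
    with pytest.warns(UserWarning, match="unknown elements"):
        masses = atom_masses(atoms)
    assert masses[0] == 12.0
    assert masses[1] == pytest.approx(15.999)
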