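import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arbdock.errors import (EmptyInputError, InsufficientDataError,
                            SelectionError, TopologyError)
from arbdock.structure_io import (ResidueSelection, Structure, Trajectory,
                                  center_of_mass, pair_distance_series,
                                  read_pdb, rmsd_series, rmsf_per_residue,
                                  write_pdb)
from arbdock.synthetic_data import gen_trajectory

from conftest import make_atoms


def sel(*resids):
    return ResidueSelection.residues(resids)


class TestCenterOfMass:
    @pytest.mark.parametrize("positions, masses, expected", [
        ([(1, 2, 3)], [12.0], (1, 2, 3)),                       # single atom
        ([(0, 0, 0), (2, 0, 0)], [12.0, 12.0], (1, 0, 0)),      # equal masses
        ([(0, 0, 0), (13, 0, 0)], [12.0, 1.0], (1, 0, 0)),      # 12:1 weighting
    ])
    def test_examples(self, positions, masses, expected):
        s = Structure(make_atoms(positions, masses=masses))
        com = center_of_mass(s, sel(*range(1, len(positions) + 1)))
        assert np.allclose(com, expected)

    def test_geometric_flag_ignores_masses(self):
        s = Structure(make_atoms([(0, 0, 0), (13, 0, 0)], masses=[12.0, 1.0]))
        assert np.allclose(center_of_mass(s, sel(1, 2), geometric=True), (6.5, 0, 0))

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(4)
        s = Structure(make_atoms(rng.normal(size=(6, 3)), masses=rng.uniform(1, 16, 6)))
        com = center_of_mass(s, sel(*range(1, 7)))
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3)
        s2 = s.with_coords(s.coords @ rot.T + shift)
        assert np.allclose(center_of_mass(s2, sel(*range(1, 7))),
                           com @ rot.T + shift, atol=1e-9)

    def test_unmatched_selection_raises(self):
        s = Structure(make_atoms([(0, 0, 0)]))
        with pytest.raises(SelectionError, match="99"):
            center_of_mass(s, sel(99))


class TestPairDistances:
    def test_planted_separations(self):
        frames = [Structure(make_atoms([(0, 0, 0), (d, 0, 0)])) for d in (5.0, 7.0)]
        t = Trajectory(frames)
        assert np.allclose(pair_distance_series(t, sel(1), sel(2)), [5.0, 7.0])

    def test_identical_selections_zero(self):
        t = Trajectory([Structure(make_atoms([(1, 1, 1), (2, 2, 2)]))] * 3)
        assert np.allclose(pair_distance_series(t, sel(1), sel(1)), 0.0)

    def test_static_trajectory_constant(self):
        t = Trajectory([Structure(make_atoms([(0, 0, 0), (3, 4, 0)]))] * 5)
        d = pair_distance_series(t, sel(1), sel(2))
        assert np.allclose(d, 5.0) and d.std() == 0.0


class TestRmsd:
    def test_identity_is_zero(self):
        ref = Structure(make_atoms(np.arange(12).reshape(4, 3)))
        t = Trajectory([ref])
        assert rmsd_series(t, ref, sel(1, 2, 3, 4), superpose=False)[0] == 0.0

    def test_translation_without_superposition(self):
        ref = Structure(make_atoms(np.arange(12, dtype=float).reshape(4, 3)))
        shifted = ref.with_coords(ref.coords + [3.0, 0, 0])
        t = Trajectory([shifted])
        assert np.isclose(rmsd_series(t, ref, sel(1, 2, 3, 4), superpose=False)[0], 3.0)

    def test_single_displaced_atom(self):
        # one of four atoms moved 2 A: RMSD = sqrt((2^2 + 0 + 0 + 0)/4) = 1
        ref = Structure(make_atoms([(0, 0, 0), (5, 0, 0), (0, 5, 0), (0, 0, 5)]))
        moved = ref.coords.copy()
        moved[0] += [2.0, 0, 0]
        t = Trajectory([ref.with_coords(moved)])
        assert np.isclose(rmsd_series(t, ref, sel(1, 2, 3, 4), superpose=False)[0], 1.0)

    def test_superposed_rmsd_rigid_invariant(self):
        rng = np.random.default_rng(7)
        ref = Structure(make_atoms(rng.normal(size=(8, 3), scale=4)))
        frames = [ref.with_coords(ref.coords + rng.normal(size=(8, 3), scale=0.3))
                  for _ in range(4)]
        t = Trajectory(frames)
        base = rmsd_series(t, ref, sel(*range(1, 9)), superpose=True)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3, scale=20)
        t2 = Trajectory.from_coords(t.topology, t.xyz @ rot.T + shift)
        moved = rmsd_series(t2, ref, sel(*range(1, 9)), superpose=True)
        assert np.allclose(base, moved, atol=1e-6)

    def test_topology_mismatch(self):
        ref = Structure(make_atoms([(0, 0, 0), (1, 0, 0)]))
        t = Trajectory([Structure(make_atoms([(0, 0, 0)]))])
        with pytest.raises(SelectionError):
            rmsd_series(t, ref, sel(1, 2), superpose=False)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        s = Structure(make_atoms([(0, 0, 0), (5, 0, 0)]))
        t = Trajectory([s, s, s])
        assert all(v <= 1e-12 for v in rmsf_per_residue(t, sel(1, 2)).values())

    def test_two_frame_hand_value(self):
        # residue at x=0 then x=2: mean 1, deviations +-1 -> RMSF 1
        frames = [Structure(make_atoms([(x, 0, 0)])) for x in (0.0, 2.0)]
        t = Trajectory(frames)
        assert np.isclose(rmsf_per_residue(t, sel(1))[1], 1.0)

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(3)
        s = Structure(make_atoms(rng.normal(size=(5, 3))))
        t, _ = gen_trajectory(s, seed=9, n_frames=40, sigma=0.4)
        base = rmsf_per_residue(t, sel(*range(1, 6)))
        perm = rng.permutation(t.n_frames)
        t2 = Trajectory.from_coords(t.topology, t.xyz[perm])
        permuted = rmsf_per_residue(t2, sel(*range(1, 6)))
        assert permuted == pytest.approx(base, rel=1e-12)

    def test_single_frame_raises(self):
        t = Trajectory([Structure(make_atoms([(0, 0, 0)]))])
        with pytest.raises(InsufficientDataError):
            rmsf_per_residue(t, sel(1))


class TestPdbIO:
    def test_round_trip_preserves_topology_and_coords(self, bundle, tmp_path):
        s, _ = bundle
        path = tmp_path / "bundle.pdb"
        write_pdb(s, path)
        t = read_pdb(path)
        assert t.n_frames == 1
        assert t.topology.topology_keys() == s.topology_keys()
        assert np.abs(t.xyz[0] - s.coords).max() <= 1e-3

    def test_multi_model_round_trip(self, bundle, tmp_path):
        s, _ = bundle
        traj, _ = gen_trajectory(s, seed=2, n_frames=3, sigma=0.2)
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        back = read_pdb(path)
        assert back.n_frames == 3
        assert np.abs(back.xyz - traj.xyz).max() <= 1e-3
        assert sum(line.startswith("MODEL") for line in path.read_text().splitlines()) == 3

    def test_single_frame_has_no_model_records(self, tmp_path):
        s = Structure(make_atoms([(0, 0, 0), (1, 1, 1)]))
        path = tmp_path / "one.pdb"
        write_pdb(s, path)
        assert not any(line.startswith("MODEL")
                       for line in path.read_text().splitlines())

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(EmptyInputError):
            read_pdb(path)

    def test_element_inferred_from_name(self, tmp_path):
        path = tmp_path / "noelem.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00\n"
            "END\n")
        t = read_pdb(path)
        a = t.topology.atoms[0]
        assert a.element == "C" and a.mass > 11


class TestTrajectoryContract:
    def test_mismatched_frames_rejected(self):
        a = Structure(make_atoms([(0, 0, 0), (1, 0, 0)]))
        b = Structure(make_atoms([(0, 0, 0)]))
        with pytest.raises(TopologyError):
            Trajectory([a, b])

    def test_backbone_only_selection(self, bundle):
        s, _ = bundle
        full = ResidueSelection.residues([1, 2]).resolve(s)
        bb = ResidueSelection.residues([1, 2], backbone_only=True).resolve(s)
        assert len(bb) == len(full) == 8  # poly-ALA backbone has exactly N,CA,C,O
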