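import numpy as np
import pytest

from arbdock.errors import ParameterError, SelectionError
from arbdock.pocket_geometry import (PocketDefinition, SphereProbe,
                                     load_pocket_definition, nearest_ion_distance,
                                     pocket_centroid, pocket_volume,
                                     pocket_volume_exhaustive, solvent_occupancy)
from arbdock.structure_io import Structure, Trajectory
from arbdock.synthetic_data import _sphere_lens_volume

from conftest import make_atoms, probe_phantom

SPHERE_VOL_R5 = 4.0 / 3.0 * np.pi * 5.0 ** 3  # 523.598...


class TestCentroid:
    def test_cube_corner_probes(self):
        corners = [(x, y, z) for x in (0, 2) for y in (0, 2) for z in (0, 2)]
        s, pocket = probe_phantom(corners)
        center, seed_r = pocket_centroid(s, pocket)
        assert np.allclose(center, (1, 1, 1))
        assert np.isclose(seed_r, np.sqrt(3))

    def test_two_probe_midpoint(self):
        s, pocket = probe_phantom([(0, 0, 0), (10, 0, 0)])
        center, seed_r = pocket_centroid(s, pocket)
        assert np.allclose(center, (5, 0, 0)) and np.isclose(seed_r, 5.0)

    def test_missing_probe_named(self):
        s, _ = probe_phantom([(0, 0, 0), (10, 0, 0)])
        pocket = PocketDefinition(anchor=SphereProbe(167, "NH2", 11.0),
                                  satellites=(SphereProbe(1, "PRB", 5.0),))
        with pytest.raises(SelectionError, match="167:NH2"):
            pocket_centroid(s, pocket)


class TestVolume:
    def test_sphere_phantom_within_2pct(self):
        # centroid sphere (r=5) entirely covered by the probe-sphere union
        s, pocket = probe_phantom([(0, 0, 0), (10, 0, 0)], bfs_radius=8.0,
                                  spacing=0.25)
        v, _ = pocket_volume(s, pocket)
        assert abs(v - SPHERE_VOL_R5) / SPHERE_VOL_R5 < 0.02

    def test_spacing_convergence(self):
        s, _ = probe_phantom([(0, 0, 0), (10, 0, 0)])
        v_fine, _ = pocket_volume(s, probe_phantom([(0, 0, 0), (10, 0, 0)],
                                                   spacing=0.25)[1])
        v_coarse, _ = pocket_volume(s, probe_phantom([(0, 0, 0), (10, 0, 0)],
                                                     spacing=0.5)[1])
        assert abs(v_fine - v_coarse) / v_fine < 0.05

    def test_lens_phantom_analytic(self):
        # bfs radius 6 on probes 10 apart: two symmetric sphere-sphere lenses
        # minus their shared triple-overlap lens
        s, pocket = probe_phantom([(0, 0, 0), (10, 0, 0)], bfs_radius=6.0,
                                  spacing=0.25)
        expected = 2 * _sphere_lens_volume(5.0, 6.0, 5.0) - _sphere_lens_volume(6.0, 6.0, 10.0)
        v, _ = pocket_volume(s, pocket)
        assert abs(v - expected) / expected < 0.03

    def test_bfs_equals_enumeration_when_connected(self, bundle):
        s, truth = bundle
        v_bfs, lattice = pocket_volume(s, truth["pocket"])
        v_enum, pts = pocket_volume_exhaustive(s, truth["pocket"])
        assert lattice.occupied_points == pts
        assert v_bfs == v_enum

    def test_bfs_bounded_by_enumeration_when_disconnected(self):
        # a far probe ball disjoint from the seed component
        s, pocket = probe_phantom([(0, 0, 0), (1, 0, 0), (14, 0, 0)],
                                  bfs_radius=4.5, spacing=0.5)
        v_bfs, lattice = pocket_volume(s, pocket, centroid_radius=20.0)
        v_enum, pts = pocket_volume_exhaustive(s, pocket, centroid_radius=20.0)
        assert v_bfs < v_enum
        assert lattice.occupied_points < pts

    def test_monotone_in_bfs_radius(self, bundle):
        s, truth = bundle
        base: PocketDefinition = truth["pocket"]
        vols = []
        for r in (5.0, 5.5, 6.5, 8.0):  # all >= the seed radius: no degenerate case
            p = PocketDefinition(base.anchor, base.satellites, bfs_radius=r,
                                 lattice_spacing=0.5)
            vols.append(pocket_volume(s, p)[0])
        assert all(a <= b for a, b in zip(vols, vols[1:]))

    def test_monotone_in_centroid_radius(self):
        s, pocket = probe_phantom([(0, 0, 0), (10, 0, 0)], spacing=0.5)
        vols = [pocket_volume(s, pocket, centroid_radius=r)[0] for r in (3, 4, 5)]
        assert all(a <= b for a, b in zip(vols, vols[1:]))

    def test_degenerate_pocket_warns_and_returns_zero(self):
        s, pocket = probe_phantom([(0, 0, 0), (30, 0, 0)], bfs_radius=8.0,
                                  spacing=0.5)  # seed 15 A from both probes
        with pytest.warns(UserWarning, match="degenerate"):
            v, lattice = pocket_volume(s, pocket)
        assert v == 0.0 and not lattice.occupied_points

    def test_volume_metadata(self):
        s, pocket = probe_phantom([(0, 0, 0), (10, 0, 0)], spacing=0.5)
        v, lattice = pocket_volume(s, pocket)
        assert v == len(lattice.occupied_points) * 0.5 ** 3
        assert lattice.spacing == 0.5


def _solvent_phantom(water_frames, water_in=(10.0, 0, 0), n_frames=10):
    """Anchor at origin (r 11), satellite at (13,0,0) (r 4); a water sits at
    ``water_in`` — inside both spheres — during ``water_frames`` only."""
    atoms = make_atoms([(0, 0, 0), (13, 0, 0)])
    frames = []
    for f in range(n_frames):
        pos = water_in if f in water_frames else (400.0, 0, 0)
        water = make_atoms([pos], names=["OH2"], residue_ids=[500],
                           residue_name="TIP3")[0]
        water.serial = 77
        frames.append(Structure(atoms + [water]))
    pocket = PocketDefinition(anchor=SphereProbe(1, "PRB", 11.0),
                              satellites=(SphereProbe(2, "PRB", 4.0),),
                              lattice_spacing=0.5)
    return Trajectory(frames), pocket


class TestSolventOccupancy:
    def test_dual_sphere_rule_requires_both(self):
        # at the anchor atom but > satellite radius from the satellite
        t, pocket = _solvent_phantom({0}, water_in=(0.5, 0, 0), n_frames=1)
        occ = solvent_occupancy(t, pocket, ("TIP3", "OH2"))
        assert occ.occurrences == 0 and not occ.unique_atom_serials

    def test_scripted_occupancy_counts(self):
        t, pocket = _solvent_phantom({1, 2, 5, 6}, n_frames=10)
        occ = solvent_occupancy(t, pocket, ("TIP3", "OH2"))
        assert occ.unique_atom_serials == {77}
        assert occ.occurrences == 4
        assert occ.frames_occupied == 4
        assert np.isclose(occ.fraction_occurrences, 0.4)

    def test_frame_permutation_invariance(self):
        t, pocket = _solvent_phantom({0, 3, 4}, n_frames=8)
        occ = solvent_occupancy(t, pocket, ("TIP3", "OH2"))
        perm = np.random.default_rng(0).permutation(t.n_frames)
        t2 = Trajectory.from_coords(t.topology, t.xyz[perm])
        occ2 = solvent_occupancy(t2, pocket, ("TIP3", "OH2"))
        assert occ2.occurrences == occ.occurrences
        assert occ2.unique_atom_serials == occ.unique_atom_serials

    def test_no_solvent_records(self):
        t, pocket = _solvent_phantom(set(), n_frames=3)
        occ = solvent_occupancy(t, pocket, ("SOD", "SOD"))
        assert occ.occurrences == 0 and occ.per_frame_count == [0, 0, 0]


class TestIonDistance:
    def _traj_with_ions(self, ion_positions_per_frame):
        atoms = make_atoms([(0, 0, 0), (13, 0, 0)])
        frames = []
        for ions in ion_positions_per_frame:
            extra = []
            for i, pos in enumerate(ions):
                a = make_atoms([pos], names=["SOD"], residue_ids=[600 + i],
                               residue_name="SOD")[0]
                a.serial = 90 + i
                extra.append(a)
            frames.append(Structure(atoms + extra))
        pocket = PocketDefinition(anchor=SphereProbe(1, "PRB", 11.0),
                                  satellites=(SphereProbe(2, "PRB", 4.0),),
                                  lattice_spacing=0.5)
        return Trajectory(frames), pocket

    def test_fixed_ion(self):
        t, pocket = self._traj_with_ions([[(21.3, 0, 0)]] * 4)
        summary = nearest_ion_distance(t, pocket, ("SOD", "SOD"), cutoff=25.0)
        assert np.isclose(summary.mean, 21.3) and summary.sd == 0.0

    def test_nearest_of_two(self):
        t, pocket = self._traj_with_ions([[(10, 0, 0), (0, 20, 0)]])
        summary = nearest_ion_distance(t, pocket, ("SOD", "SOD"), cutoff=25.0)
        assert np.isclose(summary.per_frame_nearest[0], 10.0)
        assert summary.unique_ion_serials == {90, 91}

    def test_random_walk_matches_direct_computation(self):
        rng = np.random.default_rng(5)
        positions = []
        pos = np.array([15.0, 0, 0])
        for _ in range(30):
            pos = pos + rng.normal(scale=0.5, size=3)
            positions.append([tuple(pos)])
        t, pocket = self._traj_with_ions(positions)
        summary = nearest_ion_distance(t, pocket, ("SOD", "SOD"), cutoff=100.0)
        direct = np.array([np.linalg.norm(p[0]) for p in positions])
        assert np.allclose(summary.per_frame_nearest, direct)
        assert np.isclose(summary.mean, direct.mean())
        assert np.isclose(summary.sd, direct.std())

    def test_never_within_cutoff_flagged(self):
        t, pocket = self._traj_with_ions([[(50, 0, 0)]])
        with pytest.warns(UserWarning, match="no SOD"):
            summary = nearest_ion_distance(t, pocket, ("SOD", "SOD"), cutoff=25.0)
        assert summary.empty


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "pocket.yaml"
        cfg.write_text(
            "anchor: {residue_id: 167, atom_name: NH2, radius: 11.0}\n"
            "satellites:\n"
            "  - {residue_id: 88, atom_name: HG1, radius: 4.0}\n"
            "  - {residue_id: 292, atom_name: HH, radius: 7.0}\n"
            "bfs_radius: 8.0\nlattice_spacing: 0.5\n")
        p = load_pocket_definition(cfg)
        assert p.anchor == SphereProbe(167, "NH2", 11.0)
        assert len(p.satellites) == 2 and p.bfs_radius == 8.0

    def test_default_definition_matches_study_probes(self):
        p = PocketDefinition()
        assert p.anchor.radius == 11.0 and len(p.satellites) == 8
        assert p.bfs_radius == 8.0

    def test_spacing_validation(self):
        with pytest.raises(ParameterError):
            PocketDefinition(lattice_spacing=3.0)  # > half the smallest radius
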