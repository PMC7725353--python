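"""Ligand-binding-pocket geometry: lattice flood-fill volume and solvent occupancy.

The pocket is defined by probe atoms lining it: an anchor (R167:NH2 with an
11 Å radius in the AT1R model) plus satellite atoms with small radii that
rarely reach outside the pocket.  Two algorithms consume this definition:

* **Volume** — the centroid of the probe atoms defines a *centroid sphere*
  whose radius is the distance to the nearest probe; a uniform search radius
  (8 Å by default) is applied around every probe atom.  A breadth-first
  search over a cubic lattice, seeded at the centroid, counts the points that
  lie inside the centroid sphere and inside at least one probe sphere; the
  count times the lattice-cell volume is the pocket volume in Å³.

* **Solvent occupancy** — a solvent atom is inside the pocket in a frame iff
  it is within the anchor's radius of the anchor atom and within the
  satellite's own radius of at least one satellite (the dual-sphere rule).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError, SelectionError
from .structure_io import Structure, Trajectory

_NEIGHBOR_STEPS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=int)


@dataclass(frozen=True)
class SphereProbe:
    """A probe sphere anchored on one atom of the structure."""

    residue_id: int
    atom_name: str
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"probe {self.residue_id}:{self.atom_name}: radius must be > 0")


# The nine pocket-lining atoms of the AT1R model with their occupancy radii.
DEFAULT_ANCHOR = SphereProbe(167, "NH2", 11.0)   # R167
DEFAULT_SATELLITES = (
    SphereProbe(88, "HG1", 4.0),    # T88
    SphereProbe(92, "HE1", 5.0),    # Y92
    SphereProbe(109, "OG", 5.0),    # S109
    SphereProbe(199, "HZ2", 5.0),   # K199
    SphereProbe(256, "HE1", 5.0),   # H256
    SphereProbe(264, "CG2", 5.0),   # V264
    SphereProbe(284, "CE", 7.0),    # M284
    SphereProbe(292, "HH", 7.0),    # Y292
)


@dataclass
class PocketDefinition:
    """Anchor + satellite probes plus the lattice parameters of the volume search."""

    anchor: SphereProbe = DEFAULT_ANCHOR
    satellites: tuple[SphereProbe, ...] = DEFAULT_SATELLITES
    bfs_radius: float = 8.0
    lattice_spacing: float = 0.5
    chain: str | None = None

    def __post_init__(self) -> None:
        self.satellites = tuple(self.satellites)
        if 1 + len(self.satellites) < 2:
            raise ParameterError("a pocket needs at least 2 probes")
        min_radius = min([self.anchor.radius, self.bfs_radius]
                         + [p.radius for p in self.satellites])
        if not 0 < self.lattice_spacing <= min_radius / 2:
            raise ParameterError(
                f"lattice_spacing must be in (0, {min_radius / 2}] "
                f"(half the smallest probe radius)")

    @property
    def probes(self) -> tuple[SphereProbe, ...]:
        return (self.anchor, *self.satellites)

    def probe_positions(self, s: Structure) -> np.ndarray:
        """(n_probes, 3) probe-atom coordinates; raises naming missing probes."""
        missing, pos = [], []
        for p in self.probes:
            try:
                pos.append(s.coords[s.atom_index(p.residue_id, p.atom_name, self.chain)])
            except SelectionError:
                missing.append(f"{p.residue_id}:{p.atom_name}")
        if missing:
            raise SelectionError(f"pocket probe atoms not found: {', '.join(missing)}")
        return np.array(pos)


def load_pocket_definition(path: str | Path) -> PocketDefinition:
    """Pocket definition from a YAML config:

    .. code-block:: yaml

        anchor: {residue_id: 167, atom_name: NH2, radius: 11.0}
        satellites:
          - {residue_id: 88, atom_name: HG1, radius: 4.0}
        bfs_radius: 8.0
        lattice_spacing: 0.5
    """
    cfg = yaml.safe_load(Path(path).read_text())
    return PocketDefinition(
        anchor=SphereProbe(**cfg["anchor"]),
        satellites=tuple(SphereProbe(**p) for p in cfg.get("satellites", [])),
        bfs_radius=float(cfg.get("bfs_radius", 8.0)),
        lattice_spacing=float(cfg.get("lattice_spacing", 0.5)),
        chain=cfg.get("chain"),
    )


@dataclass
class PocketLattice:
    """Occupied lattice points (integer offsets from ``origin``) of one search."""

    occupied_points: set[tuple[int, int, int]]
    spacing: float
    origin: np.ndarray

    @property
    def volume(self) -> float:
        return len(self.occupied_points) * self.spacing ** 3


def pocket_centroid(s: Structure, p: PocketDefinition) -> tuple[np.ndarray, float]:
    """Centroid of the probe atoms and the minimal sphere radius that reaches
    the nearest probe atom (the centroid-sphere radius)."""
    pos = p.probe_positions(s)
    center = pos.mean(axis=0)
    seed_radius = float(np.linalg.norm(pos - center, axis=1).min())
    return center, seed_radius


def _occupancy_mask(points: np.ndarray, center: np.ndarray, seed_radius: float,
                    probe_pos: np.ndarray, bfs_radius: float) -> np.ndarray:
    """Vectorized membership test: inside the centroid sphere AND inside >=1
    probe sphere of radius ``bfs_radius``."""
    inside_centroid = ((points - center) ** 2).sum(axis=1) <= seed_radius ** 2
    d2 = ((points[:, None, :] - probe_pos[None, :, :]) ** 2).sum(axis=2)
    inside_probe = (d2 <= bfs_radius ** 2).any(axis=1)
    return inside_centroid & inside_probe


def pocket_volume(s: Structure, p: PocketDefinition,
                  centroid_radius: float | None = None) -> tuple[float, PocketLattice]:
    """Pocket volume (Å³) by breadth-first flood fill on a cubic lattice.

    The search starts at the lattice point nearest the probe centroid and
    expands over 6-connected neighbours; only the connected component holding
    the seed is counted.  A seed that falls outside every probe sphere is a
    degenerate pocket: a warning is issued and volume 0 returned.
    """
    center, seed_radius = pocket_centroid(s, p)
    if centroid_radius is not None:
        seed_radius = centroid_radius
    probe_pos = p.probe_positions(s)
    h = p.lattice_spacing

    def occupied(batch: np.ndarray) -> np.ndarray:
        return _occupancy_mask(center + batch * h, center, seed_radius,
                               probe_pos, p.bfs_radius)

    seed = (0, 0, 0)
    if not occupied(np.array([seed], dtype=int))[0]:
        warnings.warn("pocket seed point is outside every probe sphere; "
                      "degenerate pocket, volume 0", stacklevel=2)
        return 0.0, PocketLattice(set(), h, center)

    visited: set[tuple[int, int, int]] = {seed}
    frontier = np.array([seed], dtype=int)
    while frontier.size:
        cand = (frontier[:, None, :] + _NEIGHBOR_STEPS[None, :, :]).reshape(-1, 3)
        cand = np.unique(cand, axis=0)
        new = np.array([tuple(c) not in visited for c in cand])
        cand = cand[new]
        if cand.size == 0:
            break
        occ = occupied(cand)
        frontier = cand[occ]
        visited.update(map(tuple, frontier.tolist()))
    lattice = PocketLattice(visited, h, center)
    return lattice.volume, lattice


def pocket_volume_exhaustive(s: Structure, p: PocketDefinition,
                             centroid_radius: float | None = None
                             ) -> tuple[float, set[tuple[int, int, int]]]:
    """Exhaustive lattice enumeration over the centroid sphere's bounding box.

    Counts every occupied point regardless of connectivity; used as the
    independent check of the flood fill (equal on connected pockets, an upper
    bound otherwise).
    """
    center, seed_radius = pocket_centroid(s, p)
    if centroid_radius is not None:
        seed_radius = centroid_radius
    probe_pos = p.probe_positions(s)
    h = p.lattice_spacing
    n = int(np.ceil(seed_radius / h))
    ax = np.arange(-n, n + 1)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    occ = _occupancy_mask(center + grid * h, center, seed_radius, probe_pos, p.bfs_radius)
    pts = set(map(tuple, grid[occ].tolist()))
    return len(pts) * h ** 3, pts


def pocket_volume_series(t: Trajectory, p: PocketDefinition) -> np.ndarray:
    """Per-frame pocket volume (Å³) over a trajectory."""
    return np.array([pocket_volume(t.frame(i), p)[0] for i in range(t.n_frames)])


@dataclass
class SolventOccupancy:
    """Dual-sphere pocket occupancy of one solvent species over a trajectory."""

    per_frame_count: list[int]
    unique_atom_serials: set[int]
    frames_occupied: int           # frames with >= 1 solvent atom in the pocket
    occurrences: int               # sum of per-frame counts
    fraction_occurrences: float    # occurrences / n_frames (one frame can count > 1)
    fraction_frames: float         # frames_occupied / n_frames

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_count)


def solvent_occupancy(t: Trajectory, p: PocketDefinition,
                      solvent_atom: tuple[str, str]) -> SolventOccupancy:
    """Count solvent atoms (e.g. ``("TIP3", "OH2")``) inside the pocket.

    An atom is in-pocket in a frame iff it is within the anchor radius of the
    anchor atom and within the satellite's own radius of at least one
    satellite atom.  Both percentage conventions are reported because a frame
    containing several waters contributes several occurrences.
    """
    resname, atname = solvent_atom
    top = t.topology
    sol_idx = np.array([i for i, a in enumerate(top.atoms)
                        if a.residue_name == resname and a.name == atname], dtype=int)
    anchor_i = top.atom_index(p.anchor.residue_id, p.anchor.atom_name, p.chain)
    sat_idx = np.array([top.atom_index(q.residue_id, q.atom_name, p.chain)
                        for q in p.satellites], dtype=int)
    sat_r = np.array([q.radius for q in p.satellites])

    counts: list[int] = []
    uniques: set[int] = set()
    if sol_idx.size == 0:
        return SolventOccupancy([0] * t.n_frames, set(), 0, 0, 0.0, 0.0)
    serials = np.array([top.atoms[i].serial for i in sol_idx])
    for f in range(t.n_frames):
        xyz = t.xyz[f]
        sol = xyz[sol_idx]
        near_anchor = ((sol - xyz[anchor_i]) ** 2).sum(axis=1) <= p.anchor.radius ** 2
        d2 = ((sol[:, None, :] - xyz[sat_idx][None, :, :]) ** 2).sum(axis=2)
        near_sat = (d2 <= (sat_r ** 2)[None, :]).any(axis=1)
        inside = near_anchor & near_sat
        counts.append(int(inside.sum()))
        uniques.update(serials[inside].tolist())
    occurrences = int(sum(counts))
    frames_occ = int(sum(c > 0 for c in counts))
    n = t.n_frames
    return SolventOccupancy(counts, uniques, frames_occ, occurrences,
                            occurrences / n, frames_occ / n)


@dataclass
class IonDistanceSummary:
    """Nearest-ion distances from the pocket anchor over a trajectory."""

    per_frame_nearest: np.ndarray   # NaN where no ion was within the cutoff
    mean: float
    sd: float
    n_observed: int
    unique_ion_serials: set[int]

    @property
    def empty(self) -> bool:
        return self.n_observed == 0


def nearest_ion_distance(t: Trajectory, p: PocketDefinition,
                         ion: tuple[str, str], cutoff: float) -> IonDistanceSummary:
    """Per-frame minimum anchor-to-ion distance among ions within ``cutoff`` Å.

    Frames with no ion inside the cutoff are recorded as no-observation (NaN);
    the mean/SD summarise observed frames only.  An all-empty summary is
    flagged with a warning.
    """
    resname, atname = ion
    top = t.topology
    ion_idx = np.array([i for i, a in enumerate(top.atoms)
                        if a.residue_name == resname and a.name == atname], dtype=int)
    anchor_i = top.atom_index(p.anchor.residue_id, p.anchor.atom_name, p.chain)
    nearest = np.full(t.n_frames, np.nan)
    uniques: set[int] = set()
    if ion_idx.size:
        serials = np.array([top.atoms[i].serial for i in ion_idx])
        for f in range(t.n_frames):
            d = np.linalg.norm(t.xyz[f, ion_idx] - t.xyz[f, anchor_i], axis=1)
            within = d <= cutoff
            if within.any():
                nearest[f] = d[within].min()
                uniques.update(serials[within].tolist())
    observed = nearest[np.isfinite(nearest)]
    if observed.size == 0:
        warnings.warn(f"no {resname}:{atname} ion ever within {cutoff} Å of the anchor",
                      stacklevel=2)
        return IonDistanceSummary(nearest, float("nan"), float("nan"), 0, uniques)
    return IonDistanceSummary(nearest, float(observed.mean()),
                              float(observed.std()), int(observed.size), uniques)
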