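"""PDB structure / trajectory I/O and the geometric primitives used downstream.

Structures are plain in-memory records (one :class:`AtomRecord` per atom site);
multi-model PDB files become a :class:`Trajectory` whose frames share one
topology.  Coordinates are in angstroms throughout and residue numbering is the
receptor's own (1-based).  Parsing and writing of the fixed-column PDB format
is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    SelectionError,
    TopologyError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(slots=True)
class AtomRecord:
    """One atom site: identity, position (Å) and mass (Da)."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    element: str
    mass: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")
        if self.residue_id < 1:
            raise ValueError(f"atom {self.serial}: residue_id must be >= 1")


class Structure:
    """An ordered set of atoms for a single model."""

    def __init__(self, atoms: Sequence[AtomRecord], label: str = ""):
        if len(atoms) == 0:
            raise EmptyInputError("a Structure needs at least one atom")
        self.atoms = list(atoms)
        self.label = label
        keys = [(a.residue_id, a.name, a.chain) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue_id, atom name, chain) triples")
        self._key_index = {k: i for i, k in enumerate(keys)}
        self._coords: np.ndarray | None = None
        self._masses: np.ndarray | None = None

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        if self._masses is None:
            self._masses = np.array([a.mass for a in self.atoms], dtype=float)
        return self._masses

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def topology_keys(self) -> list[tuple[int, str, str]]:
        return [(a.residue_id, a.name, a.chain) for a in self.atoms]

    def atom_index(self, residue_id: int, atom_name: str, chain: str | None = None):
        """Index of one atom; chain defaults to 'A' when the structure has several."""
        if chain is None:
            chain = "A" if len(self.chains) > 1 else next(iter(self.chains))
        key = (residue_id, atom_name, chain)
        if key not in self._key_index:
            raise SelectionError(f"atom {residue_id}:{atom_name} (chain {chain}) not found")
        return self._key_index[key]

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "Structure":
        """A copy of this topology carrying different coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        atoms = [
            AtomRecord(a.serial, a.name, a.residue_name, a.residue_id, a.chain,
                       xyz[i], a.element, a.mass)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, label if label is not None else self.label)

    def __len__(self) -> int:
        return len(self.atoms)


class Trajectory:
    """An ordered list of structures sharing one topology.

    Internally stores the shared topology plus an ``(n_frames, n_atoms, 3)``
    coordinate array; ``frames`` materialises :class:`Structure` views lazily.
    """

    def __init__(self, frames: Sequence[Structure], timestep_ps: float = 10.0):
        if len(frames) == 0:
            raise EmptyInputError("a Trajectory needs at least one frame")
        if timestep_ps <= 0:
            raise ValueError("timestep_ps must be positive")
        keys0 = frames[0].topology_keys()
        for i, f in enumerate(frames[1:], start=2):
            if f.topology_keys() != keys0:
                raise TopologyError(f"frame {i} does not share the topology of frame 1")
        self.topology = frames[0]
        self.xyz = np.stack([f.coords for f in frames])
        self.timestep_ps = float(timestep_ps)

    @classmethod
    def from_coords(cls, topology: Structure, xyz: np.ndarray,
                    timestep_ps: float = 10.0) -> "Trajectory":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.ndim != 3 or xyz.shape[1:] != (len(topology), 3):
            raise TopologyError("xyz must have shape (n_frames, n_atoms, 3)")
        t = cls.__new__(cls)
        if timestep_ps <= 0:
            raise ValueError("timestep_ps must be positive")
        t.topology = topology
        t.xyz = xyz
        t.timestep_ps = float(timestep_ps)
        return t

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def frames(self) -> list[Structure]:
        return [self.frame(i) for i in range(self.n_frames)]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.xyz[i], label=f"{self.topology.label}[{i}]")

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Structure]:
        return (self.frame(i) for i in range(self.n_frames))


@dataclass
class ResidueSelection:
    """A set of (residue_id, optional atom name) entries, resolvable in a Structure.

    ``atom name None`` selects every atom of the residue (or only N/CA/C/O when
    ``backbone_only`` is set).  ``chain None`` defaults to chain A for
    multi-chain structures.
    """

    entries: Sequence[tuple[int, str | None]]
    backbone_only: bool = False
    chain: str | None = None

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise SelectionError("empty selection")

    @classmethod
    def residues(cls, residue_ids: Sequence[int], backbone_only: bool = False,
                 chain: str | None = None) -> "ResidueSelection":
        return cls([(r, None) for r in residue_ids], backbone_only, chain)

    @classmethod
    def residue_range(cls, first: int, last: int, backbone_only: bool = False,
                      chain: str | None = None) -> "ResidueSelection":
        return cls.residues(range(first, last + 1), backbone_only, chain)

    def resolve(self, s: Structure) -> np.ndarray:
        """Atom indices in ``s``, in structure order; raises on unmatched entries."""
        chain = self.chain
        if chain is None:
            chain = "A" if len(s.chains) > 1 else next(iter(s.chains))
        wanted_any: set[int] = set()
        wanted_named: set[tuple[int, str]] = set()
        for resid, name in self.entries:
            if name is None:
                wanted_any.add(resid)
            else:
                wanted_named.add((resid, name))
        idx, seen_any, seen_named = [], set(), set()
        for i, a in enumerate(s.atoms):
            if a.chain != chain:
                continue
            if (a.residue_id, a.name) in wanted_named:
                idx.append(i)
                seen_named.add((a.residue_id, a.name))
            elif a.residue_id in wanted_any:
                if self.backbone_only and a.name not in BACKBONE_ATOMS:
                    continue
                idx.append(i)
                seen_any.add(a.residue_id)
        missing = sorted(wanted_any - seen_any) + sorted(wanted_named - seen_named)
        if missing:
            raise SelectionError(f"unmatched selection entries (chain {chain}): {missing}")
        return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _element_and_mass(name: str, element_hint: str) -> tuple[str, float]:
    sym = element_hint.strip()
    if sym and sym != "X":
        el = gemmi.Element(sym)
        if el.weight > 0:
            return el.name, el.weight
    # infer from the atom name: strip digits/primes, try 2- then 1-letter symbols
    letters = "".join(c for c in name if c in string.ascii_letters)
    for cand in (letters[:2].capitalize(), letters[:1].upper()):
        if cand:
            el = gemmi.Element(cand)
            if el.name != "X" and el.weight > 0:
                return el.name, el.weight
    raise FormatError(f"cannot infer element for atom name {name!r}")


def read_pdb(path: str | Path, timestep_ps: float = 10.0) -> Trajectory:
    """Read a PDB file into a Trajectory (one frame per MODEL block).

    Files without MODEL records yield a single-frame trajectory.  Elements are
    taken from the element column when present, otherwise inferred from the
    atom name; masses come from the standard element table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise FormatError(f"{path}: {exc}") from exc
    frames: list[Structure] = []
    for mi, model in enumerate(st):
        atoms: list[AtomRecord] = []
        serial = 0
        for ch in model:
            for res in ch:
                for at in res:
                    serial += 1
                    el, mass = _element_and_mass(at.name, at.element.name)
                    atoms.append(AtomRecord(
                        serial=at.serial if at.serial else serial,
                        name=at.name,
                        residue_name=res.name,
                        residue_id=res.seqid.num,
                        chain=ch.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=el,
                        mass=mass,
                    ))
        if atoms:
            frames.append(Structure(atoms, label=f"{path.stem}:{mi + 1}"))
    if not frames:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    frames[0].label = path.stem
    return Trajectory(frames, timestep_ps=timestep_ps)


def write_pdb(t: Trajectory | Structure, path: str | Path) -> None:
    """Write a Structure or Trajectory as fixed-column PDB.

    Multi-frame trajectories are written as MODEL/ENDMDL blocks;
    ``read_pdb(write_pdb(x))`` preserves atom count, ordering and residue ids
    exactly, and coordinates to the format's 1e-3 Å precision.
    """
    if isinstance(t, Structure):
        t = Trajectory([t])
    st = gemmi.Structure()
    st.name = t.topology.label or "arbdock"
    for fi in range(t.n_frames):
        frame = t.frame(fi)
        model = gemmi.Model(fi + 1)
        chain = None
        residue = None
        res_key = None
        for a in frame.atoms:
            if chain is None or chain.name != a.chain:
                chain = gemmi.Chain(a.chain)
                model.add_chain(chain)
                chain = model[len(model) - 1]
                res_key = None
            if res_key != (a.residue_id, a.residue_name):
                residue = gemmi.Residue()
                residue.name = a.residue_name
                residue.seqid = gemmi.SeqId(a.residue_id, " ")
                chain.add_residue(residue)
                residue = chain[len(chain) - 1]
                res_key = (a.residue_id, a.residue_name)
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.position)
            at.occ = 1.0
            residue.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

def center_of_mass(s: Structure, sel: ResidueSelection,
                   geometric: bool = False) -> np.ndarray:
    """Mass-weighted (default) or geometric mean position of the selection, Å."""
    idx = sel.resolve(s)
    xyz = s.coords[idx]
    if geometric:
        return xyz.mean(axis=0)
    w = s.masses[idx]
    return (xyz * w[:, None]).sum(axis=0) / w.sum()


def _com_series(t: Trajectory, sel: ResidueSelection, geometric: bool) -> np.ndarray:
    idx = sel.resolve(t.topology)
    xyz = t.xyz[:, idx, :]
    if geometric:
        return xyz.mean(axis=1)
    w = t.topology.masses[idx]
    return (xyz * w[None, :, None]).sum(axis=1) / w.sum()


def pair_distance_series(t: Trajectory, a: ResidueSelection, b: ResidueSelection,
                         geometric: bool = False) -> np.ndarray:
    """Per-frame distance between the centers of mass of two selections, Å."""
    return np.linalg.norm(_com_series(t, a, geometric) - _com_series(t, b, geometric),
                          axis=1)


def rmsd_series(t: Trajectory, ref: Structure, sel: ResidueSelection,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms relative to ``ref``.

    With ``superpose`` each frame is first optimally superposed onto the
    reference (closed-form least-squares rotation + translation); without it
    the deviation is measured in the shared laboratory frame, which is how a
    mobile segment is compared against a fixed reference model.
    """
    ref_idx = sel.resolve(ref)
    frm_idx = sel.resolve(t.topology)
    if len(ref_idx) != len(frm_idx):
        raise TopologyError("selection resolves to different atom sets in ref and frames")
    ref_xyz = ref.coords[ref_idx]
    out = np.empty(t.n_frames)
    n = len(ref_idx)
    if not superpose:
        diff = t.xyz[:, frm_idx, :] - ref_xyz[None]
        return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
    ref_c = ref_xyz - ref_xyz.mean(axis=0)
    for i in range(t.n_frames):
        mov = t.xyz[i, frm_idx, :]
        mov_c = mov - mov.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mov_c)
        out[i] = rssd / np.sqrt(n)
    return out


def rmsf_per_residue(t: Trajectory, sel: ResidueSelection) -> dict[int, float]:
    """Per-residue RMSF (Å): RMS displacement of the residue's selected-atom
    centroid from its time-average position, over all frames."""
    if t.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    idx = sel.resolve(t.topology)
    resids = np.array([t.topology.atoms[i].residue_id for i in idx])
    out: dict[int, float] = {}
    for resid in sorted(set(resids.tolist())):
        sub = idx[resids == resid]
        centroid = t.xyz[:, sub, :].mean(axis=1)          # (F, 3)
        dev = centroid - centroid.mean(axis=0)
        out[resid] = float(np.sqrt((dev ** 2).sum(axis=1).mean()))
    return out
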