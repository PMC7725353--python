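"""Activation-state classification and DEER-mode comparison for GPCR trajectories.

Class-A GPCRs switch between inactive and active conformations that are
separable by a handful of inter-residue center-of-mass distances (e.g. the
TM3-TM6 opening on activation).  Each monitored pair carries reference
mean/SD distances for the inactive and active consensus ensembles; an
observed trajectory votes pair-by-pair for the state whose reference it is
closest to in SD units, and the majority decides the call.

The DEER comparison is the complementary experimental check: for residue
pairs probed by double electron-electron resonance, it asks what fraction of
the spectroscopic major modes falls inside the simulated distance range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .errors import ParameterError
from .structure_io import ResidueSelection, Trajectory, pair_distance_series


@dataclass
class StatePair:
    """A monitored residue pair with inactive/active reference distances (Å)."""

    label: str
    residue_a: int | None
    residue_b: int | None
    inactive_mean: float
    inactive_sd: float
    active_mean: float
    active_sd: float

    def __post_init__(self) -> None:
        if self.inactive_mean <= 0 or self.active_mean <= 0:
            raise ParameterError(f"{self.label}: reference means must be positive")
        if self.inactive_sd < 0 or self.active_sd < 0:
            raise ParameterError(f"{self.label}: reference SDs must be non-negative")


def default_state_pairs(bw_map: dict[str, int] | None = None) -> list[StatePair]:
    """The four consensus activation pairs with published reference values.

    ``bw_map`` maps Ballesteros-Weinstein positions (e.g. ``"3.46"``) to
    residue ids; the AT1R positions the study names are pre-filled, the rest
    stay ``None`` until supplied (classification does not need them, distance
    measurement does).
    """
    mapping = dict(reference.BW_TO_AT1R_RESIDUE)
    if bw_map:
        mapping.update(bw_map)
    pairs = []
    for label, (im, isd, am, asd) in reference.STATE_PAIR_REFERENCES.items():
        bw_a, bw_b = label.split(" to ")
        pairs.append(StatePair(label, mapping.get(bw_a), mapping.get(bw_b),
                               im, isd, am, asd))
    return pairs


@dataclass
class DeerPair:
    """A residue pair probed by DEER with its major-mode distances (Å)."""

    residue_a: int
    residue_b: int
    major_modes: tuple[float, ...]

    def __post_init__(self) -> None:
        self.major_modes = tuple(self.major_modes)
        if not self.major_modes or any(m <= 0 for m in self.major_modes):
            raise ParameterError("each DEER pair needs >= 1 positive major mode")


@dataclass
class PairVote:
    label: str
    observed_mean: float
    observed_sd: float
    z_inactive: float
    z_active: float
    vote: str  # "inactive" | "active"


@dataclass
class StateReport:
    votes: list[PairVote]
    call: str  # "inactive" | "active" | "indeterminate"


def _resolve_window(n_frames: int, window: tuple[int, int] | None) -> slice:
    if window is None:
        return slice(0, n_frames)
    start, stop = window
    if not (0 <= start < stop <= n_frames):
        raise ParameterError(f"window {window} outside trajectory of {n_frames} frames")
    return slice(start, stop)


def measure_state_pairs(t: Trajectory, pairs: list[StatePair],
                        window: tuple[int, int] | None = None
                        ) -> dict[str, tuple[float, float]]:
    """Per-pair COM-distance mean and population SD over the frame window."""
    sl = _resolve_window(t.n_frames, window)
    sub = Trajectory.from_coords(t.topology, t.xyz[sl], t.timestep_ps)
    out: dict[str, tuple[float, float]] = {}
    for p in pairs:
        if p.residue_a is None or p.residue_b is None:
            raise ParameterError(
                f"pair {p.label}: residue ids not mapped; supply them via bw_map")
        d = pair_distance_series(sub, ResidueSelection.residues([p.residue_a]),
                                 ResidueSelection.residues([p.residue_b]))
        out[p.label] = (float(d.mean()), float(d.std()))
    return out


def classify_state(observed: dict[str, tuple[float, float]] | dict[str, float],
                   pairs: list[StatePair], sd_floor: float = 0.1) -> StateReport:
    """Vote each pair for the reference state nearer in SD units; majority call.

    ``observed`` maps pair label to a mean (or ``(mean, sd)``).  z-distances
    use the reference SDs with a floor so a zero printed SD cannot dominate.
    The call is the state winning strictly more than half the votes, else
    ``indeterminate``.
    """
    votes: list[PairVote] = []
    for p in pairs:
        if p.label not in observed:
            continue
        obs = observed[p.label]
        mean, sd = (obs if isinstance(obs, tuple) else (obs, 0.0))
        z_in = abs(mean - p.inactive_mean) / max(p.inactive_sd, sd_floor)
        z_act = abs(mean - p.active_mean) / max(p.active_sd, sd_floor)
        votes.append(PairVote(p.label, mean, sd, z_in, z_act,
                              "inactive" if z_in <= z_act else "active"))
    n = len(votes)
    n_inactive = sum(v.vote == "inactive" for v in votes)
    if n_inactive * 2 > n:
        call = "inactive"
    elif (n - n_inactive) * 2 > n:
        call = "active"
    else:
        call = "indeterminate"
    return StateReport(votes, call)


@dataclass
class DeerComparison:
    per_pair_distances: dict[tuple[int, int], np.ndarray]
    modes_inside: dict[tuple[int, int], int]
    fraction_inside: float


def deer_compare(t: Trajectory, pairs: list[DeerPair],
                 window: tuple[int, int] | None = None) -> DeerComparison:
    """Raw per-frame COM distances per DEER pair plus the fraction of major
    modes inside the closed [min, max] of the sampled distances."""
    sl = _resolve_window(t.n_frames, window)
    sub = Trajectory.from_coords(t.topology, t.xyz[sl], t.timestep_ps)
    dists: dict[tuple[int, int], np.ndarray] = {}
    inside: dict[tuple[int, int], int] = {}
    total_modes = 0
    total_inside = 0
    for p in pairs:
        key = (p.residue_a, p.residue_b)
        d = pair_distance_series(sub, ResidueSelection.residues([p.residue_a]),
                                 ResidueSelection.residues([p.residue_b]))
        dists[key] = d
        lo, hi = float(d.min()), float(d.max())
        k = sum(lo <= m <= hi for m in p.major_modes)
        inside[key] = k
        total_modes += len(p.major_modes)
        total_inside += k
    return DeerComparison(dists, inside, total_inside / total_modes if total_modes else 0.0)
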