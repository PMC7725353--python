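"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of (seed, parameters): the same call gives
bit-identical output.  Generators return their dataset together with a
machine-readable ground-truth dict so tests (and the acceptance script) can
assert recovery of planted quantities:

* :func:`gen_bundle_structure` — a poly-alanine helical bundle enclosing a
  cavity, with probe pseudo-atoms whose sphere-intersection volume is
  measured independently by Monte-Carlo rejection sampling;
* :func:`gen_trajectory` — reference coordinates plus Gaussian displacement
  noise of known per-residue scale, with optional planted pair distances and
  scripted pocket waters/ions;
* :func:`gen_docking_runs` — pose-energy ensembles with the exact
  Boltzmann-weighted mean recorded per run (plus a DLG emission mode);
* :func:`gen_calibration_surface` — smooth 2-parameter affinity surfaces
  with planted optima sampled on the 7×7 design;
* :func:`gen_variant_panel` — replicate variant × ligand affinity panels
  with planted fold-change effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax

from . import reference
from .affinity import DEFAULT_THERMO, DockingRun, Thermo
from .calibration import DEFAULT_GPS_VALUES, DEFAULT_Z_VALUES, CalibrationPoint
from .errors import ParameterError
from .pocket_geometry import PocketDefinition, SphereProbe
from .structure_io import AtomRecord, Structure, Trajectory
from .variant_stats import VariantPanel

# Ideal alpha-helix backbone parameters.
_HELIX_RISE = 1.5          # Å per residue along the axis
_HELIX_TWIST = 100.0       # degrees per residue
_HELIX_CA_RADIUS = 2.3     # Å

_BACKBONE_OFFSETS = {      # local offsets from CA, enough geometry for analysis
    "N": np.array([-1.20, -0.60, -0.50]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.50, 0.55]),
    "O": np.array([1.35, 1.70, 0.70]),
}
_MASSES = {"N": 14.007, "C": 12.011, "O": 15.999}


def _sphere_lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres (radii r1, r2, centers d apart)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r ** 3
    return (np.pi * (r1 + r2 - d) ** 2
            * (d ** 2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d))


def _helix_backbone(helix_axis_origin: np.ndarray, n_residues: int,
                    first_resid: int, chain: str, serial_start: int,
                    direction: int = 1) -> list[AtomRecord]:
    atoms = []
    serial = serial_start
    for j in range(n_residues):
        theta = np.deg2rad(_HELIX_TWIST * j)
        ca = helix_axis_origin + np.array([
            _HELIX_CA_RADIUS * np.cos(theta),
            _HELIX_CA_RADIUS * np.sin(theta),
            direction * _HELIX_RISE * j,
        ])
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1]])
        for name in ("N", "CA", "C", "O"):
            serial += 1
            pos = ca + rot @ _BACKBONE_OFFSETS[name]
            el = name[0]
            atoms.append(AtomRecord(serial, name, "ALA", first_resid + j, chain,
                                    pos, el, _MASSES[el]))
    return atoms


def gen_bundle_structure(
    seed: int = 0,
    n_helices: int = 7,
    residues_per_helix: int = 12,
    ring_radius: float = 12.0,
    probes: Sequence[tuple[int, str, Sequence[float]]] | None = None,
    probe_anchor_radius: float = 11.0,
    probe_satellite_radius: float = 5.0,
    bfs_radius: float = 5.5,
    lattice_spacing: float = 0.25,
    mc_samples: int = 1_000_000,
) -> tuple[Structure, dict]:
    """A poly-alanine helical bundle on a ring, enclosing a probed cavity.

    ``probes`` is a list of (residue_id, atom_name, position) pseudo-atoms
    defining the pocket; the default places eight probes on a 5 Å circle
    inside the bundle, giving a non-trivial sphere-intersection region.  The
    ground truth carries the probe coordinates, a matching
    :class:`PocketDefinition`, and a Monte-Carlo reference volume obtained by
    rejection sampling (independent of the lattice flood fill).
    """
    if ring_radius <= 0:
        raise ParameterError("ring_radius must be positive")
    if n_helices < 1 or residues_per_helix < 1:
        raise ParameterError("need >= 1 helix and >= 1 residue per helix")
    rng = np.random.default_rng(seed)

    atoms: list[AtomRecord] = []
    z0 = -residues_per_helix * _HELIX_RISE / 2
    for k in range(n_helices):
        phi = 2 * np.pi * k / n_helices
        origin = np.array([ring_radius * np.cos(phi), ring_radius * np.sin(phi), z0])
        direction = 1 if k % 2 == 0 else -1
        if direction == -1:
            origin[2] = -z0
        atoms.extend(_helix_backbone(origin, residues_per_helix,
                                     first_resid=k * residues_per_helix + 1,
                                     chain="A", serial_start=len(atoms),
                                     direction=direction))

    if probes is None:
        n_probes = 8
        probes = []
        for i in range(n_probes):
            ang = 2 * np.pi * i / n_probes
            pos = [5.0 * np.cos(ang), 5.0 * np.sin(ang), 1.5 * np.sin(2 * ang)]
            probes.append((900 + i, "PRB", pos))
    probe_pos = np.array([p[2] for p in probes], dtype=float)
    if len(probes) < 2 or np.allclose(probe_pos.std(axis=0), 0):
        raise ParameterError("probe placement degenerate: need >= 2 distinct probes")
    for resid, name, pos in probes:
        atoms.append(AtomRecord(len(atoms) + 1, name, "PRB", resid, "A",
                                np.asarray(pos, dtype=float), "C", 12.011))

    pocket = PocketDefinition(
        anchor=SphereProbe(probes[0][0], probes[0][1], probe_anchor_radius),
        satellites=tuple(SphereProbe(r, n, probe_satellite_radius)
                         for r, n, _ in probes[1:]),
        bfs_radius=bfs_radius,
        lattice_spacing=lattice_spacing,
    )

    # Monte-Carlo reference volume: rejection sampling in the centroid-sphere
    # bounding box against the same membership definition the lattice uses.
    center = probe_pos.mean(axis=0)
    seed_radius = float(np.linalg.norm(probe_pos - center, axis=1).min())
    box_lo = center - seed_radius
    samples = rng.uniform(box_lo, center + seed_radius, size=(mc_samples, 3))
    inside_centroid = ((samples - center) ** 2).sum(axis=1) <= seed_radius ** 2
    d2 = ((samples[:, None, :] - probe_pos[None, :, :]) ** 2).sum(axis=2)
    inside = inside_centroid & (d2 <= bfs_radius ** 2).any(axis=1)
    box_volume = (2 * seed_radius) ** 3
    frac = inside.mean()
    mc_volume = float(frac * box_volume)
    mc_se = float(box_volume * np.sqrt(frac * (1 - frac) / mc_samples))

    structure = Structure(atoms, label=f"bundle-seed{seed}")
    truth = {
        "seed": seed,
        "probe_positions": probe_pos.tolist(),
        "pocket": pocket,
        "centroid": center.tolist(),
        "seed_radius": seed_radius,
        "mc_volume": mc_volume,
        "mc_se": mc_se,
        "mc_samples": mc_samples,
    }
    return structure, truth


def gen_trajectory(
    base: Structure,
    seed: int = 0,
    n_frames: int = 100,
    sigma: float | Mapping[int, float] = 0.5,
    timestep_ps: float = 10.0,
    planted_pair_distances: Sequence[float] | None = None,
    solvent_events: Sequence[dict] | None = None,
) -> tuple[Trajectory, dict]:
    """Reference coordinates plus per-atom isotropic Gaussian noise.

    ``sigma`` is a scalar or a residue_id → σ map (Å per axis); with σ the
    per-axis SD, the expected per-residue RMSF is σ·√3.  ``planted_pair
    _distances`` adds two noise-free single-atom residues (ids 801/802, atom
    COM) separated by the scripted distance in each frame.  ``solvent_events``
    adds solvent atoms that sit at the pocket centroid in the scripted frames
    and far outside otherwise, e.g.::

        {"residue_name": "TIP3", "atom_name": "OH2", "residue_id": 5001,
         "in_frames": [2, 3, 7], "inside_position": [0, 0, 0]}
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")

    def sigma_for(resid: int) -> float:
        s = sigma[resid] if isinstance(sigma, Mapping) else sigma
        if s < 0:
            raise ParameterError(f"sigma for residue {resid} must be >= 0")
        return float(s)

    rng = np.random.default_rng(seed)
    atoms = list(base.atoms)
    sigmas = np.array([sigma_for(a.residue_id) for a in atoms])

    extra_atoms: list[AtomRecord] = []
    serial = max(a.serial for a in atoms)
    if planted_pair_distances is not None:
        planted = np.asarray(planted_pair_distances, dtype=float)
        if planted.size != n_frames:
            raise ParameterError("planted_pair_distances must have one value per frame")
        far = np.array([500.0, 0.0, 0.0])
        # unit masses keep single-atom centers of mass bit-exact
        extra_atoms.append(AtomRecord(serial + 1, "COM", "PNT", 801, "A",
                                      far, "H", 1.0))
        extra_atoms.append(AtomRecord(serial + 2, "COM", "PNT", 802, "A",
                                      far + [1.0, 0, 0], "H", 1.0))
        serial += 2
    events: list[dict] = []
    for ev_in in (solvent_events or []):
        serial += 1
        ev = dict(ev_in)
        inside = np.asarray(ev["inside_position"], dtype=float)
        outside = np.asarray(ev.get("outside_position", inside + [500.0, 0.0, 0.0]),
                             dtype=float)
        ev.update(inside_position=inside, outside_position=outside,
                  serial=serial, in_frames=set(ev["in_frames"]))
        events.append(ev)
        extra_atoms.append(AtomRecord(serial, ev["atom_name"], ev["residue_name"],
                                      ev["residue_id"], "A", outside, "O", 15.999))
    topology = Structure(atoms + extra_atoms, label=f"{base.label}-traj")
    n_base = len(atoms)

    xyz = np.empty((n_frames, len(topology), 3))
    base_xyz = topology.coords
    for f in range(n_frames):
        noise = rng.normal(0.0, 1.0, size=(n_base, 3)) * sigmas[:, None]
        frame = base_xyz.copy()
        frame[:n_base] += noise
        cursor = n_base
        if planted_pair_distances is not None:
            frame[cursor] = [500.0, 0.0, 0.0]
            frame[cursor + 1] = [500.0 + planted[f], 0.0, 0.0]
            cursor += 2
        for ev in events:
            frame[cursor] = (ev["inside_position"] if f in ev["in_frames"]
                             else ev["outside_position"])
            cursor += 1
        xyz[f] = frame

    traj = Trajectory.from_coords(topology, xyz, timestep_ps)
    truth = {
        "seed": seed,
        "sigma": dict(sigma) if isinstance(sigma, Mapping) else float(sigma),
        "expected_rmsf": {
            a.residue_id: sigma_for(a.residue_id) * np.sqrt(3.0) for a in atoms},
        "planted_pair_distances": (planted.tolist()
                                   if planted_pair_distances is not None else None),
        "solvent_in_frames": {ev["serial"]: sorted(ev["in_frames"]) for ev in events},
    }
    return traj, truth


def gen_docking_runs(
    seed: int = 0,
    n_runs: int = 6,
    n_poses: int = 100,
    mu: float = -8.0,
    pose_sd: float = 0.5,
    energies: Sequence[Sequence[float]] | None = None,
    ligand: str = "synthetic-ligand",
    receptor: str = "synthetic-receptor",
    th: Thermo = DEFAULT_THERMO,
) -> tuple[list[DockingRun], dict]:
    """Docking runs with normally distributed pose energies (or fixed lists).

    Ground truth stores each run's exact Boltzmann-weighted mean energy
    computed through an independent route (softmax weights) so consumers of
    the package's own weighted sum have an oracle to compare against.
    """
    if n_poses < 1:
        raise ParameterError("n_poses must be >= 1")
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    runs: list[DockingRun] = []
    if energies is not None:
        for i, e in enumerate(energies):
            runs.append(DockingRun(ligand, receptor, np.asarray(e, dtype=float), i))
    else:
        for i in range(n_runs):
            e = rng.normal(mu, pose_sd, size=n_poses)
            runs.append(DockingRun(ligand, receptor, e, i))
    true_dg = []
    for r in runs:
        e = r.pose_energies
        w = softmax(-e / th.RT)
        # anchor at the minimum so degenerate runs come out exact
        true_dg.append(float(e.min() + (w * (e - e.min())).sum()))
    truth = {"seed": seed, "true_dg_bw": true_dg,
             "true_pkd": [-np.log10(np.exp(d / th.RT)) for d in true_dg]}
    return runs, truth


def write_dlg(run: DockingRun, path: str | Path) -> None:
    """Emit a minimal AutoDock-4.2-style DLG with one energy banner per pose."""
    lines = [f"DOCKED: USER  Run = {run.run_id}",
             f"DOCKED: USER  ligand = {run.ligand}"]
    for i, e in enumerate(run.pose_energies, start=1):
        lines.append(f"DOCKED: MODEL {i}")
        lines.append(f"DOCKED: USER    Estimated Free Energy of Binding    ="
                     f" {e:+8.2f} kcal/mol  [=(1)+(2)+(3)-(4)]")
        lines.append("DOCKED: ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


SURFACE_FORMS = ("bilinear", "quadratic", "bimodal")


def gen_calibration_surface(
    seed: int = 0,
    form: str = "quadratic",
    noise_sd: float = 0.0,
    gps_values: Sequence[float] = DEFAULT_GPS_VALUES,
    z_values: Sequence[float] = DEFAULT_Z_VALUES,
    optimum: tuple[float, float] | None = None,
    peak_pkd: float = 8.5,
) -> tuple[list[CalibrationPoint], dict]:
    """pKd design points from a smooth surface with a planted structure.

    Forms: ``bilinear`` (a·gps + b·z + c, recovered exactly by the linear
    fit), ``quadratic`` (a concave bowl with its maximum planted at
    ``optimum``, drawn uniformly inside the design interior by default) and
    ``bimodal`` (two Gaussian bumps, mimicking the rugged response the 7×7
    design was built to interrogate).  Gaussian noise of SD ``noise_sd``
    (pKd units) is added to every cell.
    """
    if form not in SURFACE_FORMS:
        raise ParameterError(f"unknown surface form {form!r}; choose from {SURFACE_FORMS}")
    rng = np.random.default_rng(seed)
    gps_values = np.asarray(sorted(gps_values), dtype=float)
    z_values = np.asarray(sorted(z_values), dtype=float)
    g_lo, g_hi = gps_values[0], gps_values[-1]
    z_lo, z_hi = z_values[0], z_values[-1]

    if form == "bilinear":
        a = rng.uniform(-4.0, 4.0)
        b = rng.uniform(-0.5, 0.5)
        c = 8.0 - a * gps_values.mean() - b * z_values.mean()
        func = lambda g, z: a * g + b * z + c
        truth_extra = {"coefficients": {"a": float(a), "b": float(b), "c": float(c)}}
    elif form == "quadratic":
        if optimum is None:
            span_g, span_z = g_hi - g_lo, z_hi - z_lo
            optimum = (float(rng.uniform(g_lo + 0.25 * span_g, g_hi - 0.25 * span_g)),
                       float(rng.uniform(z_lo + 0.25 * span_z, z_hi - 0.25 * span_z)))
        cg = 4.0 / (g_hi - g_lo) ** 2
        cz = 4.0 / (z_hi - z_lo) ** 2
        g0, z0 = optimum
        func = lambda g, z: peak_pkd - cg * (g - g0) ** 2 - cz * (z - z0) ** 2
        truth_extra = {"optimum": (float(g0), float(z0)), "peak_pkd": float(peak_pkd),
                       "curvature": (float(cg), float(cz))}
    else:  # bimodal
        g1 = rng.uniform(g_lo, g_lo + 0.4 * (g_hi - g_lo))
        g2 = rng.uniform(g_hi - 0.4 * (g_hi - g_lo), g_hi)
        z1, z2 = rng.uniform(z_lo, z_hi, size=2)
        func = lambda g, z: (8.0
                             + 0.6 * np.exp(-((g - g1) / 0.05) ** 2 - ((z - z1) / 0.7) ** 2)
                             + 0.4 * np.exp(-((g - g2) / 0.05) ** 2 - ((z - z2) / 0.7) ** 2))
        truth_extra = {"modes": [(float(g1), float(z1)), (float(g2), float(z2))]}

    points = []
    for g in gps_values:
        for z in z_values:
            pkd = float(func(g, z)) + float(rng.normal(0.0, noise_sd)) if noise_sd else float(func(g, z))
            points.append(CalibrationPoint(float(g), float(z), pkd))
    truth = {"seed": seed, "form": form, "noise_sd": float(noise_sd),
             "function": func, **truth_extra}
    return points, truth


def gen_variant_panel(
    seed: int = 0,
    variants: Sequence[str] = ("A163T", "W84C", "F248L"),
    ligands: Sequence[str] = reference.ARB_NAMES,
    n_reps: int = 6,
    replicate_sd: float = 0.05,
    effects: Mapping[tuple[str, str], float] | None = None,
    wt_pkd: Mapping[str, float] | None = None,
) -> tuple[VariantPanel, dict]:
    """Replicate pKd panels with planted fold-change effects.

    Wild-type base affinities default to the published median ARB affinities
    (as positive pKd).  ``effects`` maps (variant, ligand) to a planted Kd
    fold change (> 1 weakens binding by shifting the variant's pKd down by
    log10(fold)); unlisted cells are null.  Replicate noise is Gaussian with
    SD ``replicate_sd`` pKd units.
    """
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")
    effects = dict(effects or {})
    for key, fold in effects.items():
        if fold <= 0:
            raise ParameterError(f"effect fold for {key} must be positive")
    rng = np.random.default_rng(seed)
    if wt_pkd is None:
        wt_pkd = {lig: -reference.ARB_PARAMETERS[lig].median_log_m
                  if lig in reference.ARB_PARAMETERS else 8.2
                  for lig in ligands}
    reps: dict[tuple[str, str], np.ndarray] = {}
    wt: dict[str, np.ndarray] = {}
    for lig in ligands:
        base = wt_pkd[lig]
        wt[lig] = base + rng.normal(0.0, replicate_sd, size=n_reps)
        for v in variants:
            shift = -np.log10(effects.get((v, lig), 1.0))
            reps[(v, lig)] = base + shift + rng.normal(0.0, replicate_sd, size=n_reps)
    panel = VariantPanel(list(variants), list(ligands), reps, wt)
    truth = {"seed": seed, "effects": dict(effects),
             "wt_pkd": {k: float(v) for k, v in wt_pkd.items()},
             "replicate_sd": float(replicate_sd)}
    return panel, truth


def panel_to_long_table(panel: VariantPanel, wildtype_label: str = "WT"):
    """Long-format DataFrame (variant, ligand, run_id, pkd) mirroring the
    package's TSV exchange format."""
    import pandas as pd

    rows = []
    for lig, vals in panel.wildtype_pkd.items():
        rows += [{"variant": wildtype_label, "ligand": lig, "run_id": i, "pkd": x}
                 for i, x in enumerate(vals)]
    for (v, lig), vals in panel.replicate_pkd.items():
        rows += [{"variant": v, "ligand": lig, "run_id": i, "pkd": x}
                 for i, x in enumerate(vals)]
    return pd.DataFrame(rows)


def ground_truth_to_json(truth: Mapping, path: str | Path) -> None:
    """Serialise a ground-truth dict (dropping non-serialisable members)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, PocketDefinition):
            return {"anchor": asdict(o.anchor),
                    "satellites": [asdict(s) for s in o.satellites],
                    "bfs_radius": o.bfs_radius,
                    "lattice_spacing": o.lattice_spacing}
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    clean = {k: v for k, v in truth.items() if not callable(v)}
    clean = {("|".join(map(str, k)) if isinstance(k, tuple) else k): v
             for k, v in clean.items()}
    Path(path).write_text(json.dumps(clean, indent=2, default=default))
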