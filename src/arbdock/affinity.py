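"""Boltzmann-weighted docking affinities and affinity unit conversions.

A docking run yields one binding free energy per pose (ΔG_i, kcal/mol).  The
run-level affinity used throughout this package is the Boltzmann-weighted
mean energy

    ΔG_bw = Σ_i ΔG_i · exp(−ΔG_i / RT) / Σ_i exp(−ΔG_i / RT),

which favours the lowest-energy (highest-affinity) poses, mirroring the
pharmacological expectation that binding is dominated by the tightest pose.
ΔG converts to a dissociation constant via Kd = exp(ΔG / RT); affinities are
reported as pKd = −log10(Kd in M).  Replicate runs are aggregated by the
arithmetic mean of per-run pKd with a Student-t 95% CI.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import EmptyInputError, FormatError

#: Molar gas constant in kcal/(mol·K).
R_KCAL = 1.98720425864e-3
#: Body temperature, K.
BODY_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class Thermo:
    """Thermodynamic constants for energy <-> Kd conversion."""

    R: float = R_KCAL
    T: float = BODY_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")

    @property
    def RT(self) -> float:
        """RT in kcal/mol (~0.6164 at body temperature)."""
        return self.R * self.T


DEFAULT_THERMO = Thermo()


@dataclass
class DockingRun:
    """Per-pose binding free energies (kcal/mol) of one docking execution."""

    ligand: str
    receptor: str
    pose_energies: np.ndarray
    run_id: int = 0

    def __post_init__(self) -> None:
        self.pose_energies = np.asarray(self.pose_energies, dtype=float)
        if self.pose_energies.size == 0:
            raise EmptyInputError("a DockingRun needs at least one pose energy")
        if not np.all(np.isfinite(self.pose_energies)):
            raise ValueError("pose energies must be finite")


def boltzmann_dg(run: DockingRun, th: Thermo = DEFAULT_THERMO) -> float:
    """Boltzmann-weighted mean pose energy, kcal/mol.

    Computed with a max-shift (log-sum-exp pattern): the minimum energy is
    subtracted before exponentiating, so arbitrarily deep wells cannot
    overflow.
    """
    e = run.pose_energies
    shifted = -(e - e.min()) / th.RT
    w = np.exp(shifted)
    return float((e * w).sum() / w.sum())


def dg_to_kd(dg: float, th: Thermo = DEFAULT_THERMO) -> float:
    """Dissociation constant (M) from a binding free energy (kcal/mol)."""
    return math.exp(dg / th.RT)


def kd_to_dg(kd: float, th: Thermo = DEFAULT_THERMO) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant (M)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return th.RT * math.log(kd)


def kd_to_pkd(kd: float) -> float:
    return -math.log10(kd)


def pkd_to_nm(log_m: float) -> float:
    """Affinity in nM from a signed log10(M) value (e.g. −8.51 → 3.09 nM),
    rounded to 2 decimals for display."""
    return round(10.0 ** (log_m + 9.0), 2)


def literal_printed_kd(run: DockingRun, th: Thermo = DEFAULT_THERMO) -> float:
    """Compatibility form that exponentiates the *sum* of all pose energies.

    This literal transcription of the published conversion formula is
    dimensionally inconsistent with a weighted average and is provided only
    for comparison; :func:`boltzmann_dg` + :func:`dg_to_kd` is the default
    pathway.  For typical runs (many negative energies) the value overflows
    to ``inf``, which is itself the diagnostic that the literal form cannot
    be what was computed.
    """
    with np.errstate(over="ignore"):
        return float(np.exp(-run.pose_energies.sum() / th.RT))


@dataclass
class AffinitySummary:
    """Replicate-aggregated affinity for one (ligand, receptor)."""

    per_run_kd: list[float]          # M
    per_run_pkd: list[float]         # -log10 M
    mean_pkd: float
    ci95: tuple[float, float] | None
    n_runs: int


def aggregate_runs(runs: list[DockingRun], th: Thermo = DEFAULT_THERMO,
                   ci: float = 0.95) -> AffinitySummary:
    """Arithmetic mean of per-run Boltzmann pKd with a Student-t CI (n−1 df).

    A single run yields a point estimate with a warning instead of a CI.
    """
    if not runs:
        raise EmptyInputError("no docking runs to aggregate")
    kds = [dg_to_kd(boltzmann_dg(r, th), th) for r in runs]
    pkds = [kd_to_pkd(k) for k in kds]
    mean = float(np.mean(pkds))
    n = len(pkds)
    if n < 2:
        warnings.warn("fewer than 2 runs: returning a point estimate without a CI",
                      stacklevel=2)
        return AffinitySummary(kds, pkds, mean, None, n)
    sem = stats.sem(pkds)
    if sem == 0:
        lo = hi = mean
    else:
        lo, hi = stats.t.interval(ci, n - 1, loc=mean, scale=sem)
    return AffinitySummary(kds, pkds, mean, (float(lo), float(hi)), n)


# ---------------------------------------------------------------------------
# Input formats
# ---------------------------------------------------------------------------

_DLG_ENERGY = re.compile(
    r"Estimated Free Energy of Binding\s*=\s*([-+]?\d+(?:\.\d+)?)")


def parse_dlg(path: str | Path, ligand: str = "", receptor: str = "",
              run_id: int = 0) -> DockingRun:
    """Extract every pose's 'Estimated Free Energy of Binding' (kcal/mol) from
    an AutoDock 4.2 DLG log, in file order."""
    text = Path(path).read_text()
    energies = [float(m.group(1)) for m in _DLG_ENERGY.finditer(text)]
    if not energies:
        raise FormatError(f"{path}: no 'Estimated Free Energy of Binding' entries found")
    return DockingRun(ligand, receptor, np.array(energies), run_id)


def parse_energy_table(path: str | Path, ligand: str = "", receptor: str = "",
                       run_id: int = 0) -> DockingRun:
    """One pose energy per line (plain TSV/whitespace); '#' lines are comments."""
    energies = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            energies.append(float(line.split()[0]))
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: not a number: {line!r}") from exc
    if not energies:
        raise FormatError(f"{path}: no energies found")
    return DockingRun(ligand, receptor, np.array(energies), run_id)


def read_docking_run(path: str | Path, **kw) -> DockingRun:
    """Dispatch on content: DLG logs by their energy banner, otherwise a plain
    energy table."""
    text = Path(path).read_text()
    if _DLG_ENERGY.search(text):
        return parse_dlg(path, **kw)
    return parse_energy_table(path, **kw)
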