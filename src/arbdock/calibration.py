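"""Docking-grid calibration by interpolated affinity response surfaces.

AutoDock's predicted affinity depends non-linearly on two search-space
parameters: the grid-point spacing (GPS, Å) and the Z-coordinate of the grid
box center.  Calibration docks a ligand on a small rectangular design —
seven GPS values crossed with seven Z-centers — fits the resulting pKd
matrix with interpolating surfaces (nearest, linear, cubic, bivariate
spline), and picks the (GPS, Z) point whose predicted affinity best matches
the experimentally known median affinity for that ligand.

The X/Y box centers are fixed passthrough metadata; only GPS and Z-center
are calibrated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator

from .errors import CompletenessError, DomainError, ParameterError

#: Default 7-value GPS axis (Å).  The published design names eight spacings
#: but a seven-by-seven matrix; the seven-value axis below (dropping 0.250)
#: is the package default and the full eight-value axis is kept alongside.
DEFAULT_GPS_VALUES: tuple[float, ...] = (0.150, 0.225, 0.275, 0.300, 0.325, 0.350, 0.375)
FULL_GPS_VALUES: tuple[float, ...] = (0.150, 0.225, 0.250, 0.275, 0.300, 0.325, 0.350, 0.375)
#: Default Z-center axis: three 0.5 Å steps either side of 35.5.
DEFAULT_Z_VALUES: tuple[float, ...] = (34.0, 34.5, 35.0, 35.5, 36.0, 36.5, 37.0)

METHODS = ("nearest", "linear", "cubic", "bivariate-spline")


@dataclass(frozen=True)
class CalibrationPoint:
    """One docking batch result: pKd at a (GPS, Z-center) design point."""

    gps: float
    z_center: float
    pkd: float

    def __post_init__(self) -> None:
        if self.gps <= 0:
            raise ParameterError("gps must be positive")
        if not np.isfinite(self.pkd):
            raise ParameterError("pkd must be finite")


@dataclass
class CalibrationMatrix:
    """Complete rectangular pKd grid over sorted (GPS, Z-center) axes."""

    gps_values: np.ndarray
    z_values: np.ndarray
    grid: np.ndarray              # shape (n_gps, n_z)
    ligand: str = ""

    def cell(self, gps: float, z: float) -> float:
        i = int(np.argmin(np.abs(self.gps_values - gps)))
        j = int(np.argmin(np.abs(self.z_values - z)))
        return float(self.grid[i, j])


def build_matrix(points: list[CalibrationPoint], ligand: str = "") -> CalibrationMatrix:
    """Assemble design points into a complete rectangular matrix.

    Axes are sorted ascending; duplicate or missing cells raise a
    :class:`CompletenessError` naming the offending (gps, z) cells.
    """
    if not points:
        raise CompletenessError("no calibration points")
    gps_values = np.array(sorted({p.gps for p in points}))
    z_values = np.array(sorted({p.z_center for p in points}))
    grid = np.full((len(gps_values), len(z_values)), np.nan)
    for p in points:
        i = int(np.searchsorted(gps_values, p.gps))
        j = int(np.searchsorted(z_values, p.z_center))
        if not np.isnan(grid[i, j]):
            raise CompletenessError(f"duplicate cell (gps={p.gps}, z={p.z_center})")
        grid[i, j] = p.pkd
    if np.isnan(grid).any():
        missing = [(float(gps_values[i]), float(z_values[j]))
                   for i, j in zip(*np.nonzero(np.isnan(grid)))]
        raise CompletenessError(f"missing cells: {missing}")
    return CalibrationMatrix(gps_values, z_values, grid, ligand)


def read_matrix_tsv(path: str | Path, ligand: str | None = None) -> CalibrationMatrix:
    """Matrix from a TSV with columns ligand, gps, z_center, pkd."""
    df = pd.read_csv(path, sep="\t")
    if ligand is not None:
        df = df[df["ligand"] == ligand]
    pts = [CalibrationPoint(r.gps, r.z_center, r.pkd) for r in df.itertuples()]
    return build_matrix(pts, ligand or "")


class CalibrationSurface:
    """A continuous pkd(gps, z) surface over the matrix bounding rectangle."""

    def __init__(self, m: CalibrationMatrix, method: str, smoothing: float = 0.0):
        if method not in METHODS:
            raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
        if method in ("cubic", "bivariate-spline") and (
                len(m.gps_values) < 4 or len(m.z_values) < 4):
            raise ParameterError(f"{method} fitting needs >= 4 points per axis")
        self.method = method
        self.matrix = m
        self.bounds = ((float(m.gps_values[0]), float(m.gps_values[-1])),
                       (float(m.z_values[0]), float(m.z_values[-1])))
        if method == "bivariate-spline":
            self._spline = RectBivariateSpline(m.gps_values, m.z_values, m.grid,
                                               kx=3, ky=3, s=smoothing)
            self._interp = None
        elif method == "cubic":
            # interpolating bicubic spline (s=0): node-exact, unlike smoothed fits
            self._spline = RectBivariateSpline(m.gps_values, m.z_values, m.grid,
                                               kx=3, ky=3, s=0.0)
            self._interp = None
        else:
            self._interp = RegularGridInterpolator(
                (m.gps_values, m.z_values), m.grid, method=method,
                bounds_error=True)
            self._spline = None
        node_pred = self(np.repeat(m.gps_values, len(m.z_values)),
                         np.tile(m.z_values, len(m.gps_values)))
        self.max_node_residual = float(np.abs(node_pred - m.grid.ravel()).max())

    def __call__(self, gps, z) -> np.ndarray:
        gps = np.asarray(gps, dtype=float)
        z = np.asarray(z, dtype=float)
        (g0, g1), (z0, z1) = self.bounds
        if np.any(gps < g0) or np.any(gps > g1) or np.any(z < z0) or np.any(z > z1):
            raise DomainError(f"evaluation outside grid rectangle {self.bounds}")
        if self._spline is not None:
            return self._spline.ev(gps, z)
        return self._interp(np.column_stack([np.ravel(gps), np.ravel(z)])).reshape(gps.shape)


def fit_surface(m: CalibrationMatrix, method: str = "cubic",
                smoothing: float = 0.0) -> CalibrationSurface:
    """Fit one interpolation surface; nearest/linear/cubic interpolate the
    nodes exactly, the spline may smooth (its max node residual is recorded)."""
    return CalibrationSurface(m, method, smoothing)


@dataclass
class CalibrationResult:
    """The (GPS, Z-center) point whose surface affinity best matches the target."""

    method: str
    chosen_gps: float
    chosen_z: float
    predicted_pkd: float
    target_pkd: float
    residual: float
    max_affinity_gps: float
    max_affinity_z: float
    max_affinity_pkd: float


def _sweep_axes(m: CalibrationMatrix, fine_step: tuple[float, float]
                ) -> tuple[np.ndarray, np.ndarray]:
    (g0, g1), (z0, z1) = ((m.gps_values[0], m.gps_values[-1]),
                          (m.z_values[0], m.z_values[-1]))
    fg, fz = fine_step
    gs = np.round(np.arange(g0, g1 + fg / 2, fg), 10)
    zs = np.round(np.arange(z0, z1 + fz / 2, fz), 10)
    gs[-1] = min(gs[-1], g1)
    zs[-1] = min(zs[-1], z1)
    return gs, zs


def select_parameters(m: CalibrationMatrix, target_pkd: float,
                      methods: tuple[str, ...] = METHODS,
                      fine_step: tuple[float, float] = (0.001, 0.01),
                      ) -> dict[str, CalibrationResult]:
    """Dense-sweep each surface for the point nearest the target affinity.

    Every requested surface is evaluated on a rectangular sweep with the given
    per-axis resolution (defaults match the precision the grid parameters are
    reported at: 3 decimals in GPS, 2 in Z).  Ties break toward smaller
    residual, then smaller GPS, then smaller Z.  Each result also carries the
    argmax-affinity point of its surface.  The dict includes a ``"best"``
    entry aliasing the method with the smallest residual, and a
    ``"matrix-node"`` entry for the best raw design node, mirroring the
    node-bypass route (a node that already hits the target needs no fit).
    """
    if not np.isfinite(target_pkd):
        raise ParameterError("target_pkd must be finite")
    if fine_step[0] <= 0 or fine_step[1] <= 0:
        raise ParameterError("fine_step must be positive")
    gs, zs = _sweep_axes(m, fine_step)
    gg, zz = np.meshgrid(gs, zs, indexing="ij")
    gflat, zflat = gg.ravel(), zz.ravel()
    out: dict[str, CalibrationResult] = {}
    for method in methods:
        surf = fit_surface(m, method)
        vals = np.asarray(surf(gflat, zflat), dtype=float).ravel()
        res = np.abs(vals - target_pkd)
        order = np.lexsort((zflat, gflat, res))
        k = order[0]
        kmax = int(np.argmax(vals))
        out[method] = CalibrationResult(
            method, float(gflat[k]), float(zflat[k]), float(vals[k]),
            float(target_pkd), float(res[k]),
            float(gflat[kmax]), float(zflat[kmax]), float(vals[kmax]))
    # raw design nodes (node-bypass route)
    ng, nz = np.meshgrid(m.gps_values, m.z_values, indexing="ij")
    nvals = m.grid.ravel()
    nres = np.abs(nvals - target_pkd)
    order = np.lexsort((nz.ravel(), ng.ravel(), nres))
    k = order[0]
    kmax = int(np.argmax(nvals))
    out["matrix-node"] = CalibrationResult(
        "matrix-node", float(ng.ravel()[k]), float(nz.ravel()[k]),
        float(nvals[k]), float(target_pkd), float(nres[k]),
        float(ng.ravel()[kmax]), float(nz.ravel()[kmax]), float(nvals[kmax]))
    best = min((r for k, r in out.items() if k in methods), key=lambda r: r.residual)
    out["best"] = best
    return out


@dataclass
class GpfParameters:
    """A docking-grid parameter record (one row of the optimal-parameter table)."""

    ligand: str
    gps: float
    x_center: float
    y_center: float
    z_center: float
    n_points: tuple[int, int, int]

    def to_stanza(self) -> str:
        """AutoDock GPF-style text stanza."""
        nx, ny, nz = self.n_points
        return (f"# {self.ligand}\n"
                f"npts {nx} {ny} {nz}\n"
                f"spacing {self.gps:.3f}\n"
                f"gridcenter {self.x_center:g} {self.y_center:g} {self.z_center:.2f}\n")

    @classmethod
    def from_stanza(cls, text: str) -> "GpfParameters":
        ligand = ""
        m = re.search(r"^#\s*(.+)$", text, re.M)
        if m:
            ligand = m.group(1).strip()
        npts = re.search(r"^npts\s+(\d+)\s+(\d+)\s+(\d+)", text, re.M)
        spacing = re.search(r"^spacing\s+([\d.]+)", text, re.M)
        center = re.search(r"^gridcenter\s+([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)", text, re.M)
        if not (npts and spacing and center):
            raise ParameterError("not a grid-parameter stanza")
        return cls(ligand, float(spacing.group(1)), float(center.group(1)),
                   float(center.group(2)), float(center.group(3)),
                   tuple(int(g) for g in npts.groups()))


def write_gpf_parameters(r: CalibrationResult, ligand: str,
                         box: tuple[float, float, tuple[int, int, int]]
                         ) -> GpfParameters:
    """Emit the parameter record for a calibration result.

    ``box`` carries the fixed X/Y centers and per-axis point counts, which are
    passthrough metadata never touched by the calibration itself.
    """
    x_center, y_center, n_points = box
    if any(n <= 0 for n in n_points):
        raise ParameterError("point counts must be positive")
    return GpfParameters(ligand, r.chosen_gps, x_center, y_center, r.chosen_z,
                         tuple(n_points))
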