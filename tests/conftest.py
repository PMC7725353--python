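import numpy as np
import pytest

from arbdock.pocket_geometry import PocketDefinition, SphereProbe
from arbdock.structure_io import AtomRecord, Structure
from arbdock.synthetic_data import gen_bundle_structure


def make_atoms(positions, masses=None, names=None, residue_ids=None,
               residue_name="PRB", chain="A"):
    """Hand-built atoms for geometric phantoms; one residue per atom."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    masses = masses if masses is not None else [12.0] * n
    names = names if names is not None else ["PRB"] * n
    residue_ids = residue_ids if residue_ids is not None else list(range(1, n + 1))
    return [AtomRecord(i + 1, names[i], residue_name, residue_ids[i], chain,
                       positions[i], "C", masses[i]) for i in range(n)]


def probe_phantom(probe_positions, anchor_radius=11.0, satellite_radius=5.0,
                  bfs_radius=8.0, spacing=0.25):
    """A structure of bare probe atoms plus its matching pocket definition."""
    s = Structure(make_atoms(probe_positions), label="phantom")
    pocket = PocketDefinition(
        anchor=SphereProbe(1, "PRB", anchor_radius),
        satellites=tuple(SphereProbe(i + 2, "PRB", satellite_radius)
                         for i in range(len(probe_positions) - 1)),
        bfs_radius=bfs_radius,
        lattice_spacing=spacing,
    )
    return s, pocket


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic helical bundle with its ground truth (shared, read-only)."""
    return gen_bundle_structure(seed=11, mc_samples=300_000)
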