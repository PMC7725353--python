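"""Published reference data for the human AT1R / ARB system.

These tables are the fixed experimental and structural anchors of the
pipeline: consensus GPCR activation distances, solvent occupancy of the apo
receptor's binding pocket across the three MD replicas, the experimentally
derived median ARB affinities with the docking-grid parameters calibrated
against them, and the A163T radioligand fold-change comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

# --- Consensus activation-state residue pairs -------------------------------
# Ballesteros-Weinstein pair label -> (inactive mean, inactive SD,
#                                      active mean, active SD), Å, center of
# mass distances across matched inactive/active GPCR crystal structures.
STATE_PAIR_REFERENCES: dict[str, tuple[float, float, float, float]] = {
    "3.46 to 6.37": (6.2, 0.5, 11.6, 1.5),
    "1.53 to 7.53": (6.8, 0.6, 11.1, 0.5),
    "5.55 to 6.41": (10.6, 2.0, 7.4, 1.5),
    "3.46 to 7.53": (11.9, 0.9, 7.0, 0.6),
}

# AT1R residue ids for the Ballesteros-Weinstein positions the study names.
# 3.46 and 6.37 are not printed and must be supplied by the user.
BW_TO_AT1R_RESIDUE: dict[str, int] = {
    "1.53": 49,    # V49
    "7.53": 302,   # Y302
    "5.55": 213,   # T213
    "6.41": 246,   # V246
}

# AT1R model distances over the last 20 ns (mean, SD), Å — replica average.
AT1R_MODEL_STATE_DISTANCES: dict[str, tuple[float, float]] = {
    "3.46 to 6.37": (6.0, 0.2),
    "1.53 to 7.53": (5.5, 0.3),
    "5.55 to 6.41": (13.3, 0.4),
    "3.46 to 7.53": (12.5, 0.2),
}

# --- Seven-transmembrane helix ranges (residue ids) -------------------------
TM_HELIX_RANGES: dict[str, tuple[int, int]] = {
    "helix 1": (25, 57),    # N25-M57
    "helix 2": (62, 89),    # V62-A89
    "helix 3": (98, 103),   # N98-I103
    "helix 4": (138, 166),  # L138-H166
    "helix 5": (190, 223),  # T190-K223
    "helix 6": (236, 268),  # D236-L268
    "helix 7": (274, 305),  # C274-L305
}
HELIX8_RANGE: tuple[int, int] = (306, 316)  # G306-L316

# --- Solvent in and around the apo receptor (per MD replica) ----------------
# replica -> (unique pocket waters, water frame-occurrences, % frames,
#             unique Na+ within 25 Å of R167, mean distance Å, SD Å)
SOLVENT_OCCUPANCY_REPLICAS: dict[int, tuple[int, int, float, int, float, float]] = {
    1: (36, 4008, 26.7, 2, 21.3, 3.3),
    2: (30, 2513, 16.8, 3, 20.0, 3.6),
    3: (32, 4790, 31.9, 3, 20.8, 3.3),
}

# Pocket volumes (Å³) of the crystal structures and the apo model.
POCKET_VOLUME_4ZUD = 1505.0
POCKET_VOLUME_4YAY = 1417.0
POCKET_VOLUME_APO_MODEL = 961.0


# --- Median ARB affinities and calibrated docking parameters ----------------
@dataclass(frozen=True)
class ArbParameters:
    """Median experimental affinity and the docking-grid parameters calibrated
    to reproduce it for one ARB."""

    median_log_m: float      # median affinity as signed log10(M), e.g. -8.51
    median_nm: float         # the same affinity in nM as printed
    gps: float               # grid-point spacing, Å
    x_center: float
    y_center: float
    z_center: float
    n_points: tuple[int, int, int]


ARB_PARAMETERS: dict[str, ArbParameters] = {
    "Azilsartan":         ArbParameters(-8.51, 3.09, 0.168, 38, 61, 36.74, (126, 126, 70)),
    "Candesartan":        ArbParameters(-8.46, 3.47, 0.342, 38, 61, 34.38, (50, 50, 30)),
    "Eprosartan":         ArbParameters(-8.26, 5.50, 0.161, 38, 61, 36.94, (126, 126, 70)),
    "Irbesartan":         ArbParameters(-8.72, 1.91, 0.168, 38, 61, 36.84, (126, 126, 70)),
    "Losartan (EXP3174)": ArbParameters(-7.71, 19.50, 0.150, 38, 61, 37.00, (126, 126, 70)),
    "Olmesartan":         ArbParameters(-8.17, 6.76, 0.357, 38, 61, 35.55, (55, 55, 30)),
    "Telmisartan":        ArbParameters(-8.17, 6.76, 0.275, 38, 61, 36.50, (70, 70, 40)),
    "Valsartan":          ArbParameters(-8.30, 5.01, 0.318, 38, 61, 35.33, (50, 50, 30)),
}

ARB_NAMES: tuple[str, ...] = tuple(ARB_PARAMETERS)

# Experimental 95% CI for olmesartan affinity, -log10(M).
OLMESARTAN_EXPERIMENTAL_CI = (7.985, 8.595)


# --- A163T variant: experimental vs docking Kd ratios (variant / wild type) --
# ARB -> (experimental ratio, SD, docking ratio, SD, printed concordance)
A163T_RATIO_COMPARISON: dict[str, tuple[float, float, float, float, bool]] = {
    "Candesartan": (0.94, 0.09, 21.24, 16.52, False),
    "Irbesartan":  (1.84, 0.22, 2.52, 0.14, True),
    "EXP3174":     (7.81, 1.12, 3.43, 0.69, False),
    "Telmisartan": (0.70, 0.14, 0.50, 0.15, True),
    "Valsartan":   (1.10, 0.22, 3.25, 1.21, True),
}
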