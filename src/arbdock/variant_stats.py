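"""Variant-vs-wild-type affinity statistics and the 2-fold resistance flag.

Replicate Boltzmann-weighted pKd values per (receptor variant, ligand) are
compared against the wild-type replicates for the same ligand: fold change
in Kd, an omnibus test across all groups, rank-based pairwise z-tests of
each variant against wild type (Dunn-type, Bonferroni adjusted), and the
flagging rule — a variant/ligand cell is called resistant when its Kd rises
at least ``fold_cutoff``-fold *and* the adjusted test is significant.

The concordance check compares predicted Kd ratios to experimentally
measured ones, ratio by ratio, with error propagated from the replicate SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, ParameterError


@dataclass
class VariantPanel:
    """Replicate pKd values per (variant, ligand), plus the wild-type reference."""

    variants: list[str]
    ligands: list[str]
    replicate_pkd: dict[tuple[str, str], np.ndarray]
    wildtype_pkd: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.replicate_pkd = {k: np.asarray(v, dtype=float)
                              for k, v in self.replicate_pkd.items()}
        self.wildtype_pkd = {k: np.asarray(v, dtype=float)
                             for k, v in self.wildtype_pkd.items()}
        for lig in self.ligands:
            if lig not in self.wildtype_pkd:
                raise ParameterError(f"wild-type replicates missing for ligand {lig!r}")
        for key, v in self.replicate_pkd.items():
            if v.size < 2:
                raise ParameterError(f"{key}: need >= 2 replicates for testing")

    @classmethod
    def from_long_table(cls, df: pd.DataFrame, wildtype_label: str = "WT"
                        ) -> "VariantPanel":
        """Panel from a long-format table with columns variant, ligand, pkd."""
        ligands = sorted(df["ligand"].unique())
        variants = sorted(v for v in df["variant"].unique() if v != wildtype_label)
        reps = {(v, l): g["pkd"].to_numpy()
                for (v, l), g in df[df["variant"] != wildtype_label].groupby(
                    ["variant", "ligand"])}
        wt = {l: g["pkd"].to_numpy()
              for l, g in df[df["variant"] == wildtype_label].groupby("ligand")}
        return cls(variants, ligands, reps, wt)


def fold_change(variant_reps: Sequence[float], wt_reps: Sequence[float]) -> float:
    """Kd ratio variant/wild-type from mean pKd difference (geometric mean Kd).

    A ratio above 1 means the variant binds the ligand more weakly.
    """
    v = np.asarray(variant_reps, dtype=float)
    w = np.asarray(wt_reps, dtype=float)
    if v.size == 0 or w.size == 0:
        raise EmptyInputError("fold_change needs non-empty replicate lists")
    return float(10.0 ** (w.mean() - v.mean()))


@dataclass
class SignificanceResult:
    """Rank-based variant-vs-WT comparisons for one ligand."""

    ligand: str
    anova_f: float
    anova_p: float
    kruskal_h: float
    kruskal_p: float
    z: dict[str, float]
    p_raw: dict[str, float]
    p_adj: dict[str, float]


def _dunn_vs_control(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Dunn-type rank z statistics of groups[1:] against groups[0].

    Pooled mid-ranks with the tie correction; z_i compares mean ranks of group
    i and the control using SE = sqrt((N(N+1)/12 − T/(12(N−1)))·(1/n_i+1/n_0)),
    T = Σ(t³−t) over tied values.  Returns (z, two-sided p).
    """
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(((counts ** 3) - counts).sum())
    if n_tot > 1:
        var_term = n_tot * (n_tot + 1) / 12.0 - ties / (12.0 * (n_tot - 1))
    else:
        var_term = 0.0
    zs, ps = [], []
    for i in range(1, len(groups)):
        se2 = var_term * (1.0 / sizes[i] + 1.0 / sizes[0])
        if se2 <= 0:
            zs.append(0.0)
            ps.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[0]) / np.sqrt(se2)
        zs.append(float(z))
        ps.append(float(2.0 * stats.norm.sf(abs(z))))
    return np.array(zs), np.array(ps)


def significance_test(panel: VariantPanel, ligand: str) -> SignificanceResult:
    """Omnibus ANOVA/Kruskal-Wallis across {WT ∪ variants} plus Dunn-type
    variant-vs-WT z-tests, Bonferroni-adjusted over the variant contrasts.

    All-tied observations degenerate gracefully: a warning and p = 1.
    """
    groups = [panel.wildtype_pkd[ligand]] + [
        panel.replicate_pkd[(v, ligand)] for v in panel.variants
        if (v, ligand) in panel.replicate_pkd]
    names = [v for v in panel.variants if (v, ligand) in panel.replicate_pkd]
    if len(groups) < 2:
        raise ParameterError(f"no variant replicates for ligand {ligand!r}")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn(f"{ligand}: all observations tied; degenerate variance",
                      stacklevel=2)
        ones = {v: 1.0 for v in names}
        zeros = {v: 0.0 for v in names}
        return SignificanceResult(ligand, 0.0, 1.0, 0.0, 1.0, zeros, ones, dict(ones))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant within-group input warnings
        f_stat, f_p = stats.f_oneway(*groups)
        try:
            h_stat, h_p = stats.kruskal(*groups)
        except ValueError:
            h_stat, h_p = 0.0, 1.0
    zs, ps = _dunn_vs_control(groups)
    k = len(names)
    p_adj = np.minimum(ps * k, 1.0)
    return SignificanceResult(
        ligand, float(f_stat), float(f_p), float(h_stat), float(h_p),
        dict(zip(names, zs)), dict(zip(names, ps)), dict(zip(names, p_adj)))


@dataclass
class VariantCall:
    variant: str
    ligand: str
    fold_change: float          # Kd_variant / Kd_wt
    z: float
    p_adj: float
    flagged: bool               # reduced affinity: fold >= cutoff AND significant
    flagged_increase: bool      # increased affinity: fold <= 1/cutoff AND significant


def flag_variants(panel: VariantPanel, alpha: float = 0.05,
                  fold_cutoff: float = 2.0,
                  gate_on_omnibus: bool = False
                  ) -> tuple[list[VariantCall], pd.DataFrame]:
    """Apply the resistance rule to every (variant, ligand) cell.

    Returns the per-cell calls and a variants × ligands heatmap matrix holding
    the fold change where flagged (reduced affinity) and NaN elsewhere.
    ``gate_on_omnibus`` additionally requires the omnibus ANOVA to reject
    before any pairwise flag is raised.
    """
    calls: list[VariantCall] = []
    heat = pd.DataFrame(np.nan, index=panel.variants, columns=panel.ligands)
    for lig in panel.ligands:
        sig = significance_test(panel, lig)
        omnibus_ok = (sig.anova_p < alpha) if gate_on_omnibus else True
        for v in panel.variants:
            if (v, lig) not in panel.replicate_pkd:
                continue
            fc = fold_change(panel.replicate_pkd[(v, lig)], panel.wildtype_pkd[lig])
            significant = omnibus_ok and sig.p_adj[v] < alpha
            flag_dec = fc >= fold_cutoff and significant
            flag_inc = fc <= 1.0 / fold_cutoff and significant
            calls.append(VariantCall(v, lig, fc, sig.z[v], sig.p_adj[v],
                                     flag_dec, flag_inc))
            if flag_dec:
                heat.loc[v, lig] = fc
    return calls, heat


@dataclass
class RatioWithError:
    """A ratio of two measured means with its propagated SD."""

    ratio: float
    sd: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ParameterError("ratio must be positive")
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")


def ratio_with_error(a: tuple[float, float], b: tuple[float, float]) -> RatioWithError:
    """r = a/b with SD propagated in quadrature from the relative errors:
    sd = |r|·sqrt((σa/a)² + (σb/b)²)."""
    (ma, sa), (mb, sb) = a, b
    if mb == 0:
        raise ZeroDivisionError("denominator mean is zero")
    r = ma / mb
    sd = abs(r) * np.sqrt((sa / ma) ** 2 + (sb / mb) ** 2)
    return RatioWithError(float(r), float(sd))


@dataclass
class ConcordanceRow:
    ligand: str
    direction_match: bool
    within_tol: bool      # ratio-of-ratios <= fold_tol, means only
    within_error: bool    # mean ± k·SD intervals overlap
    verdict: bool         # direction AND (within_tol OR within_error)


def concordance_check(predicted: Mapping[str, RatioWithError],
                      experimental: Mapping[str, RatioWithError],
                      fold_tol: float = 2.0,
                      error_k: float = 2.0) -> dict[str, ConcordanceRow]:
    """Per-ligand agreement of predicted vs experimental fold-change ratios.

    ``direction_match`` — both ratios on the same side of 1 (a ratio exactly
    at 1 matches either side).  ``within_tol`` — the two ratios differ by at
    most ``fold_tol``-fold.  ``within_error`` — the mean ± ``error_k``·SD
    intervals overlap.  The composite verdict (direction agreement and either
    closeness criterion) is this package's operational reading of a
    "within 2-fold of the error" call; the individual criteria are all
    reported so any stricter rule can be applied downstream.
    """
    missing = set(predicted) ^ set(experimental)
    if missing:
        raise KeyError(f"unmatched ligands: {sorted(missing)}")
    out: dict[str, ConcordanceRow] = {}
    for lig in predicted:
        p, e = predicted[lig], experimental[lig]
        direction = (p.ratio - 1.0) * (e.ratio - 1.0) >= 0
        ratio_of_ratios = max(p.ratio / e.ratio, e.ratio / p.ratio)
        within_tol = ratio_of_ratios <= fold_tol
        lo_p, hi_p = p.ratio - error_k * p.sd, p.ratio + error_k * p.sd
        lo_e, hi_e = e.ratio - error_k * e.sd, e.ratio + error_k * e.sd
        within_err = (lo_p <= hi_e) and (lo_e <= hi_p)
        out[lig] = ConcordanceRow(lig, bool(direction), bool(within_tol),
                                  bool(within_err),
                                  bool(direction and (within_tol or within_err)))
    return out
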