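# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the arbdock pipeline, in the order data flows through it.

## Structures, trajectories and geometric primitives

Structures are ordered atom records (coordinates in Å, element, mass in Da,
residue id/name, chain); a trajectory is a list of structures sharing one
topology, stored internally as an `(n_frames, n_atoms, 3)` array.  PDB
parsing and writing go through gemmi; one frame per `MODEL` block, elements
inferred from atom names when the element column is blank, masses from the
standard element table.  Round-tripping through the fixed-column format
preserves topology exactly and coordinates to the format's 10⁻³ Å.

Centers of mass are mass-weighted by default (the trajectory tools this
pipeline mirrors weight by mass); a `geometric` flag yields the plain
centroid.  Hydrogens participate whenever present; selections may restrict
to named atoms or to the N/CA/C/O backbone.  Multi-chain structures default
to chain A unless a chain is named.

RMSD uses closed-form least-squares superposition (Kabsch, via scipy's
`Rotation.align_vectors`) when `superpose=True`.  The default is
superposition **on** for whole-helix-bundle RMSD and **off** when a mobile
segment (e.g. the C-terminal helix 8 of a GPCR) is measured against a fixed
reference model in the laboratory frame — whether the original analyses
fitted before measuring is not documented, so both paths are explicit
options rather than assumptions.

Per-residue RMSF is the RMS displacement of the residue's selected-atom
centroid from its time-average position.  For isotropic per-axis jitter of
SD σ on a single selected atom, E[RMSF] = σ√3 (law of total variance);
that identity is what the synthetic-trajectory recovery tests assert.
Summary SDs over frame windows are population SDs (divide by n).

## Pocket volume and solvent occupancy

The binding pocket is defined by probe atoms lining it.  For the AT1R model
the probes are R167:NH2 (anchor, 11 Å) and T88:HG1@4, Y92:HE1@5, S109:OG@5,
K199:HZ2@5, H256:HE1@5, V264:CG2@5, M284:CE@7, Y292:HH@7 (satellites).

**Volume.**  The probe centroid defines a *centroid sphere* whose radius is
the distance to the nearest probe atom (the minimal sphere that reaches the
pocket wall).  A uniform search radius — 8 Å by default — is applied around
every probe atom.  A point belongs to the pocket iff it lies inside the
centroid sphere and inside at least one probe sphere; a 6-connected
breadth-first search over a cubic lattice, seeded at the lattice point
nearest the centroid, counts member points, and volume = count × spacing³.
Only the seed's connected component is counted, which is the algorithm's
safeguard against disconnected satellite cavities; an exhaustive
bounding-box enumeration is provided as the independent cross-check (equal
on connected pockets, an upper bound otherwise).  The lattice spacing is
not recoverable from the original description; the default is 0.5 Å
(0.25 Å for analytic phantoms), always reported alongside the volume, and
the sphere-phantom convergence test bounds the 0.5 → 0.25 Å drift at 5%.
The centroid-sphere bound replaces the lateral constraint a lipid membrane
provides in the original workflow, so no membrane atoms are needed.  A seed
falling outside every probe sphere is a degenerate pocket: volume 0 with a
warning rather than an exception, so per-frame scans continue.

**Solvent occupancy.**  A solvent atom (e.g. TIP3:OH2, or SOD for sodium)
is inside the pocket in a frame iff it is within the anchor radius of the
anchor atom *and* within the satellite's own radius of at least one
satellite (the dual-sphere rule).  Because one frame can hold several
waters, the occupancy percentage is ambiguous; both conventions are
reported and labelled: occurrences ÷ frames (one frame may contribute more
than 1) and frames-with-≥1 ÷ frames.  The nearest-ion summary records, per
frame, the minimum anchor-to-ion distance among ions within a cutoff
(frames with none are no-observations), plus mean ± SD over observed frames
and the count of unique ions ever seen.  The sodium-pocket proximity check
treats all atoms of the gating residue as equivalent, since no specific
atom is documented.

## Activation-state classification and DEER comparison

Four consensus residue pairs separate inactive from active class-A GPCR
ensembles; each carries reference mean ± SD distances for both states.  An
observed mean votes for the state with the smaller |obs − μ|/σ, with an SD
floor of 0.1 Å so printed zero-SD references cannot dominate; the overall
call is the state winning strictly more than half the votes, otherwise
*indeterminate*.  The z-vote formalises what is originally a qualitative
table comparison; thresholds are configurable and the scale-consistency of
votes under common offsets is asserted in tests.  Ballesteros–Weinstein
positions are mapped to residue ids by user config; the AT1R ids named in
the source material (1.53=V49, 7.53=Y302, 5.55=T213, 6.41=V246) are
pre-filled, the others must be supplied.

The DEER comparison reports raw per-frame center-of-mass distances per
probed pair (violin-plot ready) and the fraction of spectroscopic major
modes falling inside the closed [min, max] of the sampled distances.  The
closed-interval rule is this package's quantitative stand-in for what is a
visual criterion in the source; it is monotone in the frame window.  No
spin-label rotamer modelling is attempted — the COM distance is the proxy
here as in the original analysis.

## Boltzmann-weighted affinity

The published conversion formula as printed sums all pose energies inside
one exponential, which is dimensionally inconsistent with a "Boltzmann
weighted average"; this package implements the weighted mean energy the
surrounding text describes, and keeps the literal printed form available as
an explicitly non-default compatibility function (it overflows to infinity
on realistic runs, which is itself evidence it is a typographical artifact).
All poses of a run enter the weighting (whether the original used clustered
representatives is unstated).  The weighted mean is computed min-shifted
(log-sum-exp pattern) and is: never above the arithmetic mean; invariant
under pose reordering and duplication; monotone in the *lowest* pose energy.
It is **not** monotone in high-lying poses — deepening a pose that sits
more than RT above the weighted mean re-weights the sum upward — which is
why the monotonicity property is asserted only for the dominant well.

Replicates aggregate as the arithmetic mean of per-run pKd with a Student-t
95% CI on n−1 df; the t-interval is this package's choice, as the original
reports a CI over n = 6 without naming the estimator.  A single run
degrades to a point estimate with a warning.

## Grid-parameter calibration

The calibration design crosses grid-point spacings with Z-centers
(34.0–37.0 Å in 0.5 Å steps around 35.5).  The source lists eight spacings
yet calls the design seven-by-seven; the default axis here uses the seven
values {0.150, 0.225, 0.275, 0.300, 0.325, 0.350, 0.375} (dropping 0.250),
with the full eight-value axis available — an internal inconsistency of the
source, resolved in favour of the stated design size.  X/Y box centers are
passthrough metadata, never optimised.

Surfaces: nearest and linear via `RegularGridInterpolator`; cubic via an
interpolating bicubic spline (`RectBivariateSpline`, s = 0), chosen over
scipy's grid-cubic method because node-exact interpolation is part of the
contract; "bivariate-spline" is the same spline family with a configurable
smoothing factor (default 0, so its node residual is reported and ~0).
Evaluation outside the design rectangle is a domain error — no
extrapolation.

Parameter selection sweeps each surface on a dense rectangular grid
(defaults 0.001 Å in spacing, 0.01 Å in Z — the precision the calibrated
parameters are reported at), returns the point minimising |surface −
target|, breaking ties toward smaller residual, then smaller spacing, then
smaller Z, and also reports each surface's affinity maximum.  A
"matrix-node" result gives the best raw design cell, mirroring the
node-bypass route: if a design node already produces the target affinity,
no fit is needed.

## Variant statistics and the resistance flag

Fold change is Kd_variant/Kd_WT = 10^(mean pKd_WT − mean pKd_variant) — a
geometric-mean Kd ratio, consistent with how Boltzmann affinities are
averaged; ratios above 1 mean weakened binding.  The omnibus one-way ANOVA
(and Kruskal–Wallis H) across {WT ∪ variants} is computed and reported but
does not gate the pairwise tests by default (gating is a config option).
The pairwise "Kruskal–Wallis multiple-comparison z-value test" is
implemented as Dunn's rank-based z statistic restricted to variant-vs-WT
contrasts, with the tie-corrected variance and Bonferroni adjustment over
the number of contrasts; for a single contrast, z² equals the tie-corrected
Kruskal–Wallis H, which the tests assert against scipy.  α defaults to
0.05 (not stated in the source).  A cell is flagged as resistant iff fold ≥
2 *and* adjusted p < α; affinity *increases* (fold ≤ ½ and significant)
are flagged separately.  All-tied inputs degrade to p = 1 with a warning.

Ratio concordance: each ratio carries an SD propagated in quadrature,
sd = |r|·√((σa/a)² + (σb/b)²).  Agreement between a predicted and an
experimental ratio is reported as three labelled criteria — direction
(same side of 1), plain ≤2-fold ratio-of-ratios, and overlap of the
mean ± 2·SD intervals — plus a composite verdict (direction AND either
closeness criterion).  The composite is this package's operational reading
of a "within 2-fold of the error" call: the plain 2-fold rule alone cannot
reproduce the published A163T agreement column (one ligand agrees only once
replicate error is taken into account), while the composite reproduces all
five published rows, which the acceptance suite asserts.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (seed, parameters) — reruns are
bit-identical — and ships a ground-truth dict.

* **Bundle structures**: ideal poly-alanine α-helices (1.5 Å rise, 100°
  twist, 2.3 Å Cα radius) on a ring (default 7 helices, radius 12 Å,
  antiparallel), plus probe pseudo-atoms (residues 900+, atom `PRB`)
  defining a cavity.  The Monte-Carlo reference volume uses rejection
  sampling in the centroid-sphere bounding box (10⁶ samples by default,
  SE < 0.5% at pocket scale) — a continuous-space oracle independent of the
  lattice flood fill.
* **Trajectories**: base coordinates plus independent per-atom isotropic
  Gaussian noise with per-residue σ; optional noise-free marker residues
  (801/802, unit mass so single-atom COMs are bit-exact) carrying scripted
  pair distances; optional solvent atoms teleporting between an in-pocket
  and a far-outside position on scripted frames.
* **Docking runs**: normal pose-energy ensembles (default 6 runs × 100
  poses, the replicate structure used for receptor docking) with each
  run's exact weighted mean recorded via a softmax route; a DLG emission
  mode round-trips through the parser.
* **Calibration surfaces**: bilinear (linear-fit-exact), concave quadratic
  with a planted interior optimum, or bimodal Gaussian bumps, with optional
  cell noise (0.05 pKd in the recovery studies).
* **Variant panels**: wild-type pKd defaults to the published median ARB
  affinities; planted effects shift variant replicates by −log₁₀(fold);
  replicate noise 0.05 pKd, n = 6 — matching the replicate structure and
  spread of the docking campaign the statistics were designed for.

None of this emulates force-field energetics, realistic water structure,
membranes, or pose geometry.  Passing tests therefore demonstrate that the
*algorithms* recover known ground truth under the stated noise models — not
that docking itself predicts affinity; the published headline affinities
(e.g. olmesartan mean pKd 8.252, CI 8.230–8.297) and the full variant
heatmap require running AutoDock on the study's receptor models and are
outside desk scale.

## Numerical choices and degenerate inputs

* RT at 310.15 K ≈ 0.616356 kcal/mol; min-shifted exponentials throughout.
* Population SD for window summaries; Student-t CIs for replicate means.
* Flood-fill seed outside all probe spheres → volume 0 + warning.
* Empty selections, missing probe atoms, incomplete calibration grids and
  non-finite inputs raise typed errors naming the offending entries.
* Sweep tie-breaks are deterministic (residual, then spacing, then Z).
* All RNGs are `numpy.random.default_rng(seed)`; no hidden global state.

## Problem sizes used in the automated checks

Oracle comparisons use 1000 random docking runs; RMSF recovery a
2000-frame, ~350-atom trajectory; state classification 1000 reference
draws; calibration recovery 50 noisy surfaces swept at full resolution;
flag power/type-I 500 + 500 single-cell panels; phantom volumes 0.25 Å
lattices (~3×10⁴ points).  These sizes give sampling error comfortably
below each asserted bound while keeping the full suite at a few seconds.
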