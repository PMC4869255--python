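# Methods

## Scope and model

The package treats a single-pass receptor as three structural regimes and
models each with the technique that fits it: dihedral-level NMR analysis for
the transmembrane helix, residue-bead SAXS observables for the folded
extracellular domain, and a statistical-coil ensemble with bead-model
hydrodynamics for the disordered intracellular domain.  A final assembly
stage places the pieces in a common membrane frame.  Structure calculation
itself (simulated annealing against NOEs), ab initio envelope
reconstruction, hydration-shell scattering models and post-assembly
refinement are out of scope; joints are rigid superpositions and joint
quality is reported as an overlap RMSD instead.

Conventions used throughout: coordinates in Å; mature-receptor residue
numbering (1-based at the first extracellular residue); the membrane normal
is the global +z axis with the extracellular side above the slab.
Expression-tag residues (the G-S pair preceding the TMD construct) carry
construct-local numbers and are flagged, never renumbered.

## Backbone construction and helix geometry

Chains are extended atom-by-atom from internal coordinates (NeRF) with
ideal bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å and
angles CA–C–N 116.2°, C–N–CA 121.7°.  The N–CA–C angle is the tetrahedral
109.5°: with the common 111.2° crystallographic average, an ideal
(φ, ψ) = (−57°, −47°) helix builds with a 1.56 Å per-residue rise, whereas
109.5° reproduces the canonical 1.50 Å rise and 2.3 Å Cα radius that the
rest of the analysis assumes.  ω defaults to trans.

Helix axes are fitted by the rotating-bisector construction: for three
consecutive Cα positions the bisector (P_{i−1}−P_i)+(P_{i+1}−P_i) points
radially toward the axis, and cross products of successive bisectors are
parallel to it.  Unlike a principal-component fit, this is exact for ideal
helices spanning a non-integer number of turns (a PCA axis on an 11-residue
segment of a perfect helix is tilted by several degrees, which would fake a
bend).  Near-straight segments, where the bisectors do not rotate, fall
back to PCA.  The radius is the RMS Cα distance to the axis with the axis
position from a least-squares circle fit in the perpendicular plane.

Bend angles are measured between axes fitted on two disjoint flanks; when a
single pivot residue is quoted, the flanks exclude it so the kink does not
contaminate either fit.  Helix "length" follows the residue-count × 1.5 Å
convention (24 residues ↔ 36 Å); the axis-projected Cα extent is returned
as a secondary diagnostic and is one rise shorter (n−1 gaps between n
residues).  Superposition uses the SVD least-squares solution; ensemble
RMSD averages over all unordered model pairs, each pair independently
superposed rather than referred to a medoid.

## NMR-derived structure information

Secondary chemical shifts are Δδ = δ_obs − δ_rc against a bundled
random-coil table (Wishart-style solution values for Cα, Cβ, C′, Hα of the
20 standard residues).  Synthetic tests generate observed shifts *from* the
bundled table, so test outcomes are independent of which published
compilation ships.  Helix calling uses the score ΔδCα − ΔδCβ (falling back
to ΔδCα when Cβ is absent), smoothed with a centred 3-residue window, and
calls maximal runs above 0.7 ppm of length ≥ 4.  No published calling rule
is canonical; these defaults are common practice and are exposed as
configuration.  The window smoothing can extend a call by one residue at
each edge — the parameter-recovery suite asserts recovery of a known
helical stretch to ±1 residue per end in ≥ 95% of 200 seeded replicates.

The Karplus relation uses HN–Hα coefficients A, B, C = 6.51, −1.75, 1.60 Hz
with the −60° phase.  Inversion is the closed-form quadratic in
cos(φ−60°); couplings outside the curve's range [J_min, J_max] return an
empty solution set with a warning, the signature of an inconsistent
measurement.  Hydrogen-bond restraints follow the helical rule: donor i
with J < 5 Hz, both i and i−4 inside the same called segment, emitted as a
table or CNS-style assign lines.

Relaxation decays are fitted as single exponentials y = a·exp(−x/T)
(Levenberg–Marquardt seeded from a log-linear fit); series that do not
decay over the sampled window (fitted T beyond 100× the delay range, or a
non-negative trend) are flagged rather than fitted.  H–D exchange
protection is scored from the quasi-stationary intensities at several D₂O
fractions as 1 − slope of intensity against the proton fraction, clipped to
[0, 1].

## Statistical-coil ensembles

Conformers are built residue-by-residue by drawing (φ, ψ) from a
residue-class library and extending with ideal geometry.  The bundled
library is a declared surrogate for database-derived coil distributions
(the reference generator's internal library is not published): discrete
basin points with generic-class weights ≈ 0.3/0.3/0.4 over the α, β and
PPII basins, a symmetric extended set for glycine, φ ≈ −65° with bimodal ψ
for proline, and a ψ-shifted extended set for pre-proline.  It is swappable
via a plain-text file.  Self-avoidance is enforced on Cα spheres at a 4.0 Å
cutoff for |i−j| ≥ 3; on a clash the builder rewinds up to 5 residues and
redraws, bounded at 10⁴ redraws per conformer.  Ensembles derive
per-conformer seeds from one master seed (`SeedSequence.spawn`), making
runs bit-reproducible.

Diagnostics: ensemble-mean Rg and end-to-end distance, and an apparent
Flory exponent ν from regressing log(mean sub-chain Rg) on log(length).
The seeded 363-residue ensemble sits at ν ≈ 0.55 (excluded-volume coil
window 0.50–0.65) with mean Rg ≈ 60 Å — realistic coil dimensions for a
disordered chain of this length.  Tests and desk-scale runs use a generic
363-residue surrogate sequence (uniform composition, 5% proline) so nothing
needs downloading; the sampler accepts any residue-name sequence.

## Hydrodynamics

Per-conformer hydrodynamic radii use the Kirkwood bead approximation with
one bead per residue at Cα:

    1/R_H = (1/N²)·(N/a + Σ_{i≠j} 1/r_ij),   a = 4.5 Å by default.

The formula has the correct limits (single bead → a; two far beads → 2a)
and the two-bead closed form 2ar/(a+r) is used as an exact cross-check of
the general double sum.  Ensemble values are harmonic means ⟨R_H⁻¹⟩⁻¹, the
average a rapidly interconverting ensemble contributes to a diffusion
measurement.

Known limitation, quantified on the seeded ensemble: the point-bead
Kirkwood estimate tracks ≈ 0.7 × Rg for coils and therefore runs well below
atomic shell-model predictors (HYDROPRO-class) on the same conformers.  For
the 363-residue coil ensemble the harmonic-mean Kirkwood R_H is ≈ 43 Å,
whereas a shell-model average over a comparable ensemble is reported around
58 Å and the direct pulsed-field-gradient measurement of the same chain is
74 Å.  Decomposing the double sum shows about half of Σ 1/r_ij comes from
sequence separations |i−j| ≤ 50 — fixed by local chain geometry — so no
realistic global expansion closes the gap, and the bead-radius self term
(N/a, tunable over a ∈ [4, 7] Å) shifts the result by well under 1 Å at
N = 363.  The Kirkwood stage is therefore validated by its analytic limits,
invariances and reproducibility, not by absolute agreement with shell-model
values; users needing absolute R_H should apply a shell-model correction.

Experimental R_H extraction fits S = S₀·exp(−d·g²) to the protein and
reference decays and scales by the reference radius:
R_H = R_H,ref · d_ref/d_protein (α-cyclodextrin reference, 7.52 Å).
Stejskal–Tanner timing factors cancel in the ratio, so only the relative
decay constants matter.

## SAXS observables

Residue-level beads with uniform (optionally mass-proportional) form
factors replace atomic scattering factors and the hydration shell; the
intensity is the exact orientation-averaged Debye double sum with the
i = j and q → 0 limits handled analytically, chunked over q to bound
memory.  Model-to-experiment agreement is the reduced
χ² = (1/(n−p)) Σ[(I_exp − c·I_calc − b)/σ]² with the scale (and optional
constant background) at the closed-form weighted least-squares optimum;
experimental curves are interpolated onto the calculated grid over the
overlapping q range.  Guinier analysis fits ln I = ln I₀ − q²Rg²/3
iteratively until q_max·Rg ≤ 1.3; P(r) is the f_i f_j-weighted pair-distance
histogram with D_max the largest pair distance.  Because the hydration
shell is omitted, absolute χ² values against real measured curves are not
comparable to published hydration-aware fits; the stage is validated by
analytic limits (I(0) = (Σf)², the two-scatterer closed form, the uniform
sphere Rg = √(3/5)·R) and by χ² ≈ 1 under matched synthetic noise.

## Assembly

The membrane is a planar slab, default −15 to +15 Å (a 30 Å hydrocarbon
core; the natural bilayer value is ~29 Å).  The TMD is embedded by aligning
the helix axis fitted over the embedded range (T211–L234) with the normal,
N-terminal end extracellular, embedded-Cα midpoint at the slab centre; the
24-residue embedded stretch spans ~36 Å, so the flanking charged anchors
protrude beyond both faces.  "Perpendicular" ECD orientation is
operationalised as aligning the longest principal axis of the Cα cloud
with +z, C-terminal (membrane-proximal) end down; near-spherical domains
fall back to the termini vector with a warning.

Domains are joined by superposing the downstream chain onto the upstream
over the shared 5-residue overlap Cα atoms; the merged chain keeps upstream
coordinates through the overlap, numbering must be continuous, and joins
with overlap RMSD > 5 Å are refused as conformationally incompatible.
After the ECD+TMD join the merged stem is re-embedded so the membrane
frame, not the ECD frame, anchors the model.  One full-length model is
built per ICD conformer; the fold-back filter then discards any model with
a non-exempt heavy atom strictly inside the slab (only the embedded TMD
range is exempt — juxtamembrane linkers are not).  Vertical extents and
per-domain extent fractions are reported per model; with a long disordered
chain the intracellular region dominates the vertical span, mirroring the
published ~20/10/70% ECD/TMD/ICD proportions, but the absolute extent is
conformer-dependent and reported as a distribution, not a single number.

## Synthetic data and what passing tests show

Every input class has a seeded generator: helical shift offsets
(Cα +2.5, Cβ −0.5, C′ +1.5, Hα −0.3 ppm — canonical literature-style
magnitudes, declared constants of the fixture) on the bundled random-coil
baseline; couplings through the Karplus curve; exponential/Gaussian decays
with known constants; rigid-compatible toy domains whose overlap windows
share one ideal helical conformation; and noisy Debye curves from known
coordinates.  The generators emulate the *statistical structure* of the
observables, not their full experimental messiness: no peak overlap or
missing assignments, no spectrometer drift, Gaussian noise only, and toy
domains instead of real folded coordinates.  Passing parameter-recovery
tests therefore demonstrates correctness of the analysis algorithms under
the stated noise models, not robustness to every artefact of real data.

## Problem sizes in the test-suite and reproduction runs

The shared test ensemble is 200 conformers of the 363-residue surrogate
chain; the two-depth sampling consistency check runs on 120-residue chains
(n = 150 vs 600); noise studies use 100 replicates; the reproduction script
uses 500 conformers for the hydrodynamics number (its harmonic mean is
stable to well under 0.5 Å at that depth, and the published protocol's
1,000-model depth changes it by less than the seed-to-seed spread).

## Known limitations

- Kirkwood point-bead R_H is a relative, not absolute, compactness measure
  for coils (see Hydrodynamics above).
- The coil library is a surrogate; absolute ensemble observables carry
  library-choice uncertainty even where scaling behaviour is correct.
- Debye curves ignore the hydration shell and atomic form factors.
- Joints are rigid; no refinement relaxes the overlap geometry, so overlap
  RMSD is the only joint-quality measure.
- The ECD orientation rule is a convention (longest axis ⊥ membrane), not
  an experimentally determined tilt.
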