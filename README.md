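# prlrkit

Integrative "divide-and-conquer" modelling of a full-length single-pass
membrane receptor — the human prolactin receptor architecture: a folded
extracellular domain (ECD), a single transmembrane helix (TMD), and a long
intrinsically disordered intracellular domain (ICD).  No single structural
technique covers such a protein, so the pipeline derives structure from NMR
observables for the TMD, validates the ECD at Debye level against SAXS,
describes the ICD as a statistical-coil ensemble checked against
hydrodynamics, and assembles full-length models across a membrane slab.

Intended users: structural biologists and method developers who want a
scriptable, fully seeded re-implementation of each stage with synthetic-data
generators for every input class, so the whole pipeline is testable offline.

## What it computes

- **Secondary chemical shifts and helix calling** — Δδ = δ_obs − δ_rc for
  Cα, Cβ, C′ and Hα against a bundled random-coil table; helical segments
  are maximal runs where the smoothed score ΔδCα − ΔδCβ exceeds a threshold
  (default 0.7 ppm, window 3, minimum length 4).
- **Karplus relation** — ³J(HN–Hα)(φ) = A·cos²(φ−60°) + B·cos(φ−60°) + C
  with A, B, C = 6.51, −1.75, 1.60 Hz; forward evaluation, closed-form
  inversion to all φ solutions, HNHA cross/diagonal extraction
  J = atan(√(−S_cross/S_diag))/(2πζ), and emission of helical hydrogen-bond
  restraints H(N)_i → (C)O_{i−4} for residues with J < 5 Hz inside a called
  helix.
- **Helix geometry** — ideal-geometry backbone construction from (φ, ψ, ω),
  helix-axis fitting by the rotating-bisector construction, bend angles
  between segments, the axial-length convention (residues × 1.5 Å), and
  pairwise ensemble RMSD after least-squares superposition.
- **Statistical-coil ensembles** — residue-class (φ, ψ) sampling
  (generic/glycine/proline/pre-proline basins) with Cα self-avoidance
  (4.0 Å, |i−j| ≥ 3), bit-reproducible under a master seed; chain
  diagnostics include the apparent Flory exponent ν.
- **Hydrodynamics** — per-conformer Kirkwood bead-model radius
  1/R_H = (1/N²)(N/a + Σ_{i≠j} 1/r_ij) on Cα beads, ensemble-averaged as
  the harmonic mean ⟨R_H⁻¹⟩⁻¹; experimental R_H from paired
  pulsed-field-gradient decays against a reference compound
  (α-cyclodextrin, R_H = 7.52 Å).
- **SAXS** — exact Debye sums I(q) = ΣΣ f_i f_j sin(qr)/(qr) on residue
  beads, closed-form χ² scale fitting, iterative Guinier analysis, and the
  pair-distance distribution P(r).
- **Assembly** — TMD embedding in a 30 Å slab (embedded range T211–L234,
  midpoint at the slab centre, extracellular N-terminus up), perpendicular
  ECD orientation, rigid joins at the 5-residue sequence overlaps
  (F206–D210 and G236–V240), and a fold-back filter that discards models
  whose non-embedded atoms enter the bilayer slab.

## Worked example

```python
import numpy as np
from prlrkit import nmr_analysis as nmr, geometry as geo
from prlrkit import coil_ensemble as coil, hydro as hyd
from prlrkit.synthetic_data import FixtureConfig, gen_helix_shift_table

# helix calling from secondary chemical shifts (synthetic TMD-like table)
table = gen_helix_shift_table(FixtureConfig(seed=7))
profile = nmr.compute_scs(table)
print("called helix segments:", nmr.call_helix_segments(profile))

# the axial-length convention and the helical coupling regime
print(f"axial length of 210-233: {geo.helix_axial_length((210, 233)):.1f} A")
print(f"3J(HN-Ha) at phi=-57 deg: {nmr.karplus_forward(-57.0):.2f} Hz")

# statistical-coil ensemble of a 363-residue disordered chain + Kirkwood RH
ens = coil.generate_ensemble(coil.surrogate_sequence(363), n=100, seed=7)
rh = hyd.ensemble_rh([hyd.kirkwood_rh(c) for c in ens.conformers])
print(f"ensemble R_H (harmonic mean, n=100): {rh:.1f} A")
```

prints

```
called helix segments: [(209, 234)]
axial length of 210-233: 36.0 A
3J(HN-Ha) at phi=-57 deg: 3.74 Hz
ensemble R_H (harmonic mean, n=100): 43.7 A
```

The called segment recovers the synthetic helix window (210–233) to within
the one-residue smoothing margin at each edge; 36.0 Å is the 24-residue
helix length at the canonical 1.5 Å rise; 3.74 Hz is the coupling a helical
φ produces under the bundled Karplus coefficients, well below the 5 Hz
hydrogen-bond cutoff.  The ensemble R_H uses the Cα-bead Kirkwood
approximation — a point-bead surrogate that runs systematically below
shell-model predictions for coils (see `docs/methods.md`).

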