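"""Seeded generators for every input class the pipeline consumes.

Each generator emulates the statistical structure of one experimental
observable — helical secondary-shift patterns on a random-coil baseline,
couplings through the Karplus curve, exponential/Gaussian decays with known
constants, rigid-compatible toy domains with 5-residue assembly overlaps,
and noisy Debye curves from known coordinates — so that every analysis stage
can be exercised, and its truth parameters recovered, without any download.

All outputs are deterministic under the configured seed.  The helical shift
offsets (CA +2.5, CB −0.5, C +1.5, HA −0.3 ppm) are canonical
literature-style magnitudes, declared constants of the fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import AssemblySpec
from .coil_ensemble import (ConformerEnsemble, DEFAULT_COIL_LIBRARY,
                            generate_ensemble, surrogate_sequence)
from .geometry import DihedralSet, build_backbone
from .nmr_analysis import DEFAULT_KARPLUS, CouplingTable, KarplusParameters, karplus_forward
from .randomcoil import DEFAULT_RANDOM_COIL, STANDARD_RESIDUES
from .saxs import FormFactorModel, debye_curve
from .structio import ChainCoordinates, ChemicalShiftTable, DecaySeries, ScatteringCurve

__all__ = [
    "FixtureConfig",
    "HELIX_SHIFT_OFFSETS",
    "gen_helix_shift_table",
    "gen_coupling_table",
    "gen_decay",
    "gen_toy_domains",
    "gen_toy_icd_ensemble",
    "gen_saxs_from_chain",
]

#: helical secondary-shift offsets added inside the helix window (ppm)
HELIX_SHIFT_OFFSETS = {"CA": 2.5, "CB": -0.5, "C": 1.5, "HA": -0.3}

IDEAL_HELIX = (-57.0, -47.0)


@dataclass(frozen=True)
class FixtureConfig:
    """Truth parameters and noise levels for the synthetic fixtures."""

    seed: int = 0
    shift_noise_ppm: float = 0.1
    intensity_noise: float = 0.02
    sequence_length: int = 35
    first_residue: int = 206
    helix_window: tuple = (210, 233)
    t2_ms: float = 50.0          # transverse relaxation time truth
    rh_true: float = 74.0        # protein hydrodynamic radius truth (Å)
    rh_ref: float = 7.52         # reference-compound R_H (Å)
    phi_helix: float = -57.0

    def __post_init__(self):
        if self.shift_noise_ppm < 0 or self.intensity_noise < 0:
            raise ValueError("noise levels must be non-negative")
        lo, hi = self.helix_window
        first, last = self.first_residue, self.first_residue + self.sequence_length - 1
        if self.helix_window != (0, 0) and not (first <= lo <= hi <= last):
            raise ValueError("helix window must lie inside the sequence")


def _fixture_names(n: int, rng: np.random.Generator) -> list[str]:
    pool = [r for r in STANDARD_RESIDUES if r != "PRO"]
    return [pool[rng.integers(len(pool))] for _ in range(n)]


def gen_helix_shift_table(config: FixtureConfig = FixtureConfig()) -> ChemicalShiftTable:
    """Chemical shifts = bundled random-coil baseline + helical offsets inside
    the helix window + Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    n = config.sequence_length
    ids = np.arange(config.first_residue, config.first_residue + n)
    names = _fixture_names(n, rng)
    lo, hi = config.helix_window
    rows = []
    for rid, name in zip(ids, names):
        for atom in ("CA", "CB", "C", "HA"):
            base = DEFAULT_RANDOM_COIL.get(name, atom)
            if base is None:
                continue
            shift = base
            if lo <= rid <= hi:
                shift += HELIX_SHIFT_OFFSETS[atom]
            shift += rng.normal(0.0, config.shift_noise_ppm)
            rows.append((int(rid), name, atom, shift))
    frame = pd.DataFrame(rows, columns=["residue_id", "residue_name",
                                        "atom_name", "shift"])
    return ChemicalShiftTable(frame)


def gen_coupling_table(phi_by_residue: dict, noise_hz: float = 0.0,
                       params: KarplusParameters = DEFAULT_KARPLUS,
                       seed: int = 0) -> CouplingTable:
    """³J couplings generated through the Karplus curve, clipped at zero."""
    if noise_hz < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    couplings = {}
    for rid, phi in phi_by_residue.items():
        j = karplus_forward(phi, params) + rng.normal(0.0, noise_hz)
        couplings[int(rid)] = max(float(j), 0.0)
    return CouplingTable(couplings)


def gen_decay(kind: str, truth: float, x, noise: float = 0.0,
              seed: int = 0, amplitude: float = 1.0) -> DecaySeries:
    """Noisy decay with known constant.

    relaxation: y = A·exp(−x/truth); diffusion: y = A·exp(−truth·x²).
    Noise is multiplicative Gaussian with fractional width ``noise``.
    """
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    if kind == "relaxation":
        y = amplitude * np.exp(-x / truth)
    elif kind == "diffusion":
        y = amplitude * np.exp(-truth * x ** 2)
    else:
        raise ValueError(f"unknown decay kind {kind!r}")
    if noise > 0:
        y = y * (1.0 + rng.normal(0.0, noise, size=y.shape))
    return DecaySeries(x=x, y=np.maximum(y, 1e-12), kind=kind)


def gen_toy_domains(seed: int = 0) -> tuple[ChainCoordinates, ChainCoordinates, AssemblySpec]:
    """Toy ECD + TMD with rigid-compatible 5-residue assembly overlaps.

    The toy ECD (residues 150-210) is a two-helix hairpin whose C-terminal
    tail continues in the same ideal helical conformation as the toy TMD
    (residues 204-240, G-S expression tags at 204-205), so superposing the
    F206-D210 overlap reproduces the upstream conformation exactly.
    """
    rng = np.random.default_rng(seed)
    phi_h, psi_h = IDEAL_HELIX

    n_ecd = 61  # residues 150..210
    phis = np.full(n_ecd, phi_h)
    psis = np.full(n_ecd, psi_h)
    loop = slice(23, 28)  # residues 173..177: extended loop between helices
    phis[loop] = -120.0
    psis[loop] = 130.0
    ecd = build_backbone(_fixture_names(n_ecd, rng),
                         DihedralSet(phis, psis), start_id=150)

    n_tmd = 37  # residues 204..240, helical throughout
    tmd_names = ["GLY", "SER"] + _fixture_names(n_tmd - 2, rng)
    tmd = build_backbone(tmd_names, DihedralSet.uniform(n_tmd, phi_h, psi_h),
                         start_id=204)
    tmd = ChainCoordinates(tmd.residue_ids, tmd.residue_names, tmd.atoms,
                           tag_residues=frozenset({204, 205}))

    spec = AssemblySpec(ecd=(150, 202), icd=(243, 598))
    return ecd, tmd, spec


def gen_toy_icd_ensemble(seed: int = 0, n: int = 20, length: int = 45,
                         start_id: int = 236) -> ConformerEnsemble:
    """Short disordered-domain ensemble whose first five residues (the
    TMD/ICD overlap window) are pinned to the helical conformation of the
    toy TMD tail, keeping the assembly joint rigid-compatible."""
    sequence = surrogate_sequence(length, seed=seed + 1)
    fixed = {rid: IDEAL_HELIX for rid in range(start_id, start_id + 5)}
    return generate_ensemble(sequence, n=n, library=DEFAULT_COIL_LIBRARY,
                             seed=seed, start_id=start_id,
                             fixed_dihedrals=fixed)


def gen_saxs_from_chain(chain: ChainCoordinates, q_grid, noise: float = 0.0,
                        seed: int = 0,
                        ff: FormFactorModel = FormFactorModel()) -> ScatteringCurve:
    """Debye curve of a chain with multiplicative Gaussian noise; the sigma
    column is set to the applied noise level (or a 1% floor when noiseless)."""
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    curve = debye_curve(chain, q_grid, ff)
    rng = np.random.default_rng(seed)
    intensity = curve.intensity.copy()
    if noise > 0:
        sigma = noise * intensity
        intensity = intensity + rng.normal(0.0, 1.0, size=intensity.shape) * sigma
        intensity = np.maximum(intensity, 1e-12)
        sigma = np.maximum(sigma, 1e-12)
    else:
        sigma = np.maximum(0.01 * intensity, 1e-12)
    return ScatteringCurve(q=curve.q, intensity=intensity, sigma=sigma)
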