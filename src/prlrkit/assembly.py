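"""Full-receptor assembly across a membrane slab.

The integration stage: embed the transmembrane helix in a planar slab
representing the bilayer hydrocarbon core, orient the extracellular domain
perpendicular to the membrane, join domains rigidly at their 5-residue
sequence overlaps, attach each disordered intracellular conformer, and
discard assembled models whose non-embedded atoms fold back into the slab.

Conventions: the membrane normal is +z; the extracellular side is above the
slab (z > z_upper) and the cytoplasm below; within the receptor numbering
the extracellular domain is N-terminal, so the embedded helix runs N→C
downwards (−z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .coil_ensemble import ConformerEnsemble
from .geometry import fit_helix_axis, superpose
from .structio import ChainCoordinates

__all__ = [
    "MembraneSlab",
    "AssemblySpec",
    "FullReceptorModel",
    "AssemblyError",
    "place_tmd",
    "orient_ecd",
    "join_at_overlap",
    "membrane_clash_filter",
    "assemble_full_receptor",
    "extent_report",
]


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class MembraneSlab:
    """Planar bilayer hydrocarbon core, normal along +z (Å)."""

    z_lower: float = -15.0
    z_upper: float = 15.0

    def __post_init__(self):
        if self.z_upper <= self.z_lower:
            raise AssemblyError("z_upper must exceed z_lower")

    @property
    def centre(self) -> float:
        return 0.5 * (self.z_lower + self.z_upper)

    @property
    def thickness(self) -> float:
        return self.z_upper - self.z_lower

    def strictly_inside(self, z: np.ndarray) -> np.ndarray:
        return (z > self.z_lower) & (z < self.z_upper)


@dataclass(frozen=True)
class AssemblySpec:
    """Domain boundaries, overlap windows and embedding range (residue ids).

    Defaults are the mature-receptor architecture: ECD Q1-I202, JML1
    P203-N209, TMD D210-G236, JML2 Y237-C242, ICD I243-H598; 5-residue
    assembly overlaps F206-D210 (ECD/TMD) and G236-V240 (TMD/ICD); membrane
    embedded range T211-L234.
    """

    ecd: tuple = (1, 202)
    jml1: tuple = (203, 209)
    tmd: tuple = (210, 236)
    jml2: tuple = (237, 242)
    icd: tuple = (243, 598)
    overlap_ecd_tmd: tuple = (206, 210)
    overlap_tmd_icd: tuple = (236, 240)
    embedded: tuple = (211, 234)
    ensemble_size: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (self.tmd[0] <= self.embedded[0] and self.embedded[1] <= self.tmd[1]):
            raise AssemblyError("embedded range must lie inside the TMD")
        for name, (lo, hi) in (("overlap_ecd_tmd", self.overlap_ecd_tmd),
                               ("overlap_tmd_icd", self.overlap_tmd_icd)):
            if hi - lo < 2:
                raise AssemblyError(f"{name} too short")


@dataclass
class FullReceptorModel:
    """One assembled full-length model with provenance and extent metrics."""

    chain: ChainCoordinates
    spec: AssemblySpec
    provenance: dict = field(default_factory=dict)
    overlap_rmsds: dict = field(default_factory=dict)

    @property
    def vertical_extent(self) -> float:
        z = self.chain.all_coords()[:, 2]
        return float(z.max() - z.min())


# ---------------------------------------------------------------------------
# rotations


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180°: rotate about any axis perpendicular to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


# ---------------------------------------------------------------------------
# placement


def place_tmd(tmd: ChainCoordinates, spec: AssemblySpec,
              slab: MembraneSlab = MembraneSlab()) -> ChainCoordinates:
    """Embed the transmembrane helix in the slab.

    The helix axis fitted over the embedded range is aligned with the
    membrane normal, N-terminal end up (extracellular), and the embedded
    CA midpoint is put at the slab centre on the z axis.
    """
    axis = fit_helix_axis(tmd, spec.embedded)
    # N→C runs from the extracellular to the cytoplasmic side: align to −z
    R = _rotation_between(axis.direction, np.array([0.0, 0.0, -1.0]))
    moved = tmd.transformed(R, np.zeros(3))
    emb = moved.subset(*spec.embedded)
    midpoint = emb.ca.mean(axis=0)
    target = np.array([0.0, 0.0, slab.centre])
    placed = moved.transformed(np.eye(3), target - midpoint)
    n_term_z = placed.ca[0, 2]
    c_term_z = placed.ca[-1, 2]
    if n_term_z < c_term_z:
        raise AssemblyError("TMD N-terminus ended up below the C-terminus")
    return placed


def orient_ecd(ecd: ChainCoordinates,
               slab: MembraneSlab = MembraneSlab()) -> ChainCoordinates:
    """Rotate the extracellular domain so its longest principal axis is
    perpendicular to the membrane plane (parallel to +z), with the
    C-terminal residue at the membrane-proximal (lower) end."""
    if ecd.n_residues < 50:
        raise AssemblyError("ECD orientation expects a domain of >= 50 residues")
    ca = ecd.ca
    centre = ca.mean(axis=0)
    X = ca - centre
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    if svals[0] < 1.2 * svals[1]:
        warnings.warn("near-spherical domain: orienting by termini vector",
                      stacklevel=2)
        axis = ca[-1] - ca[0]
        axis = axis / np.linalg.norm(axis)
    else:
        axis = vt[0]
    R = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    rotated_ca = (ca - centre) @ R.T + centre
    # C terminus connects to the membrane: it must sit at the lower end
    if rotated_ca[-1, 2] > rotated_ca[0, 2]:
        flip = _rotation_between(np.array([0.0, 0.0, 1.0]),
                                 np.array([0.0, 0.0, -1.0]))
        R = flip @ R
    t = centre - R @ centre  # rotate about the domain centroid
    return ecd.transformed(R, t)


def join_at_overlap(upstream: ChainCoordinates, downstream: ChainCoordinates,
                    overlap: tuple[int, int],
                    max_overlap_rmsd: float = 5.0,
                    ) -> tuple[ChainCoordinates, float]:
    """Rigidly join two chains over a shared residue-numbering overlap.

    The downstream chain is superposed onto the upstream over the overlap CA
    atoms; the merged chain keeps upstream coordinates up to (and including)
    the overlap and appends the transformed downstream residues after it.
    Returns the merged chain and the overlap RMSD.
    """
    lo, hi = overlap
    if hi - lo + 1 < 3:
        raise AssemblyError(f"overlap {overlap} shorter than 3 residues")
    for chain, name in ((upstream, "upstream"), (downstream, "downstream")):
        ids = set(chain.residue_ids.tolist())
        if not all(r in ids for r in range(lo, hi + 1)):
            raise AssemblyError(f"overlap {overlap} not fully present in {name} chain")
    transform, rmsd = superpose(downstream, upstream, overlap, atom_names=("CA",))
    if rmsd > max_overlap_rmsd:
        raise AssemblyError(
            f"incompatible overlap conformations: RMSD {rmsd:.2f} Å over {overlap}"
        )
    moved = downstream.transformed(transform.rotation, transform.translation)

    up_last = int(upstream.residue_ids[-1])
    tail_mask = moved.residue_ids > up_last
    if not tail_mask.any():
        raise AssemblyError("downstream chain adds no residues beyond the upstream")
    first_tail = int(moved.residue_ids[tail_mask][0])
    if first_tail != up_last + 1:
        raise AssemblyError(
            f"numbering gap at join: upstream ends at {up_last}, "
            f"downstream continues at {first_tail}"
        )

    atoms = {}
    names = list(upstream.residue_names) + [
        nm for nm, m in zip(moved.residue_names, tail_mask) if m
    ]
    keys = set(upstream.atoms) | set(moved.atoms)
    n_up, n_tail = upstream.n_residues, int(tail_mask.sum())
    for key in keys:
        up = upstream.atoms.get(key, np.full((n_up, 3), np.nan))
        down = moved.atoms.get(key, np.full((moved.n_residues, 3), np.nan))
        atoms[key] = np.vstack([up, down[tail_mask]])
    ids = np.concatenate([upstream.residue_ids, moved.residue_ids[tail_mask]])
    merged = ChainCoordinates(ids, names, atoms,
                              tag_residues=upstream.tag_residues)
    return merged, float(rmsd)


def membrane_clash_filter(models: list, slab: MembraneSlab,
                          exempt: tuple[int, int]) -> tuple[list, int]:
    """Drop models with any non-exempt heavy atom strictly inside the slab.

    ``exempt`` is the membrane-embedded TMD range; juxtamembrane linkers are
    deliberately not exempt.  Returns (survivors, rejected count).
    """
    survivors = []
    rejected = 0
    for model in models:
        chain = model.chain if isinstance(model, FullReceptorModel) else model
        xyz = chain.heavy_coords(exclude_interval=exempt)
        if np.any(slab.strictly_inside(xyz[:, 2])):
            rejected += 1
        else:
            survivors.append(model)
    return survivors, rejected


def assemble_full_receptor(ecd: ChainCoordinates, tmd: ChainCoordinates,
                           icd_ensemble: ConformerEnsemble,
                           spec: AssemblySpec,
                           slab: MembraneSlab = MembraneSlab(),
                           ) -> tuple[list, dict]:
    """Assemble full-length models: one per ICD conformer, then filter.

    Pipeline: embed the TMD; orient the ECD; join ECD+TMD at the first
    overlap and re-embed the merged chain; join each ICD conformer at the
    second overlap; reject models folding back into the slab.  Returns
    (surviving FullReceptorModel list, report dict).
    """
    tmd_placed = place_tmd(tmd, spec, slab)
    ecd_oriented = orient_ecd(ecd, slab)
    stem, rmsd_ecd_tmd = join_at_overlap(ecd_oriented, tmd_placed,
                                         spec.overlap_ecd_tmd)
    # the join was computed in the ECD frame; re-embed the merged stem
    stem = place_tmd(stem, spec, slab)

    models = []
    for k, conformer in enumerate(icd_ensemble.conformers):
        full, rmsd_tmd_icd = join_at_overlap(stem, conformer,
                                             spec.overlap_tmd_icd)
        models.append(FullReceptorModel(
            chain=full, spec=spec,
            provenance={"icd_conformer": k, "ensemble_seed": icd_ensemble.seed},
            overlap_rmsds={"ecd_tmd": rmsd_ecd_tmd, "tmd_icd": rmsd_tmd_icd},
        ))
    survivors, rejected = membrane_clash_filter(models, slab, exempt=spec.embedded)
    for model in survivors:
        emb_mid = model.chain.subset(*spec.embedded).ca.mean(axis=0)
        if abs(emb_mid[2] - slab.centre) > 2.0:
            raise AssemblyError("embedded-range midpoint drifted from slab centre")
    report = {
        "n_input": len(models),
        "n_survivors": len(survivors),
        "n_rejected": rejected,
        "overlap_rmsd_ecd_tmd": rmsd_ecd_tmd,
        "extents": [m.vertical_extent for m in survivors],
    }
    return survivors, report


def extent_report(model: FullReceptorModel) -> tuple[float, dict]:
    """Total z extent of a model and the per-domain extent fractions."""
    chain = model.chain
    z = chain.all_coords()[:, 2]
    total = float(z.max() - z.min())
    fractions = {}
    for name in ("ecd", "tmd", "icd"):
        lo, hi = getattr(model.spec, name)
        lo = max(lo, int(chain.residue_ids[0]))
        hi = min(hi, int(chain.residue_ids[-1]))
        if lo > hi:
            fractions[name] = 0.0
            continue
        dz = chain.subset(lo, hi).all_coords()[:, 2]
        fractions[name] = float((dz.max() - dz.min()) / total) if total > 0 else 0.0
    return total, fractions
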