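"""Membrane embedding, domain joining, fold-back filtering, extent metrics."""

import numpy as np
import pytest

from prlrkit.assembly import (AssemblyError, AssemblySpec, FullReceptorModel,
                              MembraneSlab, assemble_full_receptor,
                              extent_report, join_at_overlap,
                              membrane_clash_filter, orient_ecd, place_tmd,
                              _rotation_between)
from prlrkit.geometry import DihedralSet, build_backbone, fit_helix_axis
from prlrkit.structio import ChainCoordinates


Z = np.array([0.0, 0.0, 1.0])


def make_helix(start_id, n, phi=-57.0, psi=-47.0):
    return build_backbone(["LEU"] * n, DihedralSet.uniform(n, phi, psi),
                          start_id=start_id)


def synthetic_chain(ids, z_values, x=0.0):
    """Minimal chain with CAs on a vertical line (no bond validity implied)."""
    ids = np.asarray(ids)
    n = len(ids)
    ca = np.column_stack([np.full(n, x), np.zeros(n), np.asarray(z_values)])
    atoms = {"CA": ca, "N": ca + [0.6, 0, 0], "C": ca + [0, 0.6, 0],
             "O": ca + [0, 0, 0.6]}
    return ChainCoordinates(ids, ["ALA"] * n, atoms)


# -- place_tmd --------------------------------------------------------------


def test_place_tmd_aligns_axis_and_centres(toy_assembly):
    _, tmd, _, spec = toy_assembly
    placed = place_tmd(tmd, spec)
    axis = fit_helix_axis(placed, spec.embedded)
    assert abs(np.dot(axis.direction, Z)) >= 0.9998
    emb_mid = placed.subset(*spec.embedded).ca.mean(axis=0)
    assert abs(emb_mid[2]) < 1e-6
    # N-terminal (extracellular) end up
    assert placed.ca[0, 2] > placed.ca[-1, 2]


def test_place_tmd_charged_anchors_protrude(toy_assembly):
    """The 24-residue embedded stretch spans ~36 A against a 30 A slab, so
    the flanking anchor residues protrude beyond both faces."""
    _, tmd, _, spec = toy_assembly
    slab = MembraneSlab()
    placed = place_tmd(tmd, spec, slab)
    z210 = placed.ca[placed.index_of(210), 2]
    z235 = placed.ca[placed.index_of(235), 2]
    assert z210 > slab.z_upper
    assert z235 < slab.z_lower


def test_place_tmd_idempotent(toy_assembly):
    _, tmd, _, spec = toy_assembly
    once = place_tmd(tmd, spec)
    twice = place_tmd(once, spec)
    assert np.abs(once.ca - twice.ca).max() < 1e-3


# -- orient_ecd -------------------------------------------------------------


def test_orient_ecd_aligns_long_axis(toy_assembly):
    ecd, _, _, _ = toy_assembly
    oriented = orient_ecd(ecd)
    ca = oriented.ca
    X = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    assert abs(np.dot(vt[0], Z)) >= 0.9998
    # C terminus is membrane-proximal (lower)
    assert ca[-1, 2] < ca[0, 2]


def test_orient_ecd_idempotent(toy_assembly):
    ecd, _, _, _ = toy_assembly
    once = orient_ecd(ecd)
    twice = orient_ecd(once)
    assert np.abs(once.ca - twice.ca).max() < 1e-3


def test_orient_ecd_canonicalises_rotated_copies(toy_assembly, rng):
    ecd, _, _, _ = toy_assembly
    R = _rotation_between(Z, rng.normal(size=3))
    rotated = ecd.transformed(R, np.array([5.0, -2.0, 8.0]))
    a = orient_ecd(ecd)
    b = orient_ecd(rotated)
    for chain in (a, b):
        ca = chain.ca
        X = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        assert abs(np.dot(vt[0], Z)) >= 0.9998
        assert ca[-1, 2] < ca[0, 2]


def test_orient_ecd_too_small_errors():
    small = make_helix(1, 20)
    with pytest.raises(AssemblyError):
        orient_ecd(small)


# -- join_at_overlap --------------------------------------------------------


def test_join_identical_helices_overlap_five():
    up = make_helix(1, 20)
    down = make_helix(16, 20)  # same ideal conformation, congruent overlap
    merged, rmsd = join_at_overlap(up, down, (16, 20))
    assert rmsd <= 1e-6
    assert merged.n_residues == 2 * 20 - 5
    assert np.array_equal(merged.residue_ids, np.arange(1, 36))


def test_join_toy_domains_numbering(toy_assembly):
    ecd, tmd, _, spec = toy_assembly
    merged, rmsd = join_at_overlap(ecd, tmd, spec.overlap_ecd_tmd)
    assert rmsd <= 1e-6
    ids = merged.residue_ids
    assert ids[0] == 150 and ids[-1] == 240
    assert np.all(np.diff(ids) == 1)  # no gaps across the join


def test_join_short_overlap_errors():
    up = make_helix(1, 20)
    down = make_helix(19, 20)
    with pytest.raises(AssemblyError):
        join_at_overlap(up, down, (19, 20))


def test_join_incompatible_overlap_errors(toy_assembly):
    """Deforming the overlap window (one residue displaced far out of the
    shared conformation) makes the joint unusable: a rigid superposition
    cannot absorb it and the join refuses."""
    ecd, tmd, _, spec = toy_assembly
    lo, hi = spec.overlap_ecd_tmd
    mask = tmd.residue_ids == (lo + hi) // 2
    atoms = {k: v.copy() for k, v in tmd.atoms.items()}
    for k in atoms:
        atoms[k][mask] += np.array([20.0, 0.0, 0.0])
    corrupt = ChainCoordinates(tmd.residue_ids, tmd.residue_names, atoms)
    with pytest.raises(AssemblyError, match="incompatible"):
        join_at_overlap(ecd, corrupt, spec.overlap_ecd_tmd)


def test_join_associative_on_shared_atoms(toy_assembly):
    """(ECD+TMD)+ICD equals ECD+(TMD+ICD) on shared atoms for
    rigid-compatible overlaps."""
    ecd, tmd, icd, spec = toy_assembly
    conf = icd.conformers[0]
    left, _ = join_at_overlap(ecd, tmd, spec.overlap_ecd_tmd)
    left, _ = join_at_overlap(left, conf, spec.overlap_tmd_icd)
    right_inner, _ = join_at_overlap(tmd, conf, spec.overlap_tmd_icd)
    right, _ = join_at_overlap(ecd, right_inner, spec.overlap_ecd_tmd)
    assert np.array_equal(left.residue_ids, right.residue_ids)
    assert np.abs(left.ca - right.ca).max() < 1e-3


# -- membrane filter --------------------------------------------------------


def test_filter_keeps_below_and_rejects_inside():
    slab = MembraneSlab()
    exempt = (211, 234)
    below = synthetic_chain(np.arange(236, 246), np.linspace(-20, -60, 10))
    inside = synthetic_chain(np.arange(236, 246),
                             np.r_[np.linspace(-20, -16, 9), 0.0])
    kept, rejected = membrane_clash_filter([below, inside], slab, exempt)
    assert kept == [below]
    assert rejected == 1


def test_filter_exempt_range_may_occupy_slab():
    slab = MembraneSlab()
    tmd_like = synthetic_chain(np.arange(211, 235), np.linspace(17, -17, 24))
    kept, rejected = membrane_clash_filter([tmd_like], slab, exempt=(211, 234))
    assert kept and rejected == 0


# -- full assembly ----------------------------------------------------------


def test_full_toy_assembly_survivors_and_invariants(toy_assembly):
    ecd, tmd, icd, spec = toy_assembly
    slab = MembraneSlab()
    survivors, report = assemble_full_receptor(ecd, tmd, icd, spec, slab)
    assert 0 < report["n_survivors"] < report["n_input"]
    assert report["n_survivors"] + report["n_rejected"] == report["n_input"]
    for model in survivors:
        ids = model.chain.residue_ids
        assert np.all(np.diff(ids) == 1)  # single continuous numbering
        # exactly the exempt range may occupy the slab interior
        xyz = model.chain.heavy_coords(exclude_interval=spec.embedded)
        assert not np.any(slab.strictly_inside(xyz[:, 2]))
        emb_mid = model.chain.subset(*spec.embedded).ca.mean(axis=0)
        assert abs(emb_mid[2] - slab.centre) <= 2.0


def test_full_assembly_bit_reproducible(toy_assembly):
    from prlrkit.synthetic_data import gen_toy_domains, gen_toy_icd_ensemble

    def run():
        ecd, tmd, spec = gen_toy_domains(seed=3)
        icd = gen_toy_icd_ensemble(seed=3, n=12, length=40)
        return assemble_full_receptor(ecd, tmd, icd, spec)

    sa, ra = run()
    sb, rb = run()
    assert ra["n_survivors"] == rb["n_survivors"]
    for ma, mb in zip(sa, sb):
        assert np.array_equal(ma.chain.ca, mb.chain.ca)


def test_assembly_engineered_crossing_conformer_rejected(toy_assembly):
    ecd, tmd, icd, spec = toy_assembly
    # an ICD conformer driven straight up through the slab must be filtered out
    up = synthetic_chain(np.arange(236, 286), np.linspace(-18, 40, 50))
    kept, rejected = membrane_clash_filter([up], MembraneSlab(), spec.embedded)
    assert kept == [] and rejected == 1


# -- extent report ----------------------------------------------------------


def make_fraction_model():
    """Piecewise model mirroring the published proportions: ECD 70 A,
    TMD 36 A spanning the slab, ICD 240 A below."""
    ids, zs = [], []
    for rid, z in zip(range(150, 203), np.linspace(88, 18, 53)):       # ECD
        ids.append(rid), zs.append(z)
    for rid, z in zip(range(203, 210), np.linspace(17.9, 18.1, 7)):     # JML1
        ids.append(rid), zs.append(z)
    for rid, z in zip(range(210, 237), np.linspace(18, -18, 27)):       # TMD
        ids.append(rid), zs.append(z)
    for rid, z in zip(range(237, 243), np.linspace(-18.1, -18.9, 6)):   # JML2
        ids.append(rid), zs.append(z)
    for rid, z in zip(range(243, 501), np.linspace(-19, -259, 258)):    # ICD
        ids.append(rid), zs.append(z)
    chain = synthetic_chain(np.array(ids), np.array(zs))
    # strip the off-axis helper atoms so segment extents are purely vertical
    ca = chain.atoms["CA"]
    atoms = {k: ca.copy() for k in ("N", "CA", "C", "O")}
    chain = ChainCoordinates(chain.residue_ids, chain.residue_names, atoms)
    return FullReceptorModel(chain=chain, spec=AssemblySpec(ecd=(150, 202)))


def test_extent_fractions_match_constructed_proportions():
    model = make_fraction_model()
    total, fractions = extent_report(model)
    assert total == pytest.approx(88 + 259, abs=0.5)
    assert fractions["ecd"] == pytest.approx(0.20, abs=0.02)
    assert fractions["tmd"] == pytest.approx(0.10, abs=0.02)
    assert fractions["icd"] == pytest.approx(0.70, abs=0.02)
    assert fractions["ecd"] + fractions["tmd"] + fractions["icd"] <= 1.0 + 1e-9


def test_extent_single_helix_fraction_one():
    chain = synthetic_chain(np.arange(210, 237), np.linspace(18, -18, 27))
    model = FullReceptorModel(chain=chain, spec=AssemblySpec())
    _, fractions = extent_report(model)
    assert fractions["tmd"] == pytest.approx(1.0)
    assert fractions["ecd"] == 0.0 and fractions["icd"] == 0.0


def test_extent_invariant_under_z_translation():
    model = make_fraction_model()
    ref_total, ref_fr = extent_report(model)
    moved = FullReceptorModel(
        chain=model.chain.transformed(np.eye(3), np.array([0.0, 0.0, 123.0])),
        spec=model.spec)
    total, fr = extent_report(moved)
    assert total == pytest.approx(ref_total)
    for k in fr:
        assert fr[k] == pytest.approx(ref_fr[k])


def test_membrane_slab_and_spec_guards():
    with pytest.raises(AssemblyError):
        MembraneSlab(z_lower=5.0, z_upper=-5.0)
    with pytest.raises(AssemblyError):
        AssemblySpec(embedded=(100, 120))  # outside the TMD
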