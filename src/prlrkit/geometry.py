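"""Backbone construction and helix geometry.

Chains are built by standard internal-coordinate extension (NeRF) with ideal
bond lengths and angles; helix axes come from the principal direction of the
centred CA cloud, oriented N→C.  The helix "length" convention is
residue-count × 1.5 Å (the canonical α-helical rise), with the axis-projected
CA extent available as a secondary diagnostic — the two differ by exactly one
rise for an n-residue helix (n risers vs n−1 gaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .structio import ChainCoordinates

__all__ = [
    "DihedralSet",
    "HelixAxis",
    "RigidTransform",
    "RISE_PER_RESIDUE",
    "IDEAL_GEOMETRY",
    "build_backbone",
    "fit_helix_axis",
    "bend_angle",
    "helix_axial_length",
    "superpose",
    "ensemble_pairwise_rmsd",
    "place_atom",
    "measure_dihedral",
]

#: canonical α-helical rise per residue (Å)
RISE_PER_RESIDUE = 1.5

#: ideal bond lengths (Å) and angles (deg) for chain extension.  The N-CA-C
#: angle is the tetrahedral 109.5°, which reproduces the canonical 1.5 Å
#: rise for an ideal (-57, -47) helix.
IDEAL_GEOMETRY = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "CA_CB": 1.530,
    "ang_N_CA_C": 109.5,
    "ang_CA_C_N": 116.2,
    "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.8,
    "ang_N_CA_CB": 110.5,
    "tor_C_N_CA_CB": -122.5,
}


class GeometryError(ValueError):
    pass


@dataclass
class DihedralSet:
    """Backbone dihedrals per residue, degrees in (-180, 180]."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None  # defaults to trans (180°)

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 1:
            raise GeometryError("phi and psi must be 1-D arrays of equal length")
        if self.omega is None:
            self.omega = np.full_like(self.phi, 180.0)
        else:
            self.omega = np.asarray(self.omega, dtype=float)
            if self.omega.shape != self.phi.shape:
                raise GeometryError("omega length mismatch")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float) -> "DihedralSet":
        return cls(np.full(n, phi), np.full(n, psi))


@dataclass
class HelixAxis:
    origin: np.ndarray
    direction: np.ndarray  # unit vector, oriented N→C
    radius: float  # RMS CA distance to the axis (Å)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise GeometryError("axis direction must be a unit vector")
        if self.radius < 0:
            raise GeometryError("axis radius must be non-negative")


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# internal-coordinate placement


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d) given."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("colinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_arrays(dihedrals: DihedralSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = IDEAL_GEOMETRY
    n = len(dihedrals)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["N_CA"], 0.0, 0.0)
    th = np.deg2rad(g["ang_N_CA_C"])
    d_ca_n = (N[0] - CA[0]) / g["N_CA"]
    C[0] = CA[0] + g["CA_C"] * (d_ca_n * np.cos(th) + np.array([0.0, 1.0, 0.0]) * np.sin(th))
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], g["C_N"], g["ang_CA_C_N"],
                          dihedrals.psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], g["N_CA"], g["ang_C_N_CA"],
                           dihedrals.omega[i])
        C[i] = place_atom(C[i - 1], N[i], CA[i], g["CA_C"], g["ang_N_CA_C"],
                          dihedrals.phi[i])
    return N, CA, C


def _carbonyl_oxygens(N: np.ndarray, CA: np.ndarray, C: np.ndarray,
                      psi: np.ndarray) -> np.ndarray:
    # O is anti to the next amide nitrogen: torsion N-CA-C-O = psi - 180
    g = IDEAL_GEOMETRY
    O = np.empty_like(C)
    for i in range(len(C)):
        O[i] = place_atom(N[i], CA[i], C[i], g["C_O"], g["ang_CA_C_O"], psi[i] - 180.0)
    return O


def _beta_carbons(N: np.ndarray, CA: np.ndarray, C: np.ndarray,
                  names: list[str]) -> np.ndarray:
    g = IDEAL_GEOMETRY
    CB = np.full_like(CA, np.nan)
    for i, nm in enumerate(names):
        if nm == "GLY":
            continue
        CB[i] = place_atom(C[i], N[i], CA[i], g["CA_CB"], g["ang_N_CA_CB"],
                           g["tor_C_N_CA_CB"])
    return CB


def build_backbone(sequence: list[str], dihedrals: DihedralSet,
                   start_id: int = 1, with_cb: bool = True) -> ChainCoordinates:
    """Build an ideal-geometry backbone from a dihedral set.

    The first residue's N sits at the origin with CA on +x.  ``phi[0]`` and
    ``psi[-1]`` only influence CB/O placement of the terminal residues.
    """
    if len(sequence) == 0:
        raise GeometryError("empty sequence")
    if len(sequence) != len(dihedrals):
        raise GeometryError("sequence and dihedral lengths differ")
    names = [s.upper() for s in sequence]
    N, CA, C = _backbone_arrays(dihedrals)
    O = _carbonyl_oxygens(N, CA, C, dihedrals.psi)
    atoms = {"N": N, "CA": CA, "C": C, "O": O}
    if with_cb:
        atoms["CB"] = _beta_carbons(N, CA, C, names)
    ids = np.arange(start_id, start_id + len(names))
    chain = ChainCoordinates(ids, names, atoms)
    chain.validate_bonds()
    return chain


# ---------------------------------------------------------------------------
# helix measurements


def _pca_axis(ca: np.ndarray) -> np.ndarray:
    X = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return vt[0]


def _kahn_axis(ca: np.ndarray) -> np.ndarray | None:
    """Local-axis estimate from successive radial bisectors.

    For three consecutive CAs the bisector (P_{i-1}-P_i)+(P_{i+1}-P_i) points
    radially toward the helix axis; cross products of successive bisectors
    are parallel to the axis, independent of how many turns the segment
    spans (which biases a plain PCA fit).  Returns None for degenerate
    (near-straight) chains where the bisectors do not rotate.
    """
    H = (ca[:-2] - ca[1:-1]) + (ca[2:] - ca[1:-1])
    norms = np.linalg.norm(H, axis=1)
    if np.any(norms < 1e-6):
        return None
    cross = np.cross(H[:-1], H[1:])
    sin_mag = np.linalg.norm(cross, axis=1) / (norms[:-1] * norms[1:])
    if sin_mag.mean() < 0.2:  # bisectors barely rotate: not helical
        return None
    chain_vec = ca[-1] - ca[0]
    signs = np.where(cross @ chain_vec >= 0, 1.0, -1.0)
    axis = (cross * signs[:, None]).sum(axis=0)
    norm = np.linalg.norm(axis)
    return axis / norm if norm > 1e-9 else None


def fit_helix_axis(chain: ChainCoordinates, interval: tuple[int, int]) -> HelixAxis:
    """Helix axis over a residue interval, oriented N→C.

    The direction comes from the rotating-bisector construction (exact for
    ideal helices regardless of partial turns); near-straight segments fall
    back to the principal direction of the CA cloud.  The radius is the RMS
    CA distance to the axis, with the axis position set by a least-squares
    circle fit in the plane perpendicular to the direction.
    """
    seg = chain.subset(*interval)
    if seg.n_residues < 7:
        raise GeometryError(
            f"need >= 7 residues to fit a helix axis, got {seg.n_residues}"
        )
    ca = seg.ca
    direction = _kahn_axis(ca)
    if direction is None:
        direction = _pca_axis(ca)
    if np.dot(ca[-1] - ca[0], direction) < 0:
        direction = -direction
    # in-plane circle fit (Kåsa): centre of the projected CA ring
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    x, y = ca @ e1, ca @ e2
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    cx, cy = sol[0], sol[1]
    radius = float(np.sqrt(np.mean((x - cx) ** 2 + (y - cy) ** 2)))
    origin = cx * e1 + cy * e2 + np.mean(ca @ direction) * direction
    return HelixAxis(origin=origin, direction=direction, radius=radius)


def bend_angle(chain: ChainCoordinates, range1: tuple[int, int],
               range2: tuple[int, int]) -> float:
    """Angle in degrees between the helix axes fitted on two disjoint segments."""
    if not (range1[1] < range2[0] or range2[1] < range1[0]):
        raise GeometryError(f"ranges {range1} and {range2} overlap")
    ax1 = fit_helix_axis(chain, range1)
    ax2 = fit_helix_axis(chain, range2)
    cosang = float(np.clip(np.dot(ax1.direction, ax2.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def helix_axial_length(interval: tuple[int, int],
                       chain: ChainCoordinates | None = None):
    """Helix length as residue-count × 1.5 Å.

    With a chain supplied, also returns the CA extent projected on the fitted
    axis (one rise shorter for an ideal helix: n-1 gaps between n residues).
    """
    first, last = interval
    count = last - first + 1
    if count < 1:
        raise GeometryError(f"empty residue interval {interval}")
    nominal = count * RISE_PER_RESIDUE
    if chain is None:
        return nominal
    axis = fit_helix_axis(chain, interval)
    ca = chain.subset(*interval).ca
    proj = (ca - axis.origin) @ axis.direction
    return nominal, float(proj.max() - proj.min())


# ---------------------------------------------------------------------------
# superposition


def _selected_coords(chain: ChainCoordinates, interval: tuple[int, int],
                     atom_names: tuple[str, ...]) -> np.ndarray:
    seg = chain.subset(*interval)
    rows = []
    for name in atom_names:
        if name not in seg.atoms:
            raise GeometryError(f"atom {name!r} not present in chain")
        rows.append(seg.atoms[name])
    xyz = np.concatenate(rows, axis=0)
    if not np.isfinite(xyz).all():
        raise GeometryError("selection contains missing atoms")
    return xyz


def superpose(mobile: ChainCoordinates, reference: ChainCoordinates,
              interval: tuple[int, int],
              atom_names: tuple[str, ...] = ("N", "CA", "C", "O"),
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal transform and the minimum RMSD over the selection.
    """
    x = _selected_coords(mobile, interval, atom_names)
    y = _selected_coords(reference, interval, atom_names)
    if x.shape != y.shape:
        raise GeometryError("selection sizes differ between chains")
    if len(x) < 3:
        raise GeometryError("need at least 3 atoms to superpose")
    sup = SVDSuperimposer()
    sup.set(y, x)  # reference, mobile
    sup.run()
    rot, tran = sup.get_rotran()
    # SVDSuperimposer applies x @ rot + tran; convert to row-vector R @ x + t form
    transform = RigidTransform(rotation=rot.T, translation=tran)
    return transform, float(sup.get_rms())


def ensemble_pairwise_rmsd(models: list[ChainCoordinates],
                           interval: tuple[int, int],
                           atom_names: tuple[str, ...] = ("N", "CA", "C", "O"),
                           ) -> tuple[float, float]:
    """Mean and SD of RMSD over all unordered model pairs, each pair superposed."""
    if len(models) < 2:
        raise GeometryError("need at least 2 models")
    sizes = {_selected_coords(m, interval, atom_names).shape for m in models}
    if len(sizes) != 1:
        raise GeometryError("inconsistent selections across models")
    rmsds = []
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            _, r = superpose(models[i], models[j], interval, atom_names)
            rmsds.append(r)
    rmsds = np.asarray(rmsds)
    return float(rmsds.mean()), float(rmsds.std())
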