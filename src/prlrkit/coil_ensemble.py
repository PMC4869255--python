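"""Statistical-coil conformer generation for intrinsically disordered chains.

Conformers are built residue by residue: each residue draws a (φ, ψ) pair
from a residue-class coil library (generic / glycine / proline /
pre-proline) and the backbone is extended with ideal geometry.  Self-avoidance
is enforced at the CA level: whenever a newly placed CA comes within the
clash cutoff of any CA at sequence separation >= 3, the builder rewinds a few
residues and redraws, within a bounded attempt budget.  Identical
(sequence, n, library, seed) inputs give bit-identical ensembles.

The bundled library is a declared surrogate for the residue-specific coil
distributions used by database-driven generators: discrete basin points on
the Ramachandran map with weights ~0.3/0.3/0.4 over the α/β/PPII basins for
generic residues.  It is swappable via a plain-text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import IDEAL_GEOMETRY, place_atom, _carbonyl_oxygens, _beta_carbons
from .structio import ChainCoordinates

__all__ = [
    "CoilLibrary",
    "ConformerEnsemble",
    "ChainStatistics",
    "DEFAULT_COIL_LIBRARY",
    "residue_class",
    "sample_conformer",
    "generate_ensemble",
    "chain_statistics",
    "surrogate_sequence",
]


class CoilSamplingError(RuntimeError):
    pass


RESIDUE_CLASSES = ("generic", "glycine", "proline", "pre_proline")


@dataclass
class CoilLibrary:
    """Discrete (φ, ψ) pairs with sampling weights per residue class."""

    classes: dict  # class name -> (pairs (k, 2) float array, weights (k,) array)
    library_id: str = "builtin-basins-v1"

    def __post_init__(self):
        for name in RESIDUE_CLASSES:
            if name not in self.classes:
                raise ValueError(f"coil library missing class {name!r}")
        normed = {}
        for name, (pairs, weights) in self.classes.items():
            pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
            weights = np.asarray(weights, dtype=float)
            if len(pairs) == 0:
                raise ValueError(f"coil-library class {name!r} is empty")
            if np.any(weights <= 0):
                raise ValueError(f"non-positive weight in class {name!r}")
            normed[name] = (pairs, weights / weights.sum())
        self.classes = normed

    def draw(self, class_name: str, rng: np.random.Generator) -> tuple[float, float]:
        pairs, weights = self.classes[class_name]
        k = rng.choice(len(pairs), p=weights)
        return float(pairs[k, 0]), float(pairs[k, 1])

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# coil library {self.library_id}\n# class phi psi weight\n")
            for name, (pairs, weights) in self.classes.items():
                for (phi, psi), w in zip(pairs, weights):
                    fh.write(f"{name}\t{phi:.1f}\t{psi:.1f}\t{w:.6f}\n")

    @classmethod
    def from_file(cls, path: str, library_id: str | None = None) -> "CoilLibrary":
        raw: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, phi, psi, w = line.split()
                raw.setdefault(name, []).append((float(phi), float(psi), float(w)))
        classes = {
            name: (np.array([(p, s) for p, s, _ in rows]),
                   np.array([w for _, _, w in rows]))
            for name, rows in raw.items()
        }
        return cls(classes, library_id=library_id or str(path))


def _default_library() -> CoilLibrary:
    # generic: alpha/beta/PPII basins, weights ~0.3/0.3/0.4
    generic_pairs = [
        (-63, -43), (-70, -35), (-57, -47),       # alpha
        (-120, 130), (-135, 150), (-110, 120),    # beta
        (-75, 145), (-65, 150), (-75, 160),       # PPII
    ]
    generic_w = [0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.14, 0.13, 0.13]
    glycine_pairs = [
        (-80, 170), (80, -170), (-170, 170), (170, -170),
        (90, 0), (-90, 0),
    ]
    glycine_w = [0.25, 0.25, 0.15, 0.15, 0.10, 0.10]
    proline_pairs = [(-65, 150), (-65, 145), (-65, -35)]
    proline_w = [0.35, 0.30, 0.35]
    pre_proline_pairs = [(-120, 150), (-70, 150), (-135, 160)]
    pre_proline_w = [0.4, 0.3, 0.3]
    return CoilLibrary({
        "generic": (np.array(generic_pairs), np.array(generic_w)),
        "glycine": (np.array(glycine_pairs), np.array(glycine_w)),
        "proline": (np.array(proline_pairs), np.array(proline_w)),
        "pre_proline": (np.array(pre_proline_pairs), np.array(pre_proline_w)),
    })


DEFAULT_COIL_LIBRARY = _default_library()


def residue_class(names: list[str], i: int) -> str:
    name = names[i].upper()
    if name == "GLY":
        return "glycine"
    if name == "PRO":
        return "proline"
    if i + 1 < len(names) and names[i + 1].upper() == "PRO":
        return "pre_proline"
    return "generic"


def surrogate_sequence(n: int = 363, proline_fraction: float = 0.05,
                       seed: int = 20) -> list[str]:
    """Generic disordered-chain surrogate: uniform composition with ~5%
    prolines, deterministic under seed.  Stands in for a real intracellular
    domain sequence so tests and desk-scale runs need no download."""
    rng = np.random.default_rng(seed)
    pool = ["ALA", "SER", "GLU", "LYS", "GLN", "THR", "VAL", "LEU", "ASP",
            "ASN", "ARG", "ILE", "MET", "PHE", "TYR", "HIS", "TRP", "CYS", "GLY"]
    names = [pool[rng.integers(len(pool))] for _ in range(n)]
    n_pro = int(round(proline_fraction * n))
    pos = rng.choice(np.arange(1, n - 1), size=n_pro, replace=False)
    for p in pos:
        names[int(p)] = "PRO"
    return names


@dataclass
class ConformerEnsemble:
    conformers: list  # of ChainCoordinates
    seed: int
    library_id: str
    clash_cutoff: float
    attempts: int = 0  # total redraws across the ensemble

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("empty ensemble")
        seqs = {tuple(c.residue_names) for c in self.conformers}
        if len(seqs) != 1:
            raise ValueError("conformers must share one sequence")

    def __len__(self) -> int:
        return len(self.conformers)


# ---------------------------------------------------------------------------
# sampling


def sample_conformer(sequence: list[str],
                     library: CoilLibrary = DEFAULT_COIL_LIBRARY,
                     clash_cutoff: float = 4.0,
                     seed: int | np.random.Generator = 0,
                     start_id: int = 1,
                     fixed_dihedrals: dict | None = None,
                     max_redraws: int = 10_000,
                     rewind: int = 5) -> tuple[ChainCoordinates, int]:
    """Draw one self-avoiding statistical-coil conformer.

    ``fixed_dihedrals`` optionally pins (φ, ψ) for specific residue ids
    (used to keep an overlap window in a prescribed conformation).  Returns
    the chain and the number of redraws spent.  Raises CoilSamplingError,
    naming the stuck residue, when the redraw budget is exhausted.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    names = [s.upper() for s in sequence]
    n = len(names)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fixed = fixed_dihedrals or {}
    g = IDEAL_GEOMETRY

    def draw(i: int) -> tuple[float, float]:
        rid = start_id + i
        if rid in fixed:
            return fixed[rid]
        return library.draw(residue_class(names, i), rng)

    phis = np.empty(n)
    psis = np.empty(n)
    for i in range(n):
        phis[i], psis[i] = draw(i)

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    CA[0] = (g["N_CA"], 0.0, 0.0)
    th = np.deg2rad(g["ang_N_CA_C"])
    d_ca_n = (N[0] - CA[0]) / g["N_CA"]
    C[0] = CA[0] + g["CA_C"] * (d_ca_n * np.cos(th) + np.array([0.0, 1.0, 0.0]) * np.sin(th))

    cutoff_sq = clash_cutoff * clash_cutoff
    redraws = 0
    i = 1
    while i < n:
        Ni = place_atom(N[i - 1], CA[i - 1], C[i - 1], g["C_N"], g["ang_CA_C_N"],
                        psis[i - 1])
        CAi = place_atom(CA[i - 1], C[i - 1], Ni, g["N_CA"], g["ang_C_N_CA"], 180.0)
        Ci = place_atom(C[i - 1], Ni, CAi, g["CA_C"], g["ang_N_CA_C"], phis[i])
        if i >= 3:
            d2 = np.einsum("ij,ij->i", CA[:i - 2] - CAi, CA[:i - 2] - CAi)
            if d2.min() < cutoff_sq:
                redraws += 1
                if redraws > max_redraws:
                    raise CoilSamplingError(
                        f"redraw budget exhausted while placing residue {start_id + i}"
                    )
                back = max(1, i - rewind)
                for k in range(back, i + 1):
                    phis[k], psis[k] = draw(k)
                i = back
                continue
        N[i], CA[i], C[i] = Ni, CAi, Ci
        i += 1

    O = _carbonyl_oxygens(N, CA, C, psis)
    CB = _beta_carbons(N, CA, C, names)
    ids = np.arange(start_id, start_id + n)
    chain = ChainCoordinates(ids, names, {"N": N, "CA": CA, "C": C, "O": O, "CB": CB})
    return chain, redraws


def generate_ensemble(sequence: list[str], n: int,
                      library: CoilLibrary = DEFAULT_COIL_LIBRARY,
                      seed: int = 0,
                      clash_cutoff: float = 4.0,
                      start_id: int = 1,
                      fixed_dihedrals: dict | None = None) -> ConformerEnsemble:
    """n independent conformers with per-conformer seeds spawned
    deterministically from the master seed."""
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n)
    conformers = []
    attempts = 0
    for ss in streams:
        chain, redraws = sample_conformer(
            sequence, library=library, clash_cutoff=clash_cutoff,
            seed=np.random.default_rng(ss), start_id=start_id,
            fixed_dihedrals=fixed_dihedrals,
        )
        conformers.append(chain)
        attempts += redraws
    return ConformerEnsemble(conformers=conformers, seed=seed,
                             library_id=library.library_id,
                             clash_cutoff=clash_cutoff, attempts=attempts)


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class ChainStatistics:
    mean_rg: float
    mean_end_to_end: float
    nu: float  # apparent scaling exponent from sub-chain Rg vs length
    subchain_lengths: np.ndarray = field(default=None)
    subchain_rg: np.ndarray = field(default=None)


def _radius_of_gyration(ca: np.ndarray) -> float:
    x = ca - ca.mean(axis=0)
    return float(np.sqrt((x ** 2).sum(axis=1).mean()))


def chain_statistics(ensemble: ConformerEnsemble,
                     min_subchain: int = 20) -> ChainStatistics:
    """Ensemble-mean Rg, end-to-end distance, and the apparent Flory exponent
    ν from regressing log(mean sub-chain Rg) on log(sub-chain length)."""
    if len(ensemble) < 20:
        raise ValueError("need at least 20 conformers for chain statistics")
    cas = [c.ca for c in ensemble.conformers]
    nres = cas[0].shape[0]
    rgs = np.array([_radius_of_gyration(ca) for ca in cas])
    e2e = np.array([np.linalg.norm(ca[-1] - ca[0]) for ca in cas])
    lengths = np.unique(np.geomspace(min_subchain, nres, num=6).astype(int))
    mean_rg_per_length = []
    for L in lengths:
        offsets = np.linspace(0, nres - L, num=min(4, nres - L + 1)).astype(int)
        vals = [
            _radius_of_gyration(ca[o:o + L])
            for ca in cas
            for o in offsets
        ]
        mean_rg_per_length.append(np.mean(vals))
    mean_rg_per_length = np.array(mean_rg_per_length)
    nu = float(np.polyfit(np.log(lengths), np.log(mean_rg_per_length), 1)[0])
    return ChainStatistics(
        mean_rg=float(rgs.mean()),
        mean_end_to_end=float(e2e.mean()),
        nu=nu,
        subchain_lengths=lengths,
        subchain_rg=mean_rg_per_length,
    )
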