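"""Core structural containers and file IO.

Everything downstream (helix geometry, coil sampling, hydrodynamics, SAXS,
assembly) speaks in terms of the types defined here.  Coordinates are in
Ångström throughout; residue numbering is the mature-receptor numbering
(1-based, Q1 = first extracellular residue), and the membrane normal is the
global +z axis.

Supported formats: multi-model PDB (fixed-column ATOM records, chain 'A'),
chemical-shift tables as CSV or a reduced NMR-STAR loop dialect, 2-3 column
whitespace-delimited SAXS curves with '#' comments.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ChainCoordinates",
    "ChemicalShiftTable",
    "ScatteringCurve",
    "DecaySeries",
    "StructIOError",
    "PDBParseError",
    "read_pdb_models",
    "write_pdb",
    "read_shift_table",
    "read_saxs_curve",
]

#: heavy atoms carried per residue, in canonical output order
BACKBONE_ATOMS = ("N", "CA", "C", "O")
ATOM_ORDER = ("N", "CA", "C", "O", "CB")

#: bonded-geometry invariants (Å)
CA_CA_BOND = (3.80, 0.15)
C_N_BOND = (1.33, 0.05)

SHIFT_ATOMS = ("CA", "CB", "C", "HA", "N", "HN")

#: plausible ppm windows per nucleus, used to reject corrupt tables
PPM_RANGES = {
    "CA": (40.0, 70.0),
    "CB": (10.0, 75.0),
    "C": (165.0, 185.0),
    "HA": (2.0, 7.0),
    "N": (100.0, 140.0),
    "HN": (5.0, 12.0),
}


class StructIOError(ValueError):
    """Raised when an input file violates a container invariant."""


class PDBParseError(StructIOError):
    """Raised for malformed PDB records, naming the offending line."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ChainCoordinates:
    """Per-residue backbone coordinates of a single chain.

    ``atoms`` maps atom name -> (n, 3) array; rows are NaN where the atom is
    absent (CB on glycine, optional CB elsewhere).  ``tag_residues`` marks
    expression-tag residues (e.g. the G-S pair preceding the TMD construct)
    that carry construct-local numbering.
    """

    residue_ids: np.ndarray
    residue_names: list[str]
    atoms: dict[str, np.ndarray]
    tag_residues: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = len(self.residue_ids)
        if len(self.residue_names) != n:
            raise StructIOError("residue_names length does not match residue_ids")
        if n == 0:
            raise StructIOError("empty chain")
        if n > 1 and not np.all(np.diff(self.residue_ids) > 0):
            raise StructIOError("residue_ids must be strictly increasing")
        for name, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (n, 3):
                raise StructIOError(f"atom array {name!r} has shape {arr.shape}, expected {(n, 3)}")
            self.atoms[name] = arr
        for name in BACKBONE_ATOMS:
            if name not in self.atoms:
                raise StructIOError(f"backbone atom {name!r} missing from chain")
            bad = np.nonzero(~np.isfinite(self.atoms[name]).all(axis=1))[0]
            if bad.size:
                rid = self.residue_ids[bad[0]]
                raise StructIOError(f"missing backbone atom {name} on residue {rid}")

    # -- basic queries ------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def index_of(self, residue_id: int) -> int:
        idx = np.searchsorted(self.residue_ids, residue_id)
        if idx >= len(self.residue_ids) or self.residue_ids[idx] != residue_id:
            raise KeyError(f"residue {residue_id} not in chain")
        return int(idx)

    def subset(self, first: int, last: int) -> "ChainCoordinates":
        """Residues with ``first <= id <= last`` (inclusive interval)."""
        mask = (self.residue_ids >= first) & (self.residue_ids <= last)
        if not mask.any():
            raise KeyError(f"interval {first}-{last} not in chain")
        return ChainCoordinates(
            residue_ids=self.residue_ids[mask],
            residue_names=[nm for nm, m in zip(self.residue_names, mask) if m],
            atoms={k: v[mask] for k, v in self.atoms.items()},
            tag_residues=frozenset(t for t in self.tag_residues if first <= t <= last),
        )

    def heavy_coords(self, exclude_interval: tuple[int, int] | None = None) -> np.ndarray:
        """All finite atom positions, optionally dropping a residue interval."""
        keep = np.ones(self.n_residues, dtype=bool)
        if exclude_interval is not None:
            lo, hi = exclude_interval
            keep &= ~((self.residue_ids >= lo) & (self.residue_ids <= hi))
        chunks = []
        for name in ATOM_ORDER:
            if name not in self.atoms:
                continue
            xyz = self.atoms[name][keep]
            chunks.append(xyz[np.isfinite(xyz).all(axis=1)])
        return np.concatenate(chunks, axis=0) if chunks else np.empty((0, 3))

    def all_coords(self) -> np.ndarray:
        return self.heavy_coords()

    # -- geometry helpers ---------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainCoordinates":
        """Return a rigidly moved copy: x -> R @ x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = {k: v @ R.T + t for k, v in self.atoms.items()}
        return replace(self, atoms=new_atoms)

    def validate_bonds(self) -> None:
        """Check CA-CA and peptide C-N distances for consecutively numbered residues."""
        ids = self.residue_ids
        consecutive = np.diff(ids) == 1
        dca = np.linalg.norm(self.ca[1:] - self.ca[:-1], axis=1)
        mu, tol = CA_CA_BOND
        bad = consecutive & np.isfinite(dca) & (np.abs(dca - mu) > tol)
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise StructIOError(
                f"CA-CA distance {dca[i]:.2f} Å between residues "
                f"{ids[i]}-{ids[i + 1]} outside {mu}±{tol} Å"
            )
        dcn = np.linalg.norm(self.atoms["N"][1:] - self.atoms["C"][:-1], axis=1)
        mu, tol = C_N_BOND
        bad = consecutive & np.isfinite(dcn) & (np.abs(dcn - mu) > tol)
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise StructIOError(
                f"peptide C-N bond {dcn[i]:.2f} Å between residues "
                f"{ids[i]}-{ids[i + 1]} outside {mu}±{tol} Å"
            )


@dataclass
class ChemicalShiftTable:
    """Observed chemical shifts, one row per (residue, atom)."""

    frame: pd.DataFrame  # columns: residue_id, residue_name, atom_name, shift

    def __post_init__(self):
        required = {"residue_id", "residue_name", "atom_name", "shift"}
        if not required.issubset(self.frame.columns):
            raise StructIOError(f"shift table needs columns {sorted(required)}")
        dup = self.frame.duplicated(subset=["residue_id", "atom_name"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise StructIOError(
                f"duplicate shift entry for residue {row.residue_id} atom {row.atom_name}"
            )
        if not np.isfinite(self.frame["shift"]).all():
            raise StructIOError("non-finite chemical shift in table")
        for atom, (lo, hi) in PPM_RANGES.items():
            vals = self.frame.loc[self.frame.atom_name == atom, "shift"]
            if len(vals) and ((vals < lo) | (vals > hi)).any():
                raise StructIOError(f"{atom} shift outside plausible range [{lo}, {hi}] ppm")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def residue_ids(self) -> np.ndarray:
        return np.sort(self.frame["residue_id"].unique())

    def get(self, residue_id: int, atom_name: str) -> float | None:
        sel = self.frame[
            (self.frame.residue_id == residue_id) & (self.frame.atom_name == atom_name)
        ]
        return float(sel["shift"].iloc[0]) if len(sel) else None

    def residue_name(self, residue_id: int) -> str:
        sel = self.frame[self.frame.residue_id == residue_id]
        return str(sel["residue_name"].iloc[0])


@dataclass
class ScatteringCurve:
    """Small-angle scattering curve: momentum transfer q (Å⁻¹), intensity, uncertainty."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise StructIOError("q and intensity must be 1-D arrays of equal length")
        if len(self.q) and (np.any(self.q < 0) or np.any(np.diff(self.q) <= 0)):
            raise StructIOError("q must be non-negative and strictly increasing")
        if np.any(self.intensity < 0):
            raise StructIOError("negative intensity in scattering curve")
        if self.sigma is None:
            self.sigma = np.maximum(0.01 * self.intensity, 1e-12)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise StructIOError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise StructIOError("sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class DecaySeries:
    """1-D decay: relaxation delays (ms) or gradient strengths vs intensities."""

    x: np.ndarray
    y: np.ndarray
    kind: str  # "relaxation" | "diffusion"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in ("relaxation", "diffusion"):
            raise StructIOError(f"unknown decay kind {self.kind!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise StructIOError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 4:
            raise StructIOError("decay series needs at least 4 points for fitting")
        if np.any(np.diff(self.x) <= 0):
            raise StructIOError("x must be strictly increasing")
        if not np.isfinite(self.y).all():
            raise StructIOError("non-finite intensity in decay series")


# ---------------------------------------------------------------------------
# PDB IO


def _prescan_pdb(path: str) -> None:
    # produce line-numbered errors for malformed coordinate fields before
    # handing the file to gemmi (which is lenient about them)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None


def read_pdb_models(path: str, validate: bool = True) -> list[ChainCoordinates]:
    """Read a (multi-model) PDB file into one ChainCoordinates per MODEL.

    Only the first chain of each model is read; N/CA/C/O are required per
    residue (CB optional, tolerated missing on glycine and elsewhere).
    """
    _prescan_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    models = []
    for model in st:
        if len(model) == 0:
            continue
        chain = model[0]
        ids, names, rows = [], [], []
        for res in chain:
            pos = {}
            for atom in res:
                if atom.name in ATOM_ORDER and atom.name not in pos:
                    pos[atom.name] = [atom.pos.x, atom.pos.y, atom.pos.z]
            ids.append(res.seqid.num)
            names.append(res.name)
            rows.append(pos)
        atoms = {}
        for name in ATOM_ORDER:
            if name == "CB" and not any(name in r for r in rows):
                continue
            atoms[name] = np.array(
                [r.get(name, [np.nan] * 3) for r in rows], dtype=float
            )
        cc = ChainCoordinates(np.array(ids), names, atoms)
        if validate:
            cc.validate_bonds()
        models.append(cc)
    if not models:
        raise PDBParseError(f"no models with atoms found in {path}")
    return models


def write_pdb(models: list[ChainCoordinates] | ChainCoordinates, path: str) -> None:
    """Write models as a multi-model PDB (MODEL/ENDMDL per conformer, chain A)."""
    if isinstance(models, ChainCoordinates):
        models = [models]
    if not models:
        raise StructIOError("cannot write an empty model list")
    multi = len(models) > 1
    buf = io.StringIO()
    for imodel, cc in enumerate(models, start=1):
        if multi:
            buf.write(f"MODEL     {imodel:4d}\n")
        serial = 1
        for i, (rid, rname) in enumerate(zip(cc.residue_ids, cc.residue_names)):
            for aname in ATOM_ORDER:
                if aname not in cc.atoms:
                    continue
                xyz = cc.atoms[aname][i]
                if not np.isfinite(xyz).all():
                    continue
                pad = aname.ljust(3)
                buf.write(
                    f"ATOM  {serial:5d}  {pad} {rname:>3s} A{rid:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {aname[0]:>2s}\n"
                )
                serial += 1
        buf.write("TER\n")
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# shift tables


def _read_shift_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in ("residue_id", "res_id", "seq_id", "residue"):
            rename[col] = "residue_id"
        elif key in ("residue_name", "res_name", "comp_id"):
            rename[col] = "residue_name"
        elif key in ("atom_name", "atom", "atom_id"):
            rename[col] = "atom_name"
        elif key in ("shift", "value", "val", "chemical_shift"):
            rename[col] = "shift"
    df = df.rename(columns=rename)
    missing = {"residue_id", "residue_name", "atom_name", "shift"} - set(df.columns)
    if missing:
        raise StructIOError(f"shift CSV missing columns: {sorted(missing)}")
    return df


def _read_shift_nmrstar_lite(path: str) -> pd.DataFrame:
    """Reduced NMR-STAR reader: one ``loop_`` with _Atom_chem_shift tags.

    Handles the column subset used by backbone-assignment depositions:
    Seq_ID / Comp_ID / Atom_ID / Val (with or without the
    ``_Atom_chem_shift.`` prefix).  Full NMR-STAR is out of scope.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = header_done = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "loop_":
                in_loop, header_done, tags = True, False, []
                continue
            if not in_loop:
                continue
            if line.startswith("_"):
                if header_done:  # a second header block: previous loop had no data
                    tags, header_done = [line], False
                else:
                    tags.append(line)
                continue
            if line in ("stop_", "save_"):
                if rows:
                    break
                in_loop = False
                continue
            header_done = True
            rows.append(line.split())
    if not tags or not rows:
        raise StructIOError(f"no chemical-shift loop found in {path}")
    norm = [t.split(".")[-1].lstrip("_").lower() for t in tags]

    def col(*cands):
        for c in cands:
            if c in norm:
                return norm.index(c)
        raise StructIOError(f"NMR-STAR loop lacks a {cands[0]} column")

    i_seq = col("seq_id", "residue_id")
    i_comp = col("comp_id", "residue_name")
    i_atom = col("atom_id", "atom_name")
    i_val = col("val", "value", "shift")
    data = []
    for row in rows:
        if len(row) != len(tags):
            raise StructIOError(f"NMR-STAR data row has {len(row)} fields, expected {len(tags)}")
        data.append((int(row[i_seq]), row[i_comp].upper(), row[i_atom].upper(), float(row[i_val])))
    return pd.DataFrame(data, columns=["residue_id", "residue_name", "atom_name", "shift"])


def read_shift_table(path: str, dialect: str = "csv") -> ChemicalShiftTable:
    """Read a chemical-shift table (``csv`` or ``nmrstar_lite`` dialect).

    Rows with unsupported atom names are skipped with a warning; duplicate
    (residue, atom) rows raise.
    """
    if dialect == "csv":
        df = _read_shift_csv(path)
    elif dialect == "nmrstar_lite":
        df = _read_shift_nmrstar_lite(path)
    else:
        raise StructIOError(f"unknown shift-table dialect {dialect!r}")
    df["atom_name"] = df["atom_name"].astype(str).str.upper().str.strip()
    df["residue_name"] = df["residue_name"].astype(str).str.upper().str.strip()
    known = df["atom_name"].isin(SHIFT_ATOMS)
    if (~known).any():
        skipped = sorted(df.loc[~known, "atom_name"].unique())
        warnings.warn(f"skipping unsupported atom names: {skipped}", stacklevel=2)
        df = df[known]
    df = df.reset_index(drop=True)
    df["residue_id"] = df["residue_id"].astype(int)
    df["shift"] = df["shift"].astype(float)
    return ChemicalShiftTable(df)


# ---------------------------------------------------------------------------
# SAXS curves


def read_saxs_curve(path: str) -> ScatteringCurve:
    """Read a 2-3 column whitespace-delimited SAXS .dat file ('#' comments)."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] not in (2, 3):
        raise StructIOError(f"expected 2 or 3 columns in SAXS file, got {data.shape[1]}")
    q, intensity = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] == 3 else None
    return ScatteringCurve(q=q, intensity=intensity, sigma=sigma)


def average_molecular_mass(sequence: str) -> float:
    """Average (isotope-abundance-weighted) molecular mass of a peptide in Da.

    ``sequence`` is a one-letter amino-acid string; used to check construct
    identities against masses observed by native mass spectrometry.
    """
    from Bio.SeqUtils import molecular_weight

    return float(molecular_weight(sequence.upper(), seq_type="protein",
                                  monoisotopic=False))


def write_saxs_curve(curve: ScatteringCurve, path: str) -> None:
    np.savetxt(
        path,
        np.column_stack([curve.q, curve.intensity, curve.sigma]),
        header="q(1/A) I(q) sigma",
        fmt="%.6e",
    )
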