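"""Random-coil chemical-shift reference values.

Bundled random-coil shifts (ppm) for CA, CB, C' and HA of the 20 standard
residues, after the widely used solution random-coil compilations (Wishart
and co-workers).  Synthetic test data are generated *from* this table, so
test outcomes do not depend on which published compilation is shipped; only
deviations (secondary shifts) from the bundled reference matter.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RandomCoilTable", "DEFAULT_RANDOM_COIL"]

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_COIL_SHIFTS = {
    #          CA     CB     C      HA
    "ALA": (52.5, 19.1, 177.8, 4.32),
    "ARG": (56.0, 30.9, 176.3, 4.34),
    "ASN": (52.8, 38.9, 175.2, 4.74),
    "ASP": (54.2, 41.1, 176.3, 4.64),
    "CYS": (58.2, 28.0, 174.6, 4.55),
    "GLN": (56.6, 29.2, 176.0, 4.34),
    "GLU": (56.6, 29.9, 176.6, 4.35),
    "GLY": (45.1, None, 174.9, 3.96),
    "HIS": (55.0, 29.0, 174.1, 4.73),
    "ILE": (61.1, 38.8, 176.4, 4.17),
    "LEU": (55.1, 42.4, 177.6, 4.34),
    "LYS": (56.2, 33.1, 176.6, 4.32),
    "MET": (55.4, 32.9, 176.3, 4.48),
    "PHE": (57.7, 39.6, 175.8, 4.62),
    "PRO": (63.3, 32.1, 177.3, 4.42),
    "SER": (58.3, 63.8, 174.6, 4.47),
    "THR": (61.8, 69.8, 174.7, 4.35),
    "TRP": (57.5, 29.6, 176.1, 4.66),
    "TYR": (57.9, 38.8, 175.9, 4.55),
    "VAL": (62.2, 32.9, 176.3, 4.12),
}


@dataclass(frozen=True)
class RandomCoilTable:
    """Per (residue, atom) random-coil shifts; complete for the 20 standard residues."""

    values: dict  # (residue_name, atom_name) -> ppm

    def __post_init__(self):
        for res in STANDARD_RESIDUES:
            for atom in ("CA", "C", "HA"):
                if (res, atom) not in self.values:
                    raise ValueError(f"random-coil table incomplete: missing {res} {atom}")
            if res != "GLY" and (res, "CB") not in self.values:
                raise ValueError(f"random-coil table incomplete: missing {res} CB")

    def get(self, residue_name: str, atom_name: str) -> float | None:
        return self.values.get((residue_name.upper(), atom_name.upper()))

    def supports(self, residue_name: str) -> bool:
        return (residue_name.upper(), "CA") in self.values


def _build_default() -> RandomCoilTable:
    values = {}
    for res, (ca, cb, c, ha) in _COIL_SHIFTS.items():
        values[(res, "CA")] = ca
        values[(res, "C")] = c
        values[(res, "HA")] = ha
        if cb is not None:
            values[(res, "CB")] = cb
    return RandomCoilTable(values)


DEFAULT_RANDOM_COIL = _build_default()
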