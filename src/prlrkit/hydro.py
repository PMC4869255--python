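"""Hydrodynamic-radius prediction and measurement.

Per-conformer R_H comes from the Kirkwood bead approximation with one bead
per residue at CA:

    1/R_H = (1/N²) · (N/a + Σ_{i≠j} 1/r_ij)

which has the correct single-bead (R_H = a) and far-separated two-bead
limits.  Ensemble values are harmonic means <R_H⁻¹>⁻¹, matching how a
rapidly inter-converting ensemble contributes to a diffusion measurement.
Experimental R_H extraction uses paired pulsed-field-gradient decays of the
protein and a reference compound of known R_H: each decay is fitted as
S = S₀·exp(−d·g²) and R_H = R_H,ref · d_ref / d_protein (Stejskal-Tanner
timing factors cancel in the ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial.distance import pdist

from .structio import ChainCoordinates, DecaySeries

__all__ = [
    "HydroParameters",
    "HydroResult",
    "kirkwood_rh",
    "ensemble_rh",
    "rh_from_decays",
]

#: hydrodynamic radius of the α-cyclodextrin reference compound (Å)
ALPHA_CYCLODEXTRIN_RH = 7.52


class HydroError(ValueError):
    pass


@dataclass(frozen=True)
class HydroParameters:
    """CA-bead hydrodynamic model parameters; bead radius in Å."""

    bead_radius: float = 4.5

    def __post_init__(self):
        if self.bead_radius <= 0:
            raise HydroError("bead radius must be positive")


@dataclass
class HydroResult:
    per_conformer: np.ndarray  # R_H per conformer (Å)
    ensemble: float            # harmonic mean (Å)

    def __post_init__(self):
        self.per_conformer = np.asarray(self.per_conformer, dtype=float)
        if np.any(self.per_conformer <= 0):
            raise HydroError("all per-conformer R_H must be positive")
        lo, hi = self.per_conformer.min(), self.per_conformer.max()
        if not (lo - 1e-9 <= self.ensemble <= hi + 1e-9):
            raise HydroError("ensemble R_H outside per-conformer range")


def kirkwood_rh(chain: ChainCoordinates,
                params: HydroParameters = HydroParameters()) -> float:
    """Kirkwood bead-model hydrodynamic radius of one conformer (Å)."""
    beads = chain.ca
    n = len(beads)
    if n == 1:
        return params.bead_radius
    d = pdist(beads)
    if d.min() < 1e-9:
        raise HydroError("coincident beads in Kirkwood sum")
    double_sum = 2.0 * np.sum(1.0 / d)  # ordered pairs
    inv_rh = (n / params.bead_radius + double_sum) / (n * n)
    return float(1.0 / inv_rh)


def ensemble_rh(values) -> float:
    """Harmonic mean <R_H⁻¹>⁻¹ of per-conformer hydrodynamic radii."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise HydroError("no R_H values to average")
    if np.any(arr <= 0):
        raise HydroError("R_H values must be positive")
    return float(1.0 / np.mean(1.0 / arr))


def _fit_gaussian_decay(series: DecaySeries) -> float:
    """Decay constant d of S = S0 * exp(-d g^2)."""
    g2 = series.x ** 2
    y = series.y
    pos = y > 0
    if pos.sum() < 3:
        raise HydroError("too few positive intensities in diffusion decay")
    slope, intercept = np.polyfit(g2[pos], np.log(y[pos]), 1)
    if slope >= 0:
        raise HydroError("non-decaying diffusion series")
    p0 = (math.exp(intercept), -slope)
    popt, _ = optimize.curve_fit(
        lambda g, s0, d: s0 * np.exp(-d * g * g), series.x, y, p0=p0, maxfev=10000
    )
    d = float(popt[1])
    if d <= 0:
        raise HydroError("non-decaying diffusion series")
    return d


def rh_from_decays(protein: DecaySeries, reference: DecaySeries,
                   rh_ref: float = ALPHA_CYCLODEXTRIN_RH) -> float:
    """R_H from relative diffusion decays against a reference compound."""
    if protein.kind != "diffusion" or reference.kind != "diffusion":
        raise HydroError("both series must be diffusion decays")
    if not np.allclose(protein.x, reference.x):
        raise HydroError("protein and reference must share the gradient axis")
    d_protein = _fit_gaussian_decay(protein)
    d_ref = _fit_gaussian_decay(reference)
    return float(rh_ref * d_ref / d_protein)
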