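"""Debye-level small-angle X-ray scattering observables.

Residue-level beads with per-residue effective form factors replace atomic
scattering factors and the hydration shell of full SAXS predictors; the
orientation-averaged intensity is the exact Debye double sum

    I(q) = Σ_i Σ_j f_i f_j sin(q·r_ij) / (q·r_ij)

with the i = j and q = 0 limits equal to f_i·f_j.  Model-to-experiment
agreement is scored by reduced χ² after a closed-form least-squares scale
(and optional constant background).  Guinier analysis and the pair-distance
distribution P(r) complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .structio import ChainCoordinates, ScatteringCurve

__all__ = [
    "FormFactorModel",
    "ChiSquareFit",
    "PairDistanceDistribution",
    "debye_curve",
    "fit_scale_chi2",
    "guinier_rg",
    "pair_distance_distribution",
    "coordinate_rg",
]


class SAXSError(ValueError):
    pass


#: average residue masses (Da) for the optional mass weighting
_RESIDUE_MASS = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}


@dataclass(frozen=True)
class FormFactorModel:
    """Per-residue effective scattering weights."""

    mode: str = "uniform"  # "uniform" | "mass"

    def weights(self, chain: ChainCoordinates) -> np.ndarray:
        if self.mode == "uniform":
            return np.ones(chain.n_residues)
        if self.mode == "mass":
            # scaled by a 110 Da reference so uniform and mass weights are
            # comparable in magnitude
            w = np.array([_RESIDUE_MASS.get(nm, 110.0) for nm in chain.residue_names])
            return w / 110.0
        raise SAXSError(f"unknown form-factor mode {self.mode!r}")


@dataclass
class ChiSquareFit:
    scale: float
    background: float
    chi2: float  # reduced chi-square
    n_points: int

    def __post_init__(self):
        if self.chi2 < 0:
            raise SAXSError("chi-square cannot be negative")
        if self.scale <= 0:
            raise SAXSError("fitted scale must be positive")


def debye_curve(chain: ChainCoordinates, q_grid,
                ff: FormFactorModel = FormFactorModel()) -> ScatteringCurve:
    """Theoretical scattering curve of a bead model on a q grid (Å⁻¹)."""
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or len(q) == 0:
        raise SAXSError("q grid must be a non-empty 1-D array")
    if np.any(q < 0):
        raise SAXSError("q must be non-negative")
    f = ff.weights(chain)
    beads = chain.ca
    self_term = float(np.sum(f * f))
    iu = np.triu_indices(len(beads), k=1)
    if len(iu[0]) == 0:
        intensity = np.full_like(q, self_term)
        return ScatteringCurve(q=q, intensity=intensity)
    d = pdist(beads)
    fw = (f[iu[0]] * f[iu[1]])
    # sinc(x/pi) = sin(x)/x with the correct x -> 0 limit; chunked over q to
    # bound the (n_q x n_pairs) intermediate for large bead clouds
    cross = np.empty_like(q)
    for s in range(0, len(q), 32):
        block = q[s:s + 32]
        cross[s:s + 32] = 2.0 * (np.sinc(np.outer(block, d) / np.pi) @ fw)
    intensity = self_term + cross
    return ScatteringCurve(q=q, intensity=np.maximum(intensity, 0.0))


def fit_scale_chi2(calc: ScatteringCurve, exp: ScatteringCurve,
                   fit_background: bool = False) -> ChiSquareFit:
    """Reduced χ² between an experimental and a scaled theoretical curve.

    χ² = (1/(n−p)) Σ [(I_exp − c·I_calc − b)/σ]² with the scale c (and
    optional background b) at their closed-form weighted least-squares
    optimum.  The experimental curve is linearly interpolated onto the
    calculated grid over the overlapping q range.
    """
    lo = max(calc.q[0], exp.q[0])
    hi = min(calc.q[-1], exp.q[-1])
    mask = (calc.q >= lo) & (calc.q <= hi)
    if mask.sum() < 3:
        raise SAXSError("fewer than 3 overlapping q points between curves")
    qs = calc.q[mask]
    ic = calc.intensity[mask]
    ie = np.interp(qs, exp.q, exp.intensity)
    sig = np.interp(qs, exp.q, exp.sigma)
    w = 1.0 / sig ** 2
    if fit_background:
        # weighted linear least squares in (c, b)
        A = np.column_stack([ic, np.ones_like(ic)])
        Aw = A * w[:, None]
        coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ ie, rcond=None)
        c, b = float(coef[0]), float(coef[1])
        p = 2
    else:
        c = float(np.sum(w * ic * ie) / np.sum(w * ic * ic))
        b = 0.0
        p = 1
    resid = (ie - c * ic - b) / sig
    n = len(qs)
    chi2 = float(np.sum(resid ** 2) / max(n - p, 1))
    return ChiSquareFit(scale=c, background=b, chi2=chi2, n_points=n)


def coordinate_rg(chain: ChainCoordinates,
                  ff: FormFactorModel = FormFactorModel()) -> float:
    """Direct weight-averaged radius of gyration of the bead cloud (Å)."""
    f = ff.weights(chain)
    x = chain.ca
    centre = (f[:, None] * x).sum(axis=0) / f.sum()
    return float(np.sqrt((f * ((x - centre) ** 2).sum(axis=1)).sum() / f.sum()))


def guinier_rg(curve: ScatteringCurve, qmax_rg: float = 1.3,
               max_iter: int = 50) -> tuple[float, float]:
    """Guinier radius of gyration and I(0).

    Fits ln I = ln I₀ − q²Rg²/3 on the low-q points, iteratively shrinking
    the window until q_max·Rg <= ``qmax_rg``.
    """
    q, i = curve.q, curve.intensity
    pos = i > 0
    if pos.sum() < 3:
        raise SAXSError("too few positive intensities for Guinier analysis")
    q, i = q[pos], i[pos]
    n_window = len(q)
    rg = 0.0
    i0 = float(i[0])
    for _ in range(max_iter):
        qs, is_ = q[:n_window], i[:n_window]
        slope, intercept = np.polyfit(qs ** 2, np.log(is_), 1)
        rg_new = float(np.sqrt(max(-3.0 * slope, 0.0)))
        i0 = float(np.exp(intercept))
        if rg_new < 1e-6:  # flat curve: point-like scatterer
            return 0.0, i0
        limit = qmax_rg / rg_new
        new_window = int(np.searchsorted(q, limit, side="right"))
        new_window = max(new_window, 3)
        if new_window == n_window:
            return rg_new, i0
        n_window = new_window
        rg = rg_new
    raise SAXSError("Guinier window did not converge")


@dataclass
class PairDistanceDistribution:
    r: np.ndarray       # bin centres (Å)
    pr: np.ndarray      # weight density per Å
    dmax: float         # largest pair distance (Å)
    bin_width: float

    def total_weight(self) -> float:
        return float(np.sum(self.pr) * self.bin_width)


def pair_distance_distribution(chain: ChainCoordinates, bin_width: float = 1.0,
                               ff: FormFactorModel = FormFactorModel(),
                               ) -> PairDistanceDistribution:
    """Histogram of pairwise bead distances weighted by f_i·f_j."""
    if chain.n_residues < 2:
        raise SAXSError("need at least 2 beads for P(r)")
    f = ff.weights(chain)
    d = pdist(chain.ca)
    iu = np.triu_indices(chain.n_residues, k=1)
    w = f[iu[0]] * f[iu[1]]
    dmax = float(d.max())
    nbins = max(int(np.ceil(dmax / bin_width)), 1)
    hist, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width),
                               weights=w)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return PairDistanceDistribution(r=centres, pr=hist / bin_width, dmax=dmax,
                                    bin_width=bin_width)
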