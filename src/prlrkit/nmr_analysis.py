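"""Structure information from NMR observables.

Secondary chemical shifts (Δδ = δ_obs − δ_rc) and helix calling; the Karplus
relation between the backbone φ dihedral and the three-bond ³J(HN-Hα)
coupling, forward and inverted; HNHA cross/diagonal intensity extraction;
helical hydrogen-bond restraint emission (amide of residue i to carbonyl of
i−4); single-exponential relaxation-decay fitting; and an H-D exchange
protection score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .randomcoil import DEFAULT_RANDOM_COIL, RandomCoilTable
from .structio import ChemicalShiftTable, DecaySeries

__all__ = [
    "SCSProfile",
    "KarplusParameters",
    "DEFAULT_KARPLUS",
    "CouplingTable",
    "HBondRestraint",
    "DihedralRestraint",
    "RestraintSet",
    "ExponentialFit",
    "compute_scs",
    "call_helix_segments",
    "karplus_forward",
    "karplus_invert",
    "j_from_hnha",
    "derive_hbond_restraints",
    "fit_exponential_decay",
    "hd_protection",
]

SCS_ATOMS = ("CA", "CB", "C", "HA")


class NMRAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# secondary chemical shifts


@dataclass
class SCSProfile:
    """Secondary shifts Δδ per (residue, atom), defined only where both the
    observed and random-coil tables have entries."""

    frame: pd.DataFrame  # columns: residue_id, residue_name, atom_name, delta

    def delta(self, residue_id: int, atom_name: str) -> float | None:
        sel = self.frame[
            (self.frame.residue_id == residue_id) & (self.frame.atom_name == atom_name)
        ]
        return float(sel["delta"].iloc[0]) if len(sel) else None

    @property
    def residue_ids(self) -> np.ndarray:
        return np.sort(self.frame["residue_id"].unique())

    def helix_scores(self) -> pd.Series:
        """Per-residue helix score: ΔδCA − ΔδCB, falling back to ΔδCA alone.

        Positive Cα and negative Cβ deviations both indicate helix, so the
        difference accumulates the two diagnostics with the right signs.
        """
        wide = self.frame.pivot_table(index="residue_id", columns="atom_name",
                                      values="delta")
        if "CA" not in wide.columns:
            raise NMRAnalysisError("helix score needs CA secondary shifts")
        score = wide["CA"].copy()
        if "CB" in wide.columns:
            has_cb = wide["CB"].notna()
            score[has_cb] = wide.loc[has_cb, "CA"] - wide.loc[has_cb, "CB"]
        return score.dropna()


def compute_scs(shifts: ChemicalShiftTable,
                coil: RandomCoilTable = DEFAULT_RANDOM_COIL) -> SCSProfile:
    """Δδ = δ_obs − δ_rc for every (residue, atom) present in both tables."""
    rows = []
    for rec in shifts.frame.itertuples(index=False):
        if rec.atom_name not in SCS_ATOMS:
            continue
        if not coil.supports(rec.residue_name):
            raise NMRAnalysisError(
                f"residue name {rec.residue_name!r} absent from random-coil table"
            )
        ref = coil.get(rec.residue_name, rec.atom_name)
        if ref is None:  # e.g. glycine CB
            continue
        rows.append((int(rec.residue_id), rec.residue_name, rec.atom_name,
                     float(rec.shift) - ref))
    return SCSProfile(pd.DataFrame(rows, columns=["residue_id", "residue_name",
                                                  "atom_name", "delta"]))


def _smooth_by_window(ids: np.ndarray, vals: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average over sequence neighbours; shrinks at the ends
    and across numbering gaps (only residues within the half-window in *id*
    space contribute)."""
    half = window // 2
    out = np.empty_like(vals)
    for k, rid in enumerate(ids):
        mask = np.abs(ids - rid) <= half
        out[k] = vals[mask].mean()
    return out


def call_helix_segments(profile: SCSProfile, min_len: int = 4,
                        threshold: float = 0.7, window: int = 3,
                        ) -> list[tuple[int, int]]:
    """Maximal runs of consecutively numbered residues whose window-smoothed
    helix score exceeds ``threshold`` ppm, of length >= ``min_len``."""
    if window < 1 or window % 2 == 0:
        raise NMRAnalysisError("smoothing window must be odd and >= 1")
    if not len(profile.frame):
        return []
    scores = profile.helix_scores()
    ids = scores.index.to_numpy(dtype=int)
    smooth = _smooth_by_window(ids, scores.to_numpy(dtype=float), window)
    segments: list[tuple[int, int]] = []
    start = prev = None

    def flush():
        if start is not None and prev - start + 1 >= min_len:
            segments.append((int(start), int(prev)))

    for rid, val in zip(ids, smooth):
        if val > threshold:
            if start is not None and rid == prev + 1:
                prev = rid
            else:
                flush()
                start = prev = rid
        else:
            flush()
            start = prev = None
    flush()
    return segments


# ---------------------------------------------------------------------------
# Karplus relation


@dataclass(frozen=True)
class KarplusParameters:
    """³J(φ) = A·cos²(φ+θ₀) + B·cos(φ+θ₀) + C with θ₀ = −60°."""

    A: float
    B: float
    C: float
    theta0: float = -60.0

    def __post_init__(self):
        if self.A <= 0:
            raise NMRAnalysisError("Karplus A coefficient must be positive")

    @property
    def j_max(self) -> float:
        return self.A + abs(self.B) + self.C

    @property
    def j_min(self) -> float:
        u = np.clip(-self.B / (2 * self.A), -1.0, 1.0)
        candidates = [self.A * x * x + self.B * x + self.C for x in (-1.0, 1.0, u)]
        return min(candidates)


#: HN-Hα coefficients used for φ-angle refinement (Hz)
DEFAULT_KARPLUS = KarplusParameters(A=6.51, B=-1.75, C=1.60)


def karplus_forward(phi_deg: float | np.ndarray,
                    params: KarplusParameters = DEFAULT_KARPLUS) -> float | np.ndarray:
    theta = np.deg2rad(np.asarray(phi_deg, dtype=float) + params.theta0)
    u = np.cos(theta)
    out = params.A * u * u + params.B * u + params.C
    return float(out) if out.ndim == 0 else out


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return a + 360.0 if a <= -180.0 + 1e-9 else a


def karplus_invert(j_hz: float, params: KarplusParameters = DEFAULT_KARPLUS,
                   ) -> list[float]:
    """All φ in (−180, 180] with karplus_forward(φ) = J, via the closed-form
    quadratic in cos(φ + θ₀).  Empty (with a warning) when J lies outside the
    curve's range — the signature of an inconsistent measurement."""
    if j_hz < 0:
        raise NMRAnalysisError("coupling constants are non-negative")
    disc = params.B ** 2 - 4.0 * params.A * (params.C - j_hz)
    if disc < 0:
        warnings.warn(f"J = {j_hz} Hz below the Karplus curve minimum", stacklevel=2)
        return []
    roots_u = [(-params.B + s * math.sqrt(disc)) / (2.0 * params.A) for s in (+1, -1)]
    phis = set()
    for u in roots_u:
        if abs(u) > 1.0 + 1e-9:
            continue
        u = min(max(u, -1.0), 1.0)  # clamp float error at the curve extremes
        theta = math.degrees(math.acos(u))
        for t in (theta, -theta):
            phis.add(round(_wrap_angle(t - params.theta0), 9))
    if not phis:
        warnings.warn(f"J = {j_hz} Hz outside the Karplus curve range "
                      f"[{params.j_min:.2f}, {params.j_max:.2f}] Hz", stacklevel=2)
        return []
    return sorted(phis)


def j_from_hnha(s_cross: float, s_diag: float, zeta_s: float) -> float:
    """³J from HNHA cross/diagonal peak intensities:
    J = atan(sqrt(−S_cross/S_diag)) / (2πζ), ζ the dephasing delay in s."""
    if s_diag == 0:
        raise NMRAnalysisError("diagonal intensity must be non-zero")
    if zeta_s <= 0:
        raise NMRAnalysisError("zeta must be positive")
    ratio = s_cross / s_diag
    if ratio > 0:
        raise NMRAnalysisError("positive cross/diagonal ratio is unphysical")
    return math.atan(math.sqrt(-ratio)) / (2.0 * math.pi * zeta_s)


# ---------------------------------------------------------------------------
# restraints


@dataclass
class CouplingTable:
    """³J(HN-Hα) per residue, Hz."""

    couplings: dict  # residue_id -> J (Hz)
    uncertainties: dict = field(default_factory=dict)

    def __post_init__(self):
        for rid, j in self.couplings.items():
            if j < 0:
                raise NMRAnalysisError(f"negative coupling at residue {rid}")

    def __len__(self) -> int:
        return len(self.couplings)

    def items(self):
        return sorted(self.couplings.items())


@dataclass(frozen=True)
class HBondRestraint:
    donor: int     # residue i, amide H/N
    acceptor: int  # residue i-4, carbonyl O

    def __post_init__(self):
        if self.acceptor != self.donor - 4:
            raise NMRAnalysisError("helical H-bond restraint must pair i with i-4")


@dataclass(frozen=True)
class DihedralRestraint:
    residue_id: int
    angle_name: str  # "phi" | "psi"
    target: float
    tolerance: float


@dataclass
class RestraintSet:
    hbonds: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hbonds) + len(self.dihedrals)

    def to_table(self) -> pd.DataFrame:
        rows = [("hbond", r.donor, r.acceptor, "", "") for r in self.hbonds]
        rows += [("dihedral", r.residue_id, "", r.angle_name,
                  f"{r.target}+/-{r.tolerance}") for r in self.dihedrals]
        return pd.DataFrame(rows, columns=["type", "residue", "partner",
                                           "angle", "target"])

    def to_cns_assign_lines(self, d_on: float = 1.8, d_minus: float = 0.3,
                            d_plus: float = 0.5) -> list[str]:
        """Hydrogen-bond restraints as CNS-style assign statements (HN...O)."""
        lines = []
        for r in self.hbonds:
            lines.append(
                f"assign (resid {r.donor} and name HN) "
                f"(resid {r.acceptor} and name O) {d_on:.1f} {d_minus:.1f} {d_plus:.1f}"
            )
        return lines


def derive_hbond_restraints(couplings: CouplingTable,
                            helix_segments: list[tuple[int, int]],
                            j_cutoff: float = 5.0) -> RestraintSet:
    """H-bond restraint i → i−4 for every residue with J below cutoff whose
    donor and acceptor both lie inside the same helix segment."""
    restraints = []
    for rid, j in couplings.items():
        if j >= j_cutoff:
            continue
        for lo, hi in helix_segments:
            if lo <= rid <= hi and lo <= rid - 4 <= hi:
                restraints.append(HBondRestraint(donor=rid, acceptor=rid - 4))
                break
    return RestraintSet(hbonds=restraints)


# ---------------------------------------------------------------------------
# decay fitting and exchange protection


@dataclass
class ExponentialFit:
    amplitude: float
    tau: float          # time constant, same unit as x
    residual: float     # RMS of fit residuals
    decaying: bool = True


def fit_exponential_decay(series: DecaySeries) -> ExponentialFit:
    """Least-squares fit of y = a·exp(−x/T) to a relaxation decay.

    A non-decaying series (T much longer than the sampled window, or a
    non-negative trend) is flagged with ``decaying=False`` and T = inf.
    """
    if series.kind != "relaxation":
        raise NMRAnalysisError("expected a relaxation-kind decay series")
    x, y = series.x, series.y
    span = x[-1] - x[0]
    pos = y > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    else:
        slope, intercept = 0.0, math.log(max(y.max(), 1e-12))
    if slope >= -1e-12 / max(span, 1.0):
        return ExponentialFit(amplitude=float(np.mean(y)), tau=math.inf,
                              residual=float(np.std(y)), decaying=False)
    p0 = (math.exp(intercept), -1.0 / slope)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau), x, y, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:
        raise NMRAnalysisError(f"exponential fit did not converge: {exc}") from exc
    a, tau = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((y - a * np.exp(-x / tau)) ** 2)))
    if tau <= 0 or tau > 100.0 * span:
        return ExponentialFit(amplitude=a, tau=math.inf, residual=resid,
                              decaying=False)
    return ExponentialFit(amplitude=a, tau=tau, residual=resid)


def hd_protection(intensity_by_fraction: dict) -> float:
    """Amide protection score in [0, 1] from H-D exchange at several D₂O levels.

    After a quasi-stationary state, a fully exchanging amide's peak tracks
    the proton fraction (intensity ∝ 1 − f_D2O, score 0) while a protected
    amide is D₂O-independent (score 1).  Score = 1 − slope of the
    least-squares line of intensity against (1 − f_D2O), clipped to [0, 1].
    """
    if len(intensity_by_fraction) < 3:
        raise NMRAnalysisError("need at least 3 D2O fractions")
    f = np.array(sorted(intensity_by_fraction), dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise NMRAnalysisError("D2O fractions must lie in [0, 1]")
    y = np.array([intensity_by_fraction[k] for k in sorted(intensity_by_fraction)],
                 dtype=float)
    slope = np.polyfit(1.0 - f, y, 1)[0]
    return float(np.clip(1.0 - slope, 0.0, 1.0))
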