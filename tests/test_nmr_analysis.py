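"""Secondary shifts, helix calling, Karplus relation, restraints, decays."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prlrkit.nmr_analysis import (DEFAULT_KARPLUS, CouplingTable, NMRAnalysisError, call_helix_segments,
                                  compute_scs, derive_hbond_restraints,
                                  fit_exponential_decay, hd_protection,
                                  j_from_hnha, karplus_forward, karplus_invert)
from prlrkit.randomcoil import DEFAULT_RANDOM_COIL
from prlrkit.structio import ChemicalShiftTable, DecaySeries
from prlrkit.synthetic_data import (FixtureConfig, HELIX_SHIFT_OFFSETS,
                                    gen_decay, gen_helix_shift_table)


def make_table(rows):
    return ChemicalShiftTable(pd.DataFrame(
        rows, columns=["residue_id", "residue_name", "atom_name", "shift"]))


# -- secondary chemical shifts ---------------------------------------------


def test_scs_zero_when_observed_equals_coil():
    rows = [(i, "ALA", a, DEFAULT_RANDOM_COIL.get("ALA", a))
            for i in range(1, 6) for a in ("CA", "CB", "C", "HA")]
    profile = compute_scs(make_table(rows))
    assert np.allclose(profile.frame["delta"], 0.0)


def test_scs_recovers_constructed_offsets_exactly():
    cfg = FixtureConfig(seed=4, shift_noise_ppm=0.0)
    profile = compute_scs(gen_helix_shift_table(cfg))
    lo, hi = cfg.helix_window
    for rid in (lo, (lo + hi) // 2, hi):
        assert profile.delta(rid, "CA") == pytest.approx(HELIX_SHIFT_OFFSETS["CA"])
    outside = lo - 2
    assert profile.delta(outside, "CA") == pytest.approx(0.0, abs=1e-9)


def test_scs_unknown_residue_errors():
    with pytest.raises(NMRAnalysisError):
        compute_scs(make_table([(1, "XXX", "CA", 55.0)]))


@given(st.floats(min_value=0.1, max_value=4.0))
@settings(max_examples=20, deadline=None)
def test_scs_linear_in_offsets(scale):
    """Scaling every observed offset scales each secondary shift identically."""
    base = [(i, "LEU", "CA", DEFAULT_RANDOM_COIL.get("LEU", "CA") + 1.0)
            for i in range(1, 6)]
    scaled = [(i, n, a, DEFAULT_RANDOM_COIL.get(n, a) + scale * 1.0)
              for i, n, a, _ in base]
    d1 = compute_scs(make_table(base)).frame["delta"].to_numpy()
    d2 = compute_scs(make_table(scaled)).frame["delta"].to_numpy()
    assert np.allclose(d2, scale * d1)


# -- helix calling ----------------------------------------------------------


def test_helix_call_all_zero_profile():
    rows = [(i, "ALA", "CA", DEFAULT_RANDOM_COIL.get("ALA", "CA"))
            for i in range(1, 21)]
    profile = compute_scs(make_table(rows))
    assert call_helix_segments(profile) == []


def test_helix_call_recovers_fixture_window():
    cfg = FixtureConfig(seed=7)
    profile = compute_scs(gen_helix_shift_table(cfg))
    segments = call_helix_segments(profile)
    assert len(segments) == 1
    (lo, hi), (true_lo, true_hi) = segments[0], cfg.helix_window
    # window smoothing may extend the call by one residue at each edge
    assert abs(lo - true_lo) <= 1 and abs(hi - true_hi) <= 1


def test_helix_call_short_stretch_below_min_len():
    rows = []
    for i in range(1, 16):
        shift = DEFAULT_RANDOM_COIL.get("ALA", "CA") + (3.0 if 7 <= i <= 9 else 0.0)
        rows.append((i, "ALA", "CA", shift))
    profile = compute_scs(make_table(rows))
    assert call_helix_segments(profile, window=1) == []


def test_helix_call_rejects_even_window():
    profile = compute_scs(make_table([(1, "ALA", "CA", 55.0)]))
    with pytest.raises(NMRAnalysisError):
        call_helix_segments(profile, window=2)


def test_helix_call_recovery_rate_under_noise():
    """With sub-threshold noise (sigma <= 0.2 ppm) the called segment matches
    the true helical stretch within one residue per end in >= 95% of seeded
    replicates."""
    hits = 0
    n_rep = 200
    for seed in range(n_rep):
        cfg = FixtureConfig(seed=seed, shift_noise_ppm=0.2)
        segments = call_helix_segments(compute_scs(gen_helix_shift_table(cfg)))
        if len(segments) == 1:
            lo, hi = segments[0]
            if abs(lo - cfg.helix_window[0]) <= 1 and abs(hi - cfg.helix_window[1]) <= 1:
                hits += 1
    assert hits / n_rep >= 0.95


def test_helix_call_never_overlaps_and_stays_on_scored_residues(rng):
    for _ in range(20):
        ids = np.sort(rng.choice(np.arange(1, 60), size=30, replace=False))
        rows = [(int(i), "ALA", "CA",
                 DEFAULT_RANDOM_COIL.get("ALA", "CA") + rng.normal(1.0, 2.0))
                for i in ids]
        profile = compute_scs(make_table(rows))
        segments = call_helix_segments(profile)
        scored = set(int(i) for i in ids)
        for k, (lo, hi) in enumerate(segments):
            assert lo <= hi
            assert all(r in scored for r in range(lo, hi + 1))
            if k:
                assert lo > segments[k - 1][1]


# -- Karplus ---------------------------------------------------------------


@pytest.mark.parametrize("phi, expected", [
    (-57.0, 3.74),   # helical phi: direct evaluation of the coefficients
    (60.0, 6.36),    # cos term = 1: A + B + C
    (150.0, 1.60),   # cos term = 0: C alone
])
def test_karplus_forward_reference_points(phi, expected):
    assert karplus_forward(phi) == pytest.approx(expected, abs=0.005)


def test_karplus_invert_round_trip_on_degree_grid():
    """Every phi on a 1-degree grid is recovered in the solution set of the
    inverse at its own forward coupling."""
    for phi in np.arange(-180.0, 181.0, 1.0):
        j = karplus_forward(phi)
        solutions = karplus_invert(j)
        target = 180.0 if phi == -180.0 else phi  # wrap convention
        assert solutions, f"no solutions at phi={phi}"
        assert min(abs(s - target) for s in solutions) < 0.1


def test_karplus_invert_out_of_range_empty():
    with pytest.warns(UserWarning):
        assert karplus_invert(20.0) == []  # above A + |B| + C = 9.86 Hz


def test_karplus_invert_at_c_contains_analytic_roots():
    solutions = karplus_invert(DEFAULT_KARPLUS.C)
    for expected in (150.0, -30.0):  # cos(phi - 60) = 0 branch
        assert min(abs(s - expected) for s in solutions) < 1e-6
    assert len(solutions) == 4  # plus the quadratic branch


def test_hnha_extraction():
    assert j_from_hnha(0.0, 1.0, 0.01305) == 0.0
    j_true, zeta = 5.0, 0.01305
    ratio = -np.tan(2 * np.pi * j_true * zeta) ** 2
    assert j_from_hnha(ratio, 1.0, zeta) == pytest.approx(5.0, abs=1e-9)
    with pytest.raises(NMRAnalysisError):
        j_from_hnha(0.5, 1.0, zeta)


# -- H-bond restraints ------------------------------------------------------


def test_hbond_rule_and_boundary():
    segments = [(210, 233)]
    empty = derive_hbond_restraints(CouplingTable({}), segments)
    assert len(empty) == 0
    inside = derive_hbond_restraints(CouplingTable({214: 4.0}), segments)
    assert [(r.donor, r.acceptor) for r in inside.hbonds] == [(214, 210)]
    # donor inside but acceptor (i-4) outside the segment: no restraint
    boundary = derive_hbond_restraints(CouplingTable({212: 4.0}), segments)
    assert len(boundary) == 0
    # J above the cutoff: no restraint
    high_j = derive_hbond_restraints(CouplingTable({214: 6.5}), segments)
    assert len(high_j) == 0


def test_cns_export_lines():
    rs = derive_hbond_restraints(CouplingTable({214: 4.0, 220: 3.0}), [(210, 233)])
    lines = rs.to_cns_assign_lines()
    assert len(lines) == 2
    assert "resid 214 and name HN" in lines[0]
    assert "resid 210 and name O" in lines[0]


# -- exponential decays -----------------------------------------------------


def test_exponential_fit_noise_free_recovery():
    x = np.linspace(10, 130, 7)
    series = gen_decay("relaxation", 50.0, x)
    fit = fit_exponential_decay(series)
    assert fit.decaying
    assert fit.tau == pytest.approx(50.0, rel=1e-3)


def test_exponential_fit_constant_series_flagged():
    series = DecaySeries(x=np.linspace(10, 130, 7), y=np.ones(7), kind="relaxation")
    fit = fit_exponential_decay(series)
    assert not fit.decaying
    assert np.isinf(fit.tau)


def test_exponential_fit_simulation_study():
    """5% noise, 7 delays: median relative error over 100 replicates < 10%."""
    x = np.linspace(10, 130, 7)
    errors = []
    for seed in range(100):
        series = gen_decay("relaxation", 50.0, x, noise=0.05, seed=seed)
        fit = fit_exponential_decay(series)
        errors.append(abs(fit.tau - 50.0) / 50.0)
    assert np.median(errors) < 0.10


# -- H-D protection ---------------------------------------------------------


def test_hd_protection_limits_and_midpoint():
    fractions = [0.1, 0.3, 0.4, 0.5, 0.7, 0.9]
    protected = {f: 1.0 for f in fractions}
    assert hd_protection(protected) == pytest.approx(1.0)
    exchanging = {f: 1.0 - f for f in fractions}
    assert hd_protection(exchanging) == pytest.approx(0.0, abs=1e-9)
    half = {f: 0.5 + 0.5 * (1.0 - f) for f in fractions}
    assert hd_protection(half) == pytest.approx(0.5)


def test_hd_protection_input_guards():
    with pytest.raises(NMRAnalysisError):
        hd_protection({0.1: 1.0, 0.5: 1.0})
    with pytest.raises(NMRAnalysisError):
        hd_protection({-0.1: 1.0, 0.5: 1.0, 0.9: 1.0})
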