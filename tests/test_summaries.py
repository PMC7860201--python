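"""Tests for the derived statistics over record tables."""

import numpy as np
import pandas as pd
import pytest

from sexrevsim.fixtures import (GroupSpec, PopulationSpec, TrajectorySegment,
                                make_population, make_trajectory)
from sexrevsim.summaries import (PeriodRule, asr_landmark, burrows_composite,
                                 cr_change_over, cr_change_window, decline_year,
                                 detect_periods, effective_size,
                                 generation_time, has_post_zw_xy_period,
                                 ld_coefficient, sexratio_selection_coefficient,
                                 transition_period)

ZW_PURE = (100, 0, 0)       # adult male counts (AA, Aa, aa)
ZW_MIXED = (70, 25, 5)
XY_PURE = (0, 100, 0)


def records(*segments, start=-50):
    return make_trajectory(segments, start_year=start, initial_system="ZW")


# -- period segmentation -----------------------------------------------------

def test_period_ends_at_persistent_failure():
    df = records(TrajectorySegment(60, ZW_PURE), TrajectorySegment(80, ZW_MIXED))
    periods = detect_periods(df, "ZW")
    assert periods[0] == ("ZW", -50, 9)
    assert periods[1][0] == "mixed" and periods[1][1] == 10


def test_transient_excursion_does_not_end_period():
    df = records(TrajectorySegment(60, ZW_PURE), TrajectorySegment(10, ZW_MIXED),
                 TrajectorySegment(60, ZW_PURE))
    periods = detect_periods(df, "ZW")
    assert periods[0] == ("ZW", -50, 79)


def test_three_period_turnover_labels():
    df = records(TrajectorySegment(60, ZW_PURE), TrajectorySegment(70, ZW_MIXED),
                 TrajectorySegment(60, XY_PURE))
    periods = detect_periods(df, "ZW")
    assert [p[0] for p in periods] == ["ZW", "mixed", "XY"]
    # contiguous boundaries partitioning the record
    for (_, _, e), (_, s, _) in zip(periods, periods[1:]):
        assert s == e + 1
    assert periods[0][1] == -50 and periods[-1][2] == df["year"].iloc[-1]
    assert has_post_zw_xy_period(periods)
    assert transition_period(periods) == periods[1]


def test_trailing_short_mismatch_ends_period():
    """A mismatch run shorter than the window still closes the period when
    the record ends inside it (the condition never returns)."""
    df = records(TrajectorySegment(60, ZW_PURE), TrajectorySegment(20, ZW_MIXED))
    periods = detect_periods(df, "ZW")
    assert [p[0] for p in periods] == ["ZW", "mixed"]


def test_detect_periods_against_brute_force_scan():
    """Hand-rolled forward scan oracle on a noisy constructed series."""
    rng = np.random.default_rng(5)
    segs = []
    for frac, n in ((0.0, 55), (0.08, 8), (0.0, 12), (0.2, 70), (1.0, 60)):
        for _ in range(n):
            f = min(1.0, max(0.0, frac + rng.normal(0, 0.005)))
            n_aa_or_Aa = int(round(100 * f))
            segs.append(TrajectorySegment(1, (100 - n_aa_or_Aa, n_aa_or_Aa, 0)))
    df = records(*segs)
    periods = detect_periods(df, "ZW")

    # oracle: state per year, then first failure persisting 50 years
    frac_rev = 1 - df["n_m_AA"] / (df["n_m_AA"] + df["n_m_Aa"] + df["n_m_aa"])
    fail = (frac_rev >= 0.05).to_numpy()
    end = None
    for i in range(fail.size):
        if fail[i] and (fail[i:i + 50].all() or i + 50 > fail.size):
            end = df["year"].iloc[i] - 1
            break
    assert periods[0][0] == "ZW" and periods[0][2] == end


def test_detect_periods_requires_records():
    with pytest.raises(ValueError):
        detect_periods(pd.DataFrame(columns=["year"]), "ZW")


# -- scalar statistics -------------------------------------------------------

@pytest.mark.parametrize("nf, nm, expected", [(50, 50, 100), (20, 80, 64), (0, 100, 0)])
def test_effective_size(nf, nm, expected):
    assert effective_size(nf, nm) == pytest.approx(expected)


def test_effective_size_bounded_by_census():
    rng = np.random.default_rng(0)
    for _ in range(200):
        nf, nm = rng.integers(1, 500, size=2)
        ne = effective_size(int(nf), int(nm))
        assert ne <= nf + nm
        if nf == nm:
            assert ne == pytest.approx(nf + nm)


def test_selection_coefficient_examples():
    assert sexratio_selection_coefficient(0.4, 0.4, 0.7) == pytest.approx(0.0)
    assert sexratio_selection_coefficient(0.9, 0.1, 0.5) == pytest.approx(0.0)
    # asr 0.75: V_CR = 0.25/0.75 + 0.75/0.25 = 10/3; V_CN = 8/3; s = 0.25
    assert sexratio_selection_coefficient(0.25, 0.5, 0.75) == pytest.approx(0.25)


def test_selection_coefficient_degenerate():
    assert np.isnan(sexratio_selection_coefficient(np.nan, 0.5, 0.7))
    assert np.isnan(sexratio_selection_coefficient(0.5, 0.5, 1.0))


def test_generation_time():
    assert generation_time([3, 3], [3, 3]) == pytest.approx(3.0)
    assert generation_time([2, 4], [4, 2]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        generation_time([], [])


# -- linkage disequilibrium --------------------------------------------------

def _ld_oracle(x, y):
    """Independent exhaustive per-individual computation of the composite."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    p = sum(x) / (2 * len(x))
    q = sum(y) / (2 * len(y))
    total = 0.0
    for xi, yi in zip(x, y):
        total += (xi - 2 * p) * (yi - 2 * q)
    return total / (2 * len(x))


def test_ld_monomorphic_is_zero():
    pop = make_population(PopulationSpec(
        (GroupSpec(10, "female", ("A", "a"), (1, 1), ("C_R", "C_R")),), "ZW"))
    assert ld_coefficient(pop, ("C_R", "A")) == 0.0


def test_ld_two_type_population_matches_oracle():
    """Half C_R C_R / aa, half C_N C_N / AA -> composite D = -0.5."""
    pop = make_population(PopulationSpec((
        GroupSpec(10, "female", ("a", "a"), (1, 1), ("C_R", "C_R")),
        GroupSpec(10, "male", ("A", "A"), (1, 1), ("C_N", "C_N")),
    ), "ZW"))
    d = ld_coefficient(pop, ("C_R", "A"))
    assert d == pytest.approx(-0.5)
    x = pop.p0 + pop.p1
    y = pop.c0 + pop.c1
    assert d == pytest.approx(_ld_oracle(x, y), abs=1e-12)


def test_ld_oracle_equivalence_random_genotypes():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.integers(0, 3, size=15)
        y = rng.integers(0, 3, size=15)
        if x.min() == x.max() or y.min() == y.max():
            continue
        assert burrows_composite(x, y) == pytest.approx(_ld_oracle(x, y), abs=1e-12)


def test_ld_independent_loci_near_zero():
    rng = np.random.default_rng(4)
    x = rng.binomial(2, 0.5, size=10_000)
    y = rng.binomial(2, 0.5, size=10_000)
    assert abs(burrows_composite(x, y)) < 0.01


def test_ld_tracks_gametic_d_under_random_union():
    """On random union of gametes the composite estimates gametic D."""
    rng = np.random.default_rng(6)
    # gamete pool: haplotype freqs with D = 0.15 at p = q = 0.5
    hap = np.array([0.4, 0.1, 0.1, 0.4])  # (0,0),(0,1),(1,0),(1,1)
    draws = rng.choice(4, size=(20_000, 2), p=hap)
    x = (draws // 2).sum(axis=1)
    y = (draws % 2).sum(axis=1)
    assert burrows_composite(x, y) == pytest.approx(0.15, abs=0.01)


def test_ld_thr_low_target():
    pop = make_population(PopulationSpec((
        GroupSpec(10, "female", ("A", "a"), (0, 0), ("C_R", "C_R")),
        GroupSpec(10, "male", ("A", "A"), (1, 1), ("C_N", "C_N")),
    ), "ZW"))
    assert ld_coefficient(pop, ("C_R", "thr_low")) == pytest.approx(0.5)


# -- landmarks ---------------------------------------------------------------

def asr_records(values, start=-50):
    segs = [TrajectorySegment(1, ZW_PURE, asr=v) for v in values]
    return records(*segs, start=start)


def test_asr_landmark_constant_none():
    assert asr_landmark(asr_records([0.5] * 40)) is None


def test_asr_landmark_step_series():
    # 0.5 until year 9, 0.7 afterwards (years indexed from 0)
    df = asr_records([0.5] * 10 + [0.7] * 20, start=0)
    # scan oracle: first t with mean(asr[t..t+4]) > 0.6
    vals = df["asr"].to_numpy()
    expected = next(t for t in range(len(vals) - 4) if vals[t:t + 5].mean() > 0.6)
    assert asr_landmark(df) == expected


def test_asr_landmark_single_spike_none():
    df = asr_records([0.5] * 10 + [1.0] + [0.5] * 10)
    assert asr_landmark(df) is None


def test_decline_year_constant_none():
    segs = [TrajectorySegment(60, ZW_PURE, ne=100.0)]
    assert decline_year(records(*segs)) is None


def test_decline_year_monotone_drop():
    segs = [TrajectorySegment(90, ZW_PURE, ne=100.0)] + [
        TrajectorySegment(1, ZW_PURE, ne=100.0 - k) for k in range(1, 40)]
    df = records(*segs)
    assert decline_year(df) == 39  # last year at the baseline (year index -50+89)


def test_decline_year_dip_and_recover():
    segs = ([TrajectorySegment(80, ZW_PURE, ne=100.0)]
            + [TrajectorySegment(5, ZW_PURE, ne=60.0)]
            + [TrajectorySegment(15, ZW_PURE, ne=100.0)]
            + [TrajectorySegment(40, ZW_PURE, ne=50.0)])
    df = records(*segs)
    # scan-from-end oracle
    ne = df["ne"].to_numpy()
    years = df["year"].to_numpy()
    base = ne[(years >= -10) & (years < 0)].mean()
    expected = years[np.flatnonzero(ne >= base)[-1]]
    assert decline_year(df) == expected == 49


# -- choice window -----------------------------------------------------------

def window_records():
    quiet = TrajectorySegment(60, ZW_PURE, s=0.0, ne=100.0)
    active = TrajectorySegment(41, (60, 40, 0), s=0.2, ne=100.0, freq_cr=0.2)
    late = TrajectorySegment(30, (0, 100, 0), s=0.2, ne=100.0, freq_cr=0.3)
    return records(quiet, active, late)


def test_cr_change_window_bounds():
    df = window_records()
    assert cr_change_window(df) == (10, 50)


def test_cr_change_window_none_without_reversed_males():
    df = records(TrajectorySegment(80, ZW_PURE, s=0.5, ne=100.0))
    assert cr_change_window(df) is None


def test_cr_change_window_matches_bruteforce_filter():
    df = window_records()
    frac_norm = df["frac_normal_m"].to_numpy()
    frac_rev = df["frac_rev_m"].to_numpy()
    s = df["s"].to_numpy()
    ne = df["ne"].to_numpy()
    ok = (frac_norm > 0.05) & (frac_rev > 0.05) & (np.abs(s) > 1 / (2 * ne))
    runs = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    best = max(runs, key=lambda r: r[1] - r[0])
    expected = (int(df["year"].iloc[best[0]]), int(df["year"].iloc[best[1]]))
    assert cr_change_window(df) == expected


def test_cr_change_over_five_year_means():
    df = window_records()
    got = cr_change_over(df, 10, 50, column="freq_cr")
    assert got == pytest.approx(0.0)   # constant within the window
    got = cr_change_over(df, 10, 55)
    # end mean over years 51..55 = 0.3, start mean over 10..14 = 0.2
    assert got == pytest.approx(0.1)


def test_period_rule_validation():
    with pytest.raises(ValueError):
        PeriodRule(purity_threshold=0.6)
    with pytest.raises(ValueError):
        PeriodRule(persistence_window=0)
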