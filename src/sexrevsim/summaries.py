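"""Derived statistics over per-year record tables.

Covers segmentation of the record into sex-determination periods (the
95%/5% genotype rule with a 50-year persistence clause), the adult-sex-ratio
landmarks, effective population size, the Fisherian sex-ratio selection
coefficient on the preference allele, composite linkage disequilibrium,
generation time, the year of ultimate population decline, and the window in
which the preference-allele frequency change is attributed to selection
rather than drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PeriodRule", "detect_periods", "effective_size",
           "sexratio_selection_coefficient", "ld_coefficient",
           "burrows_composite", "generation_time", "asr_landmark",
           "decline_year", "cr_change_window", "cr_change_over",
           "summarize_run", "extinction_generations", "has_post_zw_xy_period"]


@dataclass(frozen=True)
class PeriodRule:
    """A system period persists while less than ``purity_threshold`` of the
    adult males violate its genotype criterion; it ends at the first year
    after which the criterion fails for ``persistence_window`` consecutive
    years."""

    purity_threshold: float = 0.05
    persistence_window: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.purity_threshold < 0.5:
            raise ValueError("purity_threshold must be in (0, 0.5)")
        if self.persistence_window < 1:
            raise ValueError("persistence_window must be >= 1")


def _year_states(records: pd.DataFrame, rule: PeriodRule) -> np.ndarray:
    """Per-year system label: 'ZW' while <5% of adult males carry chromosome
    a (males >=95% AA), 'XY' while >=95% of adult males are Aa, else
    'mixed'.  Years without adult males inherit the previous year's state."""
    n_m = records["n_adult_m"].to_numpy(dtype=float)
    m_AA = records["n_m_AA"].to_numpy(dtype=float)
    m_Aa = records["n_m_Aa"].to_numpy(dtype=float)
    states = np.empty(len(records), dtype=object)
    prev = "mixed"
    thr = rule.purity_threshold
    for i in range(len(records)):
        if n_m[i] <= 0:
            states[i] = prev
            continue
        frac_carry_a = 1.0 - m_AA[i] / n_m[i]
        frac_not_Aa = 1.0 - m_Aa[i] / n_m[i]
        if frac_carry_a < thr:
            states[i] = "ZW"
        elif frac_not_Aa < thr:
            states[i] = "XY"
        else:
            states[i] = "mixed"
        prev = states[i]
    return states


def detect_periods(
    records: pd.DataFrame,
    initial_system: str,
    rule: PeriodRule = PeriodRule(),
) -> list[tuple[str, int, int]]:
    """Segment a run into consecutive sex-determination periods.

    Returns ``[(label, start_year, end_year), ...]`` with inclusive,
    contiguous boundaries.  A period of label L ends at the first year from
    which the yearly state differs from L for ``persistence_window``
    consecutive years (or through the end of the record); the next period
    starts there, labelled by that year's state.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    states = _year_states(records, rule)
    years = records["year"].to_numpy()
    n = len(states)
    w = rule.persistence_window

    # periods may only start in the initial system's state
    label = initial_system
    periods: list[tuple[str, int, int]] = []
    start = 0
    i = 0
    while i < n:
        mismatch = states[i] != label
        if mismatch:
            # does the mismatch persist for w consecutive years (or to the end)?
            j = i
            while j < n and states[j] != label:
                j += 1
            if j - i >= w or j == n:
                periods.append((label, int(years[start]), int(years[i - 1]) if i > start else int(years[start])))
                label = states[i]
                start = i
            else:
                i = j
                continue
        i += 1
    periods.append((label, int(years[start]), int(years[n - 1])))
    # fix zero-length degenerate first period when the record starts mixed
    return [(l, s, e) for (l, s, e) in periods if e >= s]


def period_of_label(
    periods: list[tuple[str, int, int]], label: str, after: str | None = None
) -> tuple[str, int, int] | None:
    """First period of ``label``; with ``after`` set, the first one following
    a period of that label."""
    seen_after = after is None
    for p in periods:
        if not seen_after:
            seen_after = p[0] == after
            continue
        if p[0] == label:
            return p
    return None


def has_post_zw_xy_period(periods: list[tuple[str, int, int]]) -> bool:
    """Did a ZW-origin run transition into an XX/XY system?"""
    return period_of_label(periods, "XY", after="ZW") is not None


def transition_period(periods: list[tuple[str, int, int]]) -> tuple[str, int, int] | None:
    """The mixed period between the initial ZW period and the subsequent XY
    period, if the turnover completed."""
    for i, p in enumerate(periods[:-1]):
        if p[0] == "mixed" and i > 0 and periods[i - 1][0] == "ZW" \
                and periods[i + 1][0] == "XY":
            return p
    return None


def effective_size(n_females: int, n_males: int) -> float:
    """Effective number of breeders under unequal sex numbers,
    ``4*Nf*Nm/(Nf+Nm)``; zero when either sex is absent."""
    if n_females < 0 or n_males < 0:
        raise ValueError("counts must be >= 0")
    if n_females == 0 or n_males == 0:
        return 0.0
    return 4.0 * n_females * n_males / (n_females + n_males)


def sexratio_selection_coefficient(psr_cr, psr_cn, asr) -> float:
    """Sex-ratio selection on the preference allele via Fisherian
    reproductive values.

    A brood with progeny sex ratio ``psr`` under adult sex ratio ``asr`` has
    expected grandoffspring value ``V = psr/asr + (1-psr)/(1-asr)`` (each
    son is worth 1/asr, each daughter 1/(1-asr)); the coefficient is
    ``s = V(C_R)/V(C_N) - 1``.  NaN when either maternal class is absent or
    the adult sex ratio is degenerate.
    """
    if any(x is None or not np.isfinite(x) for x in (psr_cr, psr_cn, asr)):
        return float("nan")
    if not 0.0 < asr < 1.0:
        return float("nan")
    v_cr = psr_cr / asr + (1.0 - psr_cr) / (1.0 - asr)
    v_cn = psr_cn / asr + (1.0 - psr_cn) / (1.0 - asr)
    if v_cn == 0.0:
        return float("nan")
    return v_cr / v_cn - 1.0


def burrows_composite(x: np.ndarray, y: np.ndarray) -> float:
    """Burrows composite disequilibrium from diploid copy counts:
    ``D = (1/(2n)) * sum_i (x_i - 2p)(y_i - 2q)``.

    Phase-free: usable on an unphased census of unlinked loci.  Zero when
    either locus is monomorphic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    p = x.mean() / 2.0
    q = y.mean() / 2.0
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return 0.0
    return float(np.sum((x - 2.0 * p) * (y - 2.0 * q)) / (2.0 * n))


# engine-internal alias (kept for the per-year recording hot path)
_burrows = burrows_composite


def ld_coefficient(adults, locus_pair: tuple[str, str] = ("C_R", "A")) -> float:
    """Composite LD between two loci of a :class:`Population` of adults.

    ``locus_pair`` names the indicator alleles: first element must be
    ``"C_R"``; the target is ``"A"`` (chromosome A copies) or ``"thr_low"``
    (copies of the lowest threshold allele).
    """
    if locus_pair[0] != "C_R":
        raise ValueError("first locus must be C_R")
    x = adults.p0 + adults.p1
    if locus_pair[1] == "A":
        y = adults.c0 + adults.c1
    elif locus_pair[1] == "thr_low":
        y = (adults.t0 == 0).astype(int) + (adults.t1 == 0)
    else:
        raise ValueError(f"unknown target locus {locus_pair[1]!r}")
    return burrows_composite(x, y)


def generation_time(mother_ages, father_ages) -> float:
    """Mean age of reproduction: the mean over offspring of the mean of the
    mother's and father's age at conception."""
    mother_ages = np.asarray(mother_ages, dtype=float)
    father_ages = np.asarray(father_ages, dtype=float)
    if mother_ages.size == 0:
        raise ValueError("at least one offspring required")
    return float(((mother_ages + father_ages) / 2.0).mean())


def asr_landmark(records: pd.DataFrame, level: float = 0.6, window: int = 5) -> int | None:
    """First year ``t`` whose forward ``window``-year mean ASR exceeds
    ``level``; None if never."""
    asr = records["asr"].to_numpy(dtype=float)
    years = records["year"].to_numpy()
    n = asr.size
    for i in range(n - window + 1):
        if np.nanmean(asr[i: i + window]) > level:
            return int(years[i])
    return None


def decline_year(records: pd.DataFrame, baseline_years: int = 10) -> int | None:
    """Start of the ultimate population decline: the first year after which
    N_e never again reaches its pre-warming baseline (the mean N_e over the
    final ``baseline_years`` burn-in years).  None if N_e never falls
    permanently below the baseline."""
    years = records["year"].to_numpy()
    ne = records["ne"].to_numpy(dtype=float)
    base_mask = (years >= -baseline_years) & (years < 0)
    if base_mask.sum() < baseline_years:
        raise ValueError(f"need {baseline_years} recorded burn-in years")
    baseline = float(ne[base_mask].mean())
    at_or_above = np.flatnonzero(ne >= baseline)
    if at_or_above.size == 0:
        return int(years[0])
    last = int(at_or_above[-1])
    if last == len(years) - 1:
        return None
    return int(years[last])


def cr_change_window(records: pd.DataFrame) -> tuple[int, int] | None:
    """Choice window: the maximal contiguous span of years in which (1) both
    normal and sex-reversed males each exceed 5% of the adult males and (2)
    sex-ratio selection exceeds drift, ``|s| > 1/(2 N_e)``.  Returns
    (start_year, end_year) of the longest such run, or None."""
    frac_norm = records["frac_normal_m"].to_numpy(dtype=float)
    frac_rev = records["frac_rev_m"].to_numpy(dtype=float)
    s = records["s"].to_numpy(dtype=float)
    ne = records["ne"].to_numpy(dtype=float)
    years = records["year"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (
            (frac_norm > 0.05) & (frac_rev > 0.05)
            & np.isfinite(s) & (ne > 0) & (np.abs(s) > 1.0 / (2.0 * ne))
        )
    best = None
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    return int(years[best[0]]), int(years[best[1]])


def _five_year_mean(records: pd.DataFrame, column: str, year: int,
                    forward: bool, window: int = 5) -> float:
    years = records["year"].to_numpy()
    vals = records[column].to_numpy(dtype=float)
    if forward:
        mask = (years >= year) & (years < year + window)
    else:
        mask = (years > year - window) & (years <= year)
    return float(np.nanmean(vals[mask])) if mask.any() else float("nan")


def cr_change_over(records: pd.DataFrame, start_year: int, end_year: int,
                   column: str = "freq_cr", window: int = 5) -> float:
    """Change in a frequency column between the ``window``-year means taken
    forward from the start year and backward from the end year."""
    return (
        _five_year_mean(records, column, end_year, forward=False, window=window)
        - _five_year_mean(records, column, start_year, forward=True, window=window)
    )


def extinction_generations(result) -> float:
    """Extinction time in generations: years from warming start to
    extinction divided by the run's estimated generation time."""
    if result.extinction_year is None:
        return float("nan")
    return result.extinction_year / result.generation_time


def summarize_run(result) -> dict:
    """One event-summary row for a run (consumed by the ``compare`` layer)."""
    records = result.records
    periods = result.periods
    trans = transition_period(periods)
    window = cr_change_window(records)
    out = {
        "scenario": result.scenario,
        "seed": result.seed,
        "extinction_year": result.extinction_year,
        "extinction_generations": extinction_generations(result),
        "generation_time": result.generation_time,
        "decline_year": result.decline_year,
        "asr_above_06_year": asr_landmark(records),
        "periods": [list(p) for p in periods],
        "zw_to_xy_transition": has_post_zw_xy_period(periods),
    }
    for label, s, e in periods:
        key = f"len_{label}"
        out.setdefault(key, 0)
        out[key] += e - s + 1
    if trans is not None:
        _, ts, te = trans
        mask = (records["year"] >= ts) & (records["year"] <= te)
        out["transition_start"] = ts
        out["transition_end"] = te
        out["transition_mean_asr"] = float(np.nanmean(records.loc[mask, "asr"]))
        out["cr_change_transition"] = cr_change_over(records, ts, te)
    if window is not None:
        out["choice_window"] = list(window)
        out["cr_change_window"] = cr_change_over(records, *window)
    # change from the start of the final mixed-system period to the start of
    # the ultimate population decline (the span over which sexual selection
    # erodes a rare preference allele in XY-origin runs)
    if periods and periods[-1][0] == "mixed" and result.decline_year is not None:
        final_start = periods[-1][1]
        if result.decline_year > final_start:
            out["cr_change_final_to_decline"] = cr_change_over(
                records, final_start, result.decline_year)
    return out
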