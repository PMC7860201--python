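"""Deterministic constructed populations and trajectories for tests.

These builders exercise the analysis code (classification, mating, LD,
period segmentation, landmarks) in isolation from the stochastic engine:
``make_population`` assembles an exact genotype/phenotype/age composition
and ``make_trajectory`` emits a record table with piecewise-constant metric
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genetics import Individual, thr_allele_values
from .population import Population

__all__ = ["PopulationSpec", "GroupSpec", "TrajectorySegment",
           "make_population", "make_trajectory"]


@dataclass(frozen=True)
class GroupSpec:
    """``count`` identical individuals."""

    count: int
    sex: str = "female"                 # "female" | "male"
    chrom_pair: tuple[str, str] = ("A", "a")
    thr_pair: tuple[int, int] = (0, 0)  # allele indices into the value table
    pref_pair: tuple[str, str] = ("C_N", "C_N")
    age: int = 2


@dataclass(frozen=True)
class PopulationSpec:
    """Exact composition of a constructed population."""

    groups: tuple[GroupSpec, ...]
    system: str = "ZW"
    year: int = 0


def make_population(spec: PopulationSpec, rng=None) -> Population:
    """Build the exact requested composition (deterministic; ``rng`` is
    accepted for interface symmetry but unused)."""
    thr_values = thr_allele_values(spec.system)
    individuals = []
    i = 0
    for g in spec.groups:
        if g.count < 0:
            raise ValueError("counts must be >= 0")
        for _ in range(g.count):
            individuals.append(Individual(
                id=i, age=g.age, phenotypic_sex=g.sex,
                chrom_pair=g.chrom_pair,
                thr_pair=(float(thr_values[g.thr_pair[0]]),
                          float(thr_values[g.thr_pair[1]])),
                pref_pair=g.pref_pair,
            ))
            i += 1
    pop = Population.from_individuals(individuals, thr_values, year=spec.year)
    return pop


@dataclass(frozen=True)
class TrajectorySegment:
    """``n_years`` of constant per-year metrics.

    ``male_geno`` gives the adult-male counts by sex-chromosome genotype
    (AA, Aa, aa); female counts are derived from ``asr``.
    """

    n_years: int
    male_geno: tuple[int, int, int] = (100, 0, 0)
    asr: float = 0.5
    ne: float = 100.0
    freq_cr: float = 0.0
    s: float = float("nan")
    frac_normal_m: float | None = None
    frac_rev_m: float | None = None


def make_trajectory(
    segments: Sequence[TrajectorySegment],
    start_year: int = -50,
    initial_system: str = "ZW",
) -> pd.DataFrame:
    """Emit a record table (same columns the engine writes, where needed by
    the summaries layer) from piecewise-constant segments."""
    rows = []
    year = start_year
    for seg in segments:
        if seg.n_years < 1:
            raise ValueError("segments must span at least one year")
        n_m = sum(seg.male_geno)
        n_f = int(round(n_m * (1.0 - seg.asr) / seg.asr)) if seg.asr > 0 else 0
        if initial_system == "ZW":
            frac_norm = seg.male_geno[0] / n_m if n_m else np.nan
        else:
            frac_norm = (seg.male_geno[0] + seg.male_geno[1]) / n_m if n_m else np.nan
        if seg.frac_normal_m is not None:
            frac_norm = seg.frac_normal_m
        frac_rev = (1.0 - frac_norm) if n_m else np.nan
        if seg.frac_rev_m is not None:
            frac_rev = seg.frac_rev_m
        for _ in range(seg.n_years):
            rows.append({
                "year": year,
                "n_adults": n_m + n_f, "n_adult_f": n_f, "n_adult_m": n_m,
                "asr": seg.asr,
                "n_m_AA": seg.male_geno[0], "n_m_Aa": seg.male_geno[1],
                "n_m_aa": seg.male_geno[2],
                "n_f_AA": 0, "n_f_Aa": n_f if initial_system == "ZW" else 0,
                "n_f_aa": 0 if initial_system == "ZW" else n_f,
                "frac_normal_m": frac_norm, "frac_rev_m": frac_rev,
                "freq_cr": seg.freq_cr, "ne": seg.ne, "s": seg.s,
            })
            year += 1
    return pd.DataFrame(rows)
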