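"""Age-structured population container, initialization, survival and aging.

The population is stored column-wise in numpy arrays (one row per animal)
for speed; :class:`~sexrevsim.genetics.Individual` objects are available for
construction and inspection of small populations.  Chromosomes are coded as
copy indicators (1 = ``A``, 0 = ``a``), ``thr`` alleles as indices into a
per-population allele-value table, and ``C`` alleles as 1 = ``C_R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genetics import Individual, thr_allele_values

__all__ = ["LifeHistoryParams", "Population", "build_initial_population",
           "annual_survival", "advance_year"]


@dataclass(frozen=True)
class LifeHistoryParams:
    """Demography of an iteroparous, amphibian-like life history.

    The defaults jointly give ~200 stable adults (expected recruits/year =
    Nmax * juvenile_survival^2 = 100, expected adult tenure ~2 years) and a
    generation time of about 3 years.  ``ww_viability`` is the probability
    that a conceived WW (aa in a ZW system) offspring survives to enter the
    cohort; it is applied at conception, all later survival is independent
    of genotype and sex.
    """

    maturation_age: int = 2
    adult_annual_survival: float = 0.5
    juvenile_annual_survival: float = 0.5
    max_age: int = 8
    fert_f: float = 40.0
    Nmax: int = 400
    n_start_adults: int = 200
    ww_viability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ww_viability <= 1.0:
            raise ValueError("ww_viability must be a probability")
        if self.maturation_age >= self.max_age:
            raise ValueError("maturation_age must be below max_age")


@dataclass
class Population:
    """Column-wise store of one population.

    All arrays share the same length (one entry per animal):
    ``age`` (years), ``male`` (phenotype, bool), ``c0``/``c1`` (sex-chromosome
    pair, 1 = A), ``t0``/``t1`` (thr allele index into ``thr_values``),
    ``p0``/``p1`` (preference pair, 1 = C_R).
    """

    age: np.ndarray
    male: np.ndarray
    c0: np.ndarray
    c1: np.ndarray
    t0: np.ndarray
    t1: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    thr_values: np.ndarray
    year: int = 0

    @property
    def n(self) -> int:
        return self.age.shape[0]

    def adults_mask(self, maturation_age: int) -> np.ndarray:
        return self.age >= maturation_age

    @property
    def n_A(self) -> np.ndarray:
        """Per-animal copy count of chromosome A."""
        return self.c0 + self.c1

    @property
    def n_cr(self) -> np.ndarray:
        """Per-animal copy count of allele C_R."""
        return self.p0 + self.p1

    def threshold(self) -> np.ndarray:
        return self.thr_values[self.t0] + self.thr_values[self.t1]

    def subset(self, mask_or_idx) -> "Population":
        return Population(
            age=self.age[mask_or_idx], male=self.male[mask_or_idx],
            c0=self.c0[mask_or_idx], c1=self.c1[mask_or_idx],
            t0=self.t0[mask_or_idx], t1=self.t1[mask_or_idx],
            p0=self.p0[mask_or_idx], p1=self.p1[mask_or_idx],
            thr_values=self.thr_values, year=self.year,
        )

    @staticmethod
    def empty(thr_values: np.ndarray, year: int = 0) -> "Population":
        z = np.zeros(0, dtype=np.int16)
        return Population(age=z.copy(), male=np.zeros(0, dtype=bool),
                          c0=z.copy(), c1=z.copy(), t0=z.copy(), t1=z.copy(),
                          p0=z.copy(), p1=z.copy(),
                          thr_values=np.asarray(thr_values, dtype=float), year=year)

    @classmethod
    def from_individuals(
        cls, individuals: Iterable[Individual], thr_values: Sequence[float],
        year: int = 0,
    ) -> "Population":
        inds = list(individuals)
        thr_values = np.asarray(thr_values, dtype=float)

        def thr_index(value: float) -> int:
            idx = np.flatnonzero(np.isclose(thr_values, value))
            if idx.size == 0:
                raise ValueError(f"thr allele value {value} not in allele table")
            return int(idx[0])

        return cls(
            age=np.array([i.age for i in inds], dtype=np.int16),
            male=np.array([i.phenotypic_sex == "male" for i in inds], dtype=bool),
            c0=np.array([i.chrom_pair[0] == "A" for i in inds], dtype=np.int16),
            c1=np.array([i.chrom_pair[1] == "A" for i in inds], dtype=np.int16),
            t0=np.array([thr_index(i.thr_pair[0]) for i in inds], dtype=np.int16),
            t1=np.array([thr_index(i.thr_pair[1]) for i in inds], dtype=np.int16),
            p0=np.array([i.pref_pair[0] == "C_R" for i in inds], dtype=np.int16),
            p1=np.array([i.pref_pair[1] == "C_R" for i in inds], dtype=np.int16),
            thr_values=thr_values, year=year,
        )

    def to_individuals(self) -> list[Individual]:
        chrom = np.array(["a", "A"])
        pref = np.array(["C_N", "C_R"])
        return [
            Individual(
                id=i, age=int(self.age[i]),
                phenotypic_sex="male" if self.male[i] else "female",
                chrom_pair=(str(chrom[self.c0[i]]), str(chrom[self.c1[i]])),
                thr_pair=(float(self.thr_values[self.t0[i]]),
                          float(self.thr_values[self.t1[i]])),
                pref_pair=(str(pref[self.p0[i]]), str(pref[self.p1[i]])),
            )
            for i in range(self.n)
        ]

    @staticmethod
    def concatenate(parts: Sequence["Population"]) -> "Population":
        first = parts[0]
        return Population(
            age=np.concatenate([p.age for p in parts]),
            male=np.concatenate([p.male for p in parts]),
            c0=np.concatenate([p.c0 for p in parts]),
            c1=np.concatenate([p.c1 for p in parts]),
            t0=np.concatenate([p.t0 for p in parts]),
            t1=np.concatenate([p.t1 for p in parts]),
            p0=np.concatenate([p.p0 for p in parts]),
            p1=np.concatenate([p.p1 for p in parts]),
            thr_values=first.thr_values, year=first.year,
        )


def _stationary_adult_ages(
    n: int, life: LifeHistoryParams, rng: np.random.Generator
) -> np.ndarray:
    """Ages drawn from the stationary age distribution of the adult survival
    process (geometric, truncated at max_age)."""
    ages = np.arange(life.maturation_age, life.max_age + 1)
    w = life.adult_annual_survival ** (ages - life.maturation_age)
    return rng.choice(ages, size=n, p=w / w.sum()).astype(np.int16)


def build_initial_population(system, scenario, rng: np.random.Generator) -> Population:
    """Stable pre-warming population: ``n_start_adults`` adults at 50:50
    phenotypic sex carrying only the system's normal genotypes (ZW: Aa
    females / AA males; XY: aa females / Aa males), plus juveniles at the
    stationary abundance implied by the survival rates.

    ``thr`` alleles are sampled independently per copy from the initial
    allele frequencies (0.5/0.5 biallelic, uniform for the ten-allele
    variant); ``C_R`` copies are sampled at the scenario's initial frequency.
    Pre-warming sex reversal is not seeded: it arises from the signal model.
    """
    if system not in ("XY", "ZW"):
        raise ValueError(f"unknown system {system!r}")
    if not 0.0 <= scenario.cr_init_freq <= 1.0:
        raise ValueError("cr_init_freq must be a probability")
    life = scenario.life
    gen = scenario.genetics
    thr_values = thr_allele_values(
        system, gen.sig_a, scenario.climate.sigma_total, gen.z_low, gen.thr_model
    )
    n_alleles = thr_values.shape[0]

    n_ad = life.n_start_adults
    # standing juveniles at breeding time: cohorts born 1..maturation_age-1
    # years ago, thinned by juvenile survival
    n_born = min(life.Nmax, round(life.n_start_adults / 2 * life.fert_f))
    juv_ages, juv_counts = [], []
    for a in range(1, life.maturation_age):
        juv_ages.append(a)
        juv_counts.append(int(round(n_born * life.juvenile_annual_survival ** a)))
    n_juv = int(sum(juv_counts))
    n_tot = n_ad + n_juv

    male = np.zeros(n_tot, dtype=bool)
    male[: n_ad // 2] = True                      # adult males
    juv_male = rng.random(n_juv) < 0.5            # juveniles 50:50
    male[n_ad:] = juv_male

    # normal genotypes: female = Aa (ZW) / aa (XY); male = AA (ZW) / Aa (XY)
    if system == "ZW":
        c0 = np.ones(n_tot, dtype=np.int16)
        c1 = male.astype(np.int16)
    else:
        c0 = male.astype(np.int16)
        c1 = np.zeros(n_tot, dtype=np.int16)

    age = np.empty(n_tot, dtype=np.int16)
    age[:n_ad] = _stationary_adult_ages(n_ad, life, rng)
    pos = n_ad
    for a, cnt in zip(juv_ages, juv_counts):
        age[pos: pos + cnt] = a
        pos += cnt

    t0 = rng.integers(0, n_alleles, size=n_tot).astype(np.int16)
    t1 = rng.integers(0, n_alleles, size=n_tot).astype(np.int16)
    p0 = (rng.random(n_tot) < scenario.cr_init_freq).astype(np.int16)
    p1 = (rng.random(n_tot) < scenario.cr_init_freq).astype(np.int16)

    return Population(age=age, male=male, c0=c0, c1=c1, t0=t0, t1=t1,
                      p0=p0, p1=p1, thr_values=thr_values,
                      year=-scenario.climate.burn_in_years)


def annual_survival(
    pop: Population, params: LifeHistoryParams, rng: np.random.Generator
) -> Population:
    """Apply one year of survival: independent Bernoulli draws at the
    juvenile or adult rate, plus a hard cull at ``max_age``.  Survival is
    independent of genotype and phenotypic sex (any WW-viability cost is
    charged at conception, not here)."""
    adult = pop.adults_mask(params.maturation_age)
    p = np.where(adult, params.adult_annual_survival, params.juvenile_annual_survival)
    alive = rng.random(pop.n) < p
    alive &= pop.age < params.max_age
    return pop.subset(alive)


def advance_year(pop: Population) -> Population:
    """Increment every age and the calendar year (in place; survival must
    already have been applied)."""
    pop.age += 1
    pop.year += 1
    return pop
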