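"""Preference-weighted mating market and offspring production.

Each breeding season, adult females in a random order each choose a single
mate; every male can serve at most ``libido`` (3) matings.  A female picks
between the two male colour classes — "normal-coloured" males (carrying the
initial system's male-colour cue: presence of Y/A under XY, absence of W/a
under ZW) and "sex-reversed-looking" males — with probability proportional
to her preference times the class's remaining-libido-weighted availability,
renormalized so a female always mates when any libido remains.  Within the
chosen class, a male is drawn with probability proportional to his remaining
libido.

The season's pairs then produce ``N = min(Nmax, Nmother * fert_f)``
conceptions, each from a pair drawn uniformly with replacement; each
offspring inherits one random allele per locus from each parent, draws its
developmental exogenous signal and develops its (permanent) phenotypic sex.
In ZW-origin scenarios, conceived aa (WW) offspring are retained only with
probability ``ww_viability``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .climate import ClimateParams, YearClimate
from .genetics import preference_array, signal_array
from .population import LifeHistoryParams, Population

__all__ = ["DEFAULT_LIBIDO", "MatingPair", "Pairing", "OffspringCohort",
           "normal_male_mask", "form_pairs", "reproduce"]

#: Maximum matings per male per breeding season.
DEFAULT_LIBIDO = 3


@dataclass(frozen=True)
class MatingPair:
    """One mated female-male pair (ids are row indices into the population)."""

    mother_id: int
    father_id: int
    mother_pref_expressed: float
    father_class: str


@dataclass
class Pairing:
    """The season's mating outcome, column-wise.

    ``mother_idx``/``father_idx`` are row indices into the population the
    pairing was formed from; ``mother_pref`` is each mother's expressed
    probability of choosing a normal male; ``father_normal`` flags the
    father's colour class.
    """

    mother_idx: np.ndarray
    father_idx: np.ndarray
    mother_pref: np.ndarray
    father_normal: np.ndarray

    @property
    def n_mother(self) -> int:
        return int(self.mother_idx.shape[0])

    @property
    def pairs(self) -> list[MatingPair]:
        return [
            MatingPair(int(m), int(f), float(c),
                       "normal" if nrm else "sex_reversed")
            for m, f, c, nrm in zip(self.mother_idx, self.father_idx,
                                    self.mother_pref, self.father_normal)
        ]


def normal_male_mask(pop: Population, system: Literal["XY", "ZW"], idx) -> np.ndarray:
    """Colour class of males ``idx``: True where the male displays the
    initial system's normal-male cue.  Under XY origin the male colour is
    expressed in the presence of chromosome A (Y); under ZW origin a male
    looks normal only without chromosome a (W), i.e. genotype AA."""
    n_A = pop.c0[idx] + pop.c1[idx]
    if system == "XY":
        return n_A >= 1
    if system == "ZW":
        return n_A == 2
    raise ValueError(f"unknown system {system!r}")


def form_pairs(
    pop: Population,
    system: Literal["XY", "ZW"],
    inheritance_mode: str,
    cn_value: float,
    maturation_age: int,
    rng: np.random.Generator,
    libido: int = DEFAULT_LIBIDO,
) -> Pairing:
    """Run one breeding season's sequential mate choice.

    Females are shuffled uniformly; each picks the normal class with
    probability ``c*W_N / (c*W_N + (1-c)*W_R)`` where ``c`` is her expressed
    preference and ``W`` the remaining-libido-weighted availability of each
    class (updated after every choice).  With a single class available she
    mates within it (preference is non-exclusive); with no libido left she
    goes unmated.
    """
    adult = pop.adults_mask(maturation_age)
    females = np.flatnonzero(adult & ~pop.male)
    males = np.flatnonzero(adult & pop.male)
    if females.size == 0 or males.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return Pairing(z, z.copy(), np.zeros(0), np.zeros(0, dtype=bool))

    females = rng.permutation(females)
    prefs = preference_array(pop.p0[females] + pop.p1[females],
                             inheritance_mode, cn_value)

    normal = normal_male_mask(pop, system, males)
    # one slot per unit of libido; a class's availability is its slot count
    slots_n = np.repeat(males[normal], libido)
    slots_r = np.repeat(males[~normal], libido)
    n_n, n_r = slots_n.size, slots_r.size

    u_class = rng.random(females.size)
    u_slot = rng.random(females.size)

    mothers, fathers, m_pref, f_normal = [], [], [], []
    for k in range(females.size):
        if n_n == 0 and n_r == 0:
            break
        c = prefs[k]
        w_n, w_r = c * n_n, (1.0 - c) * n_r
        tot = w_n + w_r
        pick_normal = n_r == 0 or (tot > 0 and u_class[k] < w_n / tot)
        if pick_normal and n_n > 0:
            j = int(u_slot[k] * n_n)
            father = slots_n[j]
            n_n -= 1
            slots_n[j] = slots_n[n_n]
            f_normal.append(True)
        else:
            j = int(u_slot[k] * n_r)
            father = slots_r[j]
            n_r -= 1
            slots_r[j] = slots_r[n_r]
            f_normal.append(False)
        mothers.append(females[k])
        fathers.append(father)
        m_pref.append(c)

    return Pairing(
        mother_idx=np.asarray(mothers, dtype=np.int64),
        father_idx=np.asarray(fathers, dtype=np.int64),
        mother_pref=np.asarray(m_pref, dtype=float),
        father_normal=np.asarray(f_normal, dtype=bool),
    )


@dataclass
class OffspringCohort:
    """The retained offspring of one breeding season plus the transmission
    log needed for the paternal/maternal inheritance statistics and the
    generation-time estimate."""

    offspring: Population
    conceived: int
    mother_idx: np.ndarray
    father_idx: np.ndarray
    mother_age: np.ndarray
    father_age: np.ndarray
    mat_haplotype: dict = field(default_factory=dict)   # arrays: chrom, thr, pref
    pat_haplotype: dict = field(default_factory=dict)
    mother_pref: np.ndarray = None
    father_normal: np.ndarray = None

    @property
    def n(self) -> int:
        return self.offspring.n


def reproduce(
    pop: Population,
    pairing: Pairing,
    yc: YearClimate,
    climate: ClimateParams,
    life: LifeHistoryParams,
    system: Literal["XY", "ZW"],
    sig_a: float,
    rng: np.random.Generator,
) -> OffspringCohort:
    """Produce the season's offspring cohort from the mated pairs."""
    thr_values = pop.thr_values
    n_mother = pairing.n_mother
    if n_mother == 0:
        empty = Population.empty(thr_values, year=pop.year)
        z = np.zeros(0, dtype=np.int64)
        return OffspringCohort(empty, 0, z, z.copy(), z.copy(), z.copy(),
                               mother_pref=np.zeros(0), father_normal=np.zeros(0, bool))

    n_conc = min(life.Nmax, round(n_mother * life.fert_f))  # banker's rounding
    k = rng.integers(0, n_mother, size=n_conc)
    mi = pairing.mother_idx[k]
    fi = pairing.father_idx[k]

    def gametes(parent_idx: np.ndarray):
        u = rng.random((3, n_conc)) < 0.5
        chrom = np.where(u[0], pop.c0[parent_idx], pop.c1[parent_idx])
        thr = np.where(u[1], pop.t0[parent_idx], pop.t1[parent_idx])
        pref = np.where(u[2], pop.p0[parent_idx], pop.p1[parent_idx])
        return chrom, thr, pref

    m_chrom, m_thr, m_pref = gametes(mi)
    f_chrom, f_thr, f_pref = gametes(fi)

    sig_env = yc.mean_sig + yc.eps_B_draw + (
        rng.normal(0.0, climate.sd_within, size=n_conc)
        if climate.sd_within > 0 else 0.0
    )
    n_A = m_chrom + f_chrom
    signal = signal_array(n_A, sig_env, sig_a)
    threshold = thr_values[m_thr] + thr_values[f_thr]
    male = signal > threshold

    keep = np.ones(n_conc, dtype=bool)
    if system == "ZW" and life.ww_viability < 1.0:
        ww = n_A == 0
        keep[ww] = rng.random(int(ww.sum())) < life.ww_viability

    offspring = Population(
        age=np.zeros(int(keep.sum()), dtype=np.int16),
        male=male[keep],
        c0=m_chrom[keep].astype(np.int16), c1=f_chrom[keep].astype(np.int16),
        t0=m_thr[keep].astype(np.int16), t1=f_thr[keep].astype(np.int16),
        p0=m_pref[keep].astype(np.int16), p1=f_pref[keep].astype(np.int16),
        thr_values=thr_values, year=pop.year,
    )
    return OffspringCohort(
        offspring=offspring,
        conceived=int(n_conc),
        mother_idx=mi[keep], father_idx=fi[keep],
        mother_age=pop.age[mi[keep]].astype(np.int64),
        father_age=pop.age[fi[keep]].astype(np.int64),
        mat_haplotype={"chrom": m_chrom[keep], "thr": m_thr[keep], "pref": m_pref[keep]},
        pat_haplotype={"chrom": f_chrom[keep], "thr": f_thr[keep], "pref": f_pref[keep]},
        mother_pref=pairing.mother_pref[k][keep],
        father_normal=pairing.father_normal[k][keep],
    )
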