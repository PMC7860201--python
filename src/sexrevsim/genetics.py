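"""Genome representation and the threshold-trait machinery of sex development.

Individuals are diploid and carry three unlinked loci:

* a sex-chromosome pair (``A``/``a``; ``A`` is Z or Y, ``a`` is W or X) whose
  sex-determinant locus produces the continuous "male signal" factor, with
  ``A`` producing it at 1.5 times the level of ``a``;
* the autosomal ``thr`` locus whose two allele values sum to the individual's
  masculinization threshold;
* the autosomal ``C`` locus controlling female preference for normal versus
  sex-reversed males (``C_N`` favours normal males, ``C_R`` sex-reversed ones).

An individual develops as a male iff its total male signal (genetic plus
environmental) strictly exceeds its threshold; the phenotype is fixed at birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SIGNAL_RATIO",
    "CR_VALUE",
    "CN_VALUE_DEFAULT",
    "GeneticsParams",
    "Haplotype",
    "Individual",
    "chromosome_signal",
    "individual_signal",
    "individual_threshold",
    "develop_sex",
    "classify_individual",
    "make_gamete",
    "preference_value",
    "female_genotype_mean_signal",
    "male_genotype_mean_signal",
    "thr_allele_values",
]

#: Male-signal production of chromosome A relative to chromosome a.
SIGNAL_RATIO = 1.5

#: Probability that a female expressing the C_R phenotype chooses a normal
#: male when both male classes are equally available.
CR_VALUE = 0.1

#: Same for the C_N phenotype (0.5 in the "indiscriminate" sensitivity variant).
CN_VALUE_DEFAULT = 0.9

Chromosome = Literal["A", "a"]
Sex = Literal["male", "female"]
InheritanceMode = Literal["CR_dominant", "CR_recessive", "intermediate"]
System = Literal["XY", "ZW"]


@dataclass(frozen=True)
class GeneticsParams:
    """Constants of the genetic architecture.

    Parameters
    ----------
    sig_a : float
        Male-signal production of chromosome ``a`` (signal units).  Only the
        1.5 ratio between the chromosomes is biologically constrained; the
        absolute scale is set to 1 so that, together with the threshold placement rules
        below and a warming slope of 0.003/year, extinction falls at the
        observed times.
    z_low : float
        Placement of the ``thr_low`` homozygote threshold, in units of the
        total environmental signal s.d. above the mean signal of the normal
        female genotype ("just below the maximum signal realized before
        warming"); 2.4 gives a pre-warming masculinization rate of ~0.2%
        among genetically female offspring.
    thr_model : {"biallelic", "ten_allele"}
        Biallelic ``thr`` locus (main model) or ten evenly spaced alleles
        spanning [thr_low, thr_high] (sensitivity variant).
    """

    sig_a: float = 1.0
    z_low: float = 2.4
    thr_model: Literal["biallelic", "ten_allele"] = "biallelic"

    @property
    def sig_A(self) -> float:
        return SIGNAL_RATIO * self.sig_a


def chromosome_signal(label: Chromosome, sig_a: float = 1.0) -> float:
    """Male-signal contribution of one sex chromosome."""
    if label == "A":
        return SIGNAL_RATIO * sig_a
    if label == "a":
        return sig_a
    raise ValueError(f"unknown chromosome label {label!r}")


def individual_signal(
    chrom_pair: tuple[Chromosome, Chromosome], sig_env: float, sig_a: float = 1.0
) -> float:
    """Total male-signal level of an individual.

    The endogenous contributions of the two sex chromosomes plus the
    exogenous (developmental-temperature) component ``sig_env``.  Symmetric
    in the order of the pair.
    """
    if not np.isfinite(sig_env):
        raise ValueError("sig_env must be finite")
    return (
        chromosome_signal(chrom_pair[0], sig_a)
        + chromosome_signal(chrom_pair[1], sig_a)
        + sig_env
    )


def individual_threshold(thr_pair: tuple[float, float]) -> float:
    """Masculinization threshold: the sum of the two ``thr`` allele values."""
    return thr_pair[0] + thr_pair[1]


def develop_sex(signal: float, threshold: float) -> Sex:
    """Phenotypic sex at birth: male iff the signal strictly exceeds the
    threshold (a tie develops female)."""
    return "male" if signal > threshold else "female"


@dataclass(frozen=True)
class Haplotype:
    """One gamete: exactly one allele per locus."""

    chrom: Chromosome
    thr: float
    pref: Literal["C_N", "C_R"]


@dataclass
class Individual:
    """One diploid animal."""

    id: int
    age: int
    phenotypic_sex: Sex
    chrom_pair: tuple[Chromosome, Chromosome]
    thr_pair: tuple[float, float]
    pref_pair: tuple[str, str]
    remaining_libido: int = 0


def classify_individual(ind: Individual, system: System) -> str:
    """Label an individual relative to the initial sex-chromosome system.

    Returns one of ``normal_male``, ``normal_female``, ``sexreversed_male``,
    ``ww_female`` or ``novel``.  ``ww_female`` is the masculinization-
    resistant aa (WW) genotype that arises in ZW systems from matings with
    sex-reversed males.
    """
    n_A = sum(1 for c in ind.chrom_pair if c == "A")
    male = ind.phenotypic_sex == "male"
    if system == "ZW":
        if n_A == 2:
            return "normal_male" if male else "novel"
        if n_A == 1:
            return "sexreversed_male" if male else "normal_female"
        return "sexreversed_male" if male else "ww_female"
    if system == "XY":
        if n_A == 2:
            return "novel"
        if n_A == 1:
            return "normal_male" if male else "novel"
        return "sexreversed_male" if male else "normal_female"
    raise ValueError(f"unknown system {system!r}")


def make_gamete(ind: Individual, rng: np.random.Generator) -> Haplotype:
    """Form one gamete: each locus transmits one of its two alleles with
    probability 1/2, independently across loci (the loci are unlinked)."""
    picks = rng.integers(0, 2, size=3)
    return Haplotype(
        chrom=ind.chrom_pair[picks[0]],
        thr=ind.thr_pair[picks[1]],
        pref=ind.pref_pair[picks[2]],
    )


def preference_value(
    pref_pair: Sequence[str],
    inheritance_mode: InheritanceMode,
    cn_value: float = CN_VALUE_DEFAULT,
    cr_value: float = CR_VALUE,
) -> float:
    """Probability that a female with this C genotype chooses a normal male
    when both male classes are equally available.

    Homozygotes express their allele's value.  Heterozygotes express the
    dominant allele's value under ``CR_dominant``/``CR_recessive``, or the
    midpoint under ``intermediate`` inheritance.
    """
    n_cr = sum(1 for p in pref_pair if p == "C_R")
    if n_cr == 2:
        return cr_value
    if n_cr == 0:
        return cn_value
    if inheritance_mode == "CR_dominant":
        return cr_value
    if inheritance_mode == "CR_recessive":
        return cn_value
    if inheritance_mode == "intermediate":
        return 0.5 * (cn_value + cr_value)
    raise ValueError(f"unknown inheritance mode {inheritance_mode!r}")


def female_genotype_mean_signal(system: System, sig_a: float = 1.0) -> float:
    """Mean signal of the system's normal female genotype at the pre-warming
    climate (ZW females are Aa, XY females are aa)."""
    if system == "ZW":
        return (SIGNAL_RATIO + 1.0) * sig_a
    if system == "XY":
        return 2.0 * sig_a
    raise ValueError(f"unknown system {system!r}")


def male_genotype_mean_signal(system: System, sig_a: float = 1.0) -> float:
    """Mean signal of the system's normal male genotype (ZW males AA, XY
    males Aa)."""
    if system == "ZW":
        return 2.0 * SIGNAL_RATIO * sig_a
    if system == "XY":
        return (SIGNAL_RATIO + 1.0) * sig_a
    raise ValueError(f"unknown system {system!r}")


def thr_allele_values(
    system: System,
    sig_a: float = 1.0,
    sigma_total: float = float(np.hypot(0.01, 0.05)),
    z_low: float = 2.4,
    thr_model: Literal["biallelic", "ten_allele"] = "biallelic",
) -> np.ndarray:
    """Allele values at the ``thr`` locus for a given initial system.

    Placement rules (thresholds are per-homozygote, alleles are half of it):

    * ``thr_high`` homozygotes sit midway between the mean signals of the
      normal female and normal male genotypes, so normal individuals
      essentially never reverse sex before warming;
    * ``thr_low`` homozygotes sit ``z_low`` total-s.d. units above the mean
      female-genotype signal — above its average but just below its maximum
      realized signal — so only rare warm developmental environments
      masculinize them.

    Returns the sorted array of allele values (2 for the biallelic model,
    10 evenly spaced for the sensitivity variant).
    """
    fem = female_genotype_mean_signal(system, sig_a)
    mal = male_genotype_mean_signal(system, sig_a)
    thr_high = 0.5 * (fem + mal) / 2.0
    thr_low = 0.5 * (fem + z_low * sigma_total)
    if thr_low >= thr_high:
        raise ValueError("thr_low placement exceeds thr_high; check z_low/sig_a")
    if thr_model == "biallelic":
        return np.array([thr_low, thr_high])
    if thr_model == "ten_allele":
        return np.linspace(thr_low, thr_high, 10)
    raise ValueError(f"unknown thr model {thr_model!r}")


# ---------------------------------------------------------------------------
# vectorised counterparts used by the simulation engine (same formulas,
# operating on per-individual copy-count arrays)

def signal_array(n_A: np.ndarray, sig_env: np.ndarray, sig_a: float = 1.0) -> np.ndarray:
    """Signal for individuals carrying ``n_A`` copies of chromosome A."""
    return sig_a * (2.0 + (SIGNAL_RATIO - 1.0) * n_A) + sig_env


def preference_array(
    n_cr: np.ndarray,
    inheritance_mode: InheritanceMode,
    cn_value: float = CN_VALUE_DEFAULT,
    cr_value: float = CR_VALUE,
) -> np.ndarray:
    """Expressed choice probability (of a normal male) per female, from the
    per-female count of C_R alleles."""
    if inheritance_mode == "CR_dominant":
        het = cr_value
    elif inheritance_mode == "CR_recessive":
        het = cn_value
    elif inheritance_mode == "intermediate":
        het = 0.5 * (cn_value + cr_value)
    else:
        raise ValueError(f"unknown inheritance mode {inheritance_mode!r}")
    return np.select([n_cr == 2, n_cr == 1], [cr_value, het], default=cn_value)
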