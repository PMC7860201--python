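"""Exogenous male-signal component (developmental-climate model).

The model never represents temperature itself, only its effect on male-signal
production.  The population-mean exogenous signal is constant during a
burn-in and then rises linearly (slope ``b_sig`` per year).  On top of the
mean, each year gets one shared normal deviation (between-year climatic
variance) and each newborn an independent normal deviation (within-year,
microclimatic variance).  Only newborns experience the climate: the signal
acts during the sensitive period of early development and the phenotype is
fixed thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClimateParams", "YearClimate", "mean_signal", "draw_year", "individual_sig_env"]


@dataclass(frozen=True)
class ClimateParams:
    """Warming trajectory and climatic noise, all in signal units.

    Defaults reproduce a contemporary-warming parameterization: no
    masculinization before warming starts, with the slope calibrated so a
    ZW/XY population reaches ~9% masculinization after three decades.
    """

    b_sig: float = 0.003
    sd_between: float = 0.01
    sd_within: float = 0.05
    burn_in_years: int = 50
    m0: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_between < 0 or self.sd_within < 0:
            raise ValueError("climatic standard deviations must be >= 0")

    @property
    def sigma_total(self) -> float:
        """Total s.d. of an individual's exogenous signal within a stable climate."""
        return float(np.hypot(self.sd_between, self.sd_within))


@dataclass(frozen=True)
class YearClimate:
    """One year's realized climate (year 0 = start of warming; burn-in years
    are negative)."""

    year: int
    mean_sig: float
    eps_B_draw: float


def mean_signal(year: int, params: ClimateParams) -> float:
    """Population-mean exogenous signal in a given year: ``m0`` through the
    burn-in (year <= 0) and ``m0 + b_sig * year`` afterwards."""
    if year < -params.burn_in_years:
        raise ValueError(f"year {year} precedes the burn-in start")
    return params.m0 + params.b_sig * max(0, year)


def draw_year(year: int, params: ClimateParams, rng: np.random.Generator) -> YearClimate:
    """Draw the year's shared between-year deviation."""
    eps_b = rng.normal(0.0, params.sd_between) if params.sd_between > 0 else 0.0
    return YearClimate(year=year, mean_sig=mean_signal(year, params), eps_B_draw=eps_b)


def individual_sig_env(
    yc: YearClimate,
    params: ClimateParams,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Exogenous signal for one newborn (``size=None``) or a cohort.

    Every offspring of a year shares the year's ``eps_B_draw``; the
    within-year deviations are independent across offspring.
    """
    base = yc.mean_sig + yc.eps_B_draw
    if size is None:
        return base + (rng.normal(0.0, params.sd_within) if params.sd_within > 0 else 0.0)
    if params.sd_within > 0:
        return base + rng.normal(0.0, params.sd_within, size=size)
    return np.full(size, base)
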