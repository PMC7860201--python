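"""Scenario configuration and the yearly simulation loop.

One simulated year is: census the breeding adults, form pairs, produce the
offspring cohort (recording a :class:`YearRecord` row), apply survival to
everybody including the newborns, then age the population by one year.  A
run starts ``burn_in_years`` before warming (year 0 = start of warming) and
terminates when no phenotypic females are left in any age group (extinction)
or at ``max_warming_years``.

Every run is a pure function of (scenario, seed); replicate seeds in a batch
are fanned out with :class:`numpy.random.SeedSequence` so batches are
order-independent and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .climate import ClimateParams, draw_year
from .genetics import GeneticsParams
from .mating import DEFAULT_LIBIDO, form_pairs, normal_male_mask, reproduce
from .population import (LifeHistoryParams, Population, advance_year,
                         annual_survival, build_initial_population)
from . import summaries

__all__ = ["ScenarioConfig", "RunResult", "run_simulation", "run_batch",
           "main_scenarios", "load_scenario", "scenario_path",
           "write_records", "read_records"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one simulation scenario.

    The six main scenarios are the crossing of the initial system (XY or ZW)
    with the preference setting: 0% C_R (all females prefer normal males),
    10% C_R dominant, or 90% C_R recessive.
    """

    name: str = "scenario"
    initial_system: Literal["XY", "ZW"] = "ZW"
    cr_init_freq: float = 0.0
    cr_inheritance: Literal["CR_dominant", "CR_recessive", "intermediate"] = "CR_dominant"
    cn_value: float = 0.9
    libido: int = DEFAULT_LIBIDO
    climate: ClimateParams = field(default_factory=ClimateParams)
    life: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    genetics: GeneticsParams = field(default_factory=GeneticsParams)
    max_warming_years: int = 600
    seed: int | None = None

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "climate" in d and isinstance(d["climate"], dict):
            d["climate"] = ClimateParams(**d["climate"])
        if "life" in d and isinstance(d["life"], dict):
            d["life"] = LifeHistoryParams(**d["life"])
        if "genetics" in d and isinstance(d["genetics"], dict):
            d["genetics"] = GeneticsParams(**d["genetics"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def scenario_path(name: str) -> Path:
    """Path of a bundled scenario config."""
    return Path(__file__).parent / "scenarios" / f"{name}.yaml"


def load_scenario(name_or_path) -> ScenarioConfig:
    """Load a scenario from a bundled name (e.g. ``zw_cr10``) or a file path."""
    p = Path(name_or_path)
    if not p.exists():
        p = scenario_path(str(name_or_path))
    if not p.exists():
        raise FileNotFoundError(f"no scenario file or bundled scenario {name_or_path!r}")
    return ScenarioConfig.from_yaml(p)


def main_scenarios() -> dict[str, ScenarioConfig]:
    """The six main scenarios: {XY, ZW} x {0%, 10% dominant, 90% recessive}."""
    out = {}
    for system in ("XY", "ZW"):
        s = system.lower()
        out[f"{s}_cr0"] = ScenarioConfig(
            name=f"{s}_cr0", initial_system=system, cr_init_freq=0.0)
        out[f"{s}_cr10"] = ScenarioConfig(
            name=f"{s}_cr10", initial_system=system, cr_init_freq=0.1,
            cr_inheritance="CR_dominant")
        out[f"{s}_cr90"] = ScenarioConfig(
            name=f"{s}_cr90", initial_system=system, cr_init_freq=0.9,
            cr_inheritance="CR_recessive")
    return out


@dataclass
class RunResult:
    """One run: the per-year record table plus derived run-level events."""

    scenario: str
    seed: int
    records: pd.DataFrame
    extinction_year: int | None
    periods: list[tuple[str, int, int]] = field(default_factory=list)
    decline_year: int | None = None
    generation_time: float = float("nan")

    # accumulated parental-age sums backing the generation-time estimate
    parent_age_sum: float = 0.0
    parent_age_n: int = 0


_GENO_KEYS = ("AA", "Aa", "aa")


def _record_year(pop, cohort, pairing, scenario, rec):
    """Append one census row (adults at pairing + this year's cohort)."""
    life = scenario.life
    adult = pop.adults_mask(life.maturation_age)
    a_idx = np.flatnonzero(adult)
    male = pop.male[a_idx]
    n_A = pop.c0[a_idx] + pop.c1[a_idx]
    n_ad = a_idx.size
    n_m = int(male.sum())
    n_f = n_ad - n_m

    rec["year"].append(pop.year)
    rec["n_adults"].append(n_ad)
    rec["n_adult_f"].append(n_f)
    rec["n_adult_m"].append(n_m)
    rec["asr"].append(n_m / n_ad if n_ad else np.nan)

    for g, cnt in zip(_GENO_KEYS, (2, 1, 0)):
        rec[f"n_m_{g}"].append(int(((n_A == cnt) & male).sum()))
        rec[f"n_f_{g}"].append(int(((n_A == cnt) & ~male).sum()))

    males_idx = a_idx[male]
    if n_m:
        normal = normal_male_mask(pop, scenario.initial_system, males_idx)
        frac_norm = float(normal.mean())
    else:
        frac_norm = np.nan
    rec["frac_normal_m"].append(frac_norm)
    rec["frac_rev_m"].append(1.0 - frac_norm if n_m else np.nan)

    cr = pop.p0[a_idx] + pop.p1[a_idx]
    rec["freq_cr"].append(float(cr.mean()) / 2.0 if n_ad else np.nan)
    rec["freq_cr_f"].append(float(cr[~male].mean()) / 2.0 if n_f else np.nan)
    rec["freq_cr_m"].append(float(cr[male].mean()) / 2.0 if n_m else np.nan)
    rec["freq_A"].append(float(n_A.mean()) / 2.0 if n_ad else np.nan)
    low = (pop.t0[a_idx] == 0).astype(np.int16) + (pop.t1[a_idx] == 0)
    rec["freq_thr_low"].append(float(low.mean()) / 2.0 if n_ad else np.nan)

    ne = summaries.effective_size(n_f, n_m)
    rec["ne"].append(ne)
    rec["d_cr_A"].append(summaries._burrows(cr, n_A) if n_ad >= 2 else np.nan)
    rec["d_cr_thrlow"].append(summaries._burrows(cr, low) if n_ad >= 2 else np.nan)

    # cohort statistics
    n_off = cohort.n if cohort is not None else 0
    rec["n_mother"].append(pairing.n_mother if pairing is not None else 0)
    rec["n_conceived"].append(cohort.conceived if cohort is not None else 0)
    rec["n_offspring"].append(n_off)
    if n_off:
        off = cohort.offspring
        off_nA = off.c0 + off.c1
        if scenario.initial_system == "ZW":
            fem_geno = off_nA <= 1          # Aa and aa (WW) are genetic females
        else:
            fem_geno = off_nA == 0          # aa (XX)
        at_risk = int(fem_geno.sum())
        masc = int((fem_geno & off.male).sum())
        rec["masc_at_risk"].append(at_risk)
        rec["masc_n"].append(masc)
        rec["masc_rate"].append(masc / at_risk if at_risk else np.nan)
        rec["freq_cr_pat"].append(float(cohort.pat_haplotype["pref"].mean()))
        rec["freq_cr_mat"].append(float(cohort.mat_haplotype["pref"].mean()))
        cr_mother = cohort.mother_pref < 0.5
        cn_mother = cohort.mother_pref > 0.5
        rec["psr_cr"].append(float(off.male[cr_mother].mean()) if cr_mother.any() else np.nan)
        rec["psr_cn"].append(float(off.male[cn_mother].mean()) if cn_mother.any() else np.nan)
    else:
        for k in ("masc_rate", "freq_cr_pat", "freq_cr_mat", "psr_cr", "psr_cn"):
            rec[k].append(np.nan)
        rec["masc_at_risk"].append(0)
        rec["masc_n"].append(0)
    rec["s"].append(
        summaries.sexratio_selection_coefficient(
            rec["psr_cr"][-1], rec["psr_cn"][-1], rec["asr"][-1]
        )
    )


_RECORD_COLUMNS = (
    ["year", "n_adults", "n_adult_f", "n_adult_m", "asr"]
    + [f"n_{s}_{g}" for s in ("m", "f") for g in _GENO_KEYS]
    + ["frac_normal_m", "frac_rev_m", "freq_cr", "freq_cr_f", "freq_cr_m",
       "freq_A", "freq_thr_low", "ne", "d_cr_A", "d_cr_thrlow",
       "n_mother", "n_conceived", "n_offspring", "masc_at_risk", "masc_n",
       "masc_rate", "freq_cr_pat", "freq_cr_mat", "psr_cr", "psr_cn", "s"]
)


def run_simulation(scenario: ScenarioConfig, seed: int | None = None) -> RunResult:
    """Simulate one replicate of a scenario.

    Returns the per-year :class:`pandas.DataFrame` of records together with
    the derived events (sex-determination periods, extinction and decline
    years, generation time).
    """
    if seed is None:
        seed = scenario.seed if scenario.seed is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop = build_initial_population(scenario.initial_system, scenario, rng)

    rec: dict[str, list] = {k: [] for k in _RECORD_COLUMNS}
    extinction_year = None
    age_sum = 0.0
    age_n = 0

    while True:
        yc = draw_year(pop.year, scenario.climate, rng)
        pairing = form_pairs(
            pop, scenario.initial_system, scenario.cr_inheritance,
            scenario.cn_value, scenario.life.maturation_age, rng,
            libido=scenario.libido,
        )
        cohort = reproduce(
            pop, pairing, yc, scenario.climate, scenario.life,
            scenario.initial_system, scenario.genetics.sig_a, rng,
        ) if pairing.n_mother else None

        _record_year(pop, cohort, pairing, scenario, rec)

        if cohort is not None and cohort.n:
            age_sum += float((cohort.mother_age + cohort.father_age).sum()) / 2.0
            age_n += cohort.n
            pop = Population.concatenate([pop, cohort.offspring])

        pop = annual_survival(pop, scenario.life, rng)
        pop = advance_year(pop)

        if not (~pop.male).any():
            extinction_year = pop.year
            break
        if pop.year > scenario.max_warming_years:
            break

    records = pd.DataFrame(rec)
    result = RunResult(
        scenario=scenario.name, seed=int(seed), records=records,
        extinction_year=extinction_year,
        parent_age_sum=age_sum, parent_age_n=age_n,
        generation_time=age_sum / age_n if age_n else float("nan"),
    )
    result.periods = summaries.detect_periods(records, scenario.initial_system)
    result.decline_year = summaries.decline_year(records)
    return result


def run_batch(
    scenario: ScenarioConfig,
    n_runs: int,
    base_seed: int = 0,
    progress: bool = False,
) -> list[RunResult]:
    """Run ``n_runs`` independent replicates with seeds fanned out
    deterministically (counter-based) from ``base_seed``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    iterator = range(n_runs)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc=scenario.name)
        except ImportError:
            pass
    for i in iterator:
        seed = derive_seed(base_seed, i)
        results.append(run_simulation(scenario, seed=seed))
    return results


def derive_seed(base_seed: int, index: int) -> int:
    """Replicate seed for run ``index`` of a batch (stable, < 2**31)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(index,))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


# -- record table / event-summary IO ----------------------------------------

def write_records(result: RunResult, path) -> None:
    """Write the per-year record table as CSV (UTF-8, header row)."""
    result.records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(result: RunResult, path) -> None:
    """Write the per-run event summary as JSON."""
    Path(path).write_text(json.dumps(summaries.summarize_run(result), indent=2))
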