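"""Shared fixtures: seeded RNGs and cached replicate batches.

The replicate batches back the acceptance tests; they are session-scoped so
each scenario's runs are simulated once.  Seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sexrevsim as sx
from sexrevsim.engine import main_scenarios

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def _batch(name: str, n: int, base_seed: int, **overrides):
    cfg = main_scenarios()[name]
    if overrides:
        cfg = cfg.replace(name=f"{name}_var", **overrides)
    return sx.run_batch(cfg, n, base_seed=base_seed)


@pytest.fixture(scope="session")
def xy_cr0_batch():
    return _batch("xy_cr0", 30, base_seed=101)


@pytest.fixture(scope="session")
def zw_cr0_batch():
    return _batch("zw_cr0", 30, base_seed=102)


@pytest.fixture(scope="session")
def zw_cr10_batch():
    return _batch("zw_cr10", 100, base_seed=103)


@pytest.fixture(scope="session")
def xy_cr10_batch():
    return _batch("xy_cr10", 100, base_seed=104)


@pytest.fixture(scope="session")
def xy_cr90_batch():
    return _batch("xy_cr90", 100, base_seed=105)


@pytest.fixture(scope="session")
def zw_cr90_batch():
    return _batch("zw_cr90", 100, base_seed=106)


def _phi25(cr: str):
    cfg = main_scenarios()[f"zw_{cr}"]
    return cfg.replace(name=f"zw_{cr}_phi25",
                       life=sx.LifeHistoryParams(ww_viability=0.25))


@pytest.fixture(scope="session")
def phi25_batches():
    return {
        "cr0": sx.run_batch(_phi25("cr0"), 100, base_seed=107),
        "cr10": sx.run_batch(_phi25("cr10"), 100, base_seed=108),
        "cr90": sx.run_batch(_phi25("cr90"), 100, base_seed=109),
    }


@pytest.fixture(scope="session")
def burnin_runs():
    """Extended no-warming runs (b_sig = 0 throughout, 200 recorded years)."""
    cfg = main_scenarios()["zw_cr0"].replace(
        name="burnin",
        climate=sx.ClimateParams(b_sig=0.0, burn_in_years=50),
        max_warming_years=150,
    )
    return [sx.run_simulation(cfg, seed=300 + i) for i in range(4)]
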