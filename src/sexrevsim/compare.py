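"""Scenario-level statistics on per-run metrics.

Pairwise scenario contrasts come from a one-way pooled-variance linear
model (least-squares-means style contrasts) with Bonferroni adjustment;
within-run frequency changes are tested with a paired t-test; the low
WW-viability scenarios, whose persistence times are bimodal, are compared
with Mood's median test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricSample", "bonferroni", "pairwise_contrasts",
           "paired_change_test", "median_test"]


@dataclass(frozen=True)
class MetricSample:
    """One metric's per-run values for one scenario."""

    scenario: str
    metric: str
    values: tuple[float, ...]

    @classmethod
    def from_runs(cls, scenario: str, metric: str, values) -> "MetricSample":
        return cls(scenario, metric, tuple(float(v) for v in values))


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment over a family: ``min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def pairwise_contrasts(samples: Sequence[MetricSample]) -> pd.DataFrame:
    """All pairwise mean differences among scenarios under a one-way linear
    model with pooled error variance.

    Returns a table with columns ``pair``, ``estimate`` (mean difference),
    ``t``, ``df``, ``p_raw`` and ``p_adjusted`` (Bonferroni over all
    contrasts submitted together).  Zero pooled variance yields missing
    p-values.
    """
    if len(samples) < 2:
        raise ValueError("need at least two scenarios")
    groups = {s.scenario: np.asarray(s.values, dtype=float) for s in samples}
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("need at least two runs per scenario")
    ns = {k: v.size for k, v in groups.items()}
    means = {k: v.mean() for k, v in groups.items()}
    n_total = sum(ns.values())
    df_err = n_total - len(groups)
    sse = sum(float(((v - means[k]) ** 2).sum()) for k, v in groups.items())
    mse = sse / df_err

    rows = []
    for a, b in combinations(groups, 2):
        est = means[a] - means[b]
        if mse > 0:
            se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), df_err)
        elif est == 0.0:
            t, p = 0.0, 1.0           # identical samples
        else:
            t, p = np.nan, np.nan     # zero-variance but unequal: degenerate
        rows.append({"pair": f"{a} - {b}", "estimate": est, "t": t,
                     "df": df_err, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.where(np.isfinite(out["p_raw"]),
                                 bonferroni(out["p_raw"].to_numpy()), np.nan)
    return out


def paired_change_test(start_values, end_values) -> dict:
    """Paired t-test on end - start (the within-run change of a 5-year-mean
    frequency over a window).

    Returns the mean change, its 95% CI, the t statistic with n-1 degrees
    of freedom and the two-sided p-value.  Zero-variance differences give a
    zero-width CI and p = 1 for a zero mean (p = 0 otherwise, by
    convention).
    """
    start = np.asarray(start_values, dtype=float)
    end = np.asarray(end_values, dtype=float)
    if start.size != end.size or start.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = end - start
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return {"mean_change": mean, "ci95": (mean, mean), "t": np.inf if mean else 0.0,
                "df": n - 1, "p": 0.0 if mean else 1.0}
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    half = stats.t.ppf(0.975, n - 1) * se
    return {"mean_change": mean, "ci95": (mean - half, mean + half),
            "t": float(t), "df": n - 1, "p": float(p)}


def median_test(samples: Sequence[tuple[np.ndarray, np.ndarray]] | tuple) -> np.ndarray:
    """Mood's median test for one or more sample pairs, Bonferroni-adjusted
    across the pairs submitted together.

    Accepts a single ``(x, y)`` pair or a sequence of pairs; returns the
    adjusted p-value array (a scalar array of size 1 for a single pair).
    All-equal values give p = 1.
    """
    if isinstance(samples, tuple) and len(samples) == 2 \
            and not isinstance(samples[0], tuple):
        samples = [samples]
    ps = []
    for x, y in samples:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0 or y.size == 0:
            raise ValueError("samples must be non-empty")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            ps.append(1.0)
            continue
        res = stats.median_test(x, y)
        ps.append(float(res.pvalue))
    return bonferroni(ps)
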