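"""Shared fixtures and independent oracles.

The oracles here deliberately recompute quantities the naive way (exhaustive
scans, per-segment statistics from scratch, permutation enumeration) so that
they stay independent of the production code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lagoondate import Metric, ReflectanceSeries


def make_series(values, site_id="s", start="2000-01-01", step=16) -> ReflectanceSeries:
    """Series with evenly spaced dates, for tests that only care about values."""
    values = np.asarray(values, float)
    dates = np.datetime64(start) + np.arange(values.size) * np.timedelta64(step, "D")
    return ReflectanceSeries(site_id, dates, values)


def exhaustive_changepoint(values, metric: Metric):
    """O(n^2) argmin over admissible splits, each segment cost from scratch.

    Returns (tau, cost). Ties go to the smallest tau (first strict minimum).
    """
    x = np.asarray(values, float)
    n = x.size
    m = 1 if metric is Metric.MEAN else 2
    best_tau, best_cost = None, np.inf
    for tau in range(m - 1, n - m):
        cost = 0.0
        for seg in (x[: tau + 1], x[tau + 1 :]):
            if metric is Metric.MEAN:
                cost += float(np.sum((seg - seg.mean()) ** 2))
            else:
                sigma2 = float(np.var(seg))
                cost += seg.size * float(np.log(max(sigma2, 1e-8)))
        if cost < best_cost:
            best_tau, best_cost = tau, cost
    return best_tau, best_cost


def mk_exact_p(values) -> float:
    """Two-sided exact permutation p-value for the Mann-Kendall S statistic."""
    x = np.asarray(values, float)

    def S_of(v):
        v = np.asarray(v, float)
        return int(np.triu(np.sign(v[None, :] - v[:, None]), 1).sum())

    s_obs = abs(S_of(x))
    if s_obs == 0:
        return 1.0
    count = 0
    total = 0
    for perm in itertools.permutations(x):
        total += 1
        if abs(S_of(perm)) >= s_obs:
            count += 1
    return count / total


@pytest.fixture
def rng():
    return np.random.default_rng(20231104)
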