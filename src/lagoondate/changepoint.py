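"""Single-changepoint detection under a normal-likelihood cost.

With the search constrained to exactly one changepoint, binary segmentation
coincides with the at-most-one-change (AMOC) search: scan every admissible
split of the series into segments S1 (before the change) and S2 (after), and
keep the split minimising the total segment cost. Two cost metrics are
offered:

* ``MEAN`` — change in mean at common variance: the cost of a segment is its
  sum of squared deviations from the segment mean (residual sum of squares).
* ``MEANVAR`` — change in mean and variance: the cost of a segment of length
  n_k with maximum-likelihood variance sigma2_k is ``n_k * ln(max(sigma2_k,
  eps))``, the variance-profile of twice the negative normal log-likelihood
  up to constants; ``eps`` floors the logarithm on numerically flat segments.

The scan is computed with prefix sums in O(n); an exhaustive per-split
recomputation is used only as a test oracle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .series import ReflectanceSeries

__all__ = ["Metric", "ChangepointFit", "detect_single_changepoint", "segment_costs"]

VARIANCE_FLOOR = 1e-8  # on the squared reflectance scale; guards ln(0)
DEGENERATE_MEAN_FLOOR = 1e-6  # |s1_mean - s2_mean| below this flags "no change"


class Metric(str, enum.Enum):
    """Which distributional change the normal cost is sensitive to."""

    MEAN = "mean"
    MEANVAR = "meanvar"

    @property
    def min_seg(self) -> int:
        # MEANVAR needs 2 points per segment to define a variance
        return 1 if self is Metric.MEAN else 2


@dataclass(frozen=True)
class ChangepointFit:
    """Best single split of a series.

    ``tau`` is the 0-based index of the last observation of S1; the
    changepoint date is the date of observation ``tau + 1``, i.e. the first
    observation of S2 (the first image showing the changed state).
    ``degenerate`` is set when the fit carries no meaningful change: segment
    means closer than a small floor, or a zero-variance segment under
    ``MEANVAR``.
    """

    site_id: str
    tau: int
    s1_mean: float
    s2_mean: float
    s1_var: float
    s2_var: float
    cost: float
    metric: Metric
    changepoint_date: np.datetime64
    degenerate: bool = False


def _segment_cost(values: np.ndarray, metric: Metric) -> float:
    n = values.size
    mu = values.mean()
    if metric is Metric.MEAN:
        return float(np.sum((values - mu) ** 2))
    sigma2 = float(np.mean((values - mu) ** 2))
    return n * float(np.log(max(sigma2, VARIANCE_FLOOR)))


def segment_costs(
    series: ReflectanceSeries, tau: int, metric: Metric = Metric.MEAN
) -> tuple[float, float]:
    """Costs of S1 = values[:tau+1] and S2 = values[tau+1:] under ``metric``."""
    n = len(series)
    m = metric.min_seg
    if not (m <= tau + 1 <= n - m):
        raise ValueError(f"tau={tau} is not an admissible split for n={n}, metric={metric.value}")
    return (
        _segment_cost(series.values[: tau + 1], metric),
        _segment_cost(series.values[tau + 1 :], metric),
    )


def detect_single_changepoint(
    series: ReflectanceSeries,
    metric: Metric = Metric.MEAN,
    degenerate_floor: float = DEGENERATE_MEAN_FLOOR,
) -> ChangepointFit:
    """Return the admissible split minimising total segment cost.

    Ties are broken toward the smallest ``tau``. MEAN requires n >= 2,
    MEANVAR n >= 4.
    """
    metric = Metric(metric)
    x = series.values
    n = x.size
    m = metric.min_seg
    if n < 2 * m:
        raise ValueError(
            f"series {series.site_id!r}: need at least {2 * m} observations for {metric.value}"
        )

    # prefix sums give every segment mean and sum of squares in O(1)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    taus = np.arange(m - 1, n - m)  # admissible last-index-of-S1 values
    n1 = taus + 1
    n2 = n - n1
    s1_sum, s1_sq = c1[n1], c2[n1]
    s2_sum, s2_sq = c1[n] - c1[n1], c2[n] - c2[n1]
    # MLE variance = E[x^2] - mean^2, clipped against roundoff
    v1 = np.maximum(s1_sq / n1 - (s1_sum / n1) ** 2, 0.0)
    v2 = np.maximum(s2_sq / n2 - (s2_sum / n2) ** 2, 0.0)
    if metric is Metric.MEAN:
        costs = n1 * v1 + n2 * v2
    else:
        costs = n1 * np.log(np.maximum(v1, VARIANCE_FLOOR)) + n2 * np.log(
            np.maximum(v2, VARIANCE_FLOOR)
        )

    best = int(np.argmin(costs))  # argmin returns the first minimum: smallest tau
    tau = int(taus[best])
    k = tau + 1
    s1, s2 = x[:k], x[k:]
    s1_mean, s2_mean = float(s1.mean()), float(s2.mean())
    s1_var = float(np.mean((s1 - s1_mean) ** 2))
    s2_var = float(np.mean((s2 - s2_mean) ** 2))
    degenerate = abs(s1_mean - s2_mean) < degenerate_floor
    if metric is Metric.MEANVAR and (s1_var < VARIANCE_FLOOR or s2_var < VARIANCE_FLOOR):
        degenerate = True  # variance floor engaged: the cost there is not informative
    return ChangepointFit(
        site_id=series.site_id,
        tau=tau,
        s1_mean=s1_mean,
        s2_mean=s2_mean,
        s1_var=s1_var,
        s2_var=s2_var,
        cost=float(costs[best]),
        metric=metric,
        changepoint_date=series.dates[k],
        degenerate=degenerate,
    )
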