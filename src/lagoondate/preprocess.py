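"""Cleaning of raw reflectance series before changepoint detection.

Two steps, applied in this order: removal of bright contaminated observations
(clouds and similar artifacts push scaled surface reflectance above 10,000),
then a light linear smoother. Removal runs first so the smoother never smears
a contaminated value into its neighbours.
"""

from __future__ import annotations

import numpy as np

from .series import ReflectanceSeries

__all__ = ["UnusableSeriesError", "remove_bright", "linear_filter"]

BRIGHT_THRESHOLD = 10_000.0


class UnusableSeriesError(ValueError):
    """Raised when cleaning leaves a series with no usable observations."""


def remove_bright(
    series: ReflectanceSeries, threshold: float = BRIGHT_THRESHOLD
) -> ReflectanceSeries:
    """Drop observations whose reflectance strictly exceeds ``threshold``.

    A value exactly at the threshold is retained. Idempotent; the input is
    not modified.

    Raises
    ------
    UnusableSeriesError
        If every observation exceeds the threshold.
    """
    keep = series.values <= threshold
    if not keep.any():
        raise UnusableSeriesError(
            f"series {series.site_id!r}: no observations at or below {threshold}"
        )
    return series.subset(keep)


def linear_filter(series: ReflectanceSeries, window: int = 3) -> ReflectanceSeries:
    """Centred moving average over ``window`` observations.

    The window is defined on observation index, not calendar time, mirroring
    per-image processing of irregularly spaced acquisitions. Near the series
    ends the window truncates to the available observations. ``window=1`` is
    the identity, which disables smoothing.

    Raises
    ------
    ValueError
        If ``window`` is even, < 1, or longer than the series.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(series)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series
    kernel = np.ones(window)
    sums = np.convolve(series.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return series.replace_values(sums / counts)
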