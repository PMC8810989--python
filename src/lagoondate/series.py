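"""Core time-series container for per-pixel surface reflectance.

Reflectance is on the scaled-integer convention common to atmospherically
corrected Landsat products: nominal surface reflectance multiplied by 10,000,
so physically plausible land/water values fall in roughly [0, 10000] and
cloud-contaminated pixels exceed 10,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReflectanceSeries", "decimal_year"]


@dataclass(frozen=True)
class ReflectanceSeries:
    """Dated reflectance observations for one site.

    Parameters
    ----------
    site_id
        Identifier of the site (pixel) the series was extracted at.
    dates
        Observation dates, ``numpy.datetime64[D]``, strictly increasing.
    values
        Surface reflectance values (0-10,000 scaled-integer convention;
        values above 10,000 indicate bright contamination). Finite floats.
    """

    site_id: str
    dates: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        values = np.asarray(self.values, dtype=float)
        if dates.shape != values.shape or dates.ndim != 1:
            raise ValueError("dates and values must be 1-d arrays of equal length")
        if dates.size > 1 and not np.all(dates[1:] > dates[:-1]):
            raise ValueError(f"series {self.site_id!r}: dates must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.site_id!r}: values must be finite")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def replace_values(self, values: np.ndarray) -> "ReflectanceSeries":
        """Return a copy with the same dates and new values."""
        return ReflectanceSeries(self.site_id, self.dates.copy(), np.asarray(values, float))

    def subset(self, mask: np.ndarray) -> "ReflectanceSeries":
        """Return a copy keeping only observations where ``mask`` is True."""
        mask = np.asarray(mask, bool)
        return ReflectanceSeries(self.site_id, self.dates[mask], self.values[mask])


def decimal_year(dates: np.ndarray) -> np.ndarray:
    """Convert calendar dates to decimal years (year + day_of_year/365.25).

    Intended for plotting axes only; all analysis code keeps real dates.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    years = dates.astype("datetime64[Y]")
    doy = (dates - years.astype("datetime64[D]")).astype(int)
    return years.astype(int) + 1970 + doy / 365.25
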