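"""Synthetic data with known ground truth for every pipeline stage.

The series generator emulates a Landsat-5-like near-infrared (band 4)
surface-reflectance record at one pixel: a 16-day nominal acquisition
cadence from 1984 to 2012, random cloud censoring of individual
acquisitions, a step down from a vegetated reflectance level to a water
level on the construction date (water absorbs strongly in the NIR),
additive Gaussian noise, occasional bright cloud-contaminated outliers
above 10,000, and an optional sensor-commissioning artifact affecting all
observations in 1984.

Default levels: vegetated mean 3500, water mean 800 (scaled reflectance),
noise sd 300, 20% cloud dropout, 1% bright outliers — a clear but noisy
step, representative of a Coastal-Plain crop/forest pixel converting to an
open waste lagoon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from shapely.geometry import LineString, Polygon

from .geodesic import authalic_ring_area_km2
from .series import ReflectanceSeries
from .spatial import WATER_CLASSES, LagoonSite, WaterFeature

__all__ = [
    "SeriesScenario",
    "TruthRecord",
    "DegenerateScenarioError",
    "simulate_series",
    "simulate_validation_set",
    "simulate_landscape",
]


class DegenerateScenarioError(ValueError):
    """Raised when a scenario cannot yield a usable series (e.g. empty)."""


@dataclass(frozen=True)
class SeriesScenario:
    """Parameters of one simulated reflectance record.

    ``change_date=None`` simulates a pixel that never converts. The first
    observation dated on/after ``change_date`` takes the post-change level
    (the first image showing water). Outlier levels are strictly above
    10,000 so the bright-value cleaning rule removes exactly the injected
    outliers.
    """

    site_id: str = "site"
    record_start: np.datetime64 = np.datetime64("1984-01-01")
    record_end: np.datetime64 = np.datetime64("2012-12-31")
    change_date: np.datetime64 | None = None
    pre_mean: float = 3500.0
    post_mean: float = 800.0
    noise_sd: float = 300.0
    cadence_days: int = 16
    dropout_prob: float = 0.2
    outlier_prob: float = 0.01
    outlier_low: float = 10_001.0
    outlier_high: float = 20_000.0
    artifact_1984: bool = False
    artifact_mean: float = 6000.0
    seed: int = 0

    def __post_init__(self) -> None:
        start = np.datetime64(self.record_start, "D")
        end = np.datetime64(self.record_end, "D")
        object.__setattr__(self, "record_start", start)
        object.__setattr__(self, "record_end", end)
        if self.change_date is not None:
            cd = np.datetime64(self.change_date, "D")
            object.__setattr__(self, "change_date", cd)
            if not (start <= cd <= end):
                raise ValueError("change_date must lie within the record")
        if start >= end:
            raise ValueError("record_start must precede record_end")
        if not (0 <= self.dropout_prob <= 1 and 0 <= self.outlier_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cadence_days < 1:
            raise ValueError("cadence_days must be >= 1")
        if self.outlier_low <= 10_000 or self.outlier_high < self.outlier_low:
            raise ValueError("outlier range must lie strictly above 10,000")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth construction year for one simulated site."""

    site_id: str
    true_change_year: Union[int, str, None]  # year, PRE_ERA sentinel, or None


def simulate_series(scenario: SeriesScenario) -> ReflectanceSeries:
    """Generate one reflectance series from a scenario.

    Deterministic for a given scenario (including its seed).

    Raises
    ------
    DegenerateScenarioError
        If cloud dropout censors every acquisition.
    """
    rng = np.random.default_rng(scenario.seed)
    n_nominal = int((scenario.record_end - scenario.record_start).astype(int)
                    // scenario.cadence_days) + 1
    dates = scenario.record_start + np.arange(n_nominal) * np.timedelta64(
        scenario.cadence_days, "D"
    )
    keep = rng.random(n_nominal) >= scenario.dropout_prob
    if not keep.any():
        raise DegenerateScenarioError(
            f"scenario {scenario.site_id!r}: dropout removed every observation"
        )
    dates = dates[keep]
    base = np.full(dates.size, scenario.pre_mean)
    if scenario.change_date is not None:
        base[dates >= scenario.change_date] = scenario.post_mean
    if scenario.artifact_1984:
        # commissioning-era sensor artifact: overrides whatever is on the ground
        in_1984 = dates.astype("datetime64[Y]") == np.datetime64("1984", "Y")
        base[in_1984] = scenario.artifact_mean
    values = base + rng.normal(0.0, scenario.noise_sd, size=dates.size)
    outlier = rng.random(dates.size) < scenario.outlier_prob
    values[outlier] = rng.uniform(
        scenario.outlier_low, scenario.outlier_high, size=int(outlier.sum())
    )
    return ReflectanceSeries(scenario.site_id, dates, values)


def simulate_validation_set(
    n_sites: int,
    scenario_template: SeriesScenario,
    year_range: tuple[int, int],
    seed: int,
) -> tuple[list[ReflectanceSeries], list[TruthRecord]]:
    """Simulate a validation cohort with known construction years.

    Construction years are drawn uniformly over ``year_range`` (inclusive);
    drawing years at or before the observable era start yields a pre-era
    cohort. The construction date falls on a uniform day within the drawn
    year. The truth table aligns with the series by site_id.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lo, hi = year_range
    if lo > hi:
        raise ValueError("year_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    years = rng.integers(lo, hi + 1, size=n_sites)
    site_seeds = rng.integers(0, 2**31 - 1, size=n_sites)
    series: list[ReflectanceSeries] = []
    truth: list[TruthRecord] = []
    for i, (year, site_seed) in enumerate(zip(years, site_seeds)):
        year_start = np.datetime64(f"{year}-01-01")
        n_days = (np.datetime64(f"{year + 1}-01-01") - year_start).astype(int)
        change = year_start + np.timedelta64(int(rng.integers(0, n_days)), "D")
        change = min(max(change, scenario_template.record_start), scenario_template.record_end)
        site_id = f"site{i:04d}"
        scen = replace(
            scenario_template, site_id=site_id, change_date=change, seed=int(site_seed)
        )
        series.append(simulate_series(scen))
        truth.append(TruthRecord(site_id=site_id, true_change_year=int(year)))
    return series, truth


def simulate_landscape(
    n_sites: int,
    n_features: int,
    bbox: tuple[float, float, float, float],
    seed: int,
) -> tuple[list[LagoonSite], list[WaterFeature]]:
    """Random sites and classed water features inside a lon/lat bbox.

    Features alternate between small axis-aligned rectangles (polygons, with
    geodesic areas) and two-segment polylines (area 0), with classes drawn
    from the allowed water-feature set.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ValueError("bbox must be a non-degenerate (lon_min, lat_min, lon_max, lat_max)")
    rng = np.random.default_rng(seed)
    sites = [
        LagoonSite(
            f"lagoon{i:04d}",
            float(rng.uniform(lon_min, lon_max)),
            float(rng.uniform(lat_min, lat_max)),
        )
        for i in range(n_sites)
    ]
    classes = sorted(WATER_CLASSES)
    features: list[WaterFeature] = []
    w, h = lon_max - lon_min, lat_max - lat_min
    for j in range(n_features):
        fclass = classes[int(rng.integers(len(classes)))]
        cx = float(rng.uniform(lon_min + 0.1 * w, lon_max - 0.1 * w))
        cy = float(rng.uniform(lat_min + 0.1 * h, lat_max - 0.1 * h))
        if j % 2 == 0:  # rectangle
            half_w = float(rng.uniform(0.01, 0.08)) * w / 2
            half_h = float(rng.uniform(0.01, 0.08)) * h / 2
            geom = Polygon(
                [
                    (cx - half_w, cy - half_h),
                    (cx + half_w, cy - half_h),
                    (cx + half_w, cy + half_h),
                    (cx - half_w, cy + half_h),
                ]
            )
            area = authalic_ring_area_km2(np.asarray(geom.exterior.coords))
        else:  # two-segment polyline
            pts = np.column_stack(
                [
                    cx + rng.uniform(-0.05, 0.05, 3) * w,
                    cy + rng.uniform(-0.05, 0.05, 3) * h,
                ]
            )
            geom = LineString(pts)
            area = 0.0
        features.append(WaterFeature(f"feat{j:04d}", fclass, geom, area))
    return sites, features
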