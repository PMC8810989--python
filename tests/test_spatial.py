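"""Spatial stage: geodesic distances, cohort summaries, trend test, density."""

import subprocess

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import LineString, Polygon

from lagoondate import (
    ConstructionEstimate,
    LagoonSite,
    PRE_ERA,
    WaterFeature,
    annual_median_distances,
    density_by_polygon,
    filter_water_features,
    geodesic_distance,
    mann_kendall,
    nearest_water_distance,
    summarize_by_cohort,
)
from lagoondate.geodesic import authalic_ring_area_km2
from .conftest import mk_exact_p

RECT = Polygon([(-77.6, 35.0), (-77.4, 35.0), (-77.4, 35.2), (-77.6, 35.2)])
RECT_AREA = authalic_ring_area_km2(np.asarray(RECT.exterior.coords))


def feature(geom, fid="f1", fclass="lake/pond", area=None):
    if area is None:
        area = (
            authalic_ring_area_km2(np.asarray(geom.exterior.coords))
            if geom.geom_type == "Polygon"
            else 0.0
        )
    return WaterFeature(fid, fclass, geom, area)


class TestAreaFilter:
    def test_small_polygons_removed_boundary_kept(self):
        tiny = feature(RECT, "tiny", area=0.04)
        edge = feature(RECT, "edge", area=0.05)
        line = feature(LineString([(-77.5, 35.0), (-77.5, 35.3)]), "line", area=0.0)
        kept = filter_water_features([tiny, edge, line])
        assert [f.feature_id for f in kept] == ["edge", "line"]

    def test_empty_input(self):
        assert filter_water_features([]) == []


class TestNearestDistance:
    def test_site_on_vertex_and_inside_polygon(self):
        f = feature(RECT)
        on_vertex = nearest_water_distance(LagoonSite("v", -77.4, 35.0), [f])
        inside = nearest_water_distance(LagoonSite("i", -77.5, 35.1), [f])
        assert on_vertex.distance_m == 0.0
        assert inside.distance_m == 0.0 and inside.feature_id == "f1"

    def test_offset_site_matches_direct_ellipsoidal_solve(self):
        # site due east of the rectangle: nearest boundary point is on the
        # eastern edge at the site's latitude
        site = LagoonSite("s", -77.3, 35.1)
        rec = nearest_water_distance(site, [feature(RECT)])
        oracle = geodesic_distance(-77.3, 35.1, -77.4, 35.1)
        assert rec.distance_m == pytest.approx(oracle, abs=1.0)

    def test_polyline_distance_matches_direct_solve(self):
        line = LineString([(-77.5, 34.9), (-77.5, 35.3)])
        site = LagoonSite("s", -77.45, 35.1)
        rec = nearest_water_distance(site, [feature(line, "l")])
        oracle = geodesic_distance(-77.45, 35.1, -77.5, 35.1)
        assert rec.distance_m == pytest.approx(oracle, abs=1.0)

    def test_densification_refinement_stable(self):
        site = LagoonSite("s", -77.3, 35.17)
        a = nearest_water_distance(site, [feature(RECT)], max_step_deg=0.001)
        b = nearest_water_distance(site, [feature(RECT)], max_step_deg=0.0005)
        assert abs(a.distance_m - b.distance_m) < 1.0

    def test_adding_features_never_increases_minimum(self):
        site = LagoonSite("s", -77.0, 35.1)
        far = feature(RECT, "far")
        near = feature(
            Polygon([(-77.1, 35.0), (-77.05, 35.0), (-77.05, 35.2), (-77.1, 35.2)]),
            "near",
        )
        d_far = nearest_water_distance(site, [far]).distance_m
        d_both = nearest_water_distance(site, [far, near]).distance_m
        assert d_both <= d_far and d_both >= 0.0

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_water_distance(LagoonSite("s", 0, 0), [])

    def test_vincenty_primitive_matches_r_geosphere(self):
        pairs = [(-77.0, 35.0, -77.4, 35.1), (-78.2, 34.9, -78.1, 34.95), (0.0, 0.0, 0.5, 0.25)]
        script = "library(geosphere);" + ";".join(
            f"cat(distGeo(c({a},{b}),c({c},{d})),'\\n')" for a, b, c, d in pairs
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = [float(v) for v in out.stdout.split()]
        for (a, b, c, d), e in zip(pairs, expected):
            assert geodesic_distance(a, b, c, d) == pytest.approx(e, abs=0.01)


class TestCohortSummary:
    def make(self, dists, years):
        from lagoondate import NearestDistanceRecord

        recs, ests = [], []
        for i, (d, y) in enumerate(zip(dists, years)):
            sid = f"s{i}"
            recs.append(NearestDistanceRecord(sid, f"f{i}", "stream/river", d))
            if y == PRE_ERA:
                ests.append(ConstructionEstimate(sid, PRE_ERA))
            else:
                ests.append(ConstructionEstimate(sid, "YEAR", y))
        return recs, ests

    def test_single_cohort_mean_median(self):
        recs, ests = self.make([100, 200, 300], [1990, 1990, 1991])
        df = summarize_by_cohort(recs, ests)
        row = df[(df.cohort == "1990-1991") & (df.fclass == "all")].iloc[0]
        assert row.mean_m == 200 and row.median_m == 200 and row.n == 3

    def test_absent_class_cells_are_missing_rows(self):
        recs, ests = self.make([50], [1995])
        df = summarize_by_cohort(recs, ests)
        assert not ((df.cohort == "1994-1995") & (df.fclass == "reservoir")).any()

    def test_single_record_mean_equals_median(self):
        recs, ests = self.make([123.0], [PRE_ERA])
        df = summarize_by_cohort(recs, ests)
        row = df[(df.cohort == "<1987") & (df.fclass == "all")].iloc[0]
        assert row.mean_m == row.median_m == 123.0

    def test_record_conservation_across_cohorts(self, rng):
        years = [PRE_ERA] * 5 + list(rng.integers(1987, 2011, 45))
        dists = list(rng.uniform(10, 900, 50))
        recs, ests = self.make(dists, [int(y) if y != PRE_ERA else y for y in years])
        df = summarize_by_cohort(recs, ests)
        assert df[df.fclass == "all"].n.sum() == 50

    def test_missing_estimate_raises(self):
        recs, _ = self.make([10.0], [1990])
        with pytest.raises(KeyError):
            summarize_by_cohort(recs, [])


class TestMannKendall:
    def test_constant_series_degenerate(self):
        res = mann_kendall([4.0] * 6)
        assert res.S == 0 and res.trend == "none" and res.degenerate

    def test_reversal_negates_S(self, rng):
        x = rng.normal(0, 1, 12)
        assert mann_kendall(x).S == -mann_kendall(x[::-1]).S

    def test_hand_formulas_without_ties(self):
        res = mann_kendall([1, 2, 3, 4, 5])
        assert res.S == 10
        assert res.var_S == pytest.approx(5 * 4 * 15 / 18)
        assert res.Z == pytest.approx(9 / np.sqrt(res.var_S))
        assert res.tau == pytest.approx(1.0)

    def test_hand_formulas_with_ties(self):
        # values [1, 2, 2, 3]: one tied group of t=2
        res = mann_kendall([1, 2, 2, 3])
        assert res.S == 5
        expected_var = (4 * 3 * 13 - 2 * 1 * 9) / 18
        assert res.var_S == pytest.approx(expected_var)

    def test_normal_p_within_envelope_of_exact_enumeration(self, rng):
        # measured max |p_norm - p_exact| over all achievable S is 0.0252
        # at n=4 and decreases with n; assert the documented 0.03 envelope
        for n in (4, 5, 6, 7):
            for _ in range(5):
                x = rng.permutation(np.arange(n, dtype=float) * 7 + 1)
                res = mann_kendall(x)
                assert abs(res.p_value - mk_exact_p(x)) < 0.03

    def test_strictly_increasing_p_matches_enumeration(self):
        x = [3.0, 5.0, 8.0, 13.0, 21.0]
        res = mann_kendall(x)
        assert res.S == 10 and res.trend == "increasing"
        p_exact = mk_exact_p(x)  # 2/120
        assert p_exact == pytest.approx(1 / 60)
        assert abs(res.p_value - p_exact) < 0.03

    def test_tau_matches_scipy_kendalltau(self, rng):
        x = rng.normal(0, 1, 15)
        res = mann_kendall(x)
        tau_ref = stats.kendalltau(np.arange(15), x).statistic
        assert res.tau == pytest.approx(tau_ref, abs=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0])


class TestDensity:
    def test_density_scales_with_count_and_area(self):
        polys = {"p": RECT}
        s1 = [LagoonSite("a", -77.5, 35.1)]
        s2 = s1 + [LagoonSite("b", -77.45, 35.05)]
        t1, _ = density_by_polygon(s1, polys)
        t2, _ = density_by_polygon(s2, polys)
        assert t1.density.iloc[0] == pytest.approx(1 / RECT_AREA * 100)
        assert t2.density.iloc[0] == pytest.approx(2 * t1.density.iloc[0])

    def test_boundary_site_assigned_to_first_polygon_by_id(self):
        west = Polygon([(-78, 34), (-77, 34), (-77, 35), (-78, 35)])
        east = Polygon([(-77, 34), (-76, 34), (-76, 35), (-77, 35)])
        table, unassigned = density_by_polygon(
            [LagoonSite("s", -77.0, 34.5)], {"a_east": east, "b_west": west}
        )
        assert table.set_index("polygon_id")["count"]["a_east"] == 1
        assert table.set_index("polygon_id")["count"]["b_west"] == 0
        assert unassigned == []

    def test_outside_sites_reported_separately(self):
        table, unassigned = density_by_polygon(
            [LagoonSite("far", 0.0, 0.0)], {"p": RECT}
        )
        assert table["count"].sum() == 0 and unassigned == ["far"]

    def test_zero_area_polygon_rejected(self):
        sliver = Polygon([(0, 0), (0, 0), (0, 0)])
        with pytest.raises((ValueError, Exception)):
            density_by_polygon([], {"z": sliver})


class TestAnnualMedians:
    def test_medians_by_estimated_year(self):
        from lagoondate import NearestDistanceRecord

        recs = [
            NearestDistanceRecord("a", "f", "stream/river", 100.0),
            NearestDistanceRecord("b", "f", "stream/river", 300.0),
            NearestDistanceRecord("c", "f", "stream/river", 50.0),
        ]
        ests = [
            ConstructionEstimate("a", "YEAR", 1990),
            ConstructionEstimate("b", "YEAR", 1990),
            ConstructionEstimate("c", PRE_ERA),
        ]
        med = annual_median_distances(recs, ests)
        assert list(med.index) == [1990] and med.iloc[0] == 200.0
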