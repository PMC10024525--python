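import numpy as np
import pytest

from esmap.aggregation_reporting import (
    OVERALL,
    aggregate_overall,
    rank_services,
    round_for_report,
    summarize_changes,
    summary_table,
    zonal_mean,
)
from esmap.errors import ContractError
from esmap.es_scoring import (
    ESRaster,
    ESService,
    StudyMatrix,
    build_consensus_matrix,
    default_services,
    score_raster,
    score_stack,
)
from esmap.geodata_io import pixel_areas
from esmap.synthetic_data import generate_zones

from conftest import make_grid, make_lc
from oracles import brute_zonal_mean


def es_raster(values, service_code="a", variant="max", year=2015):
    values = np.asarray(values, dtype=float)
    grid = make_grid(*values.shape)
    svc = ESService(service_code, service_code, "provisioning")
    return ESRaster(grid=grid, service=svc, variant=variant, year=year, values=values)


class TestAggregateOverall:
    def test_constant_raw_standardizes_to_zero(self):
        a = es_raster([[1, 3]], "a")
        b = es_raster([[2, 0]], "b")
        out = aggregate_overall([a, b])
        np.testing.assert_array_equal(out.raw, [[3.0, 3.0]])
        np.testing.assert_array_equal(out.standardized, [[0.0, 0.0]])

    def test_minmax_endpoints(self):
        a = es_raster([[2, 5]], "a")
        b = es_raster([[0, 2]], "b")
        out = aggregate_overall([a, b])
        np.testing.assert_array_equal(out.raw, [[2.0, 7.0]])
        np.testing.assert_array_equal(out.standardized, [[0.0, 1.0]])

    def test_single_all_zero_service(self):
        out = aggregate_overall([es_raster([[0, 0]], "a")])
        assert (out.raw == 0).all()
        assert (out.standardized == 0).all()

    def test_duplicate_service_rejected(self):
        with pytest.raises(ContractError, match="duplicate"):
            aggregate_overall([es_raster([[1]], "a"), es_raster([[2]], "a")])

    def test_invalid_anywhere_invalid_everywhere(self):
        a = es_raster([[1.0, np.nan]], "a")
        b = es_raster([[2.0, 3.0]], "b")
        out = aggregate_overall([a, b])
        assert np.isnan(out.raw[0, 1])
        assert np.isnan(out.standardized[0, 1])

    def test_maxscore_standardization(self):
        a = es_raster([[5, 0]], "a")
        b = es_raster([[5, 0]], "b")
        out = aggregate_overall([a, b], standardize="maxscore")
        np.testing.assert_array_equal(out.standardized, [[1.0, 0.0]])

    def test_bounds_property(self):
        rng = np.random.default_rng(2)
        stack = [
            es_raster(rng.uniform(0, 5, size=(8, 8)), code)
            for code in "abcde"
        ]
        out = aggregate_overall(stack)
        assert np.nanmax(out.raw) <= 5 * len(stack)
        assert np.nanmin(out.raw) >= 0
        assert np.nanmin(out.standardized) >= 0
        assert np.nanmax(out.standardized) <= 1


class TestZonalMean:
    def test_equal_areas(self):
        r = es_raster([[4, 1]])
        zones = generate_zones(r.grid, 1, 1)
        field = pixel_areas(r.grid, "nominal", 1.0)
        rows = zonal_mean(r, zones, field)
        nat = rows[rows["zone_id"] == "NAT"].iloc[0]
        assert nat["mean_per_unit_area"] == pytest.approx(2.5)
        assert nat["total_potential"] == pytest.approx(5.0)

    def test_weighted_by_pixel_area(self):
        # areas [1, 3] km², scores [4, 1] → mean 1.75, total 7
        from esmap.geodata_io import Grid, PixelAreaField

        grid = Grid("EPSG:4326", 40.0, 16.0, 0.1, -0.1, 2, 1)
        r = ESRaster(
            grid=grid,
            service=ESService("a", "a", "provisioning"),
            variant="max",
            year=2015,
            values=np.array([[4.0], [1.0]]),
        )
        field = PixelAreaField(mode="geodesic", per_row_area_km2=np.array([1.0, 3.0]))
        zones = generate_zones(grid, 1, 1)
        rows = zonal_mean(r, zones, field)
        nat = rows[rows["zone_id"] == "NAT"].iloc[0]
        assert nat["mean_per_unit_area"] == pytest.approx(1.75)
        assert nat["total_potential"] == pytest.approx(7.0)

    def test_all_nodata_zone_is_na(self):
        r = es_raster([[np.nan, np.nan]])
        zones = generate_zones(r.grid, 1, 1)
        field = pixel_areas(r.grid, "nominal", 1.0)
        rows = zonal_mean(r, zones, field)
        nat = rows[rows["zone_id"] == "NAT"].iloc[0]
        assert np.isnan(nat["mean_per_unit_area"])
        assert nat["total_potential"] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(10)
        values = rng.uniform(0, 5, size=(20, 20))
        values[rng.random((20, 20)) < 0.1] = np.nan
        r = es_raster(values)
        zones = generate_zones(r.grid, 2, 2)
        field = pixel_areas(r.grid, "nominal", 0.01)
        rows = zonal_mean(r, zones, field)
        zidx_cols = np.array([0] * 10 + [1] * 10)
        for zi, zone in enumerate(zones.at_level("regional")):
            select = [
                [zidx_cols[c] == zi for c in range(20)] for _ in range(20)
            ]
            mean, total = brute_zonal_mean(values, [0.01] * 20, select)
            row = rows[rows["zone_id"] == zone.zone_id].iloc[0]
            assert row["mean_per_unit_area"] == pytest.approx(mean, rel=1e-12)
            assert row["total_potential"] == pytest.approx(total, rel=1e-12)


class TestSummaryHierarchy:
    def make_stack(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        lc = make_lc(rng.choice([20, 30, 60], size=(n, n)))
        services = default_services()
        scores = {
            (svc.code, cls): float(rng.integers(0, 6))
            for svc in services
            for cls in lc.legend.codes
        }
        matrix = build_consensus_matrix(
            [StudyMatrix("s1", scores)], services, lc.legend
        )
        return score_stack({2015: lc}, matrix, ["max"], [2015]), lc

    def test_national_equals_area_weighted_regional(self):
        stack, lc = self.make_stack()
        zones = generate_zones(lc.grid, 3, 2)
        field = pixel_areas(lc.grid, "nominal", 0.01)
        table = summary_table(stack, zones, field)
        for code in "abcdefghij":
            nat = table[
                (table["zone_id"] == "NAT") & (table["service_code"] == code)
            ].iloc[0]
            reg = table[
                (table["level"] == "regional") & (table["service_code"] == code)
            ]
            weighted = (
                (reg["mean_per_unit_area"] * reg["valid_area_km2"]).sum()
                / reg["valid_area_km2"].sum()
            )
            assert nat["mean_per_unit_area"] == pytest.approx(weighted, rel=1e-9)
            assert nat["total_potential"] == pytest.approx(
                reg["total_potential"].sum(), rel=1e-6
            )

    def test_regional_totals_sum_subregional(self):
        stack, lc = self.make_stack(seed=4)
        zones = generate_zones(lc.grid, 3, 2)
        field = pixel_areas(lc.grid, "nominal", 0.01)
        table = summary_table(stack, zones, field)
        for region in zones.at_level("regional"):
            child_ids = [z.zone_id for z in zones.children(region.zone_id)]
            for code in "abcdefghij":
                reg = table[
                    (table["zone_id"] == region.zone_id)
                    & (table["service_code"] == code)
                ].iloc[0]
                subs = table[
                    table["zone_id"].isin(child_ids)
                    & (table["service_code"] == code)
                ]
                assert reg["total_potential"] == pytest.approx(
                    subs["total_potential"].sum(), rel=1e-6
                )

    def test_overall_is_unweighted_mean_of_service_means(self):
        stack, lc = self.make_stack(seed=8)
        zones = generate_zones(lc.grid, 1, 1)
        field = pixel_areas(lc.grid, "nominal", 0.01)
        table = summary_table(stack, zones, field)
        nat = table[table["zone_id"] == "NAT"]
        per_service = nat[nat["service_code"] != OVERALL]["mean_per_unit_area"]
        overall = nat[nat["service_code"] == OVERALL]["mean_per_unit_area"].iloc[0]
        assert overall == pytest.approx(per_service.mean())


class TestChanges:
    def table_for(self, means_by_year):
        import pandas as pd

        rows = []
        for year, means in means_by_year.items():
            for code, mean in means.items():
                rows.append(
                    {
                        "zone_id": "NAT",
                        "level": "national",
                        "service_code": code,
                        "variant": "max",
                        "year": year,
                        "mean_per_unit_area": mean,
                        "total_potential": mean * 10,
                        "valid_area_km2": 10.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_simple_subtraction(self):
        table = self.table_for({2015: {"a": 2.00}, 2019: {"a": 2.19}})
        out = summarize_changes(table, 2015, 2019)
        assert out["change_vs_baseline"].iloc[0] == pytest.approx(0.19)

    def test_identical_years_zero(self):
        table = self.table_for({2015: {"a": 1.5, "b": 3.0}, 2019: {"a": 1.5, "b": 3.0}})
        out = summarize_changes(table, 2015, 2019)
        assert (out["change_vs_baseline"] == 0).all()

    def test_key_in_one_year_is_na(self, caplog):
        table = self.table_for({2015: {"a": 1.0}, 2019: {"b": 2.0}})
        out = summarize_changes(table, 2015, 2019)
        assert out["change_vs_baseline"].isna().all()

    def test_rounding(self):
        table = self.table_for({2015: {"a": 2.004}, 2019: {"a": 2.1951}})
        out = round_for_report(summarize_changes(table, 2015, 2019))
        assert out["change_vs_baseline"].iloc[0] == pytest.approx(0.19)


class TestRankServices:
    def full_table(self, means):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "zone_id": "NAT",
                    "level": "national",
                    "service_code": code,
                    "variant": "max",
                    "year": 2019,
                    "mean_per_unit_area": mean,
                    "total_potential": 1.0,
                    "valid_area_km2": 1.0,
                }
                for code, mean in means.items()
            ]
        )

    def test_descending_order(self):
        means = {c: 0.0 for c in "abcdefghij"}
        means.update({"a": 1.0, "b": 3.0, "c": 2.0})
        table = self.full_table(means)
        ranked = rank_services(table, "NAT", 2019, "max")
        assert ranked[:3] == ["b", "c", "a"]

    def test_tie_breaks_alphabetical(self):
        table = self.full_table({c: 2.0 for c in "abcdefghij"})
        assert rank_services(table, "NAT", 2019, "max") == list("abcdefghij")

    def test_agrees_with_naive_sort(self):
        rng = np.random.default_rng(77)
        means = {c: float(rng.integers(0, 4)) for c in "abcdefghij"}
        table = self.full_table(means)
        naive = sorted(means, key=lambda c: (-means[c], c))
        assert rank_services(table, "NAT", 2019, "max") == naive

    def test_missing_service_rejected(self):
        table = self.full_table({"a": 1.0, "b": 2.0})
        with pytest.raises(ContractError):
            rank_services(table, "NAT", 2019, "max")


class TestPipelineMonotonicity:
    def test_greening_moves_means_with_score_sign(self):
        # year 2 differs only by converting bare (60) → herbaceous (30)
        rng = np.random.default_rng(5)
        vals_a = rng.choice([20, 30, 60], size=(40, 40))
        vals_b = vals_a.copy()
        bare = np.argwhere(vals_a == 60)
        flip = bare[rng.random(len(bare)) < 0.5]
        vals_b[flip[:, 0], flip[:, 1]] = 30
        lc_a = make_lc(vals_a, year=2015)
        lc_b = make_lc(vals_b, year=2016)
        services = default_services()
        scores = {
            (svc.code, cls): float(rng.integers(0, 6))
            for svc in services
            for cls in lc_a.legend.codes
        }
        matrix = build_consensus_matrix(
            [StudyMatrix("s1", scores)], services, lc_a.legend
        )
        zones = generate_zones(lc_a.grid, 1, 1)
        field = pixel_areas(lc_a.grid, "nominal", 0.01)
        stack = score_stack({2015: lc_a, 2016: lc_b}, matrix, ["max"], [2015, 2016])
        table = summary_table(stack, zones, field, include_overall=False)
        changes = summarize_changes(table, 2015, 2016)
        nat = changes[changes["zone_id"] == "NAT"]
        assert len(flip) > 0
        for svc in services:
            delta = scores[(svc.code, 30)] - scores[(svc.code, 60)]
            change = nat[nat["service_code"] == svc.code]["change_vs_baseline"].iloc[0]
            if delta > 0:
                assert change > 0
            elif delta < 0:
                assert change < 0
            else:
                assert change == pytest.approx(0.0, abs=1e-12)
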