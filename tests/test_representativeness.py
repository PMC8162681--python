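"""Network R maps, represented area/population, PHNI, seasons, districts."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from aqrep import (
    DomainMask,
    GridSpec,
    PopulationRaster,
    RepresentativenessMap,
    SFMap,
    StationSummary,
    area_population_correlation,
    district_phni,
    network_representativeness,
    phni,
    quadrant_districts,
    represented_area,
    represented_population,
    seasonal_periods,
)
from tests.conftest import uniform_population


def sfm(grid, values, sid="S1"):
    values = np.asarray(values, dtype=float)
    return SFMap(grid=grid, station_id=sid, values=values,
                 n_valid=np.where(np.isfinite(values), 24, 0))


def rmap(grid, values):
    return RepresentativenessMap(grid=grid, values=np.asarray(values, dtype=float))


class TestNetworkRepresentativeness:
    def test_single_station_passthrough(self, grid5):
        vals = np.random.default_rng(1).uniform(0, 1, (5, 5))
        r = network_representativeness([sfm(grid5, vals)])
        np.testing.assert_array_equal(r.values, vals)

    def test_max_of_two(self, grid5):
        a = np.full((5, 5), 0.3)
        b = np.full((5, 5), 0.8)
        r = network_representativeness([sfm(grid5, a, "A"), sfm(grid5, b, "B")])
        np.testing.assert_array_equal(r.values, 0.8)

    def test_matches_elementwise_max_loop(self, grid5):
        rng = np.random.default_rng(4)
        maps = [sfm(grid5, rng.uniform(0, 1, (5, 5)), f"S{i}") for i in range(5)]
        r = network_representativeness(maps)
        for i in range(5):
            for j in range(5):
                assert r.values[i, j] == max(m.values[i, j] for m in maps)

    def test_undefined_only_where_all_undefined(self, grid5):
        a = np.full((5, 5), np.nan)
        a[0, 0] = 0.4
        b = np.full((5, 5), np.nan)
        b[0, 1] = 0.6
        r = network_representativeness([sfm(grid5, a, "A"), sfm(grid5, b, "B")])
        assert r.values[0, 0] == 0.4 and r.values[0, 1] == 0.6
        assert np.isnan(r.values[1:]).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            network_representativeness([])

    def test_adding_a_station_never_decreases_r_or_phni(self, grid5):
        rng = np.random.default_rng(6)
        maps = [sfm(grid5, rng.uniform(0, 1, (5, 5)), f"S{i}") for i in range(4)]
        pop = uniform_population(grid5)
        prev_r = network_representativeness(maps[:1])
        prev_phni = phni(prev_r, pop).phni
        for k in range(2, 5):
            cur_r = network_representativeness(maps[:k])
            assert np.all(cur_r.values >= prev_r.values)
            cur_phni = phni(cur_r, pop).phni
            assert cur_phni >= prev_phni - 1e-15
            prev_r, prev_phni = cur_r, cur_phni


class TestRepresentedAreaPopulation:
    def test_no_qualifying_cells(self, grid5):
        assert represented_area(sfm(grid5, np.full((5, 5), 0.5))) == 0.0

    def test_twenty_cells_at_default_cell_size(self, grid5):
        vals = np.full((5, 5), 0.5)
        vals.ravel()[:20] = 0.95
        assert represented_area(sfm(grid5, vals)) == pytest.approx(0.0432)

    def test_cutoff_is_strict(self, grid5):
        vals = np.full((5, 5), 0.9)
        assert represented_area(sfm(grid5, vals)) == 0.0

    def test_population_masked_sum_matches_loop(self, grid5):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 1, (5, 5))
        pop = PopulationRaster(grid=grid5, counts=rng.uniform(0, 100, (5, 5)))
        got = represented_population(sfm(grid5, vals), pop)
        expect = sum(pop.counts[r, c] for r in range(5) for c in range(5) if vals[r, c] > 0.9)
        assert got == pytest.approx(expect, rel=1e-12)
        assert represented_area(sfm(grid5, vals)) == pytest.approx(
            sum(1 for v in vals.ravel() if v > 0.9) * grid5.cell_area_m2 / 1e6)

    def test_uniform_population_counts_cells(self, grid5):
        vals = np.full((5, 5), 0.95)
        assert represented_population(sfm(grid5, vals), uniform_population(grid5)) == 25.0


class TestPHNI:
    def test_perfect_representation(self, grid5):
        res = phni(rmap(grid5, np.ones((5, 5))), uniform_population(grid5))
        assert res.phni == 1.0

    def test_uniform_population_reduces_to_mean(self, grid5):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, (5, 5))
        res = phni(rmap(grid5, vals), uniform_population(grid5))
        assert res.phni == pytest.approx(vals.mean(), rel=1e-12)

    def test_small_worked_example(self):
        grid = GridSpec(origin_x=0, origin_y=0, n_cols=2, n_rows=1, dx=45, dy=48)
        pop = PopulationRaster(grid=grid, counts=np.array([[3.0, 1.0]]))
        res = phni(rmap(grid, [[1.0, 0.5]]), pop)
        assert res.phni == pytest.approx(0.875)

    def test_matches_weighted_mean_loop(self):
        grid = GridSpec(origin_x=0, origin_y=0, n_cols=20, n_rows=20, dx=45, dy=48)
        rng = np.random.default_rng(44)
        vals = rng.uniform(0, 1, (20, 20))
        counts = rng.uniform(0, 50, (20, 20))
        res = phni(rmap(grid, vals), PopulationRaster(grid=grid, counts=counts))
        num = den = 0.0
        for r in range(20):
            for c in range(20):
                num += vals[r, c] * counts[r, c]
                den += counts[r, c]
        assert res.phni == pytest.approx(num / den, rel=1e-12)
        assert 0.0 <= res.phni <= 1.0

    def test_undefined_cells_excluded_from_both_sums(self, grid5):
        vals = np.full((5, 5), np.nan)
        vals[0, 0] = 0.5
        counts = np.ones((5, 5))
        res = phni(rmap(grid5, vals), PopulationRaster(grid=grid5, counts=counts))
        assert res.phni == 0.5
        assert res.population_covered == 1.0

    def test_zero_population_domain_rejected(self, grid5):
        pop = PopulationRaster(grid=grid5, counts=np.zeros((5, 5)))
        with pytest.raises(ValueError, match="zero population"):
            phni(rmap(grid5, np.ones((5, 5))), pop)


class TestSeasonalPeriods:
    def test_month_assignment(self):
        times = pd.DatetimeIndex(["2019-07-15T10:00", "2019-12-01T00:00", "2019-04-01T06:00"])
        masks = seasonal_periods(times)
        assert masks["summer"].tolist() == [True, False, False]
        assert masks["winter"].tolist() == [False, True, False]
        assert masks["spring"].tolist() == [False, False, True]

    def test_full_year_partitions_all_hours(self):
        times = pd.date_range("2019-01-01", periods=8760, freq="h")
        masks = seasonal_periods(times)
        seasons = [masks[s] for s in ("spring", "summer", "autumn", "winter")]
        total = np.sum(seasons, axis=0)
        assert np.all(total == 1)  # each hour in exactly one season
        assert masks["annual"].sum() == 8760
        assert masks["summer"].sum() == (30 + 31 + 31) * 24
        assert masks["winter"].sum() == (31 + 28 + 31) * 24

    def test_multi_year_rejected(self):
        times = pd.date_range("2019-12-31", periods=48, freq="h")
        with pytest.raises(ValueError, match="multiple years"):
            seasonal_periods(times)


class TestDistricts:
    def test_whole_grid_district_equals_global(self, grid5):
        rng = np.random.default_rng(21)
        vals = rng.uniform(0, 1, (5, 5))
        pop = PopulationRaster(grid=grid5, counts=rng.uniform(1, 10, (5, 5)))
        r = rmap(grid5, vals)
        whole = box(0, 0, grid5.x_max, grid5.y_max)
        (res,) = district_phni(r, pop, [("all", whole)])
        assert res.phni == pytest.approx(phni(r, pop).phni, rel=1e-12)

    def test_two_halves_with_known_levels(self, grid5):
        vals = np.ones((5, 5))
        vals[:, 3:] = 0.5  # columns 3-4 in the right half (x >= 135)
        r = rmap(grid5, vals)
        pop = uniform_population(grid5)
        left = box(0, 0, 3 * 45.0, grid5.y_max)
        right = box(3 * 45.0, 0, grid5.x_max, grid5.y_max)
        res = district_phni(r, pop, [("L", left), ("R", right)])
        assert res[0].phni == pytest.approx(1.0)
        assert res[1].phni == pytest.approx(0.5)

    def test_membership_matches_centroid_containment_loop(self):
        grid = GridSpec(origin_x=0, origin_y=0, n_cols=8, n_rows=8, dx=45, dy=48)
        rng = np.random.default_rng(30)
        vals = rng.uniform(0, 1, (8, 8))
        counts = rng.uniform(1, 10, (8, 8))
        poly = box(50.0, 60.0, 260.0, 300.0)
        (res,) = district_phni(rmap(grid, vals), PopulationRaster(grid=grid, counts=counts), [("D", poly)])
        from shapely.geometry import Point

        num = den = 0.0
        for r in range(8):
            for c in range(8):
                x, y = 45 * (c + 0.5), 48 * (r + 0.5)
                if poly.contains(Point(x, y)):
                    num += vals[r, c] * counts[r, c]
                    den += counts[r, c]
        assert res.phni == pytest.approx(num / den, rel=1e-12)

    def test_zero_population_district_reported_not_raised(self, grid5):
        vals = np.ones((5, 5))
        counts = np.ones((5, 5))
        counts[:, :2] = 0.0
        pop = PopulationRaster(grid=grid5, counts=counts)
        empty = box(0, 0, 2 * 45.0, grid5.y_max)  # covers only zero-pop columns
        (res,) = district_phni(rmap(grid5, vals), pop, [("empty", empty)])
        assert np.isnan(res.phni)

    def test_quadrants_partition_grid(self, grid5):
        quads = quadrant_districts(grid5)
        total = np.sum([q.cells for q in quads], axis=0)
        assert np.all(total == 1)


class TestAreaPopulationCorrelation:
    @staticmethod
    def summaries(area, popn):
        return [StationSummary(f"S{i}", "NO2", "annual", a, p)
                for i, (a, p) in enumerate(zip(area, popn))]

    def test_identical_vectors_give_one(self):
        r, p = area_population_correlation(self.summaries([1, 2, 3], [1, 2, 3]))
        assert r == pytest.approx(1.0)

    def test_anti_ordered_gives_minus_one(self):
        r, _ = area_population_correlation(self.summaries([1, 2, 3], [3, 2, 1]))
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_sum_formula(self):
        rng = np.random.default_rng(51)
        a = rng.uniform(0, 100, 15)
        b = rng.uniform(0, 1e5, 15)
        r, p = area_population_correlation(self.summaries(a, b))
        n = 15
        sx, sy = a.sum(), b.sum()
        sxy = float(np.sum(a * b))
        sxx, syy = float(np.sum(a * a)), float(np.sum(b * b))
        expect = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
        assert r == pytest.approx(expect, rel=1e-10)
        assert 0.0 <= p <= 1.0

    def test_exclusion_list_and_degenerate_variance(self):
        s = self.summaries([1, 2, 3, 100], [1, 2, 3, 0.1])
        r_all, _ = area_population_correlation(s)
        r_excl, _ = area_population_correlation(s, exclude=("S3",))
        assert r_excl > r_all
        r_flat, p_flat = area_population_correlation(self.summaries([1, 1, 1], [1, 2, 3]))
        assert np.isnan(r_flat) and np.isnan(p_flat)
        with pytest.raises(ValueError, match="3 stations"):
            area_population_correlation(self.summaries([1, 2], [1, 2]))
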