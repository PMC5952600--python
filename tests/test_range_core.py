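"""Isopleth profiles, home ranges, core delineation and seasonal rules."""

import numpy as np
import pandas as pd
import pytest

from coreud.ctcrw import PseudoTrack
from coreud.range_core import (
    IsoplethProfile,
    SEASON_BINS,
    assign_bimonth,
    core_space,
    delineate_core,
    eligibility,
    home_range,
    intensity_of_use,
    isopleth_profile,
    metrics_row,
)
from coreud.simulate import HaulSite, Landscape
from coreud.ud import DensityGrid, kde_grid


def uniform_grid(n=20, cell=1.0):
    vals = np.full((n, n), 1.0 / (n * n * cell * cell))
    return DensityGrid(0.0, n * cell, cell, vals, 1.0, 100)


def gaussian_grid(sigma=1.0, cell=0.25, half=8.0):
    """Analytic isotropic Gaussian density evaluated on a fine grid."""
    n = int(2 * half / cell)
    xs = -half + (np.arange(n) + 0.5) * cell
    ys = half - (np.arange(n) + 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    vals = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    vals /= vals.sum() * cell * cell
    return DensityGrid(-half, half, cell, vals, 0.5, 1000)


def exponential_profile(a=0.01, b=4.6052, total_area=12000.0):
    v = np.arange(1, 100, dtype=float)
    y = a * np.exp(b * v / 100.0)
    return IsoplethProfile(v, y * total_area, y)


class TestIsoplethProfile:
    def test_uniform_ramp(self):
        grid = uniform_grid(n=20)
        prof = isopleth_profile(grid)
        N = 400
        expect = np.ceil(prof.volumes * N / 100.0)
        np.testing.assert_allclose(prof.areas, expect)

    def test_areas_non_decreasing(self, rng):
        vals = rng.random((30, 30))
        vals /= vals.sum()
        grid = DensityGrid(0, 30, 1.0, vals, 1.0, 10)
        prof = isopleth_profile(grid)
        assert (np.diff(prof.areas) >= 0).all()
        assert prof.normalized_areas.max() <= 1.0 + 1e-12

    def test_gaussian_95_closed_form(self):
        """area(95) of an isotropic Gaussian is -2 pi sigma^2 ln(0.05)."""
        prof = isopleth_profile(gaussian_grid(sigma=1.0))
        expect = -2 * np.pi * np.log(0.05)  # 18.82 km^2 for sigma = 1 km
        assert abs(prof.area_at(95) - expect) / expect < 0.05


class TestDelineateCore:
    def test_exact_exponential_recovers_v_star(self):
        a, b = 0.01, 4.6052
        fit, v_star = delineate_core(exponential_profile(a, b))
        expect = 100.0 * np.log(1.0 / (a * b)) / b  # 66.84
        assert v_star == pytest.approx(expect, rel=0.005)
        assert fit.residual_se < 1e-8

    def test_uniform_profile_has_no_core(self):
        prof = isopleth_profile(uniform_grid())
        fit, v_star = delineate_core(prof)
        assert v_star is None

    @pytest.mark.parametrize("a,b", [(0.02, 4.0), (0.005, 5.5)])
    def test_family_of_exponentials(self, a, b):
        fit, v_star = delineate_core(exponential_profile(a, b))
        assert v_star == pytest.approx(100.0 * np.log(1.0 / (a * b)) / b,
                                       rel=0.005)


class TestIntensity:
    def test_pooled_worked_arithmetic(self):
        assert round(intensity_of_use(64.4, 23.31), 2) == 2.76

    def test_simple_ratio(self):
        assert intensity_of_use(50.0, 25.0) == 2.0

    def test_rejects_nonpositive_proportion(self):
        with pytest.raises(ValueError):
            intensity_of_use(50.0, 0.0)


def _ptrack_at(points, months=None):
    n = len(points)
    if months is None:
        times = pd.Timestamp("2012-01-01") + pd.to_timedelta(
            np.arange(n) * 2.0, unit="h")
    else:
        times = pd.to_datetime([f"2012-{m:02d}-10" for m in months])
        times = times + pd.to_timedelta(np.arange(n) * 2.0, unit="h")
    df = pd.DataFrame({"time": times,
                       "x_km": [p[0] for p in points],
                       "y_km": [p[1] for p in points]})
    return PseudoTrack("A", df, 2.0, 100, 60)


class TestHomeRangeAndCore:
    def _all_water(self, n=40):
        return Landscape(0.0, 0.0, 1.0, np.zeros((n, n), dtype=bool),
                         [HaulSite("H0", 10.5, 20.5), HaulSite("H1", 35.5, 35.5)])

    def test_all_water_area_equals_cell_count(self, rng):
        pts = rng.normal(20, 3.0, (500, 2))
        grid = kde_grid(pts, 1.0, (0, 40, 0, 40), 1.0)
        hr = home_range(grid, self._all_water())
        from coreud.range_core import isopleth_cells
        n95 = isopleth_cells(grid, 95.0).sum()
        assert hr.area == pytest.approx(n95 * 1.0)

    def test_land_clipping_reduces_area(self, rng):
        pts = rng.normal(20, 3.0, (500, 2))
        grid = kde_grid(pts, 1.0, (0, 40, 0, 40), 1.0)
        land = np.zeros((40, 40), dtype=bool)
        land[:, :20] = True  # west half land
        ls = Landscape(0.0, 0.0, 1.0, land)
        hr_clipped = home_range(grid, ls)
        hr_open = home_range(grid, None)
        assert hr_clipped.area < hr_open.area

    def test_haulout_inside_counted_far_outside_not(self, rng):
        pts = rng.normal([10, 20], 2.0, (500, 2))
        grid = kde_grid(pts, 1.0, (0, 40, 0, 40), 1.0)
        hr = home_range(grid, self._all_water())
        # H0 at the cluster center is within; H1 is ~25 km away
        assert hr.n_haulouts_within == 1

    def test_core_space_metrics_consistent(self, rng):
        pts = np.vstack([rng.normal([20, 20], 1.2, (600, 2)),
                         rng.normal([20, 20], 6.0, (400, 2))])
        grid = kde_grid(pts, 0.8, (-5, 45, -5, 45), 1.0)
        ls = self._all_water(45)
        hr = home_range(grid, ls)
        fit, v_star = delineate_core(isopleth_profile(grid))
        assert v_star is not None
        core = core_space(grid, v_star, hr, ls, ls.haulouts,
                          _ptrack_at(pts[:50]))
        assert core.has_core and core.intensity_I > 1
        assert core.area <= hr.area
        assert core.intensity_I == pytest.approx(
            core.v_star / core.proportion_of_hr)
        # the tight mode's peak cell lies inside the core
        from shapely.geometry import Point
        assert core.polygons.contains(Point(20, 20))
        assert 0 <= core.pct_positions_in_core <= 100

    def test_core_centroid_on_haulout_gives_zero_distance(self):
        # exactly symmetric UD centred on the haulout: the core cell-set is
        # symmetric too, so the polygon centroid coincides with the site
        grid = gaussian_grid(sigma=1.0)
        hr = home_range(grid, None)
        fit, v_star = delineate_core(isopleth_profile(grid))
        core = core_space(grid, v_star, hr,
                          haulouts=[HaulSite("H", 0.0, 0.0)])
        assert round(core.min_dist_to_haulout, 2) == 0.00

    def test_v_star_out_of_range_rejected(self, rng):
        pts = rng.normal(20, 2.0, (200, 2))
        grid = kde_grid(pts, 1.0, (0, 40, 0, 40), 1.0)
        hr = home_range(grid, None)
        with pytest.raises(ValueError):
            core_space(grid, 96.0, hr)


class TestSeasonAssignment:
    def test_bins_tile_the_year(self):
        months = [m for pair in SEASON_BINS.values() for m in pair]
        assert sorted(months) == list(range(1, 13))

    def test_track_spanning_june_july_splits(self):
        pts = [(1, 1)] * 120
        times = pd.date_range("2012-06-28", "2012-07-03", periods=120)
        df = pd.DataFrame({"time": times, "x_km": 1.0, "y_km": 1.0})
        pt = PseudoTrack("A", df, np.diff(times)[0] / np.timedelta64(1, "h"),
                         100, 60)
        bins = assign_bimonth(pt)
        assert set(bins) == {"MJ", "JA"}
        assert sum(len(b.df) for b in bins.values()) == 120

    def test_all_january_single_bin(self):
        pt = _ptrack_at([(0, 0)] * 10, months=[1] * 10)
        bins = assign_bimonth(pt)
        assert set(bins) == {"JF"}


class TestEligibility:
    @pytest.mark.parametrize("n_pseudo,n_raw,expect", [
        (51, 20, True),    # ratio 2.55, just over 50 pseudolocations
        (50, 50, False),   # strictly more than 50 required
        (60, 20, False),   # ratio exactly 3 is ineligible
        (60, 21, True),    # ratio 2.86
        (200, 0, False),   # no raw fixes at all
    ])
    def test_boundaries(self, n_pseudo, n_raw, expect):
        assert eligibility(n_pseudo, n_raw) is expect


def test_metrics_row_without_core_is_flagged():
    grid = uniform_grid()
    hr = home_range(grid, None)
    fit, v_star = delineate_core(isopleth_profile(grid))
    row = metrics_row("A", "JF", hr, fit, None)
    assert row["has_core"] is False and np.isnan(row["intensity_I"])
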