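"""CTCRW likelihood, fitting, imputation and land repositioning."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_ctcrw_loglik, make_fixes
from coreud.ctcrw import (
    CTCRWParams,
    PseudoTrack,
    fit_ctcrw,
    impute_pseudolocations,
    kalman_loglik,
    reposition_off_land,
    smoother_pseudolocations,
)
from coreud.simulate import Landscape, HaulSite, simulate_state_space_track


class TestKalmanLoglik:
    @pytest.mark.parametrize("beta,sigma", [(0.5, 2.0), (1.5, 0.7), (0.1, 5.0)])
    def test_equals_joint_gaussian_density(self, toy_track, beta, sigma):
        t, obs, obs_var = toy_track
        k = kalman_loglik(t, obs, obs_var, beta, sigma)
        b = brute_force_ctcrw_loglik(t, obs, obs_var, beta, sigma)
        assert abs(k - b) < 1e-6

    def test_heteroscedastic_classes(self, toy_track):
        t, obs, _ = toy_track
        obs_var = np.array([0.15, 3.0, 0.35, 1.0, 2.0, 0.15]) ** 2
        k = kalman_loglik(t, obs, obs_var, 0.8, 1.5)
        b = brute_force_ctcrw_loglik(t, obs, obs_var, 0.8, 1.5)
        assert abs(k - b) < 1e-6


class TestFit:
    def test_too_few_fixes_rejected(self):
        fixes = make_fixes(np.arange(10) * 3.0, range(10), range(10))
        with pytest.raises(ValueError, match="20 fixes"):
            fit_ctcrw(fixes)

    def test_short_span_rejected(self):
        fixes = make_fixes(np.arange(25) * 0.5, range(25), range(25))
        with pytest.raises(ValueError, match="24 h"):
            fit_ctcrw(fixes)

    def test_stationary_track_flags_sigma_boundary(self, rng):
        t = np.arange(30) * 1.0
        x = rng.normal(0, 1e-4, 30)
        fixes = make_fixes(t, x, x)
        params = fit_ctcrw(fixes)
        assert params.at_boundary or params.sigma < 0.01

    def test_parameter_recovery_short(self, rng):
        """Mean (beta, sigma) over a few replicates lands near the truth."""
        beta, sigma = 0.5, 2.0
        est = []
        for rep in range(4):
            times = np.cumsum(rng.uniform(0.2, 1.0, 800))
            trk = simulate_state_space_track(times, beta, sigma, seed=100 + rep)
            p = fit_ctcrw(trk)
            est.append((p.beta, p.sigma))
        mb, ms = np.mean(est, axis=0)
        assert abs(mb - beta) / beta < 0.25
        assert abs(ms - sigma) / sigma < 0.25


class TestImputation:
    def _params(self, beta=0.8, sigma=2.0, sd=0.15):
        return CTCRWParams(beta, sigma, {"3": sd}, 0.0)

    def test_twelve_pseudolocations_per_tracking_day(self, rng):
        times = np.sort(rng.uniform(0, 23.9, 40))
        times[0] = 0.0
        trk = simulate_state_space_track(times, 0.8, 2.0, seed=1)
        pt = impute_pseudolocations(trk, self._params(), n_imputations=5, seed=0)
        assert len(pt.df) == 12  # 2-h grid, 12 locations per day

    def test_grid_spacing_exactly_two_hours(self, rng):
        times = np.cumsum(rng.uniform(0.3, 1.2, 60))
        trk = simulate_state_space_track(times, 0.8, 2.0, seed=2)
        pt = impute_pseudolocations(trk, self._params(), n_imputations=5, seed=0)
        dt = np.diff(pt.df.time.to_numpy()) / np.timedelta64(1, "h")
        np.testing.assert_allclose(dt, 2.0, atol=1e-9)
        span_h = (times[-1] - times[0])
        assert len(pt.df) <= np.ceil(span_h / 2.0) + 1

    def test_constant_velocity_line_recovered(self):
        t = np.arange(0, 48, 0.5)
        x, y = 1.2 * t, -0.4 * t
        trk = make_fixes(t, x, y)
        pt = impute_pseudolocations(trk, self._params(sd=1e-4),
                                    n_imputations=30, seed=3)
        th = (pt.df.time - pt.df.time.iloc[0]).dt.total_seconds() / 3600.0
        np.testing.assert_allclose(pt.df.x_km, 1.2 * th, atol=0.05)
        np.testing.assert_allclose(pt.df.y_km, -0.4 * th, atol=0.05)

    def test_average_converges_to_smoother_mean(self, rng):
        """Monte-Carlo average approaches the analytic smoothing mean ~ 1/sqrt(n)."""
        times = np.cumsum(rng.uniform(0.3, 1.5, 100))
        trk = simulate_state_space_track(times, 0.8, 2.0, seed=4, obs_sd=0.3)
        p = self._params(sd=0.3)
        sm = smoother_pseudolocations(trk, p).df[["x_km", "y_km"]].to_numpy()

        def rms(n, seed):
            mc = impute_pseudolocations(trk, p, n_imputations=n, seed=seed)
            return np.sqrt(np.mean(
                (mc.df[["x_km", "y_km"]].to_numpy() - sm) ** 2))

        r_small, r_big = rms(40, 11), rms(360, 12)
        assert r_big < r_small  # error shrinks with draws
        assert 1.2 < r_small / r_big < 7.5  # expected ratio 3 (sqrt 9), wide band

    def test_rejects_bad_imputation_count(self, rng):
        times = np.cumsum(rng.uniform(0.3, 1.5, 30))
        trk = simulate_state_space_track(times, 0.8, 2.0, seed=5)
        with pytest.raises(ValueError):
            impute_pseudolocations(trk, self._params(), n_imputations=0)

    def test_pseudotrack_requires_raw_count(self):
        df = pd.DataFrame({"time": pd.to_datetime(["2012-01-01"]),
                           "x_km": [0.0], "y_km": [0.0]})
        with pytest.raises(ValueError):
            PseudoTrack("A", df, 2.0, 10, 0)


class TestReposition:
    def _landscape(self):
        land = np.zeros((20, 20), dtype=bool)
        land[:, :10] = True  # west half land, coast at x = 10
        return Landscape(0.0, 0.0, 1.0, land, [HaulSite("H", 9.5, 10.5)])

    def _ptrack(self, xs, ys):
        df = pd.DataFrame({
            "time": pd.Timestamp("2012-01-01")
            + pd.to_timedelta(np.arange(len(xs)) * 2.0, unit="h"),
            "x_km": xs, "y_km": ys,
        })
        return PseudoTrack("A", df, 2.0, 10, 5)

    def test_inland_point_moved_to_adjacent_water(self):
        ls = self._landscape()
        pt = reposition_off_land(self._ptrack([9.6, 11.5], [10.5, 10.5]), ls)
        moved = pt.df.iloc[0]
        assert bool(moved.repositioned)
        assert not ls.is_land(moved.x_km, moved.y_km)
        assert np.hypot(moved.x_km - 9.6, moved.y_km - 10.5) < 1.0

    def test_all_water_identity(self):
        ls = self._landscape()
        pt0 = self._ptrack([12.5, 15.5, 18.2], [3.0, 7.0, 12.0])
        pt = reposition_off_land(pt0, ls)
        assert not pt.df.repositioned.any()
        np.testing.assert_array_equal(pt.df.x_km, pt0.df.x_km)

    def test_moved_point_is_nearest_water_cell(self):
        ls = self._landscape()
        src = (7.3, 4.9)  # a few km inland
        pt = reposition_off_land(self._ptrack([src[0]], [src[1]]), ls,
                                 search_radius_km=30.0)
        water = ls.water_cell_centers()
        d = np.hypot(water[:, 0] - src[0], water[:, 1] - src[1])
        got = np.hypot(pt.df.x_km[0] - src[0], pt.df.y_km[0] - src[1])
        assert got <= d.min() + 1e-9

    def test_error_when_no_water_in_radius(self):
        land = np.ones((50, 50), dtype=bool)
        land[0, 49] = False  # lone water cell far away
        ls = Landscape(0.0, 0.0, 1.0, land)
        with pytest.raises(ValueError, match="no water cell"):
            reposition_off_land(self._ptrack([2.0], [2.0]), ls,
                                search_radius_km=5.0)
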