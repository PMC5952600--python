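"""Synthetic landscape, movement and Argos-observation generators."""

import numpy as np
import pandas as pd
import pytest

from coreud.simulate import (
    Landscape,
    SimConfig,
    make_landscape,
    observe_track,
    ou_velocity_step,
    simulate_state_space_track,
    simulate_true_path,
)

EXTENT = (0.0, 100.0, 0.0, 100.0)


class TestMakeLandscape:
    def test_seeded_determinism(self):
        a = make_landscape(EXTENT, 1.0, 5, seed=1)
        b = make_landscape(EXTENT, 1.0, 5, seed=1)
        assert np.array_equal(a.land, b.land)
        assert [(h.x, h.y) for h in a.haulouts] == [(h.x, h.y) for h in b.haulouts]

    def test_zero_haulouts_valid(self):
        ls = make_landscape(EXTENT, 1.0, 0, seed=2)
        assert ls.haulouts == []
        assert ls.land.any() and (~ls.land).any()

    def test_zero_cell_size_rejected(self):
        with pytest.raises(ValueError):
            make_landscape(EXTENT, 0.0, 3, seed=1)

    def test_too_many_haulouts_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_landscape((0, 10, 0, 10), 1.0, 500, seed=1)

    def test_haulouts_on_coastal_land(self):
        ls = make_landscape(EXTENT, 1.0, 6, seed=3)
        for h in ls.haulouts:
            assert ls.is_land(h.x, h.y)
            # at least one 4-neighbour cell is water
            c = ls.cell_size
            assert any(
                not ls.is_land(h.x + dx, h.y + dy)
                for dx, dy in ((c, 0), (-c, 0), (0, c), (0, -c))
            )

    def test_single_connected_land_region(self):
        from scipy.ndimage import label

        ls = make_landscape(EXTENT, 1.0, 0, seed=4)
        _, n = label(ls.land)
        assert n == 1


class TestTruePath:
    def test_state_count(self):
        ls = make_landscape(EXTENT, 1.0, 3, seed=1)
        path = simulate_true_path(ls, SimConfig(seed=1), ls.haulouts[0], 10)
        assert len(path) == 2400  # 10 d at 0.1-h internal step

    def test_positions_on_water_or_haulout(self):
        ls = make_landscape(EXTENT, 1.0, 3, seed=1)
        path = simulate_true_path(ls, SimConfig(seed=2), ls.haulouts[0], 15)
        at_sea = path[~path.at_haulout]
        on_land = [ls.is_land(x, y) for x, y in zip(at_sea.x_km, at_sea.y_km)]
        assert not any(on_land)
        hauled = path[path.at_haulout]
        sites = {(h.x, h.y) for h in ls.haulouts}
        assert set(zip(hauled.x_km, hauled.y_km)) <= sites

    def test_requires_positive_duration_and_member_site(self):
        ls = make_landscape(EXTENT, 1.0, 3, seed=1)
        with pytest.raises(ValueError):
            simulate_true_path(ls, SimConfig(), ls.haulouts[0], 0)
        from coreud.simulate import HaulSite

        with pytest.raises(ValueError):
            simulate_true_path(ls, SimConfig(), HaulSite("X", 1, 1), 5)


class TestVelocityAutocorrelation:
    def test_ou_step_autocorrelation_matches_closed_form(self):
        """Velocity autocorrelation of the OU discretization is exp(-beta lag).

        Checked against Bartlett-formula Monte-Carlo standard errors at
        several lags on a long stationary simulation.
        """
        beta, sigma, dt, n = 0.8, 2.0, 0.1, 200_000
        rng = np.random.default_rng(0)
        v = np.empty(n)
        v[0] = rng.normal(0, sigma / np.sqrt(2 * beta))
        z = rng.standard_normal(n)
        for i in range(1, n):
            v[i] = ou_velocity_step(v[i - 1], beta, sigma, dt, z[i])
        v = v - v.mean()
        denom = (v**2).sum()
        rho = np.array([(v[:-k] * v[k:]).sum() / denom for k in range(1, 31)])
        for k in (1, 5, 10, 20):
            theory = np.exp(-beta * k * dt)
            se = np.sqrt((1 + 2 * (rho[: k - 1] ** 2).sum()) / n)
            assert abs(rho[k - 1] - theory) < 3 * se

    def test_at_sea_rms_speed_matches_stationary_value(self, waterworld):
        cfg = SimConfig(beta=1.0, sigma=4.0, haulout_dwell_mean=0.5,
                        trip_duration_mean=1e6, gap_injection_rate=0.0, seed=9)
        path = simulate_true_path(waterworld, cfg, waterworld.haulouts[0], 60)
        sea = path[~path.at_haulout]
        vx = np.diff(sea.x_km.to_numpy()) / 0.1
        vy = np.diff(sea.y_km.to_numpy()) / 0.1
        rms = np.sqrt(np.mean(vx**2 + vy**2))
        # step-averaged velocities shrink the instantaneous RMS slightly
        expect = cfg.sigma / np.sqrt(cfg.beta)
        assert abs(rms - expect) / expect < 0.15


class TestObserveTrack:
    def _long_track(self, waterworld, cfg):
        return simulate_true_path(waterworld, cfg, waterworld.haulouts[0], 120)

    def test_seeded_determinism(self, waterworld):
        cfg = SimConfig(seed=5)
        path = self._long_track(waterworld, cfg)
        a = observe_track(path, cfg)
        b = observe_track(path, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_class_error_sd_recovered(self, waterworld):
        """Observed-minus-true SD per LC matches configuration within 10%."""
        cfg = SimConfig(seed=6, gap_injection_rate=0.0,
                        haulout_dwell_mean=0.5, trip_duration_mean=1e6,
                        class_freqs={"3": 0.5, "B": 0.5}, z_fraction=0.0)
        path = self._long_track(waterworld, cfg)
        fixes = observe_track(path, cfg)
        for lc, sd in (("3", 0.15), ("B", 3.0)):
            sub = fixes[fixes.lc == lc]
            assert len(sub) >= 1000
            err = np.concatenate([
                sub.x_km - sub.true_x_km, sub.y_km - sub.true_y_km
            ])
            assert abs(err.std() - sd) / sd < 0.10

    def test_no_injected_gaps_means_no_long_silence(self, waterworld):
        cfg = SimConfig(seed=7, gap_injection_rate=0.0, duty_cycle_preset=None)
        path = self._long_track(waterworld, cfg)
        fixes = observe_track(path, cfg)
        gaps = np.diff(fixes.time.to_numpy()) / np.timedelta64(1, "D")
        assert gaps.max() < 4.0

    def test_lc_z_fraction_present(self, waterworld):
        cfg = SimConfig(seed=8, z_fraction=0.1)
        fixes = observe_track(self._long_track(waterworld, cfg), cfg)
        frac = (fixes.lc == "Z").mean()
        assert 0.05 < frac < 0.2


class TestSimConfigValidation:
    def test_decreasing_class_sds_rejected(self):
        sds = {"3": 0.5, "2": 0.35, "1": 1.0, "0": 1.5, "A": 2.0, "B": 3.0, "Z": 5.0}
        with pytest.raises(ValueError, match="non-decreasing"):
            SimConfig(error_sd_by_class=sds)

    def test_nonpositive_dynamics_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(beta=0.0)


def test_state_space_track_is_seeded():
    t = np.arange(0, 50, 0.5)
    a = simulate_state_space_track(t, 0.5, 2.0, seed=3)
    b = simulate_state_space_track(t, 0.5, 2.0, seed=3)
    pd.testing.assert_frame_equal(a, b)
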