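"""Seeded synthetic landscapes, haulout sites and Argos-like telemetry tracks.

Everything downstream (filtering, state-space imputation, kernel utilization
distributions, core-space metrics) is exercised on output from this module, so
it reproduces the statistical structure those stages assume:

* a coastline-like land mask with haulout/rookery sites on the land-water edge,
* central-place movement — at-sea excursions following an Ornstein-Uhlenbeck
  (correlated-velocity) process alternating with stationary dwell periods at a
  haulout,
* duty-cycled, irregular satellite fixes whose positional error depends on an
  Argos-style location class (LC), from ~150 m at LC 3 to kilometres at LC B,
  with an unusable LC Z fraction and occasional multi-day transmission gaps.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LC_LADDER = ("3", "2", "1", "0", "A", "B")

#: Nominal isotropic positional error SD per Argos location class, in km.
#: Endpoints follow the published accuracy bands (LC 3 < 150 m, LC B > 1.5 km);
#: interior values are conventional nominal Argos errors. Fully configurable.
DEFAULT_ERROR_SD_KM = {
    "3": 0.15,
    "2": 0.35,
    "1": 1.0,
    "0": 1.5,
    "A": 2.0,
    "B": 3.0,
    "Z": 5.0,
}

#: Default draw frequencies of usable location classes (Argos class mix for
#: marine tags is not standardised; these are plausible and configurable).
DEFAULT_CLASS_FREQS = {"3": 0.08, "2": 0.12, "1": 0.18, "0": 0.22, "A": 0.20, "B": 0.20}

DEFAULT_START_TIME = pd.Timestamp("2012-01-01 00:00:00")


@dataclass(frozen=True)
class HaulSite:
    """A terrestrial haulout or rookery: the central place anchoring movement."""

    site_id: str
    x: float
    y: float
    kind: str = "haulout"  # "haulout" | "rookery"


@dataclass
class SimConfig:
    """Parameters of the synthetic movement and observation processes.

    beta
        Velocity autocorrelation rate of the OU velocity process (1/h).
    sigma
        Velocity stochasticity scale (km/h per sqrt(h)); the stationary RMS
        speed of the 2-D process is ``sigma / sqrt(beta)``.
    haulout_dwell_mean / trip_duration_mean
        Means of the exponential dwell-at-haulout and at-sea trip durations (h).
    error_sd_by_class
        Isotropic Gaussian observation error SD per LC (km); must be
        non-decreasing from LC 3 to LC B.
    duty_cycle_preset
        Hours of continued transmission after hauling out before the tag goes
        silent until next wet (6 or 12; None disables the cutoff).
    gap_injection_rate
        Per-day probability of deleting a > 4-day block of fixes, mimicking
        tag or satellite outages.
    z_fraction
        Fraction of fixes relabelled LC Z (no accuracy estimate).
    """

    beta: float = 1.0
    sigma: float = 4.0
    haulout_dwell_mean: float = 18.0
    trip_duration_mean: float = 12.0
    error_sd_by_class: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_SD_KM))
    class_freqs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQS))
    duty_cycle_preset: float | None = 12.0
    gap_injection_rate: float = 0.01
    z_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.sigma <= 0:
            raise ValueError("beta and sigma must be positive")
        if self.duty_cycle_preset not in (6.0, 12.0, 6, 12, None):
            raise ValueError("duty_cycle_preset must be 6 h, 12 h or None")
        sds = [self.error_sd_by_class[c] for c in LC_LADDER]
        if any(s <= 0 for s in self.error_sd_by_class.values()):
            raise ValueError("all LC error SDs must be positive")
        if any(b < a for a, b in zip(sds, sds[1:])):
            raise ValueError("LC error SDs must be non-decreasing from LC 3 to LC B")


@dataclass
class Landscape:
    """Rectangular planar landscape (equal-area km) with a boolean land mask.

    The mask is row-major from the NW corner: ``land[0, 0]`` is the NW cell;
    cells are half-open ``[x, x+cell) x (y-cell, y]``.
    """

    xmin: float
    ymin: float
    cell_size: float
    land: np.ndarray  # bool, shape (nrows, ncols), True = land
    haulouts: list[HaulSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.land = np.asarray(self.land, dtype=bool)

    @property
    def nrows(self) -> int:
        return self.land.shape[0]

    @property
    def ncols(self) -> int:
        return self.land.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        row = int(np.floor((self.ymax - y) / self.cell_size))
        col = int(np.floor((x - self.xmin) / self.cell_size))
        return row, col

    def in_bounds(self, x: float, y: float) -> bool:
        return self.xmin <= x < self.xmax and self.ymin < y <= self.ymax

    def is_land(self, x: float, y: float) -> bool:
        if not self.in_bounds(x, y):
            return True  # treat out-of-bounds as impassable
        r, c = self.cell_of(x, y)
        r = min(max(r, 0), self.nrows - 1)
        c = min(max(c, 0), self.ncols - 1)
        return bool(self.land[r, c])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xmin + (col + 0.5) * self.cell_size
        y = self.ymax - (row + 0.5) * self.cell_size
        return x, y

    def water_cell_centers(self) -> np.ndarray:
        rows, cols = np.nonzero(~self.land)
        xs = self.xmin + (cols + 0.5) * self.cell_size
        ys = self.ymax - (rows + 0.5) * self.cell_size
        return np.column_stack([xs, ys])

    def validate(self) -> None:
        for h in self.haulouts:
            if not self.is_land(h.x, h.y):
                raise ValueError(f"haulout {h.site_id} is not on a land cell")
        ids = [h.site_id for h in self.haulouts]
        if len(set(ids)) != len(ids):
            raise ValueError("haulout site_ids must be unique")


def _boundary_cells(land: np.ndarray) -> np.ndarray:
    """Land cells with at least one 4-neighbour water cell; (row, col) pairs."""
    water = ~land
    nb = np.zeros_like(land, dtype=bool)
    nb[1:, :] |= water[:-1, :]
    nb[:-1, :] |= water[1:, :]
    nb[:, 1:] |= water[:, :-1]
    nb[:, :-1] |= water[:, 1:]
    return np.argwhere(land & nb)


def make_landscape(
    extent: tuple[float, float, float, float],
    cell_size: float,
    n_haulouts: int,
    seed: int,
) -> Landscape:
    """Generate a coastline-like landscape with haulouts on the land-water edge.

    The land mass is a single connected region attached to the western edge,
    whose eastern coastline is a smooth random curve (a sum of random
    sinusoids), giving bays and headlands along which haulouts are placed.

    Parameters
    ----------
    extent : (xmin, xmax, ymin, ymax) in km
    cell_size : cell edge length in km (> 0)
    n_haulouts : number of haulout sites to place on the coastline
    seed : RNG seed; identical seeds give identical landscapes
    """
    xmin, xmax, ymin, ymax = extent
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent is degenerate")
    if n_haulouts < 0:
        raise ValueError("n_haulouts must be >= 0")

    rng = np.random.default_rng(seed)
    ncols = int(round((xmax - xmin) / cell_size))
    nrows = int(round((ymax - ymin) / cell_size))
    width = xmax - xmin
    height = ymax - ymin

    # coastline x-position as a function of y: base fraction + random sinusoids
    yc = ymax - (np.arange(nrows) + 0.5) * cell_size
    coast = np.full(nrows, xmin + 0.25 * width)
    for k in range(1, 5):
        amp = 0.35 * width / (k + 1) * rng.uniform(0.2, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        coast += amp * np.sin(2 * np.pi * k * (yc - ymin) / height + phase)
    coast = np.clip(coast, xmin + 2 * cell_size, xmin + 0.45 * width)

    xc = xmin + (np.arange(ncols) + 0.5) * cell_size
    land = xc[None, :] < coast[:, None]  # each row a contiguous run from west

    boundary = _boundary_cells(land)
    if n_haulouts > len(boundary):
        raise ValueError(
            f"n_haulouts={n_haulouts} exceeds {len(boundary)} available coastal cells"
        )
    haulouts: list[HaulSite] = []
    if n_haulouts > 0:
        # spread sites along the coast: sort by row, take evenly spaced picks
        order = boundary[np.argsort(boundary[:, 0])]
        picks = np.linspace(0, len(order) - 1, n_haulouts)
        jitter = rng.integers(-2, 3, size=n_haulouts)
        idx = np.clip(np.round(picks + jitter).astype(int), 0, len(order) - 1)
        idx = np.unique(idx)
        while len(idx) < n_haulouts:  # collision fallback
            extra = rng.integers(0, len(order))
            idx = np.unique(np.append(idx, extra))
        ls = Landscape(xmin, ymin, cell_size, land)
        for i, (r, c) in enumerate(order[idx[:n_haulouts]]):
            x, y = ls.cell_center(r, c)
            kind = "rookery" if i % 4 == 0 else "haulout"
            haulouts.append(HaulSite(f"HS{i:02d}", x, y, kind))

    out = Landscape(xmin, ymin, cell_size, land, haulouts)
    out.validate()
    return out


def ou_velocity_step(v: float, beta: float, sigma: float, dt: float, z: float) -> float:
    """Exact discretization of dv = -beta v dt + sigma dW over a step dt."""
    e = np.exp(-beta * dt)
    sd = sigma * np.sqrt((1.0 - e * e) / (2.0 * beta))
    return v * e + sd * z


def simulate_true_path(
    landscape: Landscape,
    config: SimConfig,
    start_site: HaulSite,
    duration_days: float,
    step_h: float = 0.1,
    start_time: pd.Timestamp = DEFAULT_START_TIME,
    animal_id: str = "A00",
) -> pd.DataFrame:
    """Simulate a central-place forager's true path at a fine internal step.

    At-sea segments integrate an OU velocity (correlated random walk) reflected
    off land; haulout dwell segments are stationary at a haulout. Segment
    durations are exponential. Trips end with a deterministic homing pull
    toward the nearest haulout so the path stays continuous and cores form
    around haulouts.

    Returns a DataFrame with columns time, t_h, x_km, y_km, at_haulout.
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    if start_site not in landscape.haulouts:
        raise ValueError("start_site must belong to the landscape")
    rng = np.random.default_rng(config.seed)
    n = int(round(duration_days * 24.0 / step_h))
    beta, sigma = config.beta, config.sigma

    from scipy.spatial import cKDTree

    haul_xy = np.array([[h.x, h.y] for h in landscape.haulouts])
    water = landscape.water_cell_centers()
    water_tree = cKDTree(water)
    x, y = start_site.x, start_site.y
    vx = vy = 0.0
    mode = "dwell"
    # dwell bouts are exponential but clipped at 3x the mean: animals must
    # return to sea to feed, so multi-day fasting haulouts are not generated
    def dwell_draw():
        return min(rng.exponential(config.haulout_dwell_mean),
                   3.0 * config.haulout_dwell_mean)

    timer = dwell_draw()
    target = np.array([start_site.x, start_site.y])

    xs = np.empty(n)
    ys = np.empty(n)
    hauled = np.empty(n, dtype=bool)
    for i in range(n):
        if mode == "dwell":
            hauled[i] = True
            xs[i], ys[i] = x, y
            timer -= step_h
            if timer <= 0:
                mode = "trip"
                timer = rng.exponential(config.trip_duration_mean)
                # slip off the beach into the nearest water cell
                _, j = water_tree.query([x, y])
                x, y = water[j]
                vx, vy = rng.normal(0, sigma / np.sqrt(2 * beta), size=2)
        else:
            hauled[i] = False
            vx = ou_velocity_step(vx, beta, sigma, step_h, rng.standard_normal())
            vy = ou_velocity_step(vy, beta, sigma, step_h, rng.standard_normal())
            if mode == "homing":
                dxy = target - (x, y)
                dist = np.hypot(*dxy)
                pull = 6.0  # km/h homing speed toward the nearest haulout
                if dist > 1e-9:
                    vx += (pull * dxy[0] / dist - vx) * min(1.0, 3 * beta * step_h)
                    vy += (pull * dxy[1] / dist - vy) * min(1.0, 3 * beta * step_h)
                if dist <= landscape.cell_size:
                    x, y = target
                    mode = "dwell"
                    timer = dwell_draw()
                    xs[i], ys[i] = x, y
                    hauled[i] = True
                    continue
            nx, ny = x + vx * step_h, y + vy * step_h
            if landscape.is_land(nx, ny):
                vx, vy = -vx, -vy  # reflect off the coast
                nx, ny = x + vx * step_h, y + vy * step_h
                if landscape.is_land(nx, ny):
                    nx, ny = x, y  # cornered; stay put this step
            x, y = nx, ny
            xs[i], ys[i] = x, y
            # a cornered launch can hold the animal on its haulout cell
            hauled[i] = landscape.is_land(x, y)
            if mode == "trip":
                timer -= step_h
                if timer <= 0:
                    mode = "homing"
                    if len(haul_xy):
                        d = np.hypot(haul_xy[:, 0] - x, haul_xy[:, 1] - y)
                        target = haul_xy[np.argmin(d)]

    t_h = (np.arange(n) + 1) * step_h
    times = start_time + pd.to_timedelta(t_h, unit="h")
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "time": times,
            "t_h": t_h,
            "x_km": xs,
            "y_km": ys,
            "at_haulout": hauled,
        }
    )


def observe_track(true_path: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Thin a true path into irregular Argos-like fixes with class-typed error.

    Fix timing mimics a saltwater-switch duty cycle: frequent fixes while the
    animal is wet, sparser fixes when hauled out, and silence once the tag has
    been continuously dry longer than ``duty_cycle_preset`` hours. Each fix
    gets an LC class drawn from ``class_freqs`` (a ``z_fraction`` relabelled
    LC Z), isotropic Gaussian error with the class SD, and multi-day gaps are
    deleted at ``gap_injection_rate`` per day.

    Returns a DataFrame with columns animal_id, time, x_km, y_km, lc and the
    noiseless truth (true_x_km, true_y_km) for recovery checks.
    """
    if len(true_path) == 0:
        raise ValueError("true_path is empty")
    rng = np.random.default_rng(config.seed + 1_000_003)
    t = true_path["t_h"].to_numpy()
    hauled = true_path["at_haulout"].to_numpy()
    step = t[1] - t[0] if len(t) > 1 else 0.1

    # accumulate continuous dry time to apply the duty-cycle cutoff
    dry_h = np.zeros(len(t))
    run = 0.0
    for i in range(len(t)):
        run = run + step if hauled[i] else 0.0
        dry_h[i] = run

    fix_idx = []
    next_fix = rng.uniform(0.2, 1.0)
    for i in range(len(t)):
        if t[i] < next_fix:
            continue
        if (hauled[i] and config.duty_cycle_preset is not None
                and dry_h[i] > config.duty_cycle_preset):
            # tag silent until wet again; re-arm quickly on next wet fix
            next_fix = t[i] + 0.2
            continue
        fix_idx.append(i)
        if hauled[i]:
            next_fix = t[i] + rng.uniform(1.5, 4.0)  # slow repetition when dry
        else:
            next_fix = t[i] + rng.uniform(0.3, 1.5)  # fast repetition when wet
    fix_idx = np.array(fix_idx, dtype=int)

    # inject multi-day transmission gaps; real outages cluster late in a
    # deployment (failing battery, imminent shedding), so gaps start in the
    # last third of the track
    if config.gap_injection_rate > 0 and len(fix_idx):
        total_days = t[-1] / 24.0
        n_gaps = rng.binomial(max(int(total_days), 1), config.gap_injection_rate)
        for _ in range(n_gaps):
            g0 = rng.uniform(0.70, 0.95) * t[-1]
            g1 = g0 + rng.uniform(4.2, 6.0) * 24.0
            keep = (t[fix_idx] < g0) | (t[fix_idx] > g1)
            fix_idx = fix_idx[keep]

    classes = np.array(list(config.class_freqs.keys()))
    probs = np.array(list(config.class_freqs.values()), dtype=float)
    probs = probs / probs.sum()
    lc = rng.choice(classes, size=len(fix_idx), p=probs)
    if config.z_fraction > 0:
        lc = np.where(rng.random(len(fix_idx)) < config.z_fraction, "Z", lc)
    sd = np.array([config.error_sd_by_class[c] for c in lc])
    err = rng.standard_normal((len(fix_idx), 2)) * sd[:, None]

    sub = true_path.iloc[fix_idx]
    return pd.DataFrame(
        {
            "animal_id": sub["animal_id"].to_numpy(),
            "time": sub["time"].to_numpy(),
            "x_km": sub["x_km"].to_numpy() + err[:, 0],
            "y_km": sub["y_km"].to_numpy() + err[:, 1],
            "lc": lc,
            "true_x_km": sub["x_km"].to_numpy(),
            "true_y_km": sub["y_km"].to_numpy(),
        }
    ).reset_index(drop=True)


def simulate_state_space_track(
    times_h: np.ndarray,
    beta: float,
    sigma: float,
    seed: int,
    obs_sd: np.ndarray | float = 0.15,
    x0: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Simulate observed positions directly from the CTCRW state-space model.

    Exact transition sampling of the integrated-OU position / OU velocity
    state at the given (possibly irregular) times, plus isotropic Gaussian
    observation error. Used for parameter-recovery checks where landscape
    reflection would perturb the model.
    """
    rng = np.random.default_rng(seed)
    times_h = np.asarray(times_h, dtype=float)
    n = len(times_h)
    obs_sd = np.broadcast_to(np.asarray(obs_sd, dtype=float), (n,))
    pos = np.empty((n, 2))
    vel = rng.normal(0, sigma / np.sqrt(2 * beta), size=2)
    xy = np.array(x0, dtype=float)
    prev_t = times_h[0]
    for i, ti in enumerate(times_h):
        dt = ti - prev_t
        if dt > 0:
            e = np.exp(-beta * dt)
            qvv = sigma**2 / (2 * beta) * (1 - e * e)
            qxx = sigma**2 / beta**2 * (dt - 2 * (1 - e) / beta + (1 - e * e) / (2 * beta))
            qxv = sigma**2 / (2 * beta**2) * (1 - 2 * e + e * e)
            cov = np.array([[qxx, qxv], [qxv, qvv]])
            L = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
            for k in range(2):
                w = L @ rng.standard_normal(2)
                xy[k] = xy[k] + vel[k] * (1 - e) / beta + w[0]
                vel[k] = vel[k] * e + w[1]
        pos[i] = xy
        prev_t = ti
    obs = pos + rng.standard_normal((n, 2)) * obs_sd[:, None]
    times = DEFAULT_START_TIME + pd.to_timedelta(times_h, unit="h")
    return pd.DataFrame(
        {
            "animal_id": "SSM",
            "time": times,
            "x_km": obs[:, 0],
            "y_km": obs[:, 1],
            "lc": "3",
            "true_x_km": pos[:, 0],
            "true_y_km": pos[:, 1],
        }
    )


def replace(config: SimConfig, **kwargs) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return dataclasses.replace(config, **kwargs)
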