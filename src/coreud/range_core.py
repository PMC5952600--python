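"""Home ranges, quantitative core-space delineation and space-use metrics.

The home range is the 95% volume isopleth of a utilization distribution,
land-clipped. Rather than declaring a fixed isopleth (50% or 25%) the core,
the core boundary is found quantitatively: an exponential curve is fitted to
UD area against isopleth volume (both axes normalized to [0, 1]) and the core
boundary v* is the volume at which the fitted slope equals 1 — the point
where area starts growing faster than probability of use. The relative
intensity-of-use index I = v* / (core area as a percent of home-range area)
then verifies a core exists: I < 1 means use in the would-be core is not
distinguishable from the rest of the home range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from shapely.geometry import box, Point
from shapely.ops import unary_union

from .ctcrw import PseudoTrack
from .simulate import HaulSite, Landscape
from .ud import DensityGrid

logger = logging.getLogger(__name__)

HOME_RANGE_ISOPLETH = 95.0

#: the six bi-monthly season bins tiling the calendar year
SEASON_BINS = {
    "JF": (1, 2),
    "MA": (3, 4),
    "MJ": (5, 6),   # pupping
    "JA": (7, 8),   # breeding / molting
    "SO": (9, 10),
    "ND": (11, 12),
}
_MONTH_TO_BIN = {m: lab for lab, pair in SEASON_BINS.items() for m in pair}


@dataclass
class IsoplethProfile:
    volumes: np.ndarray        # percent levels 1..99
    areas: np.ndarray          # km^2 at each level
    normalized_areas: np.ndarray  # areas / area at 99%

    def area_at(self, v: float) -> float:
        return float(np.interp(v, self.volumes, self.areas))


@dataclass
class ExponentialFit:
    a: float
    b: float
    residual_se: float


@dataclass
class HomeRange:
    isopleth: float
    polygons: object  # shapely (Multi)Polygon, land-clipped
    area: float
    perimeter: float
    n_haulouts_within: int


@dataclass
class CoreSpace:
    v_star: float
    polygons: object
    area: float
    n_polygons: int
    proportion_of_hr: float   # percent of home-range area
    intensity_I: float
    pct_positions_in_core: float
    min_dist_to_haulout: float
    has_core: bool


def isopleth_profile(grid: DensityGrid) -> IsoplethProfile:
    """UD area against isopleth volume at 1% steps, 1-99.

    The v% isopleth region is the smallest set of highest-density cells whose
    cumulative probability reaches v/100; its area is the cell count times the
    cell area. Density ties are broken by cell index for determinism.
    """
    if abs(grid.integral() - 1.0) > 1e-6:
        raise ValueError("grid must be normalized")
    masses = grid.cell_masses().ravel()
    order = np.argsort(-masses, kind="stable")  # ties by flat index
    csum = np.cumsum(masses[order])
    vols = np.arange(1, 100)
    counts = np.searchsorted(csum, vols / 100.0 - 1e-12, side="left") + 1
    counts = np.minimum(counts, len(masses))
    areas = counts * grid.cell_area
    return IsoplethProfile(vols.astype(float), areas.astype(float),
                           areas / areas[-1])


def isopleth_cells(grid: DensityGrid, v: float) -> np.ndarray:
    """Boolean mask of the cells making up the v% isopleth region."""
    masses = grid.cell_masses().ravel()
    order = np.argsort(-masses, kind="stable")
    csum = np.cumsum(masses[order])
    k = int(np.searchsorted(csum, v / 100.0 - 1e-12, side="left")) + 1
    mask = np.zeros(masses.shape, dtype=bool)
    mask[order[:min(k, len(masses))]] = True
    return mask.reshape(grid.values.shape)


def _cells_to_polygons(grid: DensityGrid, mask: np.ndarray):
    """Union of the square cell boxes of a cell mask (raster-faithful)."""
    rows, cols = np.nonzero(mask)
    c = grid.cell_size
    boxes = [
        box(grid.xmin + col * c, grid.ymax - (row + 1) * c,
            grid.xmin + (col + 1) * c, grid.ymax - row * c)
        for row, col in zip(rows, cols)
    ]
    return unary_union(boxes)


def land_polygon(landscape: Landscape):
    """Union of the landscape's land-cell boxes (cached on the landscape)."""
    cached = getattr(landscape, "_land_poly", None)
    if cached is not None:
        return cached
    rows, cols = np.nonzero(landscape.land)
    c = landscape.cell_size
    poly = unary_union([
        box(landscape.xmin + col * c, landscape.ymax - (row + 1) * c,
            landscape.xmin + (col + 1) * c, landscape.ymax - row * c)
        for row, col in zip(rows, cols)
    ])
    landscape._land_poly = poly
    return poly


def _as_polygon_list(geom) -> list:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    return [g for g in geom.geoms if g.geom_type == "Polygon"]


def home_range(grid: DensityGrid, landscape: Landscape | None = None) -> HomeRange:
    """95% isopleth home range: polygons, land-clipped area, perimeter.

    Haulouts are counted as inside when within one cell of a polygon, since
    clipping removes the land cells the sites themselves sit on.
    """
    mask = isopleth_cells(grid, HOME_RANGE_ISOPLETH)
    if not mask.any():
        raise ValueError("95% isopleth cell set is empty")
    poly = _cells_to_polygons(grid, mask)
    haulouts: list[HaulSite] = []
    if landscape is not None:
        poly = poly.difference(land_polygon(landscape))
        haulouts = landscape.haulouts
    if poly.is_empty:
        raise ValueError("home range is empty after land clipping")
    tol = grid.cell_size
    n_within = sum(poly.distance(Point(h.x, h.y)) <= tol for h in haulouts)
    return HomeRange(
        isopleth=HOME_RANGE_ISOPLETH,
        polygons=poly,
        area=float(poly.area),
        perimeter=float(poly.length),
        n_haulouts_within=int(n_within),
    )


def delineate_core(profile: IsoplethProfile):
    """Fit area(v) = a exp(b v/100) on normalized axes; solve slope = 1.

    Both axes are scaled to [0, 1] (volume as v/100, area relative to the 99%
    area) before fitting, so the residual standard error is dimensionless and
    small for well-behaved profiles. The core boundary is
    ``v* = 100 ln(1/(a b)) / b``, where the fitted slope d(area)/d(v/100)
    reaches 1. Returns ``(fit, v_star)``; ``v_star`` is None (no core) when
    the fitted rate is non-positive, v* falls outside (0, 95), or the profile
    itself implies intensity I < 1 at v* (area growing as fast as volume, as
    for a uniform UD).
    """
    u = profile.volumes / 100.0
    y = profile.normalized_areas
    pos = y > 0
    slope, icept = np.polyfit(u[pos], np.log(y[pos]), 1)
    p0 = (float(np.exp(icept)), float(max(slope, 1e-3)))
    try:
        (a, b), pcov = curve_fit(lambda x, a, b: a * np.exp(b * x), u, y,
                                 p0=p0, maxfev=10000)
    except RuntimeError:
        return ExponentialFit(np.nan, np.nan, np.nan), None
    resid = y - a * np.exp(b * u)
    dof = max(len(u) - 2, 1)
    fit = ExponentialFit(float(a), float(b),
                         float(np.sqrt((resid**2).sum() / dof)))
    if b <= 0 or a * b <= 0:
        return fit, None
    v_star = 100.0 * np.log(1.0 / (a * b)) / b
    if not (0.0 < v_star < HOME_RANGE_ISOPLETH):
        return fit, None
    # a core must concentrate use: check the implied intensity at v*
    prop = 100.0 * profile.area_at(v_star) / profile.area_at(HOME_RANGE_ISOPLETH)
    if prop <= 0 or v_star / prop < 1.0:
        return fit, None
    return fit, float(v_star)


def intensity_of_use(v_star: float, proportion_of_hr: float) -> float:
    """Relative intensity-of-use index I = v* / (core % of home-range area).

    Both arguments are percentages; I >= 1 indicates concentrated use (a true
    core), I < 1 no difference between core and home-range utilization.
    """
    if proportion_of_hr <= 0:
        raise ValueError("proportion_of_hr must be positive")
    return v_star / proportion_of_hr


def core_space(
    grid: DensityGrid,
    v_star: float,
    hr: HomeRange,
    landscape: Landscape | None = None,
    haulouts: list[HaulSite] | None = None,
    pseudo_track: PseudoTrack | None = None,
) -> CoreSpace:
    """Core polygons at the v* isopleth with the headline space-use metrics.

    Reports total core area and polygon count (land-clipped), the core as a
    percent of home-range area, the intensity index I, the percent of the
    period's pseudolocations inside the core, and the minimum Euclidean
    distance from any core-polygon centroid to a haulout.
    """
    if not (0.0 < v_star < HOME_RANGE_ISOPLETH):
        raise ValueError("v_star must lie in (0, 95)")
    mask = isopleth_cells(grid, v_star)
    poly = _cells_to_polygons(grid, mask)
    if landscape is not None:
        poly = poly.difference(land_polygon(landscape))
        if haulouts is None:
            haulouts = landscape.haulouts
    parts = _as_polygon_list(poly)
    area = float(poly.area)
    proportion = 100.0 * area / hr.area
    I = intensity_of_use(v_star, proportion)

    pct_in = np.nan
    pos_df = pseudo_track.df if hasattr(pseudo_track, "df") else pseudo_track
    if pos_df is not None and len(pos_df):
        pts = [Point(x, y) for x, y in zip(pos_df["x_km"], pos_df["y_km"])]
        tol = grid.cell_size * 1e-9
        inside = sum(poly.distance(p) <= tol for p in pts)
        pct_in = 100.0 * inside / len(pts)

    min_dist = np.nan
    if haulouts:
        cents = [p.centroid for p in parts]
        min_dist = min(
            np.hypot(c.x - h.x, c.y - h.y) for c in cents for h in haulouts
        )
    return CoreSpace(
        v_star=float(v_star),
        polygons=poly,
        area=area,
        n_polygons=len(parts),
        proportion_of_hr=proportion,
        intensity_I=I,
        pct_positions_in_core=pct_in,
        min_dist_to_haulout=float(min_dist),
        has_core=I >= 1.0,
    )


def assign_bimonth(pseudo_track: PseudoTrack) -> dict[str, PseudoTrack]:
    """Split a pseudo-track into the six bi-monthly season bins by month.

    An animal can contribute to several bins; raw-fix provenance counts are
    apportioned by the share of pseudolocations in each bin (rounded, minimum
    1) so eligibility ratios stay meaningful.
    """
    df = pseudo_track.df
    labels = df["time"].dt.month.map(_MONTH_TO_BIN)
    out: dict[str, PseudoTrack] = {}
    for lab in SEASON_BINS:
        sub = df[labels == lab]
        if len(sub) == 0:
            continue
        n_raw = max(int(round(pseudo_track.n_raw * len(sub) / len(df))), 1)
        out[lab] = PseudoTrack(
            pseudo_track.animal_id, sub.reset_index(drop=True),
            pseudo_track.interval_h, pseudo_track.n_imputations, n_raw,
        )
    return out


def eligibility(n_pseudo: int, n_raw: int) -> bool:
    """Bi-monthly sample eligibility: > 50 pseudolocations and ratio < 3.

    The pseudolocation-to-raw-fix ratio guards against UDs dominated by
    interpolation rather than observation. Both thresholds are strict.
    """
    if n_raw <= 0:
        logger.warning("eligibility called with n_raw = 0; ineligible")
        return False
    return n_pseudo > 50 and n_pseudo / n_raw < 3.0


def metrics_row(
    animal_id: str,
    season: str,
    hr: HomeRange,
    fit: ExponentialFit,
    core: CoreSpace | None,
) -> dict:
    """One summary-table row of home-range and core-space characteristics."""
    row = {
        "animal_id": animal_id,
        "season": season,
        "hr_area_km2": hr.area,
        "hr_perimeter_km": hr.perimeter,
        "n_haulouts_in_hr": hr.n_haulouts_within,
        "residual_se": fit.residual_se,
    }
    if core is not None:
        row.update({
            "core_area_km2": core.area,
            "proportion_core_pct": core.proportion_of_hr,
            "isopleth_volume_core_pct": core.v_star,
            "pct_positions_in_core": core.pct_positions_in_core,
            "n_core_polygons": core.n_polygons,
            "min_dist_core_haulout_km": core.min_dist_to_haulout,
            "intensity_I": core.intensity_I,
            "has_core": core.has_core,
        })
    else:
        row.update({
            "core_area_km2": np.nan, "proportion_core_pct": np.nan,
            "isopleth_volume_core_pct": np.nan,
            "pct_positions_in_core": np.nan, "n_core_polygons": 0,
            "min_dist_core_haulout_km": np.nan, "intensity_I": np.nan,
            "has_core": False,
        })
    return row
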