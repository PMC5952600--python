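"""Kernel utilization distributions on a regular planar grid.

Gridded Gaussian-kernel density estimates (default 1 km x 1 km cells) with a
fixed likelihood cross-validation bandwidth, plus the effort-corrected pooled
UD used for population-level space-use summaries. All coordinates are
projected equal-area planar km.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

_CHUNK = 256  # grid rows per broadcasting chunk in kde evaluation


@dataclass
class DensityGrid:
    """Gridded probability density (1/km^2), row-major from the NW corner.

    Cells are half-open ``[x, x+cell) x (y-cell, y]``; ``values[0, 0]`` is the
    NW cell. The grid integrates to 1: ``values.sum() * cell_size**2 == 1``.
    """

    xmin: float
    ymax: float
    cell_size: float
    values: np.ndarray
    bandwidth: float
    n_points: int

    def __post_init__(self) -> None:
        if self.bandwidth <= 0 or self.cell_size <= 0:
            raise ValueError("bandwidth and cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def cell_masses(self) -> np.ndarray:
        """Per-cell probability mass (values * cell area)."""
        return self.values * self.cell_area

    def bin_points(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing each point (clipped)."""
        pts = np.asarray(points, dtype=float)
        col = np.floor((pts[:, 0] - self.xmin) / self.cell_size).astype(int)
        row = np.floor((self.ymax - pts[:, 1]) / self.cell_size).astype(int)
        return (np.clip(row, 0, self.nrows - 1), np.clip(col, 0, self.ncols - 1))


@dataclass
class BandwidthResult:
    h: float
    loo_loglik: float
    search_grid: list = field(default_factory=list)  # (h, score) pairs
    at_lower_bound: bool = False


def _loo_loglik(sq_dists: np.ndarray, h: float) -> float:
    """Leave-one-out log-likelihood for an isotropic 2-D Gaussian kernel.

    ``sq_dists`` is the dense pairwise squared-distance matrix with the
    diagonal (and any zero-distance pair) marked NaN so duplicates cannot
    drive the bandwidth to zero.
    """
    with np.errstate(over="ignore", under="ignore"):
        k = np.exp(-sq_dists / (2.0 * h * h)) / (2.0 * np.pi * h * h)
    counts = np.sum(~np.isnan(sq_dists), axis=1)
    dens = np.nansum(k, axis=1) / np.maximum(counts, 1)
    dens = np.maximum(dens, 1e-300)
    return float(np.log(dens).sum())


def lcv_bandwidth(
    points: np.ndarray,
    cell_size: float = 1.0,
    n_candidates: int = 60,
) -> BandwidthResult:
    """Fixed likelihood cross-validation bandwidth for a 2-D Gaussian kernel.

    Maximizes the sum over points of the leave-one-out log density, searching
    a log-spaced candidate grid from ``cell_size / 2`` up to the diagonal of
    the point bounding box, then refining around the best candidate with a
    bounded scalar optimizer. Zero-distance pairs are excluded from each
    point's LOO sum, so exactly duplicated points still yield a finite
    bandwidth. Ties prefer the smaller bandwidth.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    if n < 5:
        logger.warning("lcv_bandwidth called with fewer than 5 points")

    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.nan)
    d2[d2 == 0.0] = np.nan

    lo = cell_size / 2.0
    if np.all(np.isnan(d2)):
        warnings.warn("all points identical; returning lower-bound bandwidth")
        return BandwidthResult(lo, -np.inf, [], at_lower_bound=True)

    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    hi = max(diag, 4.0 * cell_size)
    cands = np.exp(np.linspace(np.log(lo), np.log(hi), n_candidates))
    scores = [_loo_loglik(d2, h) for h in cands]
    best = int(np.argmax(scores))  # argmax takes the first (smallest h) on ties

    a = cands[max(best - 1, 0)]
    b = cands[min(best + 1, n_candidates - 1)]
    if a < b:
        res = minimize_scalar(
            lambda h: -_loo_loglik(d2, h), bounds=(a, b), method="bounded",
            options={"xatol": 1e-9},
        )
        h_opt, score = float(res.x), float(-res.fun)
        if score < scores[best]:
            h_opt, score = float(cands[best]), float(scores[best])
    else:
        h_opt, score = float(cands[best]), float(scores[best])
    if h_opt <= lo + 1e-12:
        h_opt = lo
    return BandwidthResult(
        h=h_opt,
        loo_loglik=score,
        search_grid=list(zip(cands.tolist(), map(float, scores))),
        at_lower_bound=h_opt == lo,
    )


def kde_grid(
    points: np.ndarray,
    h: float,
    extent: tuple[float, float, float, float],
    cell_size: float = 1.0,
) -> DensityGrid:
    """Gaussian-kernel density surface evaluated at cell centers.

    ``extent`` is (xmin, xmax, ymin, ymax) and must cover every point with a
    3h margin. The surface is renormalized so it integrates to exactly 1 over
    the grid.
    """
    pts = np.asarray(points, dtype=float)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    xmin, xmax, ymin, ymax = extent
    margin = 3.0 * h
    if (
        pts[:, 0].min() < xmin + margin - 1e-9
        or pts[:, 0].max() > xmax - margin + 1e-9
        or pts[:, 1].min() < ymin + margin - 1e-9
        or pts[:, 1].max() > ymax - margin + 1e-9
    ):
        raise ValueError("extent must cover all points with a 3h margin")

    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    top = ymin + nrows * cell_size
    xs = xmin + (np.arange(ncols) + 0.5) * cell_size
    ys = top - (np.arange(nrows) + 0.5) * cell_size

    inv2h2 = 1.0 / (2.0 * h * h)
    norm = 1.0 / (2.0 * np.pi * h * h * len(pts))
    values = np.empty((nrows, ncols))
    dx2 = (xs[None, :] - pts[:, 0][:, None]) ** 2  # (npts, ncols)
    for r0 in range(0, nrows, _CHUNK):
        r1 = min(r0 + _CHUNK, nrows)
        dy2 = (ys[r0:r1][None, :] - pts[:, 1][:, None]) ** 2  # (npts, rows)
        # sum over points of exp(-(dx2 + dy2)/2h^2)
        block = np.einsum(
            "pr,pc->rc", np.exp(-dy2 * inv2h2), np.exp(-dx2 * inv2h2)
        )
        values[r0:r1] = block * norm
    total = values.sum() * cell_size**2
    values /= total
    return DensityGrid(xmin, top, cell_size, values, h, len(pts))


def pooled_effort_corrected_ud(
    per_animal_points: dict[str, np.ndarray],
    h: float,
    extent: tuple[float, float, float, float],
    cell_size: float = 1.0,
) -> tuple[DensityGrid, np.ndarray]:
    """Effort-corrected pooled UD across animals.

    A pooled sample dominated by animals released at one site over-represents
    that site; to reflect equal sampling effort the pooled kernel surface is
    weighted, cell by cell, by the fraction of distinct animals with at least
    one pseudolocation in the cell, then renormalized. Cells no animal visits
    carry only kernel spill-over and keep their mass unweighted, so the
    correction is a no-op when every animal occupies every visited cell.
    Returns the corrected grid and the per-cell animal-count grid.
    """
    if len(per_animal_points) < 2:
        raise ValueError("need at least 2 animals for the pooled UD")
    pooled = np.vstack(list(per_animal_points.values()))
    grid = kde_grid(pooled, h, extent, cell_size)
    counts = np.zeros_like(grid.values)
    for pts in per_animal_points.values():
        rows, cols = grid.bin_points(np.asarray(pts, dtype=float))
        visited = np.zeros_like(counts, dtype=bool)
        visited[rows, cols] = True
        counts += visited
    weights = np.where(counts > 0, counts / len(per_animal_points), 1.0)
    weighted = grid.values * weights
    total = weighted.sum() * grid.cell_area
    if total <= 0:
        raise ValueError("effort weighting removed all density mass")
    corrected = DensityGrid(
        grid.xmin, grid.ymax, grid.cell_size, weighted / total, h, grid.n_points
    )
    return corrected, counts
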