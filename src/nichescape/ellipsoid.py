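"""Minimum-volume ellipsoid (MVE) niche models and their geographic projection.

The fundamental niche of a species is modelled as an ellipsoid in
environmental (principal-component) space: the smallest-volume ellipsoid
containing a prescribed fraction of the species' occurrence environments
(default 95%, i.e. 5% omission).  Presence is predicted wherever the local
climate falls inside the ellipsoid, and the resulting binary map is clipped
to an accessible area (minimum convex polygon around the occurrences plus a
dispersal buffer).

Exact MVE search is combinatorial; :func:`fit_mve` uses a seeded multi-start
concentration heuristic in the spirit of robust minimum-covariance
estimation: draw a random h-subset, iterate "compute centroid/covariance,
re-select the h points with smallest squared Mahalanobis distance" to a
fixed point, and keep the smallest-volume solution over all starts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from shapely.geometry import MultiPoint, Point

from .occurrences import OccurrenceSet
from .raster import ClimateStack

logger = logging.getLogger(__name__)


def unit_ball_volume(d: int) -> float:
    """Volume of the unit d-ball, V_d = pi^{d/2} / Gamma(d/2 + 1)."""
    return math.pi ** (d / 2) / math.gamma(d / 2 + 1)


@dataclass
class Ellipsoid:
    """A climatic niche ellipsoid: points x with (x-mu)' Sigma^{-1} (x-mu) <= c^2.

    ``volume`` is V_d * sqrt(det Sigma) * c^d in component-space units^d.
    """

    centroid: np.ndarray
    covariance: np.ndarray
    radius2: float
    species_id: str = ""

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.centroid.size
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape does not match centroid dimension")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() <= 1e-12:
            raise ValueError("covariance is not positive definite")
        if self.radius2 <= 0:
            raise ValueError("radius2 must be positive")
        self._cho = cho_factor(self.covariance)

    @property
    def d(self) -> int:
        return self.centroid.size

    @property
    def volume(self) -> float:
        det = float(np.linalg.det(self.covariance))
        return unit_ball_volume(self.d) * math.sqrt(det) * self.radius2 ** (self.d / 2)

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray | float:
        """Squared Mahalanobis distance(s) of point(s) to the centroid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        diff = pts - self.centroid
        sol = cho_solve(self._cho, diff.T).T
        d2 = np.einsum("ij,ij->i", diff, sol)
        d2 = np.maximum(d2, 0.0)
        return float(d2[0]) if np.ndim(points) == 1 else d2

    def contains(self, points: np.ndarray) -> np.ndarray | bool:
        return self.mahalanobis2(points) <= self.radius2

    def to_dict(self) -> dict:
        return {
            "species": self.species_id,
            "d": self.d,
            "centroid": self.centroid.tolist(),
            "covariance": self.covariance.ravel().tolist(),
            "radius2": self.radius2,
            "volume": self.volume,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        k = d["d"]
        return cls(
            centroid=np.asarray(d["centroid"]),
            covariance=np.asarray(d["covariance"]).reshape(k, k),
            radius2=float(d["radius2"]),
            species_id=d.get("species", ""),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Ellipsoid":
        return cls.from_dict(json.loads(Path(path).read_text()))


def mahalanobis2(point: np.ndarray, ellipsoid: Ellipsoid) -> float:
    """Squared Mahalanobis distance of a point to an ellipsoid's centroid."""
    point = np.asarray(point, dtype=float)
    if point.size != ellipsoid.d:
        raise ValueError(f"point has dimension {point.size}, ellipsoid {ellipsoid.d}")
    return float(ellipsoid.mahalanobis2(point))


def _subset_stats(points: np.ndarray, idx: np.ndarray):
    sub = points[idx]
    mu = sub.mean(axis=0)
    diff = sub - mu
    cov = diff.T @ diff / len(idx)
    return mu, cov


def _ellipsoid_from_subset(points: np.ndarray, idx: np.ndarray, h: int):
    """Centroid/cov from a subset; radius2 = h-th smallest D^2 over all points.

    Returns (mu, cov, radius2, volume, inside_idx) or None when the subset is
    degenerate.
    """
    d = points.shape[1]
    mu, cov = _subset_stats(points, idx)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        return None
    cho = cho_factor(cov)
    diff = points - mu
    d2 = np.einsum("ij,ij->i", diff, cho_solve(cho, diff.T).T)
    order = np.argsort(d2, kind="stable")
    inside = order[:h]
    radius2 = float(d2[order[h - 1]])
    if radius2 <= 0:
        return None
    vol = unit_ball_volume(d) * math.sqrt(float(np.linalg.det(cov))) * radius2 ** (d / 2)
    return mu, cov, radius2, vol, inside


def fit_mve(points: np.ndarray, coverage: float = 0.95, seed: int = 0,
            n_starts: int = 50, species_id: str = "") -> Ellipsoid:
    """Fit the minimum-volume ellipsoid covering ``ceil(coverage * n)`` points.

    Parameters
    ----------
    points : (n, d) array of occurrence environments.
    coverage : fraction of points the ellipsoid must contain, in (0.5, 1].
    seed : RNG seed for the multi-start subset draws (deterministic result).
    n_starts : number of random starting subsets for the concentration search.

    The returned ellipsoid contains exactly h = ceil(coverage * n) of the
    fitting points (boundary counts as inside, assuming no exact distance
    ties), with radius2 equal to the h-th smallest squared Mahalanobis
    distance under the final centroid/covariance.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if not (0.5 < coverage <= 1.0):
        raise ValueError("coverage must be in (0.5, 1]")
    if n < d + 2:
        raise ValueError(f"too few occurrences: n={n} < d+2={d + 2}")
    if np.linalg.matrix_rank(points - points.mean(axis=0)) < d:
        raise ValueError(
            "occurrence environments are rank-deficient; reduce the number of components")
    h = math.ceil(coverage * n)
    h = max(h, d + 1)
    rng = np.random.default_rng(seed)

    best = None
    starts = [np.arange(n)] if h == n else [rng.choice(n, size=h, replace=False) for _ in range(n_starts)]
    for start in starts:
        idx = np.sort(np.asarray(start))
        for _ in range(200):  # concentration to a fixed point
            res = _ellipsoid_from_subset(points, idx, h)
            if res is None:
                break
            # every examined subset is a candidate, not just the fixed point
            if best is None or res[3] < best[3]:
                best = res
            new_idx = np.sort(res[4])
            if np.array_equal(new_idx, idx):
                break
            idx = new_idx
    if best is None:
        raise ValueError("MVE search failed: every candidate subset was degenerate")
    mu, cov, radius2, vol, _ = best
    return Ellipsoid(centroid=mu, covariance=cov, radius2=radius2, species_id=species_id)


def predict_presence(ellipsoid: Ellipsoid, pc_stack: ClimateStack) -> np.ndarray:
    """Binary presence grid: 1 where the cell climate lies inside the
    ellipsoid, 0 outside, NaN on nodata cells."""
    if len(pc_stack.layers) != ellipsoid.d:
        raise ValueError(
            f"stack has {len(pc_stack.layers)} layers but ellipsoid is {ellipsoid.d}-dimensional")
    cube = np.stack([pc_stack.layers[k] for k in pc_stack.layers], axis=-1)
    flat = cube.reshape(-1, ellipsoid.d)
    out = np.full(flat.shape[0], np.nan)
    valid = ~pc_stack.nodata_mask.ravel()
    d2 = ellipsoid.mahalanobis2(flat[valid])
    out[valid] = (d2 <= ellipsoid.radius2).astype(float)
    return out.reshape(pc_stack.shape)


def mcp_buffer(occ: OccurrenceSet, buffer_km: float = 25.0):
    """Minimum convex polygon around the occurrences, dilated by buffer_km.

    Degenerate inputs (single point, collinear points) fall back to the
    buffered point/segment, which shapely's buffer of the hull handles
    naturally.
    """
    pts = MultiPoint([Point(x, y) for x, y, _ in occ.records])
    hull = pts.convex_hull  # point, line or polygon depending on input
    if buffer_km > 0:
        return hull.buffer(buffer_km, quad_segs=64)
    return hull


@dataclass
class RangeMap:
    """A species' predicted geographic range as a set of fine-grid cells."""

    species_id: str
    cells: set  # of (row, col)
    constraint_polygon: object = None

    @property
    def size(self) -> int:
        return len(self.cells)


def constrain_range(presence: np.ndarray, constraint, stack: ClimateStack,
                    species_id: str = "") -> RangeMap:
    """Clip a binary presence grid to cells whose centers fall inside the
    accessible-area polygon."""
    import shapely

    rows, cols = np.nonzero(presence == 1)
    x, y = stack.transform.cell_center(rows, cols)
    inside = shapely.contains_xy(constraint, x, y) if len(rows) else np.empty(0, bool)
    cells = {(int(r), int(c)) for r, c, ok in zip(rows, cols, inside) if ok}
    if not cells:
        logger.warning("%s: empty range after accessible-area constraint", species_id)
    return RangeMap(species_id=species_id, cells=cells, constraint_polygon=constraint)
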