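"""Presence-absence matrix (PAM) on a coarse equal-area grid, species
richness, per-cell mean niche-property maps, and richness-surface comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ellipsoid import RangeMap
from .raster import ClimateStack, GridTransform

logger = logging.getLogger(__name__)


@dataclass
class PAM:
    """cells x species binary matrix on a coarse equal-area analysis grid.

    ``cell_ids`` are (coarse_row, coarse_col) tuples; ``cell_centroids`` are
    the planar km coordinates of the coarse-cell centers.  Empty cells
    (richness zero) are retained as all-zero rows so the grid is complete
    over the study domain.
    """

    cell_ids: list
    cell_centroids: np.ndarray  # (n_cells, 2) planar km
    matrix: np.ndarray          # (n_cells, n_species) in {0, 1}
    species_ids: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.cell_ids), len(self.species_ids)):
            raise ValueError("PAM matrix shape does not match ids")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("PAM entries must be 0/1")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicated species_id in PAM")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def range_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.species_ids)
        df.insert(0, "cell_row", [r for r, _ in self.cell_ids])
        df.insert(1, "cell_col", [c for _, c in self.cell_ids])
        df.insert(2, "x", self.cell_centroids[:, 0])
        df.insert(3, "y", self.cell_centroids[:, 1])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PAM":
        df = pd.read_csv(path)
        species = [c for c in df.columns if c not in ("cell_row", "cell_col", "x", "y")]
        return cls(
            cell_ids=list(zip(df.cell_row.astype(int), df.cell_col.astype(int))),
            cell_centroids=df[["x", "y"]].to_numpy(float),
            matrix=df[species].to_numpy(int),
            species_ids=species,
        )


def coarse_grid_transform(fine: GridTransform, grid_res_km: float) -> GridTransform:
    return GridTransform(x0=fine.x0, y0=fine.y0, cell_size=grid_res_km)


def build_pam(ranges: Sequence[RangeMap], stack: ClimateStack,
              grid_res_km: float = 110.0) -> PAM:
    """Aggregate fine-resolution range maps onto a coarse grid.

    A species occupies a coarse cell iff at least one of its fine range
    cells' centers falls inside it (presence-anywhere rule).  The coarse
    grid is axis-aligned with the raster's bounding box; coarse cells that
    contain no valid (study-area) fine cell are dropped, all others are
    retained even when empty.
    """
    ids = [r.species_id for r in ranges]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated species_id among ranges")
    fine = stack.transform
    coarse = coarse_grid_transform(fine, grid_res_km)

    def to_coarse(rows, cols):
        x, y = fine.cell_center(rows, cols)
        return coarse.index_of(x, y)

    nrows, ncols = stack.shape
    vr, vc = np.nonzero(~stack.nodata_mask)
    if vr.size == 0:
        raise ValueError("stack has no valid cells")
    crr, ccc = to_coarse(vr, vc)
    domain = sorted(set(zip(crr.tolist(), ccc.tolist())))
    index = {cid: i for i, cid in enumerate(domain)}

    mat = np.zeros((len(domain), len(ids)), dtype=np.int8)
    for j, rmap in enumerate(ranges):
        if not rmap.cells:
            continue
        rr = np.array([r for r, _ in rmap.cells])
        cc = np.array([c for _, c in rmap.cells])
        cr, ccid = to_coarse(rr, cc)
        for cell in set(zip(cr.tolist(), ccid.tolist())):
            i = index.get(cell)
            if i is not None:
                mat[i, j] = 1

    cx, cy = coarse.cell_center(np.array([r for r, _ in domain]),
                                np.array([c for _, c in domain]))
    return PAM(cell_ids=domain, cell_centroids=np.column_stack([cx, cy]),
               matrix=mat, species_ids=ids)


def richness(pam: PAM) -> np.ndarray:
    """Per-cell species richness: row sums of the PAM."""
    return pam.matrix.sum(axis=1)


def map_property(pam: PAM, prop: Mapping[str, float] | Callable[[str], float]) -> np.ndarray:
    """Per-cell arithmetic mean of a species-level property over the species
    present in each cell; cells with richness zero get NaN.

    Species whose property is missing (NaN or absent from the mapping) are
    dropped from this map with a warning.
    """
    if callable(prop):
        values = np.array([prop(s) for s in pam.species_ids], dtype=float)
    else:
        values = np.array([prop.get(s, np.nan) for s in pam.species_ids], dtype=float)
    keep = np.isfinite(values)
    if not keep.all():
        missing = [s for s, k in zip(pam.species_ids, keep) if not k]
        logger.warning("property missing for %d species (dropped from map): %s",
                       len(missing), missing[:5])
    sub = pam.matrix[:, keep].astype(float)
    vals = values[keep]
    counts = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (sub @ vals) / counts
    means[counts == 0] = np.nan
    return means


def compare_richness(r1: np.ndarray, r2: np.ndarray):
    """Spearman rank correlation (average ranks for ties, two-sided p)
    between two richness surfaces on the same cells; cells empty in both
    surfaces are excluded."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("richness surfaces differ in length")
    keep = ~((r1 == 0) & (r2 == 0)) & np.isfinite(r1) & np.isfinite(r2)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared non-empty cells")
    rho, p = stats.spearmanr(r1[keep], r2[keep])
    return float(rho), float(p)
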