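"""Planar climate raster stacks, study-area masking, and environmental PCA.

A :class:`ClimateStack` is the package's in-memory container for a set of
co-registered climate layers (bioclim-style grids) on a planar equal-area
grid.  Distances are in kilometres; cells are square.  Real-world rasters
must be reprojected to an equal-area frame before import; the synthetic
landscape generator produces planar grids directly.

Raster I/O uses the ESRI ASCII grid format (plain text) with a JSON sidecar
for the stack-level metadata, so stacks round-trip through ordinary text
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from shapely.geometry import shape, mapping
from sklearn.decomposition import PCA as _SKPCA


@dataclass(frozen=True)
class GridTransform:
    """Affine mapping between (row, col) indices and planar (x, y) km.

    ``x0, y0`` locate the *top-left corner* of cell (0, 0); ``cell_size``
    is the square cell edge in km.  y decreases with increasing row index,
    matching raster conventions.
    """

    x0: float
    y0: float
    cell_size: float

    def cell_center(self, row, col):
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y):
        """Row/col of the cell containing planar point(s) (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        return row, col


@dataclass
class ClimateStack:
    """Named co-registered 2-D climate layers with a shared nodata mask."""

    layers: dict[str, np.ndarray]
    transform: GridTransform
    crs_tag: str = "planar-km"
    nodata_mask: np.ndarray | None = None  # True where nodata

    def __post_init__(self):
        if not self.layers:
            raise ValueError("ClimateStack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        self._shape = shapes.pop()
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self._shape, dtype=bool)
        if self.nodata_mask.shape != self._shape:
            raise ValueError("nodata_mask shape does not match layers")

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def values_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid x n_layers) matrix of valid-cell values and their flat indices."""
        valid = ~self.nodata_mask
        idx = np.flatnonzero(valid.ravel())
        mat = np.column_stack([self.layers[k].ravel()[idx] for k in self.layers])
        return mat, idx

    def copy_with(self, layers=None, nodata_mask=None) -> "ClimateStack":
        return ClimateStack(
            layers={k: v.copy() for k, v in (layers or self.layers).items()},
            transform=self.transform,
            crs_tag=self.crs_tag,
            nodata_mask=(self.nodata_mask if nodata_mask is None else nodata_mask).copy(),
        )


NODATA_VALUE = -9999.0


def write_stack(stack: ClimateStack, directory: str | Path) -> None:
    """Write each layer as an ESRI ASCII grid plus a ``stack.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nrows, ncols = stack.shape
    t = stack.transform
    yll = t.y0 - nrows * t.cell_size
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {t.x0!r}\nyllcorner {yll!r}\n"
        f"cellsize {t.cell_size!r}\nNODATA_value {NODATA_VALUE}\n"
    )
    for name, arr in stack.layers.items():
        out = np.where(stack.nodata_mask, NODATA_VALUE, arr)
        with open(directory / f"{name}.asc", "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.8g")
    meta = {"crs_tag": stack.crs_tag, "layers": stack.layer_names}
    (directory / "stack.json").write_text(json.dumps(meta, indent=1))


def read_stack(directory: str | Path) -> ClimateStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers: dict[str, np.ndarray] = {}
    transform = None
    mask = None
    for name in meta["layers"]:
        path = directory / f"{name}.asc"
        hdr = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            arr = np.loadtxt(fh)
        arr = np.atleast_2d(arr)
        t = GridTransform(
            x0=hdr["xllcorner"],
            y0=hdr["yllcorner"] + hdr["nrows"] * hdr["cellsize"],
            cell_size=hdr["cellsize"],
        )
        transform = transform or t
        nodata = hdr.get("nodata_value", NODATA_VALUE)
        m = arr == nodata
        mask = m if mask is None else (mask | m)
        arr = np.where(m, np.nan, arr)
        layers[name] = arr
    return ClimateStack(layers=layers, transform=transform, crs_tag=meta.get("crs_tag", "planar-km"), nodata_mask=mask)


def drop_excluded_layers(stack: ClimateStack, excluded: Iterable[str]) -> ClimateStack:
    """Remove layers by name (e.g. the outlier-prone bio8/bio9/bio18/bio19)."""
    excluded = list(excluded)
    unknown = [e for e in excluded if e not in stack.layers]
    if unknown:
        raise KeyError(f"unknown layer(s): {unknown}")
    kept = {k: v for k, v in stack.layers.items() if k not in excluded}
    if not kept:
        raise ValueError("cannot exclude every layer")
    return stack.copy_with(layers=kept)


def mask_to_area(stack: ClimateStack, area) -> ClimateStack:
    """Set cells whose centers fall outside ``area`` (shapely polygon) to nodata."""
    import shapely

    nrows, ncols = stack.shape
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    x, y = stack.transform.cell_center(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(area, x, y).reshape(nrows, ncols)
    new_mask = stack.nodata_mask | ~inside
    if new_mask.all():
        raise ValueError("study area does not overlap raster")
    return stack.copy_with(nodata_mask=new_mask)


@dataclass
class PCAModel:
    """Standardized (correlation-matrix) PCA of a climate stack.

    Layers are z-scored with the stored per-layer means/sds before
    projection, so component scores are centered at the origin; the
    study-area reference point in component space is the zero vector.
    """

    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # layers x components, orthonormal columns
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "layer_names": self.layer_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            layer_names=d["layer_names"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance_fraction=np.asarray(d["explained_variance_fraction"]),
        )


def fit_pca(stack: ClimateStack, n_components: int) -> PCAModel:
    """Fit a standardized PCA over the valid (study-area) cells."""
    mat, _ = stack.values_matrix()
    n, p = mat.shape
    if p < n_components:
        raise ValueError(f"{n_components} components requested but only {p} layers")
    if n < n_components + 1:
        raise ValueError("too few valid cells for PCA")
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    if np.any(sds < 1e-12):
        bad = [stack.layer_names[i] for i in np.flatnonzero(sds < 1e-12)]
        raise ValueError(f"zero-variance layer(s) over valid cells: {bad}")
    z = (mat - means) / sds
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    sk.fit(z)
    loadings = sk.components_.T.copy()  # p x k
    # sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    evf = sk.explained_variance_ratio_.copy()
    return PCAModel(list(stack.layers), means, sds, loadings, evf)


def project_pca(model: PCAModel, stack: ClimateStack) -> ClimateStack:
    """Project a stack onto the fitted components; returns layers pc1..pcK."""
    missing = [k for k in model.layer_names if k not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing layer(s) required by the PCA: {missing}")
    nrows, ncols = stack.shape
    cube = np.stack([stack.layers[k] for k in model.layer_names], axis=-1)
    z = (cube - model.means) / model.sds
    scores = z.reshape(-1, len(model.layer_names)) @ model.loadings
    scores = scores.reshape(nrows, ncols, model.n_components)
    layers = {}
    for j in range(model.n_components):
        lay = scores[..., j].copy()
        lay[stack.nodata_mask] = np.nan
        layers[f"pc{j + 1}"] = lay
    return ClimateStack(layers=layers, transform=stack.transform,
                        crs_tag=stack.crs_tag, nodata_mask=stack.nodata_mask.copy())


@dataclass
class EnvSummary:
    """Study-area climate reference: per-layer means and the PC-space origin."""

    mean_by_layer: dict[str, float]
    pc_origin: np.ndarray

    def __getitem__(self, layer: str) -> float:
        return self.mean_by_layer[layer]


def env_summary(stack: ClimateStack, n_components: int = 3) -> EnvSummary:
    """Mean of each layer over valid cells; pc_origin is the zero vector
    because the PCA is centered on the same cells."""
    mat, _ = stack.values_matrix()
    if mat.shape[0] == 0:
        raise ValueError("no valid cells in stack")
    means = {k: float(m) for k, m in zip(stack.layers, mat.mean(axis=0))}
    return EnvSummary(mean_by_layer=means, pc_origin=np.zeros(n_components))


def polygon_to_geojson(poly, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"type": "Feature", "properties": {}, "geometry": mapping(poly)}))


def polygon_from_geojson(path: str | Path):
    d = json.loads(Path(path).read_text())
    if d.get("type") == "FeatureCollection":
        d = d["features"][0]
    geom = d["geometry"] if d.get("type") == "Feature" else d
    return shape(geom)
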