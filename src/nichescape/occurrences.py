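"""Occurrence-record cleaning: coordinate-precision filtering, per-pixel
deduplication, distance-based spatial thinning, and environmental extraction.

Coordinates are carried both as floats and as the raw text they were read
from, because the precision filter counts decimal digits *as written* —
round-tripping through floats would destroy trailing-zero information.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .raster import ClimateStack

logger = logging.getLogger(__name__)

_DECIMALS_RE = re.compile(r"^-?\d+(?:\.(\d*))?$")


@dataclass
class OccurrenceSet:
    """Cleaned or raw occurrence records for one species.

    ``records`` is a list of (x, y, source_id); ``raw_coords`` preserves the
    textual coordinate pair for each record.
    """

    species_id: str
    records: list[tuple[float, float, str]]
    raw_coords: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.species_id:
            raise ValueError("species_id must be nonempty")
        for x, y, _ in self.records:
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"{self.species_id}: non-finite coordinate")
        if not self.raw_coords:
            self.raw_coords = [(repr(x), repr(y)) for x, y, _ in self.records]
        if len(self.raw_coords) != len(self.records):
            raise ValueError("raw_coords length mismatch")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        if not self.records:
            return np.empty((0, 2))
        return np.array([(x, y) for x, y, _ in self.records], dtype=float)

    def n_unique_localities(self) -> int:
        return len({(x, y) for x, y, _ in self.records})

    def subset(self, keep_idx) -> "OccurrenceSet":
        keep_idx = list(keep_idx)
        return OccurrenceSet(
            species_id=self.species_id,
            records=[self.records[i] for i in keep_idx],
            raw_coords=[self.raw_coords[i] for i in keep_idx],
        )


def read_occurrences_csv(path: str | Path) -> list[OccurrenceSet]:
    """Read a CSV with columns species, lon, lat, source_id (header required).

    Coordinates are read as strings so the precision filter can count
    decimal digits faithfully.
    """
    df = pd.read_csv(path, dtype={"species": str, "lon": str, "lat": str, "source_id": str})
    required = {"species", "lon", "lat"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence CSV must have columns {sorted(required)}")
    if "source_id" not in df.columns:
        df["source_id"] = [str(i) for i in range(len(df))]
    out = []
    for sp, grp in df.groupby("species", sort=True):
        records, raw = [], []
        for _, row in grp.iterrows():
            records.append((float(row.lon), float(row.lat), str(row.source_id)))
            raw.append((str(row.lon).strip(), str(row.lat).strip()))
        out.append(OccurrenceSet(species_id=sp, records=records, raw_coords=raw))
    return out


def write_occurrences_csv(occ_sets, path: str | Path) -> None:
    rows = []
    for occ in occ_sets:
        for (x, y, sid), (rx, ry) in zip(occ.records, occ.raw_coords):
            rows.append({"species": occ.species_id, "lon": rx, "lat": ry, "source_id": sid})
    pd.DataFrame(rows, columns=["species", "lon", "lat", "source_id"]).to_csv(path, index=False)


def _n_decimals(text: str) -> int:
    m = _DECIMALS_RE.match(text.strip())
    if m is None:
        # scientific notation or junk: fall back to float repr
        m = _DECIMALS_RE.match(repr(float(text)))
    return len(m.group(1) or "")


def filter_precision(occ: OccurrenceSet, min_decimals: int = 2) -> OccurrenceSet:
    """Keep records where *both* coordinates carry >= min_decimals decimal
    digits as written (low-accuracy records are dropped)."""
    keep = [
        i for i, (rx, ry) in enumerate(occ.raw_coords)
        if _n_decimals(rx) >= min_decimals and _n_decimals(ry) >= min_decimals
    ]
    return occ.subset(keep)


def dedupe_pixel(occ: OccurrenceSet, stack: ClimateStack) -> OccurrenceSet:
    """Retain a single occurrence per raster cell (first in input order).

    Records outside the raster extent are dropped with a warning.
    """
    nrows, ncols = stack.shape
    seen: set[tuple[int, int]] = set()
    keep = []
    n_outside = 0
    for i, (x, y, _) in enumerate(occ.records):
        r, c = stack.transform.index_of(x, y)
        r, c = int(r), int(c)
        if not (0 <= r < nrows and 0 <= c < ncols):
            n_outside += 1
            continue
        if (r, c) in seen:
            continue
        seen.add((r, c))
        keep.append(i)
    if n_outside:
        logger.warning("%s: %d record(s) outside raster extent dropped", occ.species_id, n_outside)
    return occ.subset(keep)


def thin_distance(occ: OccurrenceSet, min_km: float = 5.0, seed: int = 0) -> OccurrenceSet:
    """Thin records so all pairwise distances are >= min_km.

    Greedy elimination: repeatedly remove the record with the most
    neighbours closer than min_km, breaking ties with a seeded RNG.  Records
    are canonicalized by coordinate sort first so the result does not depend
    on input order.
    """
    n = len(occ)
    if n <= 1:
        return occ
    order = sorted(range(n), key=lambda i: (occ.records[i][0], occ.records[i][1], occ.records[i][2]))
    xy = occ.xy[order]
    d = squareform(pdist(xy))
    close = (d < min_km)
    np.fill_diagonal(close, False)
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    counts = close.sum(axis=1)
    while True:
        active = np.flatnonzero(alive & (counts > 0))
        if active.size == 0:
            break
        cmax = counts[active].max()
        ties = active[counts[active] == cmax]
        victim = ties[rng.integers(len(ties))]
        alive[victim] = False
        counts[close[victim]] -= 1
        counts[victim] = 0
    kept_sorted = [order[i] for i in np.flatnonzero(alive)]
    return occ.subset(sorted(kept_sorted))


def check_min_records(occ: OccurrenceSet, minimum: int = 5) -> bool:
    """True iff the species has at least ``minimum`` unique localities."""
    return occ.n_unique_localities() >= minimum


def extract_env(occ: OccurrenceSet, stack: ClimateStack) -> np.ndarray:
    """Per-record environment matrix (one row per record, one column per
    layer) by nearest-cell lookup; nodata/off-grid rows are dropped."""
    if len(occ) == 0:
        return np.empty((0, len(stack.layers)))
    nrows, ncols = stack.shape
    xy = occ.xy
    r, c = stack.transform.index_of(xy[:, 0], xy[:, 1])
    ok = (r >= 0) & (r < nrows) & (c >= 0) & (c < ncols)
    r2, c2 = r[ok], c[ok]
    valid = ~stack.nodata_mask[r2, c2]
    rows = np.column_stack([stack.layers[k][r2[valid], c2[valid]] for k in stack.layers])
    n_drop = len(occ) - rows.shape[0]
    if n_drop:
        logger.warning("%s: %d record(s) on nodata or off-grid dropped from extraction",
                       occ.species_id, n_drop)
    if rows.shape[0] == 0:
        raise ValueError(f"{occ.species_id}: all records fall on nodata cells")
    return rows


def clean_pipeline(occ: OccurrenceSet, stack: ClimateStack, *, min_decimals: int = 2,
                   thin_km: float = 5.0, seed: int = 0) -> OccurrenceSet:
    """Standard cleaning order: precision filter -> per-pixel dedup -> thinning."""
    occ = filter_precision(occ, min_decimals)
    occ = dedupe_pixel(occ, stack)
    return thin_distance(occ, thin_km, seed)
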