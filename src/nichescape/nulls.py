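"""Randomization null models for richness-niche relationships.

Two nulls are provided:

* geometric-constraint (spreading dye): each species' range is regrown as a
  cohesive random blob of the observed size at a random position in the
  domain, preserving species number and all range sizes, and the richness ~
  property SAR is refitted on each random presence-absence matrix;
* property shuffle: ranges are kept fixed but the species-level niche
  properties are permuted among species before the per-cell means are
  recomputed.

Observed SAR slopes are compared with the null slope distribution by a
two-sided magnitude test with the add-one rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import PAM, map_property, richness
from .spatial import SpatialErrorModel, build_weights

logger = logging.getLogger(__name__)

NULL_TYPES = ("spreading_dye", "property_shuffle")

_ROOK = ((1, 0), (-1, 0), (0, 1), (0, -1))
_QUEEN = _ROOK + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def spreading_dye(domain, range_size: int, seed: int, adjacency: str = "rook",
                  max_restarts: int = 100) -> set:
    """Grow a cohesive random range of exactly ``range_size`` cells.

    A seed cell is drawn uniformly from the domain; at each step one cell is
    drawn uniformly from the current frontier (unoccupied domain neighbours
    of the occupied set).  If growth stalls inside a disconnected pocket the
    draw restarts from a new seed cell.
    """
    domain = set(domain)
    if not (1 <= range_size <= len(domain)):
        raise ValueError(f"range_size {range_size} outside [1, {len(domain)}]")
    offsets = _ROOK if adjacency == "rook" else _QUEEN
    rng = np.random.default_rng(seed)
    cells = sorted(domain)
    for _ in range(max_restarts):
        start = cells[rng.integers(len(cells))]
        occupied = {start}
        # frontier kept duplicate-free so draws are uniform over frontier cells
        frontier = [c for c in _neighbors(start, offsets) if c in domain]
        in_frontier = set(frontier)
        while len(occupied) < range_size and frontier:
            i = rng.integers(len(frontier))
            new = frontier[i]
            frontier[i] = frontier[-1]
            frontier.pop()
            in_frontier.discard(new)
            occupied.add(new)
            for nb in _neighbors(new, offsets):
                if nb in domain and nb not in occupied and nb not in in_frontier:
                    frontier.append(nb)
                    in_frontier.add(nb)
        if len(occupied) == range_size:
            return occupied
    raise RuntimeError(
        f"spreading dye failed to reach size {range_size} after {max_restarts} restarts")


def _neighbors(cell, offsets):
    r, c = cell
    return [(r + dr, c + dc) for dr, dc in offsets]


def random_pam(pam: PAM, seed: int, adjacency: str = "rook") -> PAM:
    """Spreading-dye randomization of a PAM: same species, same range sizes,
    random cohesive positions within the PAM's cell domain."""
    domain = list(pam.cell_ids)
    index = {cid: i for i, cid in enumerate(domain)}
    sizes = pam.range_sizes()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(pam.n_species)
    mat = np.zeros_like(pam.matrix)
    for j, size in enumerate(sizes):
        if size == 0:
            continue
        blob = spreading_dye(domain, int(size), seed=child[j].generate_state(1)[0] % (2 ** 31),
                             adjacency=adjacency)
        for cell in blob:
            mat[index[cell], j] = 1
    return PAM(cell_ids=list(pam.cell_ids), cell_centroids=pam.cell_centroids.copy(),
               matrix=mat, species_ids=list(pam.species_ids))


def shuffle_properties(prop: dict, seed: int) -> dict:
    """Permute property values uniformly among species (multiset preserved)."""
    keys = sorted(prop)
    vals = [prop[k] for k in keys]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(keys))
    return {k: vals[p] for k, p in zip(keys, perm)}


def _shuffle_table(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute whole property rows among species, keeping each species'
    property tuple together."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    out = table.copy()
    out.loc[:, :] = table.to_numpy()[perm]
    return out


def assemblage_design(pam: PAM, prop_table: pd.DataFrame, predictors) :
    """Per-cell response and design for the richness ~ properties SAR.

    Returns (y, X, centroids): richness, per-cell mean of each predictor,
    and the centroids of the retained cells.  Cells with richness zero or a
    non-finite property mean are excluded.
    """
    rich = richness(pam)
    cols = []
    for p in predictors:
        cols.append(map_property(pam, prop_table[p].to_dict()))
    X = np.column_stack(cols)
    keep = (rich > 0) & np.isfinite(X).all(axis=1)
    return rich[keep].astype(float), X[keep], pam.cell_centroids[keep]


@dataclass
class NullEnsemble:
    """Null distribution of SAR slopes for one model specification."""

    null_type: str
    n_reps: int
    slopes: pd.DataFrame        # replicate x predictor (NaN = failed replicate)
    seeds: list[int]
    n_failures: int = 0

    def to_csv(self, path) -> None:
        long = self.slopes.reset_index(names="replicate").melt(
            id_vars="replicate", var_name="predictor", value_name="slope")
        long["seed"] = long["replicate"].map(dict(enumerate(self.seeds)))
        long.to_csv(path, index=False)


def null_slope_distribution(pam: PAM, prop_table: pd.DataFrame, predictors,
                            null_type: str, n_reps: int = 100, *,
                            scheme: str = "W_row", distance_class: str = "min",
                            threshold_km: float | None = None,
                            master_seed: int = 0, adjacency: str = "rook",
                            max_failure_frac: float = 0.2) -> NullEnsemble:
    """Refit the richness ~ properties SAR under ``n_reps`` randomizations.

    Per replicate the PAM (spreading dye) or the species property table
    (shuffle) is randomized, the per-cell richness and mean-property maps
    are recomputed, and the same SAR specification (scheme, distance class)
    is refitted; the slope of each predictor is recorded.
    """
    if null_type not in NULL_TYPES:
        raise ValueError(f"null_type must be one of {NULL_TYPES}")
    predictors = list(predictors)
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_reps)]
    rows = []
    n_fail = 0
    for rep, seed in enumerate(seeds):
        try:
            if null_type == "spreading_dye":
                rep_pam, rep_table = random_pam(pam, seed, adjacency), prop_table
            else:
                rep_pam, rep_table = pam, _shuffle_table(prop_table, seed)
            y, X, cent = assemblage_design(rep_pam, rep_table, predictors)
            w = build_weights(cent, scheme=scheme, distance_class=distance_class,
                              threshold_km=threshold_km)
            fit = SpatialErrorModel(y, X, w, exog_names=predictors).fit()
            rows.append(dict(zip(predictors, fit.params[1:])))
        except Exception as err:  # noqa: BLE001 - replicate failure is recorded
            logger.warning("null replicate %d failed: %s", rep, err)
            rows.append({p: np.nan for p in predictors})
            n_fail += 1
    if n_fail > max_failure_frac * n_reps:
        raise RuntimeError(f"{n_fail}/{n_reps} null replicates failed")
    slopes = pd.DataFrame(rows, columns=predictors)
    return NullEnsemble(null_type=null_type, n_reps=n_reps, slopes=slopes,
                        seeds=seeds, n_failures=n_fail)


def null_slope_test(observed_slope: float, ensemble: NullEnsemble,
                    predictor: str | None = None) -> float:
    """Two-sided magnitude test of an observed SAR slope against the null
    ensemble: ``p = (1 + #{|slope_null| >= |slope_obs|}) / (n_reps + 1)``."""
    if predictor is None:
        if ensemble.slopes.shape[1] != 1:
            raise ValueError("predictor must be named for multi-predictor ensembles")
        col = ensemble.slopes.iloc[:, 0]
    else:
        col = ensemble.slopes[predictor]
    vals = col.dropna().to_numpy()
    if vals.size == 0:
        raise ValueError("ensemble contains no successful replicates")
    k = int((np.abs(vals) >= abs(observed_slope) - 1e-12).sum())
    return (1 + k) / (ensemble.n_reps + 1)
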