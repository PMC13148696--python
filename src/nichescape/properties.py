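"""Per-species climatic niche properties.

Three properties are computed per species, each under two approaches:

* breadth — multivariate: the fitted ellipsoid volume (NB); univariate: the
  max-minus-min range of a temperature (TB, degC) and a precipitation (PB, mm)
  variable over the species' occurrence climates.
* marginality — distance from the species' niche centroid to the average
  climate of the study area: Mahalanobis distance through the species'
  ellipsoid to the principal-component origin (NM), or absolute difference
  to the study-area mean of the reference variable (TM, PM).
* phylogenetic position — distance from the niche centroid to the
  reconstructed ancestral centroid (NP, TP, PP); computed in the
  comparative module and merged here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .ellipsoid import Ellipsoid
from .raster import EnvSummary

#: documented column order of the property table
PROPERTY_COLUMNS = [
    "NB", "NM", "NP", "TB", "TM", "TP", "PB", "PM", "PP",
    "t_centroid", "p_centroid",
]


@dataclass(frozen=True)
class UnivariateExtremes:
    """Per-species climate extremes over occupied cells.

    ``t_max`` is the maximum of the warm-extreme temperature variable,
    ``t_min`` the minimum of the cold-extreme variable (degC); ``p_max`` /
    ``p_min`` likewise for the wet/dry precipitation variables (mm).
    """

    t_min: float
    t_max: float
    p_min: float
    p_max: float


def compute_extremes(env: np.ndarray, layer_names: list[str], *,
                     temp_max_layer: str, temp_min_layer: str,
                     precip_max_layer: str, precip_min_layer: str) -> UnivariateExtremes:
    """Extract the univariate extremes from an occurrence-environment matrix.

    The warm/cold (wet/dry) extremes may come from distinct layers (e.g.
    warmest-month vs coldest-month temperature) or from a single layer.
    """
    cols = {name: i for i, name in enumerate(layer_names)}
    for lay in (temp_max_layer, temp_min_layer, precip_max_layer, precip_min_layer):
        if lay not in cols:
            raise KeyError(f"layer {lay!r} not present in extracted environments")
    return UnivariateExtremes(
        t_min=float(env[:, cols[temp_min_layer]].min()),
        t_max=float(env[:, cols[temp_max_layer]].max()),
        p_min=float(env[:, cols[precip_min_layer]].min()),
        p_max=float(env[:, cols[precip_max_layer]].max()),
    )


def univariate_breadth(extremes: UnivariateExtremes) -> tuple[float, float]:
    """TB = warm-extreme max - cold-extreme min; PB analogously for
    precipitation. Both are non-negative by construction of the extremes."""
    return extremes.t_max - extremes.t_min, extremes.p_max - extremes.p_min


def univariate_centroid(extremes: UnivariateExtremes) -> tuple[float, float]:
    """Mid-range centroid per dimension: (min + max) / 2."""
    return (extremes.t_min + extremes.t_max) / 2, (extremes.p_min + extremes.p_max) / 2


def univariate_marginality(centroid: tuple[float, float],
                           temp_reference: float, precip_reference: float) -> tuple[float, float]:
    """Absolute (1-D Euclidean) distance from the species centroid to the
    study-area mean annual temperature / annual precipitation."""
    t_c, p_c = centroid
    return abs(t_c - temp_reference), abs(p_c - precip_reference)


def multivariate_marginality(ellipsoid: Ellipsoid, reference: EnvSummary) -> float:
    """Mahalanobis distance, through the species' own ellipsoid covariance,
    from the niche centroid to the study-area reference point in component
    space (the origin, since the PCA is centered there)."""
    origin = np.asarray(reference.pc_origin, dtype=float)
    if origin.size != ellipsoid.d:
        raise ValueError("reference dimension does not match ellipsoid")
    return float(np.sqrt(ellipsoid.mahalanobis2(origin)))


def assemble_property_table(
    ellipsoids: Mapping[str, Ellipsoid],
    extremes: Mapping[str, UnivariateExtremes],
    reference: EnvSummary,
    *,
    temp_reference_layer: str,
    precip_reference_layer: str,
    positions: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """One row per modelled species with columns NB, NM, NP, TB, TM, TP, PB,
    PM, PP and the univariate centroids.

    ``positions`` maps species -> {"NP": .., "TP": .., "PP": ..}; species
    without a phylogeny placement get NaN positions and are excluded from
    position maps downstream.
    """
    sp_e = set(ellipsoids)
    sp_x = set(extremes)
    if sp_e != sp_x:
        raise KeyError(
            f"species mismatch between ellipsoids and extremes: "
            f"only-ellipsoids={sorted(sp_e - sp_x)[:5]}, only-extremes={sorted(sp_x - sp_e)[:5]}")
    t_ref = reference[temp_reference_layer]
    p_ref = reference[precip_reference_layer]
    positions = positions or {}
    rows = []
    for sp in sorted(sp_e):
        ell = ellipsoids[sp]
        ext = extremes[sp]
        tb, pb = univariate_breadth(ext)
        cent = univariate_centroid(ext)
        tm, pm = univariate_marginality(cent, t_ref, p_ref)
        pos = positions.get(sp, {})
        rows.append({
            "species": sp,
            "NB": ell.volume,
            "NM": multivariate_marginality(ell, reference),
            "NP": pos.get("NP", np.nan),
            "TB": tb, "TM": tm, "TP": pos.get("TP", np.nan),
            "PB": pb, "PM": pm, "PP": pos.get("PP", np.nan),
            "t_centroid": cent[0], "p_centroid": cent[1],
        })
    df = pd.DataFrame(rows).set_index("species")[PROPERTY_COLUMNS]
    return df
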