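"""Continuous-trait evolution on a phylogeny: model fitting and selection
(Brownian motion, Ornstein-Uhlenbeck, Early Burst, rate trend), root-state
reconstruction, and phylogenetic niche position.

The modelling interface follows the Model/Results convention:
``TraitEvolutionModel(tree, trait).fit("OU")`` returns a
:class:`TraitEvolutionResults` carrying the maximum-likelihood parameters,
log-likelihood, AIC and the generalized-least-squares root state.

All four models induce a multivariate-normal distribution of tip values
with mean ``z0 * 1`` and covariance ``sigma2 * V0(params)``, where ``V0`` is
a structure matrix built from shared path lengths on the tree:

* BM: ``V0_ij = C_ij`` (shared path length from the root).
* OU (stationary): ``V0_ij = e^{-alpha (t_i + t_j - 2 C_ij)}
  (1 - e^{-2 alpha C_ij}) / (2 alpha)``; on an ultrametric tree this is the
  familiar ``e^{-2 alpha (T - C_ij)} (1 - e^{-2 alpha C_ij}) / (2 alpha)``.
* EB: ``V0_ij = (e^{r C_ij} - 1) / r`` with ``r < 0`` (exponentially
  decelerating rate).
* trend: rate changes linearly in time, ``sigma2(t) = sigma2 (1 + b t)``,
  so ``V0_ij = C_ij + b C_ij^2 / 2`` (accumulated variance along the shared
  path).

Given the structure parameter, ``z0`` and ``sigma2`` have closed-form ML
solutions, so each fit is a one-dimensional profile-likelihood optimization
solved by a deterministic coarse grid plus bounded refinement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .ellipsoid import Ellipsoid

MODELS = ("BM", "OU", "EB", "trend")
_N_PARAMS = {"BM": 2, "OU": 3, "EB": 3, "trend": 3}  # incl. sigma2 and z0/theta


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch length")


def prune_to_species(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on the kept tips; degree-2 internal nodes are
    collapsed with branch lengths summed, so tip-to-tip path lengths are
    preserved."""
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    kept = tips & set(keep)
    if not kept:
        raise ValueError("no requested species present in the tree")
    sub = tree.extract_tree_with_taxa_labels(kept, suppress_unifurcations=True)
    return sub


def tree_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Shared-path-length matrix C (C_ij = depth of the MRCA of tips i, j;
    C_ii = root-to-tip distance) and the tip label order."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for i, lf in enumerate(leaves):
        C[i, i] = lf.root_distance or 0.0
    # postorder: at each internal node, pairs of leaves from different child
    # subtrees have their MRCA here
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = [index[id(node)]]
            continue
        depth = node.root_distance or 0.0
        child_sets = [leafsets.pop(id(ch)) for ch in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = depth
        merged = [i for s in child_sets for i in s]
        leafsets[id(node)] = merged
    return C, labels


def tree_height(tree: dendropy.Tree) -> float:
    C, _ = tree_covariance(tree)
    return float(np.diag(C).max())


def is_ultrametric(C: np.ndarray, rtol: float = 1e-6) -> bool:
    t = np.diag(C)
    return bool(np.allclose(t, t.max(), rtol=rtol, atol=rtol * max(t.max(), 1.0)))


def _structure_matrix(model: str, C: np.ndarray, param: float) -> np.ndarray:
    t = np.diag(C)
    if model == "BM":
        return C
    if model == "OU":
        a = param
        ti = t[:, None] + t[None, :]
        return np.exp(-a * (ti - 2 * C)) * (1.0 - np.exp(-2.0 * a * C)) / (2.0 * a)
    if model == "EB":
        r = param
        return (np.exp(r * C) - 1.0) / r
    if model == "trend":
        b = param
        return C + b * C ** 2 / 2.0
    raise ValueError(f"unknown model {model!r}")


def _profile_loglik(V0: np.ndarray, z: np.ndarray):
    """ML z0, sigma2 and log-likelihood given the unit-rate structure V0."""
    n = len(z)
    try:
        cho = cho_factor(V0)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    one = np.ones(n)
    Vi1 = cho_solve(cho, one)
    Viz = cho_solve(cho, z)
    denom = one @ Vi1
    z0 = (one @ Viz) / denom
    resid = z - z0
    q = resid @ cho_solve(cho, resid)
    if q <= 0:
        q = 1e-300
    sigma2 = q / n
    ll = -0.5 * n * math.log(2 * math.pi) - 0.5 * n * math.log(sigma2) - 0.5 * logdet - 0.5 * n
    return z0, sigma2, ll, denom


@dataclass
class TraitEvolutionResults:
    """ML fit of one trait-evolution model; produced by
    :meth:`TraitEvolutionModel.fit`."""

    model: str
    params: dict
    z0: float
    sigma2: float
    loglik: float
    n_params: int
    n_tips: int
    warnings: list = field(default_factory=list)
    _model_obj: "TraitEvolutionModel | None" = None

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": self.model, "params": self.params, "z0": self.z0,
            "sigma2": self.sigma2, "loglik": self.loglik, "AIC": self.aic,
            "n_params": self.n_params, "n_tips": self.n_tips,
        }

    def summary(self) -> str:
        lines = [f"Trait evolution model: {self.model} (n={self.n_tips} tips)"]
        lines.append(f"  logLik = {self.loglik:.4f}   AIC = {self.aic:.4f}   k = {self.n_params}")
        lines.append(f"  sigma2 = {self.sigma2:.6g}   root/mean z0 = {self.z0:.6g}")
        for k, v in self.params.items():
            lines.append(f"  {k} = {v:.6g}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


class TraitEvolutionModel:
    """Continuous-trait model on a fixed rooted phylogeny.

    Parameters
    ----------
    tree : dendropy.Tree with branch lengths.
    trait : mapping tip label -> trait value; must cover every tip.
    """

    def __init__(self, tree: dendropy.Tree, trait: Mapping[str, float]):
        self.tree = tree
        C, labels = tree_covariance(tree)
        missing = [l for l in labels if l not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        self.C = C
        self.tip_labels = labels
        self.z = np.array([float(trait[l]) for l in labels])
        self.T = float(np.diag(C).max())
        self.ultrametric = is_ultrametric(C)

    @classmethod
    def from_series(cls, tree: dendropy.Tree, series) -> "TraitEvolutionModel":
        return cls(tree, dict(series))

    def _bounds(self, model: str) -> tuple[float, float]:
        T = self.T
        if model == "OU":
            return 1e-8 / T, 50.0 / T
        if model == "EB":
            return -10.0 / T, -1e-8 / T
        if model == "trend":
            return -0.99 / T, 10.0 / T
        raise ValueError(model)

    def _loglik_at(self, model: str, param: float):
        V0 = _structure_matrix(model, self.C, param)
        return _profile_loglik(V0, self.z)

    def fit(self, model: str = "BM", n_grid: int = 40) -> TraitEvolutionResults:
        """Maximum-likelihood fit of one model.

        The structure parameter (OU alpha, EB r, trend slope) is profiled:
        a deterministic coarse grid over the documented bounds is followed
        by bounded scalar refinement around the best grid point.
        """
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        warns = []
        if model == "OU" and not self.ultrametric:
            warns.append("non-ultrametric tree: using the general (non-stationary) OU covariance")
        if model == "BM":
            res = self._loglik_at("BM", 0.0)
            if res is None:
                raise ValueError("non-finite BM likelihood (singular covariance)")
            z0, sigma2, ll, _ = res
            return TraitEvolutionResults("BM", {}, z0, sigma2, ll,
                                         _N_PARAMS["BM"], len(self.z), warns, self)
        lo, hi = self._bounds(model)
        if model == "OU":
            grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
        else:
            grid = np.linspace(lo, hi, n_grid)

        def neg_ll(p):
            out = self._loglik_at(model, p)
            return np.inf if out is None else -out[2]

        vals = np.array([neg_ll(p) for p in grid])
        if not np.isfinite(vals).any():
            raise ValueError(f"non-finite likelihood for model {model}")
        i = int(np.nanargmin(vals))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, len(grid) - 1)]
        opt = minimize_scalar(neg_ll, bounds=(blo, bhi), method="bounded",
                              options={"xatol": 1e-10})
        cand = [(opt.x, opt.fun), (grid[i], vals[i])]
        p_hat, nll = min(cand, key=lambda t: t[1])
        z0, sigma2, ll, _ = self._loglik_at(model, p_hat)
        pname = {"OU": "alpha", "EB": "r", "trend": "slope"}[model]
        params = {pname: float(p_hat)}
        if model == "OU":
            params["theta"] = z0
            if p_hat > 0.99 * hi:
                warns.append("alpha at upper bound")
        return TraitEvolutionResults(model, params, z0, sigma2, ll,
                                     _N_PARAMS[model], len(self.z), warns, self)

    def fit_all(self, models: Sequence[str] = MODELS) -> list[TraitEvolutionResults]:
        return [self.fit(m) for m in models]


def select_model(fits: Sequence[TraitEvolutionResults]):
    """Akaike-weight model selection.

    Returns ``(best_fit, weights)`` where ``weights`` maps model name to the
    AIC weight ``exp(-Delta_i/2) / sum_j exp(-Delta_j/2)``.  AIC ties are
    broken in favour of the model with fewest parameters.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    order = sorted(range(len(fits)), key=lambda i: (round(aics[i], 9), fits[i].n_params))
    best = fits[order[0]]
    return best, {f.model: float(wi) for f, wi in zip(fits, w)}


@dataclass
class ReconResult:
    """Root-state (ancestral centroid) reconstruction for one trait."""

    ancestral_value: float
    se: float
    model_used: str

    def interval(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return self.ancestral_value - z * self.se, self.ancestral_value + z * self.se


def reconstruct_root(fit: TraitEvolutionResults) -> ReconResult:
    """GLS estimate of the root state under the fitted covariance:
    ``z0 = (1' V^-1 1)^-1 1' V^-1 z`` with standard error from
    ``sigma2 (1' V0^-1 1)^-1``."""
    model_obj = fit._model_obj
    if model_obj is None:
        raise ValueError("fit is detached from its model; refit before reconstructing")
    param = next(iter(fit.params.values()), 0.0) if fit.model != "BM" else 0.0
    V0 = _structure_matrix(fit.model, model_obj.C, param)
    out = _profile_loglik(V0, model_obj.z)
    if out is None:
        raise np.linalg.LinAlgError("singular covariance in root reconstruction")
    z0, sigma2, _, denom = out
    se = math.sqrt(fit.sigma2 / denom)
    return ReconResult(ancestral_value=float(z0), se=float(se), model_used=fit.model)


def phylo_position(species_centroid, ancestral, metric: str = "euclidean",
                   ellipsoid: Ellipsoid | None = None) -> float:
    """Distance from a species' niche centroid to the ancestral centroid.

    ``euclidean`` operates per dimension (scalars or vectors);
    ``mahalanobis`` requires the species' ellipsoid and uses its covariance.
    """
    mu = np.atleast_1d(np.asarray(species_centroid, dtype=float))
    if isinstance(ancestral, ReconResult):
        anc_vals = ancestral.ancestral_value
    elif isinstance(ancestral, (list, tuple)) and ancestral and isinstance(ancestral[0], ReconResult):
        anc_vals = [a.ancestral_value for a in ancestral]
    else:
        anc_vals = ancestral
    anc = np.atleast_1d(np.asarray(anc_vals, dtype=float))
    if mu.shape != anc.shape:
        raise ValueError("centroid and ancestral dimension mismatch")
    if metric == "euclidean":
        return float(np.linalg.norm(mu - anc))
    if metric == "mahalanobis":
        if ellipsoid is None:
            raise ValueError("mahalanobis metric requires the species' ellipsoid")
        shifted = Ellipsoid(centroid=anc, covariance=ellipsoid.covariance,
                            radius2=ellipsoid.radius2)
        return float(np.sqrt(shifted.mahalanobis2(mu)))
    raise ValueError(f"unknown metric {metric!r}")
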