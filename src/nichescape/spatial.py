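"""Spatial weights, simultaneous autoregressive (SAR) error models, Moran's
I, and predictor-correlation screening.

The SAR error model is ``y = X beta + u`` with ``u = lambda W u + eps``,
``eps ~ N(0, sigma2 I)``.  It is estimated by maximum likelihood with the
log-likelihood concentrated over ``lambda``; the Jacobian term
``ln |I - lambda W|`` is evaluated from the (real) eigenvalues of ``W``,
which exist for all three supported weighting schemes because each is
similar to a symmetric matrix.  The interface follows the Model/Results
convention: ``SpatialErrorModel(y, X, weights).fit()`` returns a
:class:`SARResults` with coefficient table, ``summary()``, AIC and
residuals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

SCHEMES = ("W_row", "C_global", "S_varstab")
DISTANCE_CLASSES = ("min", "max")


@dataclass
class SpatialWeights:
    """Spatial weight matrix over grid-cell centroids.

    ``scheme``: ``W_row`` (row-standardized), ``C_global`` (globally
    standardized, total weight = n) or ``S_varstab`` (rows scaled by their
    L2 norm, then globally rescaled to total weight = n).  The neighbour
    structure is symmetric; the scaled matrix need not be.
    """

    W: np.ndarray
    scheme: str
    distance_class: str
    threshold_km: float
    _B: np.ndarray = field(repr=False, default=None)
    _D: np.ndarray = field(repr=False, default=None)  # W = D^{-1/2-similar} form

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def S0(self) -> float:
        return float(self.W.sum())

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W via the similar symmetric matrix
        ``D^{-1/2} B' D^{-1/2}`` (B' = globally scaled binary links)."""
        d = self._D
        s = 1.0 / np.sqrt(d)
        M = (self._B * s[:, None]) * s[None, :]
        return np.linalg.eigvalsh(M)

    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        i, j = np.nonzero(self.W)
        pd.DataFrame({"i": i, "j": j, "w": self.W[i, j]}).to_csv(
            prefix.with_suffix(".csv"), index=False)
        prefix.with_suffix(".json").write_text(json.dumps({
            "n": self.n, "scheme": self.scheme,
            "distance_class": self.distance_class,
            "threshold_km": self.threshold_km,
        }, indent=1))


def neighbor_thresholds(centroids: np.ndarray) -> dict[str, float]:
    """Default distance-class thresholds: ``min`` is the largest
    first-nearest-neighbour distance (guarantees every cell has a
    neighbour); ``max`` is twice that."""
    d = squareform(pdist(np.asarray(centroids, dtype=float)))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    t = float(nn.max()) * (1 + 1e-9)
    return {"min": t, "max": 2.0 * t}


def build_weights(centroids: np.ndarray, scheme: str = "W_row",
                  distance_class: str = "min",
                  threshold_km: float | None = None) -> SpatialWeights:
    """Distance-band spatial weights over cell centroids."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if distance_class not in DISTANCE_CLASSES:
        raise ValueError(f"distance_class must be one of {DISTANCE_CLASSES}")
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    if n < 2:
        raise ValueError("need at least 2 cells")
    explicit = threshold_km is not None
    if threshold_km is None:
        threshold_km = neighbor_thresholds(centroids)[distance_class]
    d = squareform(pdist(centroids))
    B = ((d <= threshold_km) & (d > 0)).astype(float)
    deg = B.sum(axis=1)
    if (deg == 0).any():
        islands = np.flatnonzero(deg == 0).tolist()
        if explicit:
            raise ValueError(f"isolated cell(s) under threshold {threshold_km}: {islands}")
        raise ValueError(f"isolated cell(s): {islands}")  # defensive; defaults prevent this

    if scheme == "W_row":
        D = deg.copy()
        W = B / deg[:, None]
        Bscaled = B
    elif scheme == "C_global":
        S0 = B.sum()
        W = n * B / S0
        Bscaled = W  # already symmetric
        D = np.ones(n)
    else:  # S_varstab
        q = np.sqrt((B ** 2).sum(axis=1))  # = sqrt(deg) for binary links
        W1 = B / q[:, None]
        g = n / W1.sum()
        W = g * W1
        Bscaled = g * B
        D = q.copy()
    return SpatialWeights(W=W, scheme=scheme, distance_class=distance_class,
                          threshold_km=float(threshold_km), _B=Bscaled, _D=D)


@dataclass
class SARResults:
    """Fitted SAR error model; produced by :meth:`SpatialErrorModel.fit`."""

    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lam: float
    sigma2: float
    loglik: float
    nobs: int
    exog_names: list[str]
    resid: np.ndarray
    weights: SpatialWeights

    @property
    def aic(self) -> float:
        # k = regression coefficients + lambda + sigma2
        k = len(self.params) + 2
        return 2 * k - 2 * self.loglik

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Estimate": self.params, "Std.Error": self.bse,
            "z": self.zvalues, "p-value": self.pvalues,
        }, index=self.exog_names)

    def summary(self) -> str:
        lines = [
            "Simultaneous autoregressive error model (ML)",
            f"  n = {self.nobs}   scheme = {self.weights.scheme}"
            f"   distance class = {self.weights.distance_class}",
            f"  lambda = {self.lam:.4f}   sigma2 = {self.sigma2:.6g}",
            f"  logLik = {self.loglik:.4f}   AIC = {self.aic:.4f}",
            "",
            self.coef_table().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SpatialErrorModel:
    """SAR spatial-error regression of a per-cell response on per-cell
    predictors.

    Parameters
    ----------
    endog : (n,) response (e.g. species richness per cell).
    exog : (n, p) predictor matrix *without* constant; an intercept is
        prepended automatically.
    weights : SpatialWeights on the same cells.
    exog_names : optional predictor names.
    """

    def __init__(self, endog, exog, weights: SpatialWeights,
                 exog_names: Sequence[str] | None = None, add_constant: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        if X.shape[0] != y.size:
            raise ValueError("endog/exog length mismatch")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("missing values in endog/exog")
        names = list(exog_names) if exog_names is not None else [
            f"x{i + 1}" for i in range(X.shape[1])]
        if add_constant:
            X = np.column_stack([np.ones(y.size), X])
            names = ["const"] + names
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("exog is rank deficient")
        if weights.n != y.size:
            raise ValueError("weights dimension does not match data")
        self.y, self.X, self.weights, self.exog_names = y, X, weights, names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       predictors: Sequence[str], weights: SpatialWeights) -> "SpatialErrorModel":
        return cls(df[response].to_numpy(), df[list(predictors)].to_numpy(),
                   weights, exog_names=list(predictors))

    def _concentrated(self, lam: float, eig: np.ndarray):
        n = self.y.size
        A = np.eye(n) - lam * self.weights.W
        ys = A @ self.y
        Xs = A @ self.X
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = float(e @ e) / n
        if sigma2 <= 0:
            sigma2 = 1e-300
        logjac = float(np.log(np.maximum(1.0 - lam * eig, 1e-300)).sum())
        ll = -0.5 * n * (math.log(2 * math.pi) + 1.0) - 0.5 * n * math.log(sigma2) + logjac
        return ll, beta, sigma2, Xs, e

    def fit(self, n_grid: int = 50) -> SARResults:
        """Concentrated-ML fit: grid search over the feasible lambda
        interval followed by bounded scalar refinement."""
        eig = self.weights.eigenvalues()
        emin, emax = float(eig.min()), float(eig.max())
        lo = 1.0 / emin + 1e-6 if emin < 0 else -0.9999
        hi = 1.0 / emax - 1e-6 if emax > 0 else 0.9999
        grid = np.linspace(lo, hi, n_grid)
        lls = np.array([self._concentrated(l, eig)[0] for l in grid])
        i = int(np.argmax(lls))

        def neg(l):
            return -self._concentrated(l, eig)[0]

        blo, bhi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
        opt = minimize_scalar(neg, bounds=(blo, bhi), method="bounded",
                              options={"xatol": 1e-8})
        lam = float(opt.x) if -opt.fun >= lls[i] else float(grid[i])
        ll, beta, sigma2, Xs, e = self._concentrated(lam, eig)
        if not np.isfinite(ll):
            raise RuntimeError("SAR fit did not converge: non-finite likelihood "
                               f"(lambda={lam:.4f}, sigma2={sigma2:.3g})")
        XtX = Xs.T @ Xs
        cov = sigma2 * np.linalg.inv(XtX)
        bse = np.sqrt(np.diag(cov))
        z = beta / bse
        p = 2 * stats.norm.sf(np.abs(z))
        resid = self.y - self.X @ beta
        return SARResults(params=beta, bse=bse, zvalues=z, pvalues=p, lam=lam,
                          sigma2=sigma2, loglik=float(ll), nobs=self.y.size,
                          exog_names=self.exog_names, resid=resid,
                          weights=self.weights)


def select_sar(endog, exog, candidates: Sequence[SpatialWeights],
               exog_names: Sequence[str] | None = None):
    """Fit the SAR specification under every candidate weight matrix and
    pick the minimum-AIC fit.  Returns ``(best_fit, table)`` where the table
    lists scheme, distance class, AIC and logLik sorted ascending by AIC."""
    if not candidates:
        raise ValueError("no candidate weights supplied")
    rows, fits = [], []
    for w in candidates:
        try:
            f = SpatialErrorModel(endog, exog, w, exog_names=exog_names).fit()
        except Exception as err:  # noqa: BLE001 - recorded, not fatal per candidate
            rows.append({"scheme": w.scheme, "distance_class": w.distance_class,
                         "AIC": np.nan, "logLik": np.nan, "lambda": np.nan,
                         "error": str(err)})
            fits.append(None)
            continue
        rows.append({"scheme": w.scheme, "distance_class": w.distance_class,
                     "AIC": f.aic, "logLik": f.loglik, "lambda": f.lam, "error": ""})
        fits.append(f)
    table = pd.DataFrame(rows)
    ok = table["AIC"].notna()
    if not ok.any():
        raise RuntimeError("every candidate SAR fit failed")
    table = table.sort_values("AIC", kind="stable", na_position="last").reset_index(drop=True)
    best = fits[int(np.nanargmin([r["AIC"] if np.isfinite(r.get("AIC", np.nan)) else np.inf
                                  for r in rows]))]
    return best, table


def morans_i(x: np.ndarray, w: SpatialWeights, n_perm: int = 999, seed: int = 0):
    """Moran's I with analytic expectation and a seeded permutation p-value.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with
    ``z = x - mean(x)``; ``E[I] = -1/(n-1)``; two-sided permutation p with
    the add-one rule ``(k + 1) / (m + 1)``.
    """
    x = np.asarray(x, dtype=float)
    if np.var(x) == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    n = x.size

    def stat(v):
        z = v - v.mean()
        return (n / w.S0) * float(z @ w.W @ z) / float(z @ z)

    I = stat(x)
    expectation = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    dev = abs(I - expectation)
    k = 0
    for _ in range(n_perm):
        Ip = stat(rng.permutation(x))
        if abs(Ip - expectation) >= dev - 1e-12:
            k += 1
    p = (k + 1) / (n_perm + 1)
    return I, expectation, p


def screen_predictors(props: pd.DataFrame, cutoff: float = 0.7) -> list[list[str]]:
    """Split predictors into models so that no model contains a pair with
    Spearman |rho| > cutoff (greedy first-fit in column order)."""
    cols = list(props.columns)
    if len(cols) < 2:
        return [cols]
    rho = props.corr(method="spearman").abs()
    models: list[list[str]] = []
    for c in cols:
        placed = False
        for m in models:
            if all(rho.loc[c, other] <= cutoff for other in m):
                m.append(c)
                placed = True
                break
        if not placed:
            models.append([c])
    return models
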