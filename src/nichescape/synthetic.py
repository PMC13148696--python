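"""Seeded synthetic scenarios: landscape, phylogeny, niche evolution, and
occurrence sampling.

The generator emulates the statistical structure the analysis assumes about
its real-world inputs — a spatially autocorrelated multi-layer climate on a
planar equal-area grid with a strong "tropical" temperature gradient and a
patchy, bimodal precipitation field; an ultrametric pure-birth phylogeny;
tip niche centroids evolved under an Ornstein-Uhlenbeck process in the
landscape's own principal-component space; per-species ellipsoidal niches
whose breadth can be coupled to the centroid position (building a
breadth-richness gradient into the scenario); and point occurrences sampled
from within each species' true niche.  Every stage is driven by a single
master seed, so scenarios are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.ndimage import gaussian_filter

from .ellipsoid import Ellipsoid
from .occurrences import OccurrenceSet, write_occurrences_csv
from .raster import ClimateStack, GridTransform, PCAModel, fit_pca, project_pca, write_stack

PRESETS = ("breadth_gradient", "neutral", "conserved_position")


def _grf(shape, range_km, rng):
    """Unit-variance Gaussian random field with squared-exponential
    correlation of the stated range (km; cell = 1 km)."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=range_km, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_landscape(n_rows: int = 150, n_cols: int = 150, n_layers: int = 3,
                   gradient_strength: float = 15.0, autocorr_range_km: float = 10.0,
                   seed: int = 0) -> ClimateStack:
    """Planar multi-layer climate landscape (1-km cells).

    ``temperature`` carries a strong latitudinal gradient (warm at low row
    indices, the "tropical" end) plus autocorrelated noise, in degC;
    ``precipitation`` is patchy and bimodal (wet/dry regimes), in mm;
    additional layers mix the gradient with independent fields.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("landscape must be at least 10x10")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    lat = np.linspace(0.5, -0.5, n_rows)[:, None] * np.ones((1, n_cols))

    layers = {}
    layers["temperature"] = 20.0 + gradient_strength * lat + 1.5 * _grf(shape, autocorr_range_km, rng)
    # bimodal precipitation: soft threshold of a long-range field
    wetdry = _grf(shape, 3 * autocorr_range_km, rng)
    layers["precipitation"] = (600.0 + 900.0 / (1.0 + np.exp(-wetdry / 0.3))
                               + 60.0 * _grf(shape, autocorr_range_km, rng))
    for k in range(2, n_layers):
        mix = lat * gradient_strength / 15.0
        layers[f"env{k + 1}"] = mix + _grf(shape, autocorr_range_km, rng)
    t = GridTransform(x0=0.0, y0=float(n_rows), cell_size=1.0)
    return ClimateStack(layers=layers, transform=t, crs_tag="synthetic-planar-km")


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_tips`` extant tips, rescaled to
    height 1.  Tip labels are ``sp001, sp002, ...``."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    # exact Yule process: exponential waiting times, uniform lineage splits;
    # a final waiting interval keeps every pendant edge strictly positive
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            node.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in tree.preorder_node_iter():
        if node.child_nodes():
            node.end_time = node.child_nodes()[0].birth_time
        else:
            node.end_time = t
        node.edge.length = node.end_time - node.birth_time
    first_split = tree.seed_node.end_time
    tree.seed_node.edge.length = None  # no root stem
    height = t - first_split
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= height
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = taxa.new_taxon(label=f"sp{i + 1:03d}")
    tree.is_rooted = True
    return tree


def simulate_ou_on_tree(tree: dendropy.Tree, alpha: float, sigma2: float,
                        theta: float, z0: float, seed: int) -> dict[str, float]:
    """Exact per-branch OU simulation (alpha = 0 reduces to BM).

    Transition along a branch of length t:
    ``z_child ~ N(z_parent e^{-alpha t} + theta (1 - e^{-alpha t}),
    sigma2 (1 - e^{-2 alpha t}) / (2 alpha))``.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = z0
        else:
            t = node.edge.length or 0.0
            zp = values[id(node.parent_node)]
            if alpha > 0:
                decay = np.exp(-alpha * t)
                mean = zp * decay + theta * (1 - decay)
                var = sigma2 * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)
            else:
                mean, var = zp, sigma2 * t
            values[id(node)] = mean + np.sqrt(max(var, 0.0)) * rng.standard_normal()
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_niche_evolution(tree: dendropy.Tree, root: np.ndarray,
                             ou_params: dict, seed: int,
                             breadth_model: dict | None = None,
                             base_sd: float = 0.6, sd_lognorm_sigma: float = 0.25,
                             radius2: float | None = None) -> dict[str, Ellipsoid]:
    """Evolve tip niche centroids under per-axis OU and draw ellipsoidal
    niches around them.

    ``ou_params`` has keys ``alpha``, ``sigma2`` and optionally ``theta``
    (d-vector; defaults to the root).  Ellipsoid covariances are diagonal
    with log-normal axis standard deviations around ``base_sd``;
    ``breadth_model = {"axis": a, "slope": s, "center": c}`` shifts the log
    *volume* by ``s * (centroid[a] - c)`` (spread evenly over the axes),
    coupling niche breadth to the centroid position along one component
    without making the volume distribution extremely heavy-tailed.
    """
    root = np.asarray(root, dtype=float)
    d = root.size
    alpha = float(ou_params.get("alpha", 0.0))
    sigma2 = float(ou_params.get("sigma2", 1.0))
    theta = np.asarray(ou_params.get("theta", root), dtype=float)
    ss = np.random.SeedSequence(seed)
    axis_seeds = ss.spawn(d + 1)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    cent = np.zeros((len(tips), d))
    for a in range(d):
        s = int(axis_seeds[a].generate_state(1)[0] % (2 ** 31))
        vals = simulate_ou_on_tree(tree, alpha, sigma2, float(theta[a]), float(root[a]), s)
        cent[:, a] = [vals[t] for t in tips]
    rng = np.random.default_rng(axis_seeds[d].generate_state(2))
    r2 = float(radius2) if radius2 is not None else d + 2.0
    niches = {}
    for i, sp in enumerate(tips):
        log_sds = np.log(base_sd) + sd_lognorm_sigma * rng.standard_normal(d)
        if breadth_model:
            shift = breadth_model["slope"] * (cent[i, breadth_model["axis"]]
                                              - breadth_model.get("center", 0.0))
            log_sds = log_sds + shift / d  # log-volume shifts by `shift`
        sds = np.exp(np.clip(log_sds, -2.0, 3.0))
        cov = np.diag(sds ** 2)
        niches[sp] = Ellipsoid(centroid=cent[i], covariance=cov, radius2=r2,
                               species_id=sp)
    return niches


def sample_occurrences(ellipsoid: Ellipsoid, pc_stack: ClimateStack,
                       n_points: int, seed: int,
                       dispersal_km: float | None = None) -> OccurrenceSet:
    """Sample ``n_points`` occurrence records from cells whose environment
    lies inside the species' true ellipsoid (cells drawn with replacement,
    coordinates jittered uniformly within the cell).

    ``dispersal_km`` imposes dispersal-limited occupancy: a range center is
    drawn uniformly among the suitable cells and cells are sampled with
    probability proportional to a Gaussian kernel of that scale around it,
    so the species occupies a cohesive region of its suitable area rather
    than all of it — the situation the accessible-area (hull + buffer)
    constraint of the analysis is designed for.
    """
    mat, flat_idx = pc_stack.values_matrix()
    inside = ellipsoid.contains(mat)
    if not inside.any():
        raise ValueError(f"no suitable cell on the landscape for species "
                         f"{ellipsoid.species_id or '<unnamed>'}")
    cand = flat_idx[inside]
    rng = np.random.default_rng(seed)
    if dispersal_km is None:
        pick = rng.choice(cand, size=n_points, replace=True)
    else:
        ncols_ = pc_stack.shape[1]
        rr, cc = np.divmod(cand, ncols_)
        cx, cy = pc_stack.transform.cell_center(rr, cc)
        center = rng.integers(len(cand))
        d2 = (cx - cx[center]) ** 2 + (cy - cy[center]) ** 2
        wgt = np.exp(-d2 / (2 * dispersal_km ** 2))
        wgt /= wgt.sum()
        pick = rng.choice(cand, size=n_points, replace=True, p=wgt)
    nrows, ncols = pc_stack.shape
    rows, cols = np.divmod(pick, ncols)
    x, y = pc_stack.transform.cell_center(rows, cols)
    cs = pc_stack.transform.cell_size
    x = x + (rng.random(n_points) - 0.5) * cs
    y = y + (rng.random(n_points) - 0.5) * cs
    records, raw = [], []
    for i in range(n_points):
        records.append((float(x[i]), float(y[i]), f"{ellipsoid.species_id}-{i}"))
        raw.append((f"{x[i]:.3f}", f"{y[i]:.3f}"))
    return OccurrenceSet(species_id=ellipsoid.species_id, records=records, raw_coords=raw)


@dataclass
class SyntheticScenario:
    """A complete generated study system with its ground truth."""

    landscape: ClimateStack
    pca: PCAModel
    pc_stack: ClimateStack
    tree: dendropy.Tree
    true_niches: dict[str, Ellipsoid]
    true_root: np.ndarray
    occurrences: list[OccurrenceSet]
    config: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_stack(self.landscape, directory / "landscape")
        self.pca.to_json(directory / "pca.json")
        self.tree.write(path=str(directory / "tree.nwk"), schema="newick",
                        suppress_rooting=True)
        write_occurrences_csv(self.occurrences, directory / "occurrences.csv")
        truth = {
            "true_root": self.true_root.tolist(),
            "niches": {sp: e.to_dict() for sp, e in self.true_niches.items()},
            "config": self.config,
        }
        (directory / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _climate_pole(pc_stack: ClimateStack, landscape: ClimateStack,
                  layer: str = "temperature", top_frac: float = 0.1) -> np.ndarray:
    """Mean component-space position of the warmest ``top_frac`` of cells —
    the scenario's "tropical" climate pole."""
    temp = landscape.layers[layer]
    valid = ~landscape.nodata_mask
    cutoff = np.quantile(temp[valid], 1 - top_frac)
    sel = valid & (temp >= cutoff)
    mat = np.stack([pc_stack.layers[k] for k in pc_stack.layers], axis=-1)
    return mat[sel].mean(axis=0)


def make_scenario(preset: str = "neutral", master_seed: int = 0, *,
                  n_species: int = 24, n_rows: int = 150, n_cols: int = 150,
                  n_layers: int = 3, n_components: int = 3,
                  n_points: int = 60, gradient_strength: float = 15.0,
                  autocorr_range_km: float = 10.0,
                  dispersal_km: float | None = 60.0) -> SyntheticScenario:
    """Generate a full scenario under one of three presets.

    * ``breadth_gradient`` — niche centroids are pulled (OU) toward the warm
      climate pole and niche breadth grows with distance from it, so
      richness peaks where niches are narrow (expected negative
      richness ~ breadth slope, significant against both nulls);
    * ``neutral`` — centroids wander under weak pull and breadth is drawn
      independently of position (expected null-test p > 0.05);
    * ``conserved_position`` — strong OU pull toward the ancestral (root)
      centroid at the warm pole, so high-richness assemblages hold species
      close to the ancestral niche (expected negative richness ~ position
      slope).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    ss = np.random.SeedSequence(master_seed)
    s_land, s_tree, s_niche, s_occ = (int(c.generate_state(1)[0] % (2 ** 31))
                                      for c in ss.spawn(4))
    landscape = make_landscape(n_rows, n_cols, n_layers,
                               gradient_strength, autocorr_range_km, seed=s_land)
    pca = fit_pca(landscape, n_components)
    pc_stack = project_pca(pca, landscape)
    pole = _climate_pole(pc_stack, landscape)
    tree = simulate_tree(n_species, seed=s_tree)

    if preset == "breadth_gradient":
        root = pole
        ou = {"alpha": 2.0, "sigma2": 2.0, "theta": pole}
        axis = int(np.argmax(np.abs(pole)))  # component carrying the gradient
        sign = -np.sign(pole[axis]) if pole[axis] != 0 else 1.0
        breadth = {"axis": axis, "slope": 3.5 * sign, "center": float(pole[axis])}
        sd_sigma = 0.1  # tight coupling: breadth dominated by the gradient
    elif preset == "conserved_position":
        root = pole
        ou = {"alpha": 4.0, "sigma2": 2.0, "theta": pole}
        breadth = None
        sd_sigma = 0.25
    else:  # neutral
        root = np.zeros(n_components)
        ou = {"alpha": 0.5, "sigma2": 1.5, "theta": root}
        breadth = None
        sd_sigma = 0.25

    niches = simulate_niche_evolution(tree, root, ou, seed=s_niche,
                                      breadth_model=breadth,
                                      sd_lognorm_sigma=sd_sigma)
    occ_seeds = np.random.SeedSequence(s_occ).spawn(len(niches))
    occurrences = []
    for (sp, ell), cs in zip(sorted(niches.items()), occ_seeds):
        # species whose centroid falls just outside the realized climate get
        # a proportionally broader tolerance so every tip is sampleable
        for _ in range(12):
            try:
                occ = sample_occurrences(
                    ell, pc_stack, n_points, seed=int(cs.generate_state(1)[0] % (2 ** 31)),
                    dispersal_km=dispersal_km)
                break
            except ValueError:
                ell = Ellipsoid(centroid=ell.centroid, covariance=ell.covariance,
                                radius2=ell.radius2 * 1.6, species_id=sp)
        else:
            raise ValueError(f"species {sp}: niche never intersects the landscape")
        niches[sp] = ell
        occurrences.append(occ)
    config = {
        "preset": preset, "master_seed": master_seed, "n_species": n_species,
        "n_rows": n_rows, "n_cols": n_cols, "n_layers": n_layers,
        "n_components": n_components, "n_points": n_points,
        "gradient_strength": gradient_strength,
        "autocorr_range_km": autocorr_range_km,
        "dispersal_km": dispersal_km,
        "ou_params": {k: (list(v) if isinstance(v, np.ndarray) else v)
                      for k, v in ou.items()},
        "breadth_model": breadth,
    }
    return SyntheticScenario(landscape=landscape, pca=pca, pc_stack=pc_stack,
                             tree=tree, true_niches=niches,
                             true_root=np.asarray(root, dtype=float),
                             occurrences=occurrences, config=config)
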