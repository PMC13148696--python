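"""End-to-end orchestration: cleaning -> PCA -> ellipsoid niche models ->
ranges -> PAM -> niche properties -> trait-evolution models -> SAR selection
-> randomization nulls, from a single seeded configuration.

The pipeline can run either on a named synthetic preset or on user-supplied
files (occurrence CSV, ASCII-grid raster directory, Newick tree, GeoJSON
study area).  One master seed deterministically derives every per-stage and
per-replicate seed, so identical configurations produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblage, ellipsoid as enm, evolution, nulls as nullmod, occurrences as occmod
from . import properties as propmod, spatial, synthetic
from .raster import env_summary, fit_pca, project_pca, polygon_from_geojson, read_stack

logger = logging.getLogger(__name__)

STAGES = ("clean", "pca", "enm", "ranges", "pam", "properties",
          "comparative", "sar", "nulls")


@dataclass
class RunConfig:
    """All pipeline settings; mirrors the numeric design of the analysis."""

    # inputs: either a preset...
    preset: str | None = None
    n_species: int = 24
    n_rows: int = 150
    n_cols: int = 150
    n_points: int = 60
    # ...or files
    occurrences_csv: str | None = None
    raster_dir: str | None = None
    tree_newick: str | None = None
    study_area_geojson: str | None = None
    excluded_layers: tuple = ()
    # layer roles (synthetic defaults; real data: bio5/bio6/bio13/bio14, bio1/bio12)
    temp_max_layer: str = "temperature"
    temp_min_layer: str = "temperature"
    precip_max_layer: str = "precipitation"
    precip_min_layer: str = "precipitation"
    temp_reference_layer: str = "temperature"
    precip_reference_layer: str = "precipitation"
    # analysis parameters
    coverage: float = 0.95
    thin_km: float = 5.0
    buffer_km: float = 25.0
    pam_cell_km: float = 10.0
    n_components: int = 3
    min_records: int = 5
    min_decimals: int = 2
    corr_cutoff: float = 0.7
    n_null_reps: int = 100
    schemes: tuple = ("W_row", "C_global", "S_varstab")
    distance_classes: tuple = ("min", "max")
    null_types: tuple = ("spreading_dye", "property_shuffle")
    null_approaches: tuple = ("multivariate", "univariate_temp", "univariate_precip")
    master_seed: int = 0
    out_dir: str = "run_output"

    def __post_init__(self):
        if not (0.5 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0.5, 1]")
        for name in ("thin_km", "buffer_km", "pam_cell_km", "n_components",
                     "min_records", "corr_cutoff", "n_null_reps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key = value text config; unknown keys are errors."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            f = known[key]
            if f.type in ("int", int):
                kwargs[key] = int(val)
            elif f.type in ("float", float):
                kwargs[key] = float(val)
            elif f.type in ("tuple", tuple):
                kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
            else:
                kwargs[key] = None if val.lower() == "none" else val
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    config: RunConfig
    scenario: synthetic.SyntheticScenario | None
    kept_species: list
    excluded: pd.DataFrame
    ellipsoids: dict
    ranges: list
    pam: assemblage.PAM
    richness: np.ndarray
    prop_table: pd.DataFrame
    model_selection: pd.DataFrame
    reconstructions: dict
    sar_models: dict           # approach/model label -> (SARResults, predictors)
    sar_tables: dict           # label -> weight-selection AIC table
    null_ensembles: dict       # (label, null_type) -> NullEnsemble
    null_pvalues: pd.DataFrame
    warnings: list = field(default_factory=list)

    def table2(self) -> pd.DataFrame:
        """Coefficient table in the Approach / Model / Estimate / p-value
        layout, one row per retained predictor per SAR model."""
        rows = []
        for label, (fit, predictors) in self.sar_models.items():
            approach, model = label
            for name, est, p in zip(fit.exog_names, fit.params, fit.pvalues):
                if name == "const":
                    continue
                rows.append({"Approach": approach, "Model": model,
                             "Predictor": name, "Estimate": est, "p-value": p})
        return pd.DataFrame(rows)


def _stage_seeds(master_seed: int, n: int = 16) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def run_pipeline(config: RunConfig, write_artifacts: bool = True):
    """Execute all stages; returns ``(PipelineResult, manifest_dict)``.

    Artifacts (CSV/JSON/Newick/ASCII-grid) are written under
    ``config.out_dir`` together with ``manifest.json`` recording the config
    echo, per-stage wall times and a SHA-256 hash of every written file.
    """
    t_all = time.perf_counter()
    seeds = _stage_seeds(config.master_seed)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(config).items()},
                "stages": {}, "artifacts": {}, "warnings": []}
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    def tick(stage):
        manifest["stages"][stage] = {"t_start": time.perf_counter() - t_all}

    def tock(stage):
        manifest["stages"][stage]["wall_s"] = (
            time.perf_counter() - t_all - manifest["stages"][stage]["t_start"])

    # ---- inputs -----------------------------------------------------------
    scenario = None
    tree = None
    if config.preset is not None:
        scenario = synthetic.make_scenario(
            config.preset, master_seed=seeds[0], n_species=config.n_species,
            n_rows=config.n_rows, n_cols=config.n_cols,
            n_points=config.n_points, n_components=config.n_components)
        landscape = scenario.landscape
        occ_sets = scenario.occurrences
        tree = scenario.tree
    else:
        if not (config.occurrences_csv and config.raster_dir):
            raise ValueError("either a preset or occurrence/raster inputs are required")
        landscape = read_stack(config.raster_dir)
        if config.excluded_layers:
            from .raster import drop_excluded_layers, mask_to_area
            landscape = drop_excluded_layers(landscape, config.excluded_layers)
        if config.study_area_geojson:
            from .raster import mask_to_area
            landscape = mask_to_area(landscape, polygon_from_geojson(config.study_area_geojson))
        occ_sets = occmod.read_occurrences_csv(config.occurrences_csv)
        if config.tree_newick:
            tree = evolution.read_tree(config.tree_newick)

    # ---- stage 1: clean ---------------------------------------------------
    tick("clean")
    clean_seeds = np.random.SeedSequence(seeds[1]).spawn(len(occ_sets))
    cleaned, excluded_rows = [], []
    for occ, cs in zip(occ_sets, clean_seeds):
        c = occmod.clean_pipeline(occ, landscape, min_decimals=config.min_decimals,
                                  thin_km=config.thin_km,
                                  seed=int(cs.generate_state(1)[0] % (2 ** 31)))
        if occmod.check_min_records(c, config.min_records):
            cleaned.append(c)
        else:
            excluded_rows.append({"species": occ.species_id,
                                  "n_unique": c.n_unique_localities(),
                                  "reason": f"fewer than {config.min_records} unique localities"})
    excluded = pd.DataFrame(excluded_rows, columns=["species", "n_unique", "reason"])
    tock("clean")

    # ---- stage 2: pca -----------------------------------------------------
    tick("pca")
    pca = fit_pca(landscape, config.n_components)
    pc_stack = project_pca(pca, landscape)
    reference = env_summary(landscape, n_components=config.n_components)
    tock("pca")

    # ---- stage 3-4: enm + ranges -----------------------------------------
    tick("enm")
    enm_seeds = np.random.SeedSequence(seeds[2]).spawn(len(cleaned))
    ellipsoids, kept, extremes = {}, [], {}
    for occ, es in zip(cleaned, enm_seeds):
        try:
            env_pc = occmod.extract_env(occ, pc_stack)
            ell = enm.fit_mve(env_pc, coverage=config.coverage,
                              seed=int(es.generate_state(1)[0] % (2 ** 31)),
                              species_id=occ.species_id)
        except ValueError as err:
            warnings_log.append(f"{occ.species_id}: ENM skipped ({err})")
            continue
        env_raw = occmod.extract_env(occ, landscape)
        extremes[occ.species_id] = propmod.compute_extremes(
            env_raw, landscape.layer_names,
            temp_max_layer=config.temp_max_layer, temp_min_layer=config.temp_min_layer,
            precip_max_layer=config.precip_max_layer, precip_min_layer=config.precip_min_layer)
        ellipsoids[occ.species_id] = ell
        kept.append(occ)
    if not ellipsoids:
        raise RuntimeError("stage enm: no species could be modelled")
    tock("enm")

    tick("ranges")
    ranges = []
    for occ in kept:
        pres = enm.predict_presence(ellipsoids[occ.species_id], pc_stack)
        constraint = enm.mcp_buffer(occ, config.buffer_km)
        ranges.append(enm.constrain_range(pres, constraint, pc_stack,
                                          species_id=occ.species_id))
    tock("ranges")

    # ---- stage 5: pam -----------------------------------------------------
    tick("pam")
    pam = assemblage.build_pam(ranges, landscape, grid_res_km=config.pam_cell_km)
    rich = assemblage.richness(pam)
    tock("pam")

    # ---- stage 6-7: properties + comparative ------------------------------
    tick("comparative")
    positions, model_rows, recons = {}, [], {}
    if tree is not None:
        modeled = set(ellipsoids)
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        overlap = modeled & tips
        if overlap:
            sub = evolution.prune_to_species(tree, overlap)
            mv_traits = {f"pc{j + 1}": {sp: float(ellipsoids[sp].centroid[j])
                                        for sp in overlap}
                         for j in range(config.n_components)}
            uni_traits = {
                "t_centroid": {sp: propmod.univariate_centroid(extremes[sp])[0]
                               for sp in overlap},
                "p_centroid": {sp: propmod.univariate_centroid(extremes[sp])[1]
                               for sp in overlap},
            }
            anc = {}
            for trait_name, vals in {**mv_traits, **uni_traits}.items():
                model = evolution.TraitEvolutionModel(sub, vals)
                fits = model.fit_all()
                best, weights = evolution.select_model(fits)
                rec = evolution.reconstruct_root(best)
                anc[trait_name] = rec
                recons[trait_name] = rec
                for f in fits:
                    model_rows.append({
                        "trait": trait_name, "model": f.model, "logLik": f.loglik,
                        "AIC": f.aic, "AIC_weight": weights[f.model],
                        "selected": f.model == best.model,
                        **{f"param_{k}": v for k, v in f.params.items()},
                    })
            anc_mv = np.array([anc[f"pc{j + 1}"].ancestral_value
                               for j in range(config.n_components)])
            for sp in overlap:
                np_dist = evolution.phylo_position(
                    ellipsoids[sp].centroid, anc_mv, metric="mahalanobis",
                    ellipsoid=ellipsoids[sp])
                cent = propmod.univariate_centroid(extremes[sp])
                positions[sp] = {
                    "NP": np_dist,
                    "TP": abs(cent[0] - anc["t_centroid"].ancestral_value),
                    "PP": abs(cent[1] - anc["p_centroid"].ancestral_value),
                }
        missing_from_tree = modeled - tips
        if missing_from_tree:
            warnings_log.append(
                f"{len(missing_from_tree)} modelled species absent from the tree; "
                "positions left missing")
    else:
        warnings_log.append("no tree supplied: position properties skipped")
    model_selection = pd.DataFrame(model_rows)
    tock("comparative")

    tick("properties")
    prop_table = propmod.assemble_property_table(
        ellipsoids, extremes, reference,
        temp_reference_layer=config.temp_reference_layer,
        precip_reference_layer=config.precip_reference_layer,
        positions=positions)
    tock("properties")

    # ---- stage 8: sar -----------------------------------------------------
    tick("sar")
    approaches = {"multivariate": ["NB", "NM", "NP"],
                  "univariate_temp": ["TB", "TM", "TP"],
                  "univariate_precip": ["PB", "PM", "PP"]}
    sar_models, sar_tables = {}, {}
    for approach, preds in approaches.items():
        preds = [p for p in preds if prop_table[p].notna().any()]
        if not preds:
            continue
        y, X, cent = nullmod.assemblage_design(pam, prop_table, preds)
        if len(y) < len(preds) + 3:
            warnings_log.append(f"{approach}: too few cells for SAR; skipped")
            continue
        groups = spatial.screen_predictors(
            pd.DataFrame(X, columns=preds), cutoff=config.corr_cutoff)
        for gi, group in enumerate(groups):
            yg, Xg, centg = nullmod.assemblage_design(pam, prop_table, group)
            candidates = [spatial.build_weights(centg, scheme=s, distance_class=dc)
                          for s in config.schemes for dc in config.distance_classes]
            best, table = spatial.select_sar(yg, Xg, candidates, exog_names=group)
            label = (approach, "Richness ~ " + " + ".join(group))
            sar_models[label] = (best, group)
            sar_tables[label] = table
    tock("sar")

    # ---- stage 9: nulls ---------------------------------------------------
    tick("nulls")
    null_seeds = np.random.SeedSequence(seeds[3]).spawn(
        max(1, len(sar_models) * len(config.null_types)))
    ensembles, prows = {}, []
    si = 0
    for label, (fit, preds) in sar_models.items():
        if label[0] not in config.null_approaches:
            continue
        for ntype in config.null_types:
            ens = nullmod.null_slope_distribution(
                pam, prop_table, preds, ntype, n_reps=config.n_null_reps,
                scheme=fit.weights.scheme, distance_class=fit.weights.distance_class,
                master_seed=int(null_seeds[si].generate_state(1)[0] % (2 ** 31)))
            si += 1
            ensembles[(label, ntype)] = ens
            for pred, slope in zip(fit.exog_names[1:], fit.params[1:]):
                prows.append({
                    "Approach": label[0], "Model": label[1], "Predictor": pred,
                    "null_type": ntype, "observed_slope": slope,
                    "p": nullmod.null_slope_test(slope, ens, pred),
                })
    null_pvalues = pd.DataFrame(prows)
    tock("nulls")

    result = PipelineResult(
        config=config, scenario=scenario, kept_species=[o.species_id for o in kept],
        excluded=excluded, ellipsoids=ellipsoids, ranges=ranges, pam=pam,
        richness=rich, prop_table=prop_table, model_selection=model_selection,
        reconstructions=recons, sar_models=sar_models, sar_tables=sar_tables,
        null_ensembles=ensembles, null_pvalues=null_pvalues, warnings=warnings_log)
    manifest["warnings"] = warnings_log
    manifest["n_stages"] = len(STAGES)
    manifest["n_species_modeled"] = len(ellipsoids)

    if write_artifacts:
        _write_artifacts(result, out, manifest)
    return result, manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_artifacts(result: PipelineResult, out: Path, manifest: dict) -> None:
    paths = []
    result.excluded.to_csv(out / "excluded_species.csv", index=False)
    paths.append(out / "excluded_species.csv")
    result.pam.to_csv(out / "pam.csv")
    paths.append(out / "pam.csv")
    rich_df = pd.DataFrame({
        "cell_row": [r for r, _ in result.pam.cell_ids],
        "cell_col": [c for _, c in result.pam.cell_ids],
        "x": result.pam.cell_centroids[:, 0], "y": result.pam.cell_centroids[:, 1],
        "richness": result.richness})
    rich_df.to_csv(out / "richness.csv", index=False)
    paths.append(out / "richness.csv")
    result.prop_table.to_csv(out / "niche_properties.csv")
    paths.append(out / "niche_properties.csv")
    if len(result.model_selection):
        result.model_selection.to_csv(out / "evo_model_selection.csv", index=False)
        paths.append(out / "evo_model_selection.csv")
    ell = {sp: e.to_dict() for sp, e in result.ellipsoids.items()}
    (out / "ellipsoids.json").write_text(json.dumps(ell, indent=1, sort_keys=True))
    paths.append(out / "ellipsoids.json")
    result.table2().to_csv(out / "sar_coefficients.csv", index=False)
    paths.append(out / "sar_coefficients.csv")
    if len(result.null_pvalues):
        result.null_pvalues.to_csv(out / "null_tests.csv", index=False)
        paths.append(out / "null_tests.csv")
    for p in paths:
        manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Summary tables and figures: Table-2-style coefficients, per-property
    maps, and null-slope histograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    t2 = result.table2()
    t2.to_csv(out / "table_sar.csv", index=False)
    written.append(out / "table_sar.csv")

    rows = np.array([r for r, _ in result.pam.cell_ids])
    cols = np.array([c for _, c in result.pam.cell_ids])
    shape = (rows.max() + 1, cols.max() + 1)

    def cell_image(values):
        img = np.full(shape, np.nan)
        img[rows, cols] = values
        return img

    panels = {"richness": result.richness.astype(float)}
    for prop in ("NB", "NM", "NP", "TB", "TM", "TP", "PB", "PM", "PP"):
        if prop in result.prop_table and result.prop_table[prop].notna().any():
            panels[prop] = assemblage.map_property(
                result.pam, result.prop_table[prop].to_dict())
    fig, axes = plt.subplots(2, (len(panels) + 1) // 2,
                             figsize=(3 * ((len(panels) + 1) // 2), 6))
    for ax, (name, vals) in zip(np.ravel(axes), panels.items()):
        im = ax.imshow(cell_image(vals), origin="upper")
        ax.set_title(name)
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.7)
    for ax in np.ravel(axes)[len(panels):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "property_maps.png", dpi=120)
    plt.close(fig)
    written.append(out / "property_maps.png")

    if result.null_ensembles:
        n = len(result.null_ensembles)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
        for ax, ((label, ntype), ens) in zip(axes[0], result.null_ensembles.items()):
            pred = ens.slopes.columns[0]
            ax.hist(ens.slopes[pred].dropna(), bins=20, color="0.7")
            fit, _ = result.sar_models[label]
            obs = fit.params[fit.exog_names.index(pred)]
            ax.axvline(obs, color="crimson")
            ax.set_title(f"{ntype}\n{pred}", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "null_slopes.png", dpi=120)
        plt.close(fig)
        written.append(out / "null_slopes.png")
    return written
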