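"""End-to-end pipeline: occurrences + climate stack -> niche and range dynamics.

``run_pipeline`` composes the library stages in order — rarefaction, range
split, predictor extraction, collinearity pruning, PCA, per-range KDE niches,
COUE partition and conservatism test, per-range ensemble SDMs, MSS
binarization, spherical areas/spans, and Mapcurves concordance — and emits a
JSON-serializable report in which every value is traceable to one module's
output. All randomness flows from explicit seeds in the configuration, so a
fixed config reproduces a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import niche as nd
from . import ranges as rd
from . import sdm
from .envspace import (PredictorMatrix, compare_predictor_means, extract_predictors,
                       fit_pca, project, prune_collinear, variable_importance)
from .grids import ClimateStack
from .learners import fit_suitability_model
from .occurrences import OccurrenceTable, rarefy, read_occurrences, split_by_region
from .synthetic import (VirtualSpeciesSpec, Window, generate_climate_stack,
                        generate_virtual_occurrences)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; see ``from_dict`` for the YAML layout."""

    seed: int = 0
    simulate: dict | None = None          # synthetic-data block, or None
    occurrences: str | None = None        # CSV path (when not simulating)
    rasters: str | None = None            # directory of .asc layers
    native_polygon: str | None = None     # GeoJSON path, optional
    dialect: dict = field(default_factory=dict)
    radius_km: float = 10.0
    r_threshold: float = 0.70
    grid_resolution: int = 200
    bandwidth_rule: str = "silverman"
    mass_quantile: float = 0.95
    learners: list[str] = field(default_factory=lambda: ["logit", "envelope"])
    n_pa: int | None = None
    n_pa_sets: int = 2
    train_fraction: float = 0.7
    repeats: int = 4
    tss_retain: float = 0.7
    auc_retain: float = 0.8
    n_background: int = 2000

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must lie in (0, 1]")
        if not (0 < self.mass_quantile <= 1):
            raise ValueError("mass_quantile must lie in (0, 1]")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repeats < 1 or self.n_pa_sets < 1:
            raise ValueError("repeats and n_pa_sets must be >= 1")
        if self.simulate is None and (self.occurrences is None or self.rasters is None):
            raise ValueError("provide either a simulate block or occurrence/raster paths")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        kw: dict[str, Any] = {"seed": cfg.get("seed", 0)}
        if "simulate" in cfg:
            kw["simulate"] = cfg["simulate"]
        inputs = cfg.get("inputs", {})
        kw["occurrences"] = inputs.get("occurrences")
        kw["rasters"] = inputs.get("rasters")
        kw["native_polygon"] = inputs.get("native_polygon")
        kw["dialect"] = inputs.get("dialect", {})
        kw["radius_km"] = cfg.get("rarefaction", {}).get("radius_km", 10.0)
        kw["r_threshold"] = cfg.get("collinearity", {}).get("r_threshold", 0.70)
        niche_cfg = cfg.get("niche", {})
        kw["grid_resolution"] = niche_cfg.get("grid_resolution", 200)
        kw["bandwidth_rule"] = niche_cfg.get("bandwidth_rule", "silverman")
        kw["mass_quantile"] = niche_cfg.get("mass_quantile", 0.95)
        sdm_cfg = cfg.get("sdm", {})
        kw["learners"] = sdm_cfg.get("learners", ["logit", "envelope"])
        kw["n_pa"] = sdm_cfg.get("n_pa")
        kw["n_pa_sets"] = sdm_cfg.get("n_pa_sets", 2)
        kw["train_fraction"] = sdm_cfg.get("train_fraction", 0.7)
        kw["repeats"] = sdm_cfg.get("repeats", 4)
        kw["tss_retain"] = sdm_cfg.get("tss_retain", 0.7)
        kw["auc_retain"] = sdm_cfg.get("auc_retain", 0.8)
        kw["n_background"] = cfg.get("background", {}).get("n_cells", 2000)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _window_from(cfg: dict | None) -> Window:
    cfg = cfg or {}
    inf = float("inf")
    return Window(cfg.get("xmin", -inf), cfg.get("xmax", inf),
                  cfg.get("ymin", -inf), cfg.get("ymax", inf))


def _simulate(cfg: PipelineConfig):
    s = dict(cfg.simulate or {})
    stack = generate_climate_stack(
        seed=s.get("seed", cfg.seed),
        nrows=s.get("nrows", 96), ncols=s.get("ncols", 96),
        n_layers=s.get("n_layers", 6),
        collinear_groups=s.get("collinear_groups", [[1, 2]]),
    )
    spec = VirtualSpeciesSpec(
        niche_center=np.asarray(s.get("niche_center", [0.0, 0.0]), float),
        niche_cov=np.asarray(s.get("niche_cov", [[0.25, 0.0], [0.0, 0.25]]), float),
        native_window=_window_from(s.get("native_window")),
        introduced_window=_window_from(s.get("introduced_window")),
        n_native=s.get("n_native", 400),
        n_introduced=s.get("n_introduced", 800),
        seed=s.get("occurrence_seed", cfg.seed + 1),
    )
    table, truth = generate_virtual_occurrences(spec, stack)
    return stack, table, truth


def _provenance_hash(cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    for p in (cfg.occurrences, cfg.rasters, cfg.native_polygon):
        if p is None:
            continue
        path = Path(p)
        files = sorted(path.rglob("*")) if path.is_dir() else [path]
        for f in files:
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    if cfg.simulate is not None:
        h.update(json.dumps(cfg.simulate, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _read_polygon(path: str | Path):
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]
    if gj.get("type") == "Feature":
        gj = gj["geometry"]
    return shape(gj)


def _sample_background(stack: ClimateStack, n: int, seed: int) -> PredictorMatrix:
    rows, cols = np.nonzero(stack.valid_mask)
    rng = np.random.default_rng(seed)
    k = min(n, rows.size)
    pick = rng.choice(rows.size, size=k, replace=False)
    return PredictorMatrix(stack.values_at_cells(rows[pick], cols[pick]), list(stack.names))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def _sdm_for_range(cfg: PipelineConfig, stack: ClimateStack, table: OccurrenceTable,
                   matrix: PredictorMatrix, label: str, seed: int) -> dict:
    """Fit, evaluate and ensemble the learners for one range; binarize at MSS."""
    pa_sets = sdm.generate_pseudo_absences(stack, table, n_pa=cfg.n_pa,
                                           n_sets=cfg.n_pa_sets, seed=seed)
    pa_matrices = []
    for pa in pa_sets:
        rows, cols = stack.geometry.cell_of(pa.points[:, 0], pa.points[:, 1])
        pa_matrices.append(PredictorMatrix(stack.values_at_cells(rows, cols),
                                           list(stack.names)))
    evals: list[sdm.ModelEval] = []
    eval_rows = []
    learner_stats: dict[str, dict] = {}
    for learner in cfg.learners:
        pooled: list[sdm.ModelEval] = []
        for k, pa_m in enumerate(pa_matrices):
            ev = sdm.evaluate_split(learner, matrix, pa_m,
                                    train_fraction=cfg.train_fraction,
                                    repeats=cfg.repeats, seed=seed + 17 * k + 1,
                                    layer_names=matrix.layer_names)
            pooled.extend(ev)
        mean_tss = float(np.mean([e.tss for e in pooled]))
        mean_auc = float(np.mean([e.auc for e in pooled]))
        mean_kappa = float(np.mean([e.kappa for e in pooled]))
        retained = (mean_tss > cfg.tss_retain) or (mean_auc > cfg.auc_retain)
        learner_stats[learner] = {"mean_tss": mean_tss, "mean_auc": mean_auc,
                                  "mean_kappa": mean_kappa, "retained": retained}
        evals.extend(pooled)
        eval_rows += [{"model_id": e.model_id, "pa_set": i // cfg.repeats,
                       "repeat_id": e.repeat_id, "auc": e.auc, "tss": e.tss,
                       "kappa": e.kappa, "retained": e.retained}
                      for i, e in enumerate(pooled)]
    models, weights = [], []
    for learner, st in learner_stats.items():
        if not st["retained"] or st["mean_tss"] <= 0:
            continue
        for pa_m in pa_matrices:
            models.append(fit_suitability_model(learner, matrix.values, pa_m.values,
                                                matrix.layer_names))
            weights.append(st["mean_tss"])
    if not models:
        raise ValueError(f"no model retained for the {label} range ensemble")
    smap = sdm.ensemble_predict(models, np.asarray(weights), stack)

    # MSS threshold on the pooled evaluation data: ensemble scores at
    # presences and at all PA points
    rows, cols = stack.geometry.cell_of(table.lon, table.lat)
    on = rows >= 0
    pres_scores = smap.values[rows[on], cols[on]]
    pa_scores = np.concatenate([
        smap.values[stack.geometry.cell_of(pa.points[:, 0], pa.points[:, 1])[0],
                    stack.geometry.cell_of(pa.points[:, 0], pa.points[:, 1])[1]]
        for pa in pa_sets])
    scores = np.concatenate([pres_scores, pa_scores])
    labels = np.concatenate([np.ones(pres_scores.size, bool), np.zeros(pa_scores.size, bool)])
    keep = np.isfinite(scores)
    threshold = sdm.mss_threshold(scores[keep], labels[keep])
    brange = rd.binarize(smap, threshold)
    return {
        "label": label,
        "evaluations": eval_rows,
        "learner_stats": learner_stats,
        "mss_threshold": threshold,
        "area_km2": brange.area_km2,
        "lat_span_deg": brange.lat_span_deg,
        "lon_span_deg": brange.lon_span_deg,
        "_map": smap,
        "_range": brange,
    }


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config
    report: dict[str, Any] = {"config": _config_echo(cfg),
                              "provenance_sha256": _provenance_hash(cfg)}

    # --- inputs ------------------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        stack, table, truth = _stage("simulate")(_simulate)(cfg)
        report["synthetic_truth"] = {"expected_E_fraction": truth.expected_E_fraction,
                                     "expected_U_fraction": truth.expected_U_fraction}
    else:
        def _load():
            return (ClimateStack.read_dir(cfg.rasters),
                    read_occurrences(cfg.occurrences, cfg.dialect))
        stack, table = _stage("load")(_load)()

    # --- rarefy ------------------------------------------------------------
    table = _stage("rarefy")(rarefy)(table, cfg.radius_km)
    report["n_rarefied"] = len(table)

    # --- split -------------------------------------------------------------
    def _split():
        if cfg.native_polygon is not None:
            nat, intro = split_by_region(table, _read_polygon(cfg.native_polygon))
        else:
            nat = table.subset_label("native")
            intro = table.subset_label("introduced")
        if len(nat) == 0 or len(intro) == 0:
            raise ValueError("both native and introduced records are required")
        return nat, intro
    native_tab, intro_tab = _stage("split")(_split)()
    report["n_native"] = len(native_tab)
    report["n_introduced"] = len(intro_tab)

    # --- extract + prune ---------------------------------------------------
    pooled_tab = OccurrenceTable(
        pd.concat([native_tab.df, intro_tab.df], ignore_index=True)
        .assign(id=lambda d: range(len(d))))
    matrix = _stage("extract")(extract_predictors)(stack, pooled_tab)

    def _prune():
        background = _sample_background(stack, cfg.n_background, cfg.seed + 101)
        imp = variable_importance(matrix, background, seed=cfg.seed + 202)
        retained = prune_collinear(matrix, imp, cfg.r_threshold)
        return retained, dict(zip(matrix.layer_names, imp.tolist()))
    retained, importances = _stage("prune")(_prune)()
    report["importances"] = importances
    report["retained_predictors"] = retained
    matrix_r = matrix.subset_columns(retained)
    stack_r = stack.subset(retained)

    # --- pca ---------------------------------------------------------------
    space = _stage("pca")(fit_pca)(matrix_r)
    report["pca"] = {"explained_fraction": space.explained_fraction.tolist(),
                     "loadings": {n: space.loadings[i].tolist()
                                  for i, n in enumerate(retained)}}

    # --- niche (per range) + coue -------------------------------------------
    def _niche():
        nat_scores = project(space, matrix_r.subset_label("native"))
        int_scores = project(space, matrix_r.subset_label("introduced"))
        edges = nd.shared_grid_edges([nat_scores, int_scores], cfg.grid_resolution)
        grids = {}
        for key, scores in (("native", nat_scores), ("introduced", int_scores)):
            g = nd.estimate_density(scores, cfg.grid_resolution, cfg.bandwidth_rule,
                                    edges=edges)
            grids[key] = nd.occupancy_mask(g, cfg.mass_quantile)
        return grids, nat_scores, int_scores
    grids, nat_scores, int_scores = _stage("niche")(_niche)()
    coue = _stage("coue")(nd.coue_partition)(grids["native"], grids["introduced"])
    report["coue"] = coue.to_dict()

    # --- t-tests on the PC-defining predictors -------------------------------
    def _ttests():
        out = {}
        for axis in range(2):
            name = retained[int(np.argmax(np.abs(space.loadings[:, axis])))]
            col = matrix_r.layer_names.index(name)
            nat_v = matrix_r.subset_label("native").values[:, col]
            int_v = matrix_r.subset_label("introduced").values[:, col]
            t, p, m_n, m_i = compare_predictor_means(nat_v, int_v)
            out[f"pc{axis + 1}"] = {"predictor": name, "t": t, "p": p,
                                    "mean_native": m_n, "mean_introduced": m_i}
        return out
    report["predictor_mean_tests"] = _stage("ttest")(_ttests)()

    # --- sdm + binarize (per range) ------------------------------------------
    sdm_out = {}
    for label, tab in (("native", native_tab), ("introduced", intro_tab)):
        sdm_out[label] = _stage(f"sdm_{label}")(_sdm_for_range)(
            cfg, stack_r, tab, matrix_r.subset_label(label), label,
            seed=cfg.seed + (303 if label == "native" else 404))
    report["sdm"] = {k: {kk: vv for kk, vv in v.items() if not kk.startswith("_")}
                     for k, v in sdm_out.items()}

    # --- gof ------------------------------------------------------------------
    def _gof():
        nat_r, int_r = sdm_out["native"]["_range"], sdm_out["introduced"]["_range"]
        valid = stack_r.valid_mask
        pot = rd.mapcurve_gof(nat_r, int_r)
        inv_n = rd.BinaryRange(nat_r.geometry, valid & ~nat_r.mask, nat_r.mss_threshold_used)
        inv_i = rd.BinaryRange(int_r.geometry, valid & ~int_r.mask, int_r.mss_threshold_used)
        nonpot = rd.mapcurve_gof(inv_n, inv_i)
        return {"potential": pot.gof, "non_potential": nonpot.gof}
    report["gof"] = _stage("gof")(_gof)()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
        for label in ("native", "introduced"):
            from .grids import write_ascii_grid
            write_ascii_grid(out_dir / f"suitability_{label}.asc",
                             sdm_out[label]["_map"].values, stack_r.geometry)
            write_ascii_grid(out_dir / f"range_{label}.asc",
                             sdm_out[label]["_range"].mask.astype(float), stack_r.geometry)
    return report


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = {k: v for k, v in cfg.__dict__.items()}
    return json.loads(json.dumps(echo, sort_keys=True, default=str))
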