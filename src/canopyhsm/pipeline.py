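"""End-to-end orchestration: simulate -> detect -> covariates -> sample ->
fit -> classify -> delineate -> evaluate, with per-stage artifacts, one
root seed, and a manifest of output files and hashes."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box

from . import covariates as cov
from . import evaluation as ev
from . import pe_classification as pe
from . import sampling
from . import synthetic_forest as sf
from . import tao_detect as tao
from .maxent import FeatureSpec, FitConfig, bootstrap_fit, fit_maxent, gain
from .patches import delineate_patches, summarize_patches
from .raster import Raster

log = logging.getLogger("canopyhsm")


@dataclass
class RunConfig:
    """Every stage parameter in one place; serialized with each run."""

    out_dir: str = "hsm_run"
    seed: int = 0
    # scenario
    landscape_size_m: float = 2500.0
    n_patches: int = 4
    patch_size_range: tuple[float, float] = (300.0, 450.0)
    dsm_resolution: float = 1.0
    # detection
    tao_window_radius: float = 2.0
    tao_min_height: float = 0.0
    # covariates
    grid_cell_size: float = 5.0
    # sampling
    ha_per_point: float = 2.02
    n_points: int | None = None
    exclusion_m: float = 20.0
    # model
    rm: float = 2.0
    replicates: int = 10
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge")
    hinge_knots: int = 10
    # classification
    pe_width: float = 0.02
    pe_step: float = 0.002
    pe_start: float = 0.02
    n_breakpoints: int = 3
    # delineation
    min_class: int = 2              # "low" or better
    buffer_m: float = 80.25
    concavity: float = 0.8
    smooth_out_m: float = 60.0
    smooth_in_m: float = 55.0

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload.pop("out_dir")  # environment, not a run parameter
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    config: RunConfig
    manifest: dict
    metrics: dict
    model: object
    classes: pe.HabitatClasses
    patch_set: object
    sample: sampling.LabeledSample
    hsi_raster: Raster
    class_raster: Raster
    scenario: sf.ForestScenario
    stem_map: sf.StemMap
    taos: tao.TAOSet


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages on a synthetic scenario, writing artifacts.

    Stage seeds derive from the root seed via SeedSequence spawning, so a
    rerun with the same config is bit-identical and a different seed
    changes every random draw while the config echo stays the same.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    files: list[Path] = []

    # 1 -- simulate
    log.info("simulate: size=%.0f m, %d patches, seed=%d",
             config.landscape_size_m, config.n_patches, stage_seed[0])
    scenario = sf.demo_scenario(seed=stage_seed[0],
                                size_m=config.landscape_size_m,
                                n_patches=config.n_patches,
                                patch_size_range=tuple(config.patch_size_range))
    stem_map = sf.generate_stem_map(scenario)
    dsm = sf.render_dsm(stem_map, scenario.extent, config.dsm_resolution,
                        scenario.crown_radius_coeff)
    used_polys = sf.used_polygons_from_scenario(scenario)
    stem_map.to_csv(out / "stems.csv")
    dsm.write_ascii(out / "dsm.asc")
    sf.write_polygons_geojson(used_polys, out / "used.geojson")
    files += [out / "stems.csv", out / "dsm.asc", out / "used.geojson"]

    # 2 -- detect TAOs
    log.info("taos: window=%.1f m, min_height=%.1f m",
             config.tao_window_radius, config.tao_min_height)
    taos = tao.extract_taos(dsm, config.tao_window_radius, config.tao_min_height)
    taos.to_csv(out / "taos.csv")
    files.append(out / "taos.csv")

    # 3 -- covariates (final-model trio preset)
    grid = cov.GridSpec.from_raster(dsm, config.grid_cell_size)
    stack = cov.final_model_stack(taos, grid)
    stack.write(out / "covariates")
    files += sorted((out / "covariates").glob("*"))

    # 4 -- balanced sample + labels + design
    region = box(*scenario.extent)
    n = config.n_points or sampling.target_n_for_density(
        region.area / 10_000.0, config.ha_per_point)
    log.info("sample: n=%d (%.2f ha/pt), exclusion=%.0f m",
             n, config.ha_per_point, config.exclusion_m)
    points = sampling.bas_points(region, n, seed=stage_seed[1])
    sample = sampling.label_samples(points, used_polys, config.exclusion_m)
    used_X, avail_X = sampling.extract_design(sample, stack)
    sample.to_csv(out / "sample.csv")
    with open(out / "design.json", "w") as fh:
        json.dump(sample.design, fh, indent=2)
    files += [out / "sample.csv", out / "design.json"]

    # 5 -- fit
    fit_cfg = FitConfig(rm=config.rm, replicates=config.replicates,
                        seed=stage_seed[2])
    spec = FeatureSpec(classes=tuple(config.feature_classes),
                       hinge_knots=config.hinge_knots)
    names = stack.names
    log.info("fit: RM=%.1f, %d replicates, features=%s",
             config.rm, config.replicates, config.feature_classes)
    model = fit_maxent(used_X, avail_X, names, fit_cfg, spec)
    boots = bootstrap_fit(used_X, avail_X, names, fit_cfg, spec)
    model.to_json(out / "model.json")
    files.append(out / "model.json")

    # 6 -- classify
    used_hsi = model.predict_logistic(used_X)
    avail_hsi = model.predict_logistic(avail_X)
    curve = pe.pe_curve(used_hsi, avail_hsi, config.pe_width, config.pe_step,
                        config.pe_start)
    curve = pe.smooth_pe(curve)
    forced = pe.forced_unsuitable_break(curve)
    bfit = pe.fit_breakpoints(curve, config.n_breakpoints, forced)
    cell_xy = grid.cell_centers()
    hsi_cells = model.predict_logistic(stack.values_at(cell_xy))
    top = float(max(curve.centers[-1], hsi_cells.max()))
    classes = pe.build_classes(forced, bfit, max_hsi=top)
    hsi_raster = Raster(hsi_cells.reshape(grid.n_rows, grid.n_cols),
                        grid.x_min, grid.y_min, grid.cell_size, grid.crs)
    class_raster = pe.classify_grid(hsi_raster, classes)
    curve.to_csv(out / "pe_curve.csv")
    classes.to_json(out / "classes.json")
    hsi_raster.write_ascii(out / "hsi.asc")
    class_raster.write_ascii(out / "classes.asc")
    files += [out / "pe_curve.csv", out / "classes.json", out / "hsi.asc",
              out / "classes.asc"]

    # 7 -- delineate
    min_class = min(config.min_class, classes.n_classes - 1)
    log.info("delineate: min_class=%d, buffer=%.2f m, concavity=%.1f, "
             "smooth=%.0f/%.0f m", min_class, config.buffer_m,
             config.concavity, config.smooth_out_m, config.smooth_in_m)
    polys, groups = delineate_patches(
        class_raster, taos, min_class, config.buffer_m,
        concavity=config.concavity,
        smooth_out=config.smooth_out_m, smooth_in=config.smooth_in_m)
    patch_set = summarize_patches(
        polys, groups, hsi_raster, class_raster, used_polys,
        provenance={"min_class": min_class, "buffer_m": config.buffer_m,
                    "concavity": config.concavity,
                    "smooth_m": [config.smooth_out_m, config.smooth_in_m]})
    patch_set.to_geojson(out / "patches.geojson")
    files.append(out / "patches.geojson")

    # 8 -- evaluate at the low-class threshold
    threshold = classes.boundaries[min_class - 1]
    neg_hsi = avail_hsi[~sample.used]
    cm = ev.confusion(used_hsi, neg_hsi, threshold)
    metrics = {
        "auc": ev.auc(used_hsi, neg_hsi),
        "sensitivity": ev.sensitivity(cm),
        "ppv": ev.ppv(cm),
        "kappa": ev.kappa(cm),
        "threshold": threshold,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "train_gain": gain(model, used_X),
        "median_test_auc": boots.median_test_auc,
        "n_used": sample.n_used,
        "n_available": sample.n,
        "n_patches": len(patch_set),
        "class_boundaries": list(classes.boundaries),
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    files.append(out / "metrics.json")

    config.to_json(out / "config.json")
    files.append(out / "config.json")
    manifest = {"files": {str(f.relative_to(out)): _sha256(f) for f in files},
                "seed": config.seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(config, manifest, metrics, model, classes, patch_set,
                     sample, hsi_raster, class_raster, scenario, stem_map, taos)
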