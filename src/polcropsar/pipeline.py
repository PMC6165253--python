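"""End-to-end pipeline: features -> integrate -> train -> classify -> assess.

Pure function of (inputs, config, seed): every artifact embeds the config
hash, and a rerun with the same config and seed reproduces the report
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as pio
from .assess import AccuracyReport, confusion, metrics
from .classify import (
    ClassMap,
    NODATA,
    SVMModel,
    TrainingSet,
    svm_predict,
    svm_train,
    wishart_classify,
    wishart_train,
)
from .integration import FeatureStack, INTEGRATION_MODES, assemble, sigma_pca
from .optical import OpticalBands, TextureConfig, band_pca, entropy_texture, ndvi
from .polsar import C3Field, c3_to_intensity, intensity_to_db, rvi, yamaguchi4
from .simulate import SimConfig, default_config, generate_scene

log = logging.getLogger(__name__)

__all__ = [
    "extract_sar_features",
    "extract_optical_features",
    "classify_scene",
    "run_pipeline",
    "PipelineResult",
]


def extract_sar_features(
    c3: C3Field,
    sigma_pca_threshold: float = 0.98,
    db_floor: float = -50.0,
) -> tuple[dict[str, np.ndarray], dict]:
    """All SAR-side layers: sigma-PCA components, RVI and Yamaguchi powers.

    Returns (layers, info); info carries the sigma-PCA explained-variance
    fractions and loadings for the run log.
    """
    sigma = intensity_to_db(c3_to_intensity(c3), floor_db=db_floor)
    # the integration modes name two sigma-PCA layers, so keep at least two
    pca = sigma_pca(sigma, var_threshold=sigma_pca_threshold, min_components=2)
    yam = yamaguchi4(c3)
    layers: dict[str, np.ndarray] = {}
    for i, name in enumerate(pca.names):
        layers[name] = pca.components[..., i]
    layers["RVI"] = rvi(c3)
    layers["Ps"] = yam.ps
    layers["Pd"] = yam.pd
    layers["Ph"] = yam.pc  # helix power, named Ph in the integration modes
    layers["Pv"] = yam.pv
    info = {
        "sigma_pca_explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "sigma_pca_n_kept": pca.n_kept,
        "sigma_pca_loadings": pca.loadings.tolist(),
        "yamaguchi_n_nonpsd": yam.n_nonpsd,
    }
    return layers, info


def extract_optical_features(
    optical: OpticalBands,
    band_pca_threshold: float = 0.99,
    texture: TextureConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """All optical-side layers: band-PCA components, NDVI and entropy H."""
    texture = texture or TextureConfig()
    pca = band_pca(optical, var_threshold=band_pca_threshold, min_components=2)
    layers: dict[str, np.ndarray] = {}
    for i, name in enumerate(pca.names):
        layers[name] = pca.components[..., i]
    layers["NDVI"] = ndvi(optical["R"], optical["NIR"], optical.mask)
    layers["H"] = entropy_texture(optical[texture.band], texture, optical.mask)
    info = {
        "band_pca_explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "band_pca_n_kept": pca.n_kept,
        "band_pca_loadings": pca.loadings.tolist(),
    }
    return layers, info


def classify_scene(
    stack: FeatureStack,
    train: TrainingSet,
    cfg: pio.PipelineConfig,
) -> tuple[ClassMap, SVMModel]:
    """Train the SVM on a stack and predict the whole scene."""
    model = svm_train(
        stack,
        train,
        c_grid=tuple(cfg.svm_c_grid),
        gamma_grid=tuple(cfg.svm_gamma_grid),
        cv_folds=cfg.svm_cv_folds,
        seed=cfg.seed,
        max_train_per_class=cfg.max_train_per_class,
    )
    return svm_predict(stack, model), model


@dataclass
class PipelineResult:
    """In-memory summary of one pipeline run."""

    report: AccuracyReport
    class_map: ClassMap
    stack: FeatureStack | None
    run_log: dict


def _load_inputs(cfg: pio.PipelineConfig):
    if cfg.simulate:
        sim = default_config(seed=cfg.seed)
        sim.shape = tuple(cfg.scene_size)
        sim.field_grid = tuple(cfg.field_grid)
        sim.looks = cfg.looks
        sim.train_fields_per_class = cfg.train_fields_per_class
        scene = generate_scene(sim)
        return scene.c3, scene.optical, scene.train, scene.test
    c3_data, _ = pio.read_c3(cfg.c3_path)
    c3 = C3Field(data=c3_data, looks=cfg.looks)
    opt_data, opt_meta = pio.read_raster(cfg.optical_path)
    band_map = cfg.optical_band_map
    optical = OpticalBands(bands={b: opt_data[..., i] for b, i in band_map.items()})
    if c3.shape != optical.shape:
        raise ValueError(
            f"inputs not co-registered: C3 grid {c3.shape} vs optical {optical.shape}"
        )

    def _labels_to_set(path: str) -> TrainingSet:
        lab, meta = pio.read_raster(path)
        lab = lab[..., 0].astype(int)
        legend = {int(k): v for k, v in meta.get("legend", {}).items()}
        if not legend:
            legend = {int(i): str(i) for i in np.unique(lab) if i != NODATA}
        r, c = np.nonzero(lab != NODATA)
        return TrainingSet(rows=r, cols=c, labels=lab[r, c], legend=legend)

    return c3, optical, _labels_to_set(cfg.train_labels_path), _labels_to_set(cfg.test_labels_path)


def run_pipeline(cfg: pio.PipelineConfig, output_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain and write the five artifacts.

    Artifacts in ``output_dir``: feature_stack.tif(+json), class_map.tif
    (+json), confusion.csv, report.json, run_log.json.  Any stage failure
    aborts with the stage name in the exception message.
    """
    cfg.validate()
    chash = pio.config_hash(cfg)
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config_hash": chash, "seed": cfg.seed, "mode": cfg.mode,
                     "classifier": cfg.classifier}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    c3, optical, train, test = _stage("load", _load_inputs, cfg)

    mode = INTEGRATION_MODES[cfg.mode]
    stack = None
    if cfg.classifier == "wishart":
        model = _stage("train", wishart_train, c3, train)
        cmap = _stage("classify", wishart_classify, c3, model)
    else:
        sar_layers, sar_info = ({}, {})
        opt_layers, opt_info = ({}, {})
        if mode.sar_layers:
            sar_layers, sar_info = _stage(
                "features-sar", extract_sar_features, c3,
                cfg.sigma_pca_threshold, cfg.db_floor,
            )
        if mode.optical_layers:
            texture = TextureConfig(
                window=cfg.entropy_window, bins=cfg.entropy_bins, band=cfg.entropy_band
            )
            opt_layers, opt_info = _stage(
                "features-optical", extract_optical_features, optical,
                cfg.band_pca_threshold, texture,
            )
        run_log.update(sar_info)
        run_log.update(opt_info)
        stack = _stage(
            "integrate", assemble, mode, sar_layers, opt_layers,
            sar_mask=c3.mask, optical_mask=optical.mask,
        )
        run_log["stack_layers"] = list(stack.names)
        run_log["n_stack_layers"] = len(stack.names)
        cmap, model = _stage("train+classify", classify_scene, stack, train, cfg)
        run_log["svm_best_params"] = model.best_params
        run_log["svm_cv_accuracy"] = model.cv_accuracy

    cm = _stage("assess", confusion, cmap, test)
    report = _stage("assess", metrics, cm)
    run_log["overall_accuracy"] = report.overall_accuracy
    run_log["kappa"] = report.kappa

    # artifacts
    if stack is not None:
        pio.write_raster(
            out / "feature_stack.tif", stack.as_array(), stack.names,
            {"config_hash": chash, "norm_stats": {k: list(v) for k, v in stack.norm_stats.items()}},
        )
    pio.write_raster(
        out / "class_map.tif", cmap.labels.astype(np.int32), ("class",),
        {"config_hash": chash, "legend": {str(k): v for k, v in cmap.legend.items()},
         "nodata": NODATA},
    )
    cm.to_frame().to_csv(out / "confusion.csv")
    (out / "report.json").write_text(
        json.dumps({"config_hash": chash, **report.to_dict()}, indent=2, allow_nan=True)
    )
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    log.info("pipeline complete: OA=%.4f kappa=%.4f -> %s",
             report.overall_accuracy, report.kappa, out)
    return PipelineResult(report=report, class_map=cmap, stack=stack, run_log=run_log)
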