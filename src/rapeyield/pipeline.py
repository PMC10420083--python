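"""End-to-end pipeline: simulate -> calibrate -> unmix -> indices -> model.

`run_pipeline` chains every stage on a synthetic trial, writes all
intermediate rasters and tables to an output directory, and records a
manifest (config echo, seed, package version, per-file SHA-256 checksums) so
a run is reproducible and byte-identical given the same seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


from . import __version__
from .accuracy import ConfusionMatrix2, confusion_metrics
from .calibration import apply_elm, fit_elm_from_image
from .images import ReflectanceImage
from .raster import write_raster
from .spectra import SENSOR_PRESETS, build_endmember_matrix, read_endmember_library, read_sensor
from .synth import TrialDesign, encode_dn, generate_trial, render_scene
from .unmixing import unmix_image
from .yield_model import plot_aggregate, rank_models, reports_to_frame, write_plots_csv


class ConfigurationError(ValueError):
    """The pipeline configuration is incomplete or references missing files."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_config() -> dict:
    return {
        "seed": 0,
        "sensor": "UAV6",
        "endmember_library": None,  # path; None -> seeded synthetic library
        "snr_db": 40.0,
        "bit_depth": 8,
        "rdvi_variant": "renormalized",
        "cv_variant": "rmse_over_mean",
        "vi_convention": "mean_reflectance",
        "confusion_matrix": None,  # path to CSV/JSON for the assess stage
    }


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full synthetic pipeline; returns the manifest dict."""
    cfg = {**default_config(), **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # resolve configuration before any computation
    if cfg["sensor"] in SENSOR_PRESETS:
        sensor = SENSOR_PRESETS[cfg["sensor"]]()
    else:
        spath = Path(cfg["sensor"])
        if not spath.exists():
            raise ConfigurationError(f"sensor preset or file not found: {cfg['sensor']}")
        sensor = read_sensor(spath)
    library = None
    if cfg["endmember_library"]:
        lpath = Path(cfg["endmember_library"])
        if not lpath.exists():
            raise ConfigurationError(f"endmember library not found: {lpath}")
        library = read_endmember_library(lpath)
    matrix_path = cfg.get("confusion_matrix")
    if matrix_path and not Path(matrix_path).exists():
        raise ConfigurationError(f"confusion matrix not found: {matrix_path}")

    seed = int(cfg["seed"])
    design = TrialDesign(seed=seed)

    # simulate
    bundle = generate_trial(design, library=library, sensor=sensor)
    scene, truth = render_scene(bundle, snr_db=cfg["snr_db"], seed=seed + 1)
    dn = encode_dn(scene, bit_depth=int(cfg["bit_depth"]))
    write_raster(dn, outdir / "dn.tif")
    write_raster(truth, outdir / "abundance_truth.tif")
    write_plots_csv(bundle.plots, outdir / "plots.csv")
    bundle.table.to_csv(outdir / "truth_table.csv", index=False)

    # calibrate
    gb = fit_elm_from_image(dn)
    refl_full = apply_elm(dn, gb)
    scene_rows = dn.meta["scene_rows"]
    refl = ReflectanceImage(
        values=refl_full.values[:, :scene_rows, :], sensor=sensor, meta=refl_full.meta
    )
    write_raster(refl, outdir / "reflectance.tif")

    # unmix
    E = build_endmember_matrix(bundle.library, sensor)
    abund = unmix_image(refl, E)
    write_raster(abund, outdir / "abundance.tif")

    # aggregate + indices + yield models
    table = plot_aggregate(
        refl, abund, bundle.plots,
        vi_convention=cfg["vi_convention"], rdvi_variant=cfg["rdvi_variant"],
    )
    table.to_csv(outdir / "predictors.csv", index=False)
    reports = rank_models(table, cv_variant=cfg["cv_variant"])
    report_df = reports_to_frame(reports)
    report_df.to_csv(outdir / "yield_models.csv", index=False)

    # assess (optional)
    metrics = None
    if matrix_path:
        p = Path(matrix_path)
        m = ConfusionMatrix2.from_json(p) if p.suffix == ".json" else ConfusionMatrix2.from_csv(p)
        metrics = confusion_metrics(m)
        (outdir / "accuracy.json").write_text(json.dumps(metrics, indent=2))

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "flags": {
            "rdvi_variant": cfg["rdvi_variant"],
            "cv_variant": cfg["cv_variant"],
            "vi_convention": cfg["vi_convention"],
        },
        "generator": {"beta0": bundle.beta0, "beta1": bundle.beta1,
                      "yield_noise_sd": design.yield_noise_sd},
        "gain_bias": {"gain": gb.gain.tolist(), "bias": gb.bias.tolist()},
        "best_model": report_df.iloc[0].to_dict(),
        "accuracy": metrics,
        "checksums": {
            f.name: _checksum(f) for f in sorted(outdir.iterdir()) if f.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
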