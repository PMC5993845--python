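"""End-to-end simulated study pipeline.

Runs the full chain that a multicenter normative database build performs:
simulate phantom acquisitions per scanner/condition, quantify them with
the Southampton method, fit per-(scanner, condition) calibration curves,
simulate and measure a subject cohort, calibrate it, and fit the normative
models.  Every artifact gets a provenance sidecar (seed, config hash,
package version); deterministic stages are bit-identical across reruns of
the same config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationTable, calibrate_cohort, fit_table_from_manifest
from .cohort import Demographics, generate_cohort, measure_cohort, records_to_frame, write_cohort_csv
from .config import PipelineConfig, config_hash
from .errors import PipelineStageError
from .normative import LinearCoefficients, anova_effects, decade_summary, fit_normative_model
from .published import AI_MODEL, SBR_MODEL
from .scanner import generate_phantom_series
from .southampton import quantify_phantom
from .volume import write_volume

__all__ = ["run_pipeline", "PHANTOM_MANIFEST_COLUMNS"]

PHANTOM_MANIFEST_COLUMNS = (
    "scanner",
    "condition",
    "ratio_right",
    "ratio_left",
    "background_kbq_ml",
    "true_sbr_right",
    "true_sbr_left",
    "volume_path",
)


def _write_meta(path: Path, stage: str, config: PipelineConfig) -> None:
    meta = {
        "artifact": path.name,
        "stage": stage,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "package_version": __version__,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


@_stage("simulate-phantoms")
def _simulate_and_quantify_phantoms(config: PipelineConfig, out_dir: Path, volumes_dir: Path | None):
    rows = []
    seed_base = np.random.SeedSequence(config.seed)
    scanners = [s.build() for s in config.scanners]
    streams = seed_base.spawn(len(scanners) * len(config.conditions))
    k = 0
    for scanner in scanners:
        for condition in config.conditions:
            series_seed = int(streams[k].generate_state(1)[0] % (2**31))
            k += 1
            series = generate_phantom_series(
                scanner,
                condition,
                ratio_pairs=tuple(tuple(p) for p in config.ratio_pairs),
                background_conc=config.background_conc,
                seed=series_seed,
                add_noise=config.phantom_noise,
            )
            for i, acq in enumerate(series):
                vol_path = ""
                if volumes_dir is not None:
                    vol_path = str(
                        write_volume(
                            acq.volume,
                            volumes_dir / f"{scanner.name}_{condition}_fill{i}.nii",
                        )
                    )
                meas = quantify_phantom(acq.volume, config.quantify)
                for side in ("right", "left"):
                    rows.append(
                        {
                            "scanner": acq.scanner,
                            "condition": acq.condition,
                            "ratio_right": acq.ratio_right,
                            "ratio_left": acq.ratio_left,
                            "background_kbq_ml": acq.background_conc,
                            "true_sbr_right": acq.true_sbr_right,
                            "true_sbr_left": acq.true_sbr_left,
                            "volume_path": vol_path,
                            "side": side,
                            "true_sbr": getattr(acq, f"true_sbr_{side}"),
                            "measured_sbr": getattr(meas, f"sbr_{side}"),
                        }
                    )
    df = pd.DataFrame(rows)
    manifest_path = out_dir / "phantom_manifest.csv"
    df.to_csv(manifest_path, index=False)
    _write_meta(manifest_path, "simulate-phantoms", config)
    return df


@_stage("fit-calibration")
def _fit_calibration(config: PipelineConfig, manifest: pd.DataFrame, out_dir: Path) -> CalibrationTable:
    table = fit_table_from_manifest(
        manifest,
        orientation=config.calibration.orientation,
        min_slope=config.calibration.min_slope,
        min_r=config.calibration.min_r,
    )
    path = out_dir / "calibration_curves.json"
    table.to_json(path)
    _write_meta(path, "fit-calibration", config)
    return table


@_stage("simulate-cohort")
def _simulate_cohort(config: PipelineConfig, out_dir: Path):
    cc = config.cohort
    sbr_coeffs = LinearCoefficients(**cc.sbr_coefficients) if cc.sbr_coefficients else SBR_MODEL
    ai_coeffs = LinearCoefficients(**cc.ai_coefficients) if cc.ai_coefficients else AI_MODEL
    demo = Demographics(
        age_min=cc.age_min,
        age_max=cc.age_max,
        female_fraction=cc.female_fraction,
        start_time_mean=cc.start_time_mean,
        start_time_sd=cc.start_time_sd,
    )
    ss = np.random.SeedSequence(config.seed).spawn(2)
    truth = generate_cohort(
        cc.n,
        coefficients=sbr_coeffs,
        residual_sd=cc.residual_sd,
        ai_coefficients=ai_coeffs,
        ai_residual_sd=cc.ai_residual_sd,
        demographics=demo,
        seed=int(ss[0].generate_state(1)[0] % (2**31)),
        scanners=tuple(s.name for s in config.scanners),
        conditions=tuple(config.conditions),
    )
    scanner_models = {s.name: s.build() for s in config.scanners}
    measured = measure_cohort(
        truth,
        scanner_models,
        noise_sd=cc.measurement_noise_sd,
        seed=int(ss[1].generate_state(1)[0] % (2**31)),
    )
    path = out_dir / "cohort.csv"
    write_cohort_csv(measured, path)
    _write_meta(path, "simulate-cohort", config)
    return truth, measured


@_stage("calibrate-cohort")
def _calibrate(config: PipelineConfig, measured, table: CalibrationTable, out_dir: Path):
    calibrated = calibrate_cohort(measured, table)
    path = out_dir / "cohort_calibrated.csv"
    write_cohort_csv(calibrated, path)
    _write_meta(path, "calibrate-cohort", config)
    return calibrated


@_stage("normative-fit")
def _fit_normative(config: PipelineConfig, calibrated, out_dir: Path) -> dict:
    report: dict = {}
    for outcome in ("average_sbr", "ai"):
        model = fit_normative_model(calibrated, outcome)
        report[outcome] = {
            "coefficients": model.coefficients.as_dict(),
            "coef_se": model.coef_se,
            "t_values": model.t_values,
            "p_values": model.p_values,
            "residual_sd": model.residual_sd,
            "n": model.n,
        }
    table = decade_summary(calibrated, mode=config.normative.decade_mode,
                           level=config.normative.pi_level)
    table_path = out_dir / "decade_summary.csv"
    table.to_csv(table_path, index=False)
    _write_meta(table_path, "normative-fit", config)

    anova = anova_effects(calibrated, "average_sbr")
    report["anova_average_sbr"] = anova.drop(columns=["p_text"]).to_dict(orient="records")

    report_path = out_dir / "normative_models.json"
    report_path.write_text(json.dumps(report, indent=2, default=float) + "\n")
    _write_meta(report_path, "normative-fit", config)
    return report


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    write_volumes: bool = False,
) -> dict:
    """Execute the full simulated study; returns a summary of artifacts.

    ``write_volumes=False`` (default) skips writing NIfTI phantom volumes
    (they are quantified in memory); pass True to keep them under
    ``out_dir/volumes`` for inspection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text("")
    config.to_yaml(out_dir / "config.yaml")
    _write_meta(out_dir / "config.yaml", "config", config)
    volumes_dir = out_dir / "volumes" if write_volumes else None

    manifest = _simulate_and_quantify_phantoms(config, out_dir, volumes_dir)
    table = _fit_calibration(config, manifest, out_dir)
    truth, measured = _simulate_cohort(config, out_dir)
    calibrated = _calibrate(config, measured, table, out_dir)
    report = _fit_normative(config, calibrated, out_dir)

    return {
        "out_dir": str(out_dir),
        "config_hash": config_hash(config),
        "n_phantom_points": len(manifest),
        "n_curves": len(table.curves),
        "n_records": len(measured),
        "normative": report,
        "artifacts": sorted(p.name for p in out_dir.glob("*") if p.is_file()),
    }
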