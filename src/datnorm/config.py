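"""Pipeline configuration: YAML/JSON round-tripping and provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .phantom import DEFAULT_RATIO_PAIRS
from .scanner import DEFAULT_CONDITION_BIASES, ConditionBias, ScannerModel
from .southampton import QuantifyConfig

__all__ = ["ScannerConfig", "CohortConfig", "CalibrationConfig", "NormativeConfig",
           "PipelineConfig", "config_hash"]


@dataclass
class ScannerConfig:
    name: str
    voxel_size: float = 2.2
    psf_fwhm: float = 9.0
    noise_scale: float | None = 3.0e6
    condition_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            cond: dataclasses.asdict(bias) for cond, bias in DEFAULT_CONDITION_BIASES.items()
        }
    )

    def build(self) -> ScannerModel:
        return ScannerModel(
            name=self.name,
            voxel_size=self.voxel_size,
            psf_fwhm=self.psf_fwhm,
            noise_scale=self.noise_scale,
            condition_bias={c: ConditionBias(**b) for c, b in self.condition_bias.items()},
        )


@dataclass
class CohortConfig:
    n: int = 510
    residual_sd: float = 1.38
    ai_residual_sd: float = 3.7
    age_min: float = 30.0
    age_max: float = 83.0
    female_fraction: float = 0.55
    start_time_mean: float = 3.5
    start_time_sd: float = 0.5
    measurement_noise_sd: float = 0.2
    # generative coefficients; None means the published normative defaults
    sbr_coefficients: dict[str, float] | None = None
    ai_coefficients: dict[str, float] | None = None


@dataclass
class CalibrationConfig:
    orientation: str = "measured_on_true"
    min_slope: float | None = 0.1
    min_r: float | None = 0.9


@dataclass
class NormativeConfig:
    icc_form: str = "icc2"
    pi_level: float = 0.95
    decade_mode: str = "predicted"


@dataclass
class PipelineConfig:
    """Full configuration of an end-to-end simulated study."""

    seed: int = 0
    scanners: list[ScannerConfig] = field(
        default_factory=lambda: [
            ScannerConfig(name="scanner01", voxel_size=2.2, psf_fwhm=9.0),
            ScannerConfig(name="scanner02", voxel_size=3.2, psf_fwhm=12.0),
        ]
    )
    conditions: list[str] = field(default_factory=lambda: ["NOACNOSC", "ChangACSC"])
    ratio_pairs: list[list[float]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_RATIO_PAIRS]
    )
    background_conc: float = 5.0
    phantom_noise: bool = True
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    normative: NormativeConfig = field(default_factory=NormativeConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quantify"]["striatal_half_extents_mm"] = list(
            d["quantify"]["striatal_half_extents_mm"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "scanners" in d:
            d["scanners"] = [
                s if isinstance(s, ScannerConfig) else ScannerConfig(**s) for s in d["scanners"]
            ]
        for key, typ in (("cohort", CohortConfig), ("calibration", CalibrationConfig),
                         ("normative", NormativeConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "quantify" in d and isinstance(d["quantify"], dict):
            q = dict(d["quantify"])
            if "striatal_half_extents_mm" in q:
                q["striatal_half_extents_mm"] = tuple(q["striatal_half_extents_mm"])
            d["quantify"] = QuantifyConfig(**q)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML (JSON is a YAML subset and is accepted too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the effective configuration, for provenance."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
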