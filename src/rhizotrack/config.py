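"""Run configuration: one YAML file describing every pipeline stage.

Units are fixed package-wide: micrometres and minutes.  Unknown keys in
any section are rejected so typos fail loudly, and the seed recorded here
drives every stochastic stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationCriteria
from .synthetic import DivisionModel, KinematicsParams, OpticsParams
from .tracking import AnnealSchedule, EnergyParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _build(cls, section: dict, name: str):
    if section is None:
        return cls()
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    outdir: str = "run"
    seed: int = 0
    units: dict = field(default_factory=lambda: {"length": "um", "time": "min"})
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "deconvolve": False,
            "segment": True,
            "register": True,
            "track": True,
            "divisions": True,
            "kinematics": True,
        }
    )
    # synthetic input
    simulate: dict = field(
        default_factory=lambda: {
            "radius": 15.0,
            "length": 340.0,
            "spacing": 10.0,
            "n_steps": 30,
        }
    )
    psf_path: str | None = None
    deconvolve_iters: int = 30
    kinematics_params: KinematicsParams = field(default_factory=KinematicsParams)
    division_model: DivisionModel = field(default_factory=DivisionModel)
    optics: OpticsParams | None = None
    criteria: SegmentationCriteria = field(default_factory=SegmentationCriteria)
    energy: EnergyParams = field(default_factory=EnergyParams)
    schedule: AnnealSchedule | None = None
    division_window: int = 3
    fit_range: tuple[float, float] = (80.0, 300.0)
    velocity_bin_um: float = 5.0
    velocity_min_count: int = 36

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        simple = {
            "outdir",
            "seed",
            "units",
            "psf_path",
            "deconvolve_iters",
            "division_window",
            "velocity_bin_um",
            "velocity_min_count",
        }
        for key, value in raw.items():
            if key in simple:
                setattr(cfg, key, value)
            elif key == "fit_range":
                cfg.fit_range = tuple(value)
            elif key == "stages":
                unknown = set(value) - set(cfg.stages)
                if unknown:
                    raise ConfigError(f"unknown stages: {sorted(unknown)}")
                cfg.stages.update(value)
            elif key == "simulate":
                cfg.simulate.update(value or {})
            elif key == "kinematics":
                cfg.kinematics_params = _build(KinematicsParams, value, "kinematics")
            elif key == "division_model":
                cfg.division_model = _build(DivisionModel, value, "division_model")
            elif key == "optics":
                cfg.optics = _build(OpticsParams, value, "optics")
            elif key == "criteria":
                cfg.criteria = _build(SegmentationCriteria, value, "criteria")
            elif key == "energy":
                cfg.energy = _build(EnergyParams, value, "energy")
            elif key == "schedule":
                cfg.schedule = _build(AnnealSchedule, value, "schedule")
            else:
                raise ConfigError(f"unknown top-level key: {key}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.stages.get("deconvolve") and not self.psf_path:
            raise ConfigError(
                "deconvolution is enabled but 'psf_path' is not set"
            )
        if self.psf_path and not self.stages.get("simulate"):
            if not Path(self.psf_path).exists():
                raise ConfigError(f"psf_path does not exist: {self.psf_path}")
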