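"""Run configuration: defaults, YAML round trip, validation.

Every pipeline parameter lives in one nested mapping with a default, so a
run is fully described by its effective config (written next to the run's
outputs) plus the input files.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .registration import RegistrationParams
from .tracking import DetectionParams, LinkParams, PhaseThresholds

DEFAULTS: dict[str, Any] = {
    "input": None,
    "out_dir": "phenotrack_out",
    "seed": 0,
    "verbosity": 1,
    "plots": False,
    "calibration": {"pixel_size_um": 1.3, "frame_interval_min": 60.0},
    "channel_map": {"brightfield": 0, "red": 1, "green": 2},
    "gray_recipe": "brightfield",
    "segmentation": {
        "smoothing_sigma": 2.0,
        "threshold_method": "otsu",
        "fixed_threshold": None,
        "min_area_px": 1000,
    },
    "registration": {
        "n_templates": 6,
        "template_size_px": 64,
        "n_regions": 40,
        "bin_deg": 0.25,
        "search_window_px": 48,
        "max_search_deg": 10.0,
        "score_floor": 0.5,
        "score_ceiling": 0.3,
        "conv_tol_px": 0.5,
        "conv_tol_deg": 0.1,
        "max_iterations": 15,
        "damping": 0.5,
        "smooth_theta": False,
    },
    "detection": {
        "min_intensity": 0.0,
        "sigma_min_px": 2.0,
        "sigma_max_px": 5.0,
        "n_sigma": 4,
        "min_area_px": 4.0,
        "log_threshold": 0.02,
    },
    "phase": {"t_g1s": 25.0, "t_sg2m": 45.0, "intensity_floor_frac": 0.05,
              "pool_s_with_g2m": False},
    "linking": {"max_link_dist_px": 30.0, "max_gap": 2},
    "ranking": {"top_n": 50},
    "scene": {},  # SceneParams overrides for `simulate`
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        cfg = cls()
        cfg.update(data)
        return cfg

    def update(self, data: Mapping[str, Any]) -> None:
        def merge(dst: dict, src: Mapping) -> None:
            for k, v in src.items():
                if k not in dst and not isinstance(dst.get(k), dict):
                    dst[k] = v
                elif isinstance(dst.get(k), dict) and isinstance(v, Mapping):
                    merge(dst[k], v)
                else:
                    dst[k] = v

        merge(self.values, data)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    # -- typed parameter blocks ------------------------------------------

    def registration_params(self) -> RegistrationParams:
        return RegistrationParams(**self.values["registration"])

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.values["detection"])

    def link_params(self) -> LinkParams:
        return LinkParams(**self.values["linking"])

    def phase_thresholds(self) -> PhaseThresholds:
        ph = self.values["phase"]
        return PhaseThresholds(t_g1s=ph["t_g1s"], t_sg2m=ph["t_sg2m"])

    def validate(self) -> None:
        """Fail fast on inconsistent settings, before any computation."""
        self.phase_thresholds()
        cal = self.values["calibration"]
        if cal["pixel_size_um"] <= 0 or cal["frame_interval_min"] <= 0:
            raise ConfigError("calibration values must be > 0")
        reg = self.values["registration"]
        if reg["n_templates"] < 1 or reg["max_iterations"] < 1:
            raise ConfigError("registration counts must be >= 1")
        if not 0 < reg["damping"] <= 1:
            raise ConfigError("damping must be in (0, 1]")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=False)
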