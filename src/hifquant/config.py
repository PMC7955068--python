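"""Run configuration: every field-stated constant is a default here,
never hard-coded at call sites in the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


class ConfigError(ValueError):
    """A configuration value violates its contract."""


@dataclass
class RunConfig:
    tissue_mpp: float = 4.0
    proximity_radius_um: float = 80.0
    csi_halfwidth_um: float = 40.0
    birch_threshold_um: float = 100.0
    birch_branching: int = 10
    significant_fraction: float = 0.10
    cluster_cutoff: float = 0.95
    sgl_alpha: float = 0.95
    n_outer_folds: int = 3
    n_inner_folds: int = 5
    n_lambda: int = 30
    n_bootstrap: int = 1000
    n_permutations: int = 1000
    holdout_frac_min: float = 0.20
    holdout_frac_max: float = 0.30
    seed: int = 0
    # cohort simulation
    n_patients: int = 60
    n_sites: int = 6
    scene_shape: tuple[int, int] = (160, 160)
    signal_sd: float = 2.5
    noise_sd: float = 1.0
    n_active_clusters: int = 2

    def validate(self) -> None:
        positive = ("tissue_mpp", "proximity_radius_um", "csi_halfwidth_um",
                    "birch_threshold_um", "birch_branching", "n_outer_folds",
                    "n_inner_folds", "n_lambda", "n_bootstrap", "n_patients",
                    "n_sites")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.significant_fraction <= 1:
            raise ConfigError(
                f"significant_fraction must be in (0, 1], got {self.significant_fraction}")
        if not 0 < self.cluster_cutoff <= 1:
            raise ConfigError(
                f"cluster_cutoff must be in (0, 1], got {self.cluster_cutoff}")
        if not 0 <= self.sgl_alpha <= 1:
            raise ConfigError(f"sgl_alpha must be in [0, 1], got {self.sgl_alpha}")
        if not 0 < self.holdout_frac_min < self.holdout_frac_max < 1:
            raise ConfigError("holdout fractions must satisfy 0 < min < max < 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "scene_shape" in raw:
            raw["scene_shape"] = tuple(raw["scene_shape"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["scene_shape"] = list(self.scene_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
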