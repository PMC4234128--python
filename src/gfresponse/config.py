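"""Run configuration.

Every analysis constant — the 2-SD significance multiplier, k = 4 kinetic
clusters, the 75% dose-sensitivity ratio, the pathway scale-factor policy —
is a config field with the conventional default, never a hard-coded value,
so sensitivity to these choices can be examined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .io import Dialect


@dataclass
class RunConfig:
    # input paths (None = stage skipped or supplied in memory)
    response_path: str | None = None
    basal_path: str | None = None
    lrmap_path: str | None = None
    subtype_path: str | None = None
    dialect: Dialect = field(default_factory=Dialect)
    #: per-analyte detection thresholds (log10 units); None disables the check
    detection_thresholds: dict | None = None

    # significance rule
    sd_multiplier: float = 2.0

    # kinetic clustering
    kinetics_k: int = 4
    kinetics_restarts: int = 10
    normalize_trajectories: bool = True
    seed: int = 0

    # dose-sensitivity rule
    sensitivity_ratio: float = 0.75
    #: "fold_minus_one" compares (10^fc - 1) ratios; "fold" compares 10^fc ratios
    sensitivity_mode: str = "fold_minus_one"

    # pathway scale fitting
    scale_grid_min: float = 0.1
    scale_grid_max: float = 10.0
    scale_grid_size: int = 121
    scale_significant_only: bool = True
    #: fixed scale factor overriding the fit (policy "fixed" instead of "fit")
    fixed_alpha: float | None = None
    #: bias ratio on linear fold-changes ("fold") or log10 fold-changes ("log_fold")
    bias_scale: str = "fold"
    bias_dose: float = 100.0

    # correlation panel
    corr_method: str = "pearson"
    corr_adjust: bool = False

    outdir: str = "results"

    def __post_init__(self):
        if self.sd_multiplier <= 0:
            raise ConfigError("sd_multiplier must be > 0")
        if not (0 < self.sensitivity_ratio <= 1):
            raise ConfigError("sensitivity_ratio must lie in (0, 1]")
        if self.kinetics_k < 2:
            raise ConfigError("kinetics_k must be >= 2")
        if self.sensitivity_mode not in ("fold_minus_one", "fold"):
            raise ConfigError("sensitivity_mode must be 'fold_minus_one' or 'fold'")
        if self.corr_method not in ("pearson", "spearman"):
            raise ConfigError("corr_method must be 'pearson' or 'spearman'")
        if self.bias_scale not in ("fold", "log_fold"):
            raise ConfigError("bias_scale must be 'fold' or 'log_fold'")
        if not (0 < self.scale_grid_min < self.scale_grid_max):
            raise ConfigError("scale grid bounds must satisfy 0 < min < max")
        if self.fixed_alpha is not None and self.fixed_alpha <= 0:
            raise ConfigError("fixed_alpha must be positive")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("dialect"), dict):
            d["dialect"] = Dialect(**d["dialect"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
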