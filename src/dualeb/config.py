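"""Run configuration: defaults, file loading (YAML/JSON) and validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration; maps to exit code 2 in the CLI."""


@dataclass
class RunConfig:
    # input/output paths
    first_path: str | None = None
    second_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "."
    tissue_first: str = "first"
    tissue_second: str = "second"
    # analysis
    method: str = "single"
    k: int = 100
    n_bins: int = 120
    spline_df: int = 7
    s2_mode: str = "unit"
    standardize_combined: bool = False
    # cleaning
    min_abs_lfc: float = 0.05
    min_se: float = 1e-4
    pseudocount: float = 1.0
    # cross-validation
    n_repeats: int = 5
    train_frac: float = 0.5
    seed: int = 0
    paper_mode: bool = False
    auc_per_repeat: bool = False
    # reporting
    topk: tuple[int, ...] = (100, 200)
    z_histogram: bool = False

    def validate(self) -> "RunConfig":
        if self.method not in ("single", "weighted_gene", "weighted_z"):
            raise ConfigError(f"method: unknown value {self.method!r}")
        if self.k < 1:
            raise ConfigError(f"k: must be >= 1 (got {self.k})")
        if self.n_repeats < 1:
            raise ConfigError(f"n_repeats: must be >= 1 (got {self.n_repeats})")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigError(f"train_frac: must lie in (0, 1) (got {self.train_frac})")
        if self.s2_mode not in ("unit", "central"):
            raise ConfigError(f"s2_mode: unknown value {self.s2_mode!r}")
        if self.min_abs_lfc < 0 or self.min_se < 0:
            raise ConfigError("cleaning thresholds must be nonnegative")
        if self.n_bins < 10 or self.spline_df < 4:
            raise ConfigError("n_bins must be >= 10 and spline_df >= 4")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["topk"] = list(self.topk)
        return d


def parse_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a validated RunConfig from an optional YAML/JSON file plus
    keyword overrides; overrides (CLI flags) win over file values, and
    file values win over defaults. Unknown keys are rejected."""
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        loaded = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        loaded = loaded or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(loaded) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "topk" in values:
        values["topk"] = tuple(int(v) for v in values["topk"])
    try:
        cfg = RunConfig(**values)
    except TypeError as err:
        raise ConfigError(str(err)) from None
    return cfg.validate()
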