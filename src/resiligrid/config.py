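"""Pipeline configuration: a flat YAML-serializable parameter set."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end analysis in one place.

    Period ranges are inclusive ``[first, last]`` calendar years and are
    required in ``explicit`` period mode; ``auto`` mode detects the dry
    period from the regional precipitation anomaly instead.
    """

    # inputs / outputs
    ndvi_path: str | None = None
    precip_path: str | None = None       # gridded precip; else interpolated
    stations_path: str | None = None     # station CSV for interpolation
    mask_path: str | None = None
    output_dir: str = "resiligrid_out"
    ndvi_variable: str | None = None
    precip_variable: str | None = None

    # periods
    period_mode: str = "explicit"        # "explicit" | "auto"
    normal_range: tuple[int, int] | None = None
    dry_range: tuple[int, int] | None = None
    recovery_range: tuple[int, int] | None = None
    min_run: int = 5
    weights: str = "uniform"             # "uniform" | "cos-lat"

    # metrics
    min_ndvi_reduction: float = 0.01
    resilience_denominator: str = "normal"
    map_window: str = "all"

    # gradient
    bin_width: float = 50.0
    n_min: int = 10
    subset_lo: float = 0.05
    subset_hi: float = 0.10
    p_gate: float = 0.05

    # interpolation
    smoothing: float | str = "gcv"

    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_mode not in {"explicit", "auto"}:
            raise ValueError(f"unknown period_mode {self.period_mode!r}")
        if self.period_mode == "explicit" and (
            self.normal_range is None or self.dry_range is None
        ):
            raise ValueError("explicit period_mode requires normal/dry ranges")
        if not 0 <= self.min_ndvi_reduction <= 1:
            raise ValueError("min_ndvi_reduction must be in [0, 1]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not self.subset_lo < self.subset_hi:
            raise ValueError("require subset_lo < subset_hi")
        if not 0 < self.p_gate < 1:
            raise ValueError("p_gate must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.pop("schema_version", None)
        for key in ("normal_range", "dry_range", "recovery_range"):
            if data.get(key) is not None:
                data[key] = tuple(int(v) for v in data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = asdict(self)
        for key in ("normal_range", "dry_range", "recovery_range"):
            if data[key] is not None:
                data[key] = list(data[key])
        data["schema_version"] = CONFIG_SCHEMA_VERSION
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path
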