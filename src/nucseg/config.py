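"""Pipeline configuration.

Every tunable of the segmentation pipeline lives here, with the
published defaults: bilateral sigma_c = 1 intensity unit and
sigma_s = sigma_global (the standard deviation of the input image),
top-hat disk radius 21 px, opening radius 1 px, minimum object area
40 px (strict "smaller than"), closing radius 2 px, 5x5 regional-maxima
window, seed dilation radius 3 px, 5x5 chamfer distance mask.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Any

__all__ = [
    "BilateralParams",
    "TophatParams",
    "SeedParams",
    "WatershedParams",
    "PipelineConfig",
    "resolve_window_radius",
]

AUTO = "auto"


def resolve_window_radius(sigma_s: float, height: int, width: int) -> int:
    """Derived bilateral window radius: ceil(3*sigma_s), capped and floored.

    3 sigma captures >99% of the Gaussian mass; the cap at half the
    smaller image dimension keeps cost bounded because sigma_s defaults
    to the global intensity standard deviation, which can be large.
    """
    radius = math.ceil(3.0 * sigma_s)
    radius = min(radius, min(height, width) // 2)
    return max(radius, 1)


@dataclass(frozen=True)
class BilateralParams:
    """Edge-preserving smoothing parameters.

    ``sigma_c`` is the radiometric (intensity-similarity) standard
    deviation; ``sigma_s`` the spatial one, in pixels. ``"auto"`` for
    ``sigma_s`` means "use the global intensity std of the input image";
    ``"auto"`` for ``window_radius`` means the 3-sigma rule above.
    """

    enabled: bool = True
    sigma_c: float = 1.0
    sigma_s: float | str = AUTO
    window_radius: int | str = AUTO

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.sigma_s != AUTO and float(self.sigma_s) <= 0:
            raise ValueError("sigma_s must be positive or 'auto'")
        if self.window_radius != AUTO and int(self.window_radius) < 1:
            raise ValueError("window_radius must be >= 1 or 'auto'")


@dataclass(frozen=True)
class TophatParams:
    """White top-hat background correction with a flat disk."""

    radius: int = 21

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("top-hat radius must be >= 1")


@dataclass(frozen=True)
class SeedParams:
    """Foreground refinement and seed extraction parameters."""

    open_radius: int = 1
    min_area: int = 40
    close_radius: int = 2
    maxima_window: int = 5
    dilate_radius: int = 3
    edt_mask: int = 5
    border_is_background: bool = False

    def __post_init__(self) -> None:
        for name in ("open_radius", "min_area", "close_radius",
                     "maxima_window", "dilate_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.maxima_window % 2 != 1:
            raise ValueError("maxima_window must be odd")
        if self.edt_mask not in (3, 5):
            raise ValueError("edt_mask must be 3 or 5")


@dataclass(frozen=True)
class WatershedParams:
    """Flooding options; boundary_lines emits 1-px zero-valued dams
    between adjacent instances for visualization."""

    boundary_lines: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration with published defaults."""

    bilateral: BilateralParams = field(default_factory=BilateralParams)
    tophat: TophatParams = field(default_factory=TophatParams)
    seeds: SeedParams = field(default_factory=SeedParams)
    watershed: WatershedParams = field(default_factory=WatershedParams)
    workers: int = 1
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = dict(data)
        for key, sub in (("bilateral", BilateralParams),
                         ("tophat", TophatParams),
                         ("seeds", SeedParams),
                         ("watershed", WatershedParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load a TOML config file; missing keys keep their defaults."""
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def with_overrides(self, *assignments: str) -> "PipelineConfig":
        """Apply ``section.key=value`` overrides (the CLI ``--set`` form)."""
        cfg_dict = self.to_dict()
        for item in assignments:
            key, _, raw = item.partition("=")
            if not _:
                raise ValueError(f"override {item!r} is not of form key=value")
            value = _parse_value(raw.strip())
            node = cfg_dict
            parts = key.strip().split(".")
            for part in parts[:-1]:
                if part not in node:
                    raise KeyError(f"unknown config section {part!r}")
                node = node[part]
            if parts[-1] not in node:
                raise KeyError(f"unknown config key {key!r}")
            node[parts[-1]] = value
        return self.from_dict(cfg_dict)


def _parse_value(raw: str) -> Any:
    lowered = raw.lower()
    if lowered in ("true", "false"):
        return lowered == "true"
    if lowered == AUTO:
        return AUTO
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw
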