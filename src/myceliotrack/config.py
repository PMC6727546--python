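"""Run configuration: defaults, TOML loading and CLI overrides.

A :class:`RunConfig` holds every tunable of the pipeline.  Batch runs are
reproducible because the fully materialised configuration is serialised into
each result archive.  TOML files use nested sections (``[binarization]``,
``[cleaning]``, ...); in memory the keys are flat with ``section_key`` names.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence


@dataclass
class RunConfig:
    """All pipeline parameters.

    Length-like parameters are in µm and converted to pixels with the stack
    calibration at use time; intensity-like parameters are in the units of the
    (background-corrected) input image.
    """

    # io_stack
    calibration_um_per_px: Optional[float] = None  # None: take from metadata
    interval_s: Optional[float] = None             # None: take from metadata
    crop: Optional[tuple[int, int, int, int]] = None  # (r0, r1, c0, c1) half-open
    background_blur_um: float = 7.5

    # binarization
    binarization_method: str = "niblack-adapted"
    binarization_window_um: float = 15.0
    binarization_k: float = -0.6
    # absolute contrast floor; None derives 3x robust noise sigma per frame
    binarization_abs_contrast: Optional[float] = None
    invert: bool = False

    # cleaning
    cleaning_min_object_um2: float = 1.0
    cleaning_max_hole_um2: float = 0.5
    cleaning_closing_um: float = 0.7

    # skeleton graph
    smoothing_iterations: int = 5
    skeleton_prune_um: float = 1.5

    # tracking
    junction_radius_um: float = 2.0
    tip_radius_um: float = 10.0
    shortcut_abs_um: float = 1.0
    shortcut_rel: float = 0.10
    min_track_points: int = 3
    min_track_length_um: float = 2.0

    # storage / execution
    store_images: bool = False
    jobs: int = 1

    _SECTIONS = ("binarization", "cleaning")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["crop"] is not None:
            d["crop"] = list(d["crop"])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("crop") is not None:
            d["crop"] = tuple(int(v) for v in d["crop"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        """Load a TOML config; section tables are flattened to prefixed keys."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict[str, Any] = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}_{sub}"] = v
            else:
                flat[key] = value
        return cls.from_dict(flat)

    def replace(self, **overrides: Any) -> "RunConfig":
        """Return a copy with the given fields overridden (CLI flags win)."""
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **overrides)
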