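"""Stimulus configuration: the full specification of one stimulus run."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import yaml

__all__ = ["StimulusConfig", "load_config", "config_to_dict"]

FAMILIES = ("stereo", "pure_color", "color_border", "contrast", "luminance")
PARADIGMS = ("standstill", "joint", "capture", "flicker")


@dataclass
class StimulusConfig:
    """Everything needed to render one stimulus deterministically.

    ``figure`` and ``carrier`` are parameter dictionaries resolved to a
    :class:`~motionstill.fields.FigureField` and a
    :class:`~motionstill.textures.CarrierTexture` at composition time
    (fractional geometry keys like ``a_frac`` scale with the resolution).
    ``figure_motion`` / ``carrier_motion`` are schedule dictionaries
    ``{kind, rate..., reversal_period}``.
    """

    name: str = "custom"
    family: str = "stereo"
    figure: dict = dc_field(default_factory=lambda: {"kind": "sector_wheel"})
    carrier: dict = dc_field(default_factory=dict)
    paradigm: str = "standstill"
    figure_motion: dict = dc_field(default_factory=lambda: {"kind": "static"})
    carrier_motion: dict = dc_field(default_factory=lambda: {"kind": "static"})
    flicker_mode: str = "regenerate"
    stereo: dict = dc_field(default_factory=dict)
    palette: dict = dc_field(default_factory=dict)
    mask_palette: str = "black_transparent"
    mean_level: float = 0.5
    resolution: tuple[int, int] = (1280, 720)
    fps: float = 30.0
    duration: float = 10.0
    seed: int = 0
    markers: list = dc_field(default_factory=list)
    mask_region_radius: float | None = None
    table1: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"family: unknown value {self.family!r}, expected one of {FAMILIES}"
            )
        if self.paradigm not in PARADIGMS:
            raise ValueError(
                f"paradigm: unknown value {self.paradigm!r}, "
                f"expected one of {PARADIGMS}"
            )
        w, h = self.resolution
        if w < 8 or h < 8:
            raise ValueError(f"resolution: degenerate {self.resolution}")
        self.resolution = (int(w), int(h))
        if self.fps <= 0:
            raise ValueError(f"fps: must be > 0, got {self.fps}")
        if self.duration <= 0:
            raise ValueError(f"duration: must be > 0, got {self.duration}")
        for key in ("figure_motion", "carrier_motion"):
            d = getattr(self, key)
            if not isinstance(d, dict) or "kind" not in d:
                raise ValueError(f"{key}: expected a dict with a 'kind' entry")
            numeric = ("omega", "sigma", "axis_factor", "frequency")
            for rk, rv in d.items():
                if rk in numeric and not isinstance(rv, (int, float)):
                    raise ValueError(
                        f"{key}.{rk}: expected a number, got {type(rv).__name__}"
                    )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


def config_to_dict(config: StimulusConfig) -> dict:
    """Plain-dict form of a config (YAML/JSON serializable)."""
    d = asdict(config)
    d["resolution"] = list(d["resolution"])
    return d


def load_config(path) -> StimulusConfig:
    """Load a YAML config file.

    Either a full configuration, or ``{preset: <name>, <overrides...>}``
    where overrides replace top-level fields of the named preset. Unknown
    keys are rejected with the offending field named.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    known = set(StimulusConfig.__dataclass_fields__)
    unknown = set(raw) - known - {"preset"}
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")

    if "preset" in raw:
        from .presets import build_preset

        overrides = {k: v for k, v in raw.items() if k != "preset"}
        if "resolution" in overrides:
            overrides["resolution"] = tuple(overrides["resolution"])
        return build_preset(raw["preset"], **overrides)

    if "resolution" in raw:
        raw = dict(raw)
        raw["resolution"] = tuple(raw["resolution"])
    return StimulusConfig(**raw)
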