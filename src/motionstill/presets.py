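"""Preset registry: the demonstration-video parameter sets.

Each preset pins down one stimulus run: which family (stereo, pure color,
color border, contrast-modulated, luminance), which figure geometry, which
motion class, and — crucially — which of the two surfaces moves. The
``standstill`` paradigm moves the figure under a stationary carrier/mask,
``capture`` moves the carrier/mask over a stationary figure, and the joint
condition moves both together (the veridical-motion control).

Rate conventions (recorded per preset under ``table1`` exactly as published):

* rotation rates are deg/s, reversing direction every 5 s;
* scaling rates are percent per second (e.g. 117.6 means the figure reaches
  117.6% of its size after 1 s), reversing every 5 s;
* stereo shearing rates are the percent horizontal extent reached at the
  peak of a 0.2 Hz shearing cycle (120 = expansion to 120%, 83 = compression
  to 83%);
* color shearing rates are percent per second on a 0.1 Hz cycle (108.2%/s
  compounds to ~148% over the 5 s half-cycle, the published ~146% extent).
"""

from __future__ import annotations

import math

from .config import StimulusConfig

__all__ = ["PRESETS", "build_preset", "list_presets", "TABLE1"]

# pitch for which a 350% scaling equals a 90 deg rotation: e^{b*pi/2} = 3.5
SPIRAL_PITCH_350 = 2.0 * math.log(3.5) / math.pi

# (family, motion, figure_rate, texture_rate) -- rates as published
TABLE1: dict[str, tuple[str, str, float, float]] = {
    "stereo_rotation_standstill": ("stereo", "rotation", 12, 0),
    "stereo_rotation": ("stereo", "rotation", 12, 12),
    "stereo_rotation_capture": ("stereo", "rotation", 0, 12),
    "color_rotation_standstill_slow": ("pure_color", "rotation", 6, 0),
    "color_rotation_standstill_fast": ("pure_color", "rotation", 24, 0),
    "color_rotation": ("pure_color", "rotation", 6, 6),
    "color_rotation_capture_slow": ("pure_color", "rotation", 0, 6),
    "color_rotation_capture_fast": ("pure_color", "rotation", 0, 24),
    "color_border_rotation_standstill": ("color_border", "rotation", 4, 0),
    "color_border_rotation": ("color_border", "rotation", 4, 4),
    "color_border_capture": ("color_border", "rotation", 0, 4),
    "contrast_rotation_standstill": ("contrast", "rotation", 4, 0),
    "contrast_rotation": ("contrast", "rotation", 4, 4),
    "contrast_rotation_capture": ("contrast", "rotation", 0, 4),
    "luminance_rotation_standstill": ("luminance", "rotation", 4, 0),
    "luminance_rotation": ("luminance", "rotation", 4, 4),
    "luminance_capture": ("luminance", "rotation", 0, 4),
    "stereo_scaling_standstill": ("stereo", "scaling", 117.6, 100),
    "stereo_scaling": ("stereo", "scaling", 117.6, 117.6),
    "stereo_scaling_capture": ("stereo", "scaling", 100, 117.6),
    "color_scaling_standstill": ("pure_color", "scaling", 107.9, 100),
    "color_scaling": ("pure_color", "scaling", 107.9, 107.9),
    "color_scaling_capture": ("pure_color", "scaling", 100, 107.9),
    "contrast_scaling_standstill": ("contrast", "scaling", 103.9, 100),
    "contrast_scaling": ("contrast", "scaling", 103.9, 103.9),
    "contrast_scaling_capture": ("contrast", "scaling", 100, 103.9),
    "stereo_shearing_standstill_expansion": ("stereo", "shear", 120, 100),
    "stereo_shearing_standstill_compression": ("stereo", "shear", 83, 100),
    "stereo_shearing_capture_expansion": ("stereo", "shear", 100, 120),
    "stereo_shearing_capture_compression": ("stereo", "shear", 100, 83),
    "color_shearing_standstill_expansion": ("pure_color", "shear", 108.2, 100),
    "color_shearing_standstill_compression": ("pure_color", "shear", 92.4, 100),
    "color_shearing_capture_expansion": ("pure_color", "shear", 100, 108.2),
    "color_shearing_capture_compression": ("pure_color", "shear", 100, 92.4),
}

# spiraling demonstrations (not tabulated with the others): the color spiral
# scales to 146% over 5 s while rotating at 9 deg/s; the standstill variant
# moves the figure, the capture variant the dot texture.
EXTRA_PRESETS: dict[str, tuple[str, str, tuple, tuple]] = {
    "stereo_spiraling_standstill": ("stereo", "spiral", (9, 107.9), (0, 100)),
    "stereo_spiraling_capture": ("stereo", "spiral", (0, 100), (9, 107.9)),
    "color_spiraling_standstill": ("pure_color", "spiral", (9, 107.9), (0, 100)),
    "color_spiraling_capture": ("pure_color", "spiral", (0, 100), (9, 107.9)),
    # white-dot variant of the luminance mask (black is the default)
    "luminance_rotation_standstill_white": ("luminance", "rotation", 4, 0),
}

PRESETS = tuple(list(TABLE1) + list(EXTRA_PRESETS))

_DEFAULTS = dict(resolution=(1280, 720), fps=30.0, duration=10.0, seed=0)
REVERSAL_PERIOD = 5.0  # s; "direction is changing every 5 s"
STEREO_SHEAR_FREQUENCY = 0.2  # Hz
COLOR_SHEAR_FREQUENCY = 0.1  # Hz; 5 s half-cycle


def _motion_dict(family: str, motion: str, rate) -> dict:
    if motion == "rotation":
        return {
            "kind": "rotation",
            "omega": float(rate),
            "reversal_period": REVERSAL_PERIOD,
        }
    if motion == "scaling":
        return {
            "kind": "scaling",
            "sigma": float(rate) / 100.0,
            "reversal_period": REVERSAL_PERIOD,
        }
    if motion == "shear":
        if family == "stereo":
            axis = float(rate) / 100.0
            freq = STEREO_SHEAR_FREQUENCY
        else:
            # per-second factor compounded over the 5 s half-cycle
            axis = (float(rate) / 100.0) ** (0.5 / COLOR_SHEAR_FREQUENCY)
            freq = COLOR_SHEAR_FREQUENCY
        return {"kind": "shear", "axis_factor": axis, "frequency": freq}
    if motion == "spiral":
        omega, pct = rate
        return {
            "kind": "spiral",
            "omega": float(omega),
            "sigma": float(pct) / 100.0,
            "reversal_period": REVERSAL_PERIOD,
        }
    raise ValueError(f"unknown motion class {motion!r}")


def _figure_dict(family: str, motion: str) -> dict:
    if motion == "rotation":
        profile = "flat_alternating" if family == "color_border" else "sinusoidal"
        return {
            "kind": "sector_wheel",
            "n_sectors": 8,
            "profile": profile,
            "phase": 0.0,
            "inner_radius_frac": 0.05,
        }
    if motion in ("scaling", "shear"):
        # ratio 1.5: at 117.6%/s the rings advance exactly two positions
        # (1.176**5 = 1.5**2) over the 5 s half-cycle
        return {
            "kind": "ring_stack",
            "a_frac": 0.1,
            "ratio": 1.5,
            "profile": "sinusoidal",
            "n_visible": 8,
        }
    if motion == "spiral":
        return {
            "kind": "spiral_bundle",
            "n_arms": 12,
            "pitch": SPIRAL_PITCH_350,
            "handedness": "right",
            "inner_radius_frac": 0.15,
        }
    raise ValueError(f"unknown motion class {motion!r}")


def _carrier_dict(family: str, motion: str) -> dict:
    if family == "stereo":
        if motion in ("scaling", "spiral"):
            # statistically scale-invariant dots for looming stimuli
            return {
                "kind": "eccentricity",
                "palette": "black_white",
                "density": 0.5,
                "exponent": 1.0,
                "base_size": 2,
                "e_ref": 300.0,
            }
        return {
            "kind": "uniform",
            "palette": "black_white",
            "density": 0.5,
            "dot_size": 3,
        }
    if family == "contrast":
        return {
            "kind": "uniform",
            "palette": "black_white",
            "density": 0.5,
            "dot_size": 2,
        }
    return {
        "kind": "uniform",
        "palette": "black_transparent",
        "density": 0.5,
        "dot_size": 4,
    }


def _paradigm(figure_rate, texture_rate, motion) -> str:
    neutral = 100.0 if motion in ("scaling", "shear") else 0.0

    def moving(rate):
        if isinstance(rate, tuple):
            return rate[0] != 0.0 or rate[1] != 100.0
        return float(rate) != neutral

    fig, tex = moving(figure_rate), moving(texture_rate)
    if fig and not tex:
        return "standstill"
    if tex and not fig:
        return "capture"
    return "joint"


def build_preset(name: str, **overrides) -> StimulusConfig:
    """Resolve a preset name to a full :class:`StimulusConfig`.

    ``overrides`` replace top-level config fields (resolution, fps, duration,
    seed, markers ...), which is how verification runs use smaller rasters.
    """
    if name in TABLE1:
        family, motion, fig_rate, tex_rate = TABLE1[name]
    elif name in EXTRA_PRESETS:
        family, motion, fig_rate, tex_rate = EXTRA_PRESETS[name]
    else:
        raise KeyError(
            f"unknown preset {name!r}; see list_presets()"
        )

    paradigm = _paradigm(fig_rate, tex_rate, motion)
    fig_motion = _motion_dict(family, motion, fig_rate)
    tex_motion = _motion_dict(family, motion, tex_rate)

    cfg = dict(
        name=name,
        family=family,
        figure=_figure_dict(family, motion),
        carrier=_carrier_dict(family, motion),
        paradigm=paradigm,
        figure_motion=fig_motion,
        carrier_motion=tex_motion,
        mask_palette=(
            "white_transparent" if name.endswith("_white") else "black_transparent"
        ),
        table1={"figure": fig_rate, "texture": tex_rate},
        **_DEFAULTS,
    )
    cfg.update(overrides)
    return StimulusConfig(**cfg)


def list_presets() -> list[str]:
    return list(PRESETS)
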