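"""Stimulus composition: from a config to a rendered frame stack.

The compositor owns the paradigm logic. For each frame time t it asks each
surface's motion schedule for its planar transform and dispatches to the
family renderer; which schedule is non-static is exactly what distinguishes
the paradigms:

* ``standstill`` — the figure moves, the carrier/mask stays put;
* ``joint`` — figure and carrier share one schedule (veridical motion);
* ``capture`` — the figure stays put, the carrier/mask moves;
* ``flicker`` — the carrier is regenerated (or jittered) every frame.

For ring-stack figures under scaling motion the scale is wrapped into
[1, ratio) (see :func:`~motionstill.schedules.wrap_scale`); because the ring
profile is log-periodic this changes nothing outside the masked annuli and
lets an expansion run forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import fields as _fields
from . import textures as _textures
from .config import StimulusConfig
from .frameio import srgb_encode
from .schedules import (
    MotionSchedule,
    PlanarTransform,
    rotation_schedule,
    scaling_schedule,
    shear_schedule,
    spiral_schedule,
    static_schedule,
    translation_schedule,
    triangle_time,
    wrap_scale,
)
from .stereo import StereoParams, render_anaglyph_frame
from .surfaces import (
    ColorPalette,
    add_markers,
    render_color_frame,
    render_contrast_frame,
    render_luminance_frame,
)

__all__ = [
    "FrameStack",
    "build_figure",
    "build_carrier",
    "build_schedule",
    "render_frame",
    "compose_stimulus",
    "partial_mask",
]


@dataclass
class FrameStack:
    """Ordered RGB frames plus the metadata needed to re-render them."""

    frames: np.ndarray  # (N, H, W, 3)
    fps: float
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def build_figure(config: StimulusConfig):
    """Resolve the config's figure dict to a FigureField.

    Fractional geometry keys (``a_frac``, ``inner_radius_frac``) scale with
    the short side of the resolution so one preset renders sensibly at any
    raster size.
    """
    spec = dict(config.figure)
    kind = spec.pop("kind")
    short = min(config.resolution)
    if kind == "sector_wheel":
        inner = spec.pop("inner_radius_frac", 0.0) * short
        return _fields.sector_wheel_field(
            n_sectors=spec.get("n_sectors", 8),
            profile=spec.get("profile", "sinusoidal"),
            phase=spec.get("phase", 0.0),
            inner_radius=spec.get("inner_radius", inner),
        )
    if kind == "ring_stack":
        a = spec.get("a", spec.get("a_frac", 0.055) * short)
        return _fields.ring_field(
            a=a,
            r=spec.get("ratio", 1.5),
            profile=spec.get("profile", "sinusoidal"),
            n_visible=spec.get("n_visible", 8),
        )
    if kind == "spiral_bundle":
        inner = spec.pop("inner_radius_frac", 0.0) * short
        return _fields.spiral_field(
            n_arms=spec.get("n_arms", 12),
            b=spec["pitch"],
            handedness=spec.get("handedness", "right"),
            inner_radius=spec.get("inner_radius", inner),
        )
    if kind == "linear_grating":
        return _fields.grating_field(
            period=spec.get("period", 256.0),
            waveform=spec.get("waveform", "sinusoidal"),
            orientation=spec.get("orientation", 0.0),
            phase=spec.get("phase", 0.0),
        )
    if kind == "uniform":
        return _fields.uniform_field(spec.get("value", 0.5))
    raise ValueError(f"unknown figure kind {kind!r}")


def build_carrier(config: StimulusConfig, seed: int | None = None):
    """Resolve the config's carrier dict to a CarrierTexture."""
    spec = dict(config.carrier) if config.carrier else {}
    kind = spec.pop("kind", "uniform")
    w, h = config.resolution
    palette = spec.pop("palette", None)
    if config.family in ("stereo", "contrast"):
        palette = "black_white"  # depth/contrast carriers are fully opaque
    elif config.family == "luminance":
        # the luminance mask's dot level follows the configured mask palette
        if palette in (None, "black_transparent"):
            palette = config.mask_palette
    elif palette is None:
        palette = "black_transparent"
    if seed is None:
        seed = config.seed
    if kind == "eccentricity":
        return _textures.eccentricity_texture(
            width=w,
            height=h,
            exponent=spec.get("exponent", 1.0),
            base_size=spec.get("base_size", 2),
            seed=seed,
            palette=palette,
            density=spec.get("density", 0.5),
            e_ref=spec.get("e_ref", 300.0),
        )
    return _textures.random_dot_texture(
        width=w,
        height=h,
        palette=palette,
        density=spec.get("density", 0.5),
        dot_size=spec.get("dot_size", 3),
        seed=seed,
    )


def build_schedule(motion: dict, center=(0.0, 0.0)) -> MotionSchedule:
    kind = motion.get("kind", "static")
    rev = motion.get("reversal_period")
    if kind == "static":
        return static_schedule()
    if kind == "rotation":
        return rotation_schedule(motion["omega"], rev, center)
    if kind == "scaling":
        return scaling_schedule(motion["sigma"], rev, center)
    if kind == "shear":
        return shear_schedule(motion["axis_factor"], motion["frequency"], center)
    if kind == "spiral":
        return spiral_schedule(motion["omega"], motion["sigma"], rev, center)
    if kind == "translation":
        return translation_schedule(motion["velocity"], rev)
    raise ValueError(f"unknown motion kind {kind!r}")


def _surface_transform(config: StimulusConfig, schedule: MotionSchedule, t: float):
    """Surface transform at t, with scale wrapping on ring-stack stimuli.

    When a ring stack expands, both the rings and the dot texture restart
    from the initial display each time they have advanced a whole number of
    ring positions; wrapping the scale into [1, ratio) implements that
    restoration for figure and carrier alike.
    """
    if (
        config.figure.get("kind") == "ring_stack"
        and schedule.kind == "scaling"
        and not schedule.is_static
    ):
        tau = triangle_time(t, schedule.reversal_period)
        s = schedule.rate["sigma"] ** tau
        ratio = config.figure.get("ratio", 1.5)
        s = wrap_scale(s, ratio)
        return PlanarTransform.from_linear(np.eye(2) * s, schedule.center)
    return schedule.transform_at(t)


def _stereo_params(config: StimulusConfig) -> StereoParams:
    return StereoParams(**config.stereo) if config.stereo else StereoParams()


def _palette(config: StimulusConfig) -> ColorPalette:
    kwargs = dict(config.palette)
    if config.family == "color_border":
        kwargs.setdefault("mix_law", "square")
    return ColorPalette(**kwargs)


def render_frame(
    config: StimulusConfig,
    t: float,
    figure=None,
    carrier=None,
):
    """Render the stimulus frame at time t.

    ``figure`` and ``carrier`` may be passed in to avoid rebuilding them per
    frame (compose_stimulus does); a flickering paradigm passes the current
    frame's carrier explicitly.
    """
    if figure is None:
        figure = build_figure(config)
    if carrier is None:
        carrier = build_carrier(config)
    w, h = config.resolution
    shape = (h, w)

    fig_schedule = build_schedule(config.figure_motion)
    car_schedule = build_schedule(config.carrier_motion)
    fig_T = _surface_transform(config, fig_schedule, t)
    car_T = _surface_transform(config, car_schedule, t)

    if config.mask_region_radius is not None:
        moving = _render_dispatch(config, figure, carrier, fig_T, car_T, shape, t)
        static = _render_dispatch(
            config, figure, carrier, fig_T, PlanarTransform.identity(), shape, t
        )
        grid = _fields.pixel_grid(w, h)
        disk = np.hypot(grid[..., 0], grid[..., 1]) <= config.mask_region_radius
        moving.rgb = np.where(disk[..., None], moving.rgb, static.rgb)
        if "unmasked" in moving.metadata and "unmasked" in static.metadata:
            moving.metadata["unmasked"] = np.where(
                disk, moving.metadata["unmasked"], static.metadata["unmasked"]
            )
        frame = moving
    else:
        frame = _render_dispatch(config, figure, carrier, fig_T, car_T, shape, t)

    add_markers(frame, config.markers, figure_transform=fig_T)
    frame.metadata["figure_transform"] = fig_T
    frame.metadata["carrier_transform"] = car_T
    return frame


def _render_dispatch(config, figure, carrier, fig_T, car_T, shape, t):
    family = config.family
    if family == "stereo":
        return render_anaglyph_frame(
            figure,
            carrier,
            _stereo_params(config),
            figure_transform=fig_T,
            carrier_transform=car_T,
            shape=shape,
            t=t,
        )
    if family in ("pure_color", "color_border"):
        return render_color_frame(
            figure,
            _palette(config),
            mask=carrier,
            figure_transform=fig_T,
            mask_transform=car_T,
            shape=shape,
            t=t,
        )
    if family == "contrast":
        return render_contrast_frame(
            figure,
            carrier,
            figure_transform=fig_T,
            carrier_transform=car_T,
            shape=shape,
            mean_level=config.mean_level,
            t=t,
        )
    if family == "luminance":
        return render_luminance_frame(
            figure,
            mask_palette=config.mask_palette,
            mask=carrier,
            figure_transform=fig_T,
            mask_transform=car_T,
            shape=shape,
            t=t,
        )
    raise ValueError(f"unknown family {family!r}")


def _check_paradigm(config: StimulusConfig):
    fig = build_schedule(config.figure_motion)
    car = build_schedule(config.carrier_motion)
    p = config.paradigm
    if p == "standstill":
        if not car.is_static:
            raise ValueError("standstill paradigm requires a static carrier/mask")
        if fig.is_static:
            raise ValueError("standstill paradigm requires a moving figure")
    elif p == "capture":
        if not fig.is_static:
            raise ValueError("capture paradigm requires a static figure")
        if car.is_static:
            raise ValueError("capture paradigm requires a moving carrier/mask")
    elif p == "joint":
        if config.figure_motion != config.carrier_motion:
            raise ValueError(
                "joint paradigm requires identical figure and carrier schedules"
            )


def compose_stimulus(config: StimulusConfig, dtype: str = "uint8") -> FrameStack:
    """Render the full stimulus run.

    Deterministic given the config (including its seed): same config, same
    bits. ``dtype='uint8'`` sRGB-encodes frames for export; ``'float32'``
    keeps linear light (large — use short durations).
    """
    _check_paradigm(config)
    figure = build_figure(config)
    n = config.n_frames
    w, h = config.resolution

    flicker = config.paradigm == "flicker"
    if flicker:
        carriers = _flicker_carriers(config, n)
    else:
        carrier = build_carrier(config)

    out_dtype = np.uint8 if dtype == "uint8" else np.float32
    frames = np.empty((n, h, w, 3), dtype=out_dtype)
    per_frame = []
    for i in range(n):
        t = i / config.fps
        if flicker:
            carrier = carriers[i]
        frame = render_frame(config, t, figure=figure, carrier=carrier)
        rgb = np.clip(frame.rgb, 0.0, 1.0)
        frames[i] = srgb_encode(rgb) if dtype == "uint8" else rgb.astype(np.float32)
        fT = frame.metadata["figure_transform"]
        cT = frame.metadata["carrier_transform"]
        per_frame.append(
            {
                "t": t,
                "figure_matrix": fT.matrix.tolist(),
                "figure_offset": fT.offset.tolist(),
                "carrier_matrix": cT.matrix.tolist(),
                "carrier_offset": cT.offset.tolist(),
            }
        )

    from .config import config_to_dict

    return FrameStack(
        frames=frames,
        fps=config.fps,
        metadata={
            "config": config_to_dict(config),
            "seed": config.seed,
            "encoding": "srgb8" if dtype == "uint8" else "linear-float32",
            "transforms": per_frame,
        },
    )


def _flicker_carriers(config: StimulusConfig, n_frames: int):
    """Per-frame carriers for the flicker paradigm.

    ``regenerate`` draws true dynamic noise; ``legacy_jitter`` perturbs one
    base raster by a small random similarity transform each frame.
    """
    spec = dict(config.carrier) if config.carrier else {}
    w, h = config.resolution
    probe = build_carrier(config)  # resolves the palette rules once
    params = {
        "kind": spec.get("kind", "uniform"),
        "width": w,
        "height": h,
        "palette": probe.palette,
        "density": spec.get("density", 0.5),
    }
    if params["kind"] == "eccentricity":
        params["exponent"] = spec.get("exponent", 1.0)
        params["base_size"] = spec.get("base_size", 2)
        params["e_ref"] = spec.get("e_ref", 300.0)
    else:
        params["dot_size"] = spec.get("dot_size", 3)
    return _textures.flicker_sequence(
        params, n_frames, mode=config.flicker_mode, seed=config.seed
    )


def partial_mask(config: StimulusConfig, mask_region_radius: float) -> StimulusConfig:
    """Restrict carrier/mask motion to a central disk.

    Inside the disk the carrier follows its schedule; outside it stays
    static — the split that makes, e.g., the inner part of a wheel appear to
    rotate while the outer part stands still. Radius 0 disables carrier
    motion everywhere (pure standstill); a radius beyond the frame diagonal
    is the plain moving-carrier stimulus.
    """
    if mask_region_radius < 0:
        raise ValueError(f"mask region radius must be >= 0, got {mask_region_radius}")
    import copy

    new = copy.deepcopy(config)
    new.mask_region_radius = float(mask_region_radius)
    return new
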