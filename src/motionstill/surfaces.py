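"""Color, contrast-modulated and luminance surface rendering.

Everything here works in linear-light RGB in [0, 1]; sRGB encoding happens
only at file-write time. That makes isoluminance exact by construction: the
default palette equates the Rec.709 luma of the red and green endpoints in
linear light, and because the colormap mixes the endpoints linearly, every
intermediate hue has the same luma.

The overlaid random-dot mask plays the role the carrier plays for stereo: it
is the luminance surface whose motion (or stillness) the figure's motion is
pitted against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import warnings

import numpy as np

from .fields import evaluate_field, pixel_grid
from .schedules import PlanarTransform

__all__ = [
    "ColorPalette",
    "Frame",
    "isoluminant_colormap",
    "render_color_frame",
    "render_contrast_frame",
    "render_luminance_frame",
    "add_markers",
]

REC709_LUMA = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class ColorPalette:
    """Isoluminant red/green endpoints in linear RGB.

    The default green channel level 0.2126/0.7152 makes
    luma(green) == luma(red) == 0.2126 under Rec.709 coefficients. Real
    displays need per-monitor calibration; both endpoints and the luma
    coefficients are overridable.
    """

    red_rgb: tuple[float, float, float] = (1.0, 0.0, 0.0)
    green_rgb: tuple[float, float, float] = (0.0, 0.2126 / 0.7152, 0.0)
    luma_coefficients: tuple[float, float, float] = REC709_LUMA
    mix_law: str = "sinusoidal"

    def __post_init__(self):
        if self.mix_law not in ("sinusoidal", "square"):
            raise ValueError(f"unknown mix law {self.mix_law!r}")

    def luma(self, rgb) -> np.ndarray:
        c = np.asarray(self.luma_coefficients, dtype=float)
        return np.asarray(rgb, dtype=float) @ c


@dataclass
class Frame:
    """(H, W, 3) linear-light RGB frame with rendering metadata."""

    rgb: np.ndarray
    metadata: dict = dc_field(default_factory=dict)


def isoluminant_colormap(value, palette: ColorPalette | None = None) -> np.ndarray:
    """Map figure values in [0, 1] to linear RGB between green and red.

    Value 0 is the green endpoint, 1 the red endpoint. The ``sinusoidal``
    mix law interpolates linearly in linear light (the field itself supplies
    the sinusoid, so hue varies smoothly); ``square`` thresholds at 1/2,
    yielding exactly the two endpoint colors with a sharp border.
    """
    if palette is None:
        palette = ColorPalette()
    v = np.asarray(value, dtype=float)
    if np.any((v < -1e-9) | (v > 1.0 + 1e-9)):
        raise ValueError("colormap value out of [0, 1]")
    if palette.mix_law == "square":
        w = (v >= 0.5).astype(float)
    else:
        w = v
    red = np.asarray(palette.red_rgb, dtype=float)
    green = np.asarray(palette.green_rgb, dtype=float)
    return w[..., None] * red + (1.0 - w[..., None]) * green


def _sample_mask(mask, mask_transform, grid):
    pts = grid
    if mask_transform is not None:
        pts = mask_transform.inverse().apply(pts)
    return mask.sample(pts)


def render_color_frame(
    figure,
    palette: ColorPalette | None = None,
    mask=None,
    figure_transform: PlanarTransform | None = None,
    mask_transform: PlanarTransform | None = None,
    shape: tuple[int, int] = (720, 1280),
    t: float = 0.0,
) -> Frame:
    """Isoluminant color figure under an optional random-dot mask.

    Opaque mask dots paint black over the colormapped figure; holes reveal
    it. Figure-masked pixels (e.g. the occluder annuli of a ring stack)
    render black as well and are excluded from the frame's unmasked-pixel
    flags.
    """
    if palette is None:
        palette = ColorPalette()
    h, w = shape
    grid = pixel_grid(w, h)
    values, fmasked = evaluate_field(figure, grid, figure_transform)
    values = np.clip(values, 0.0, 1.0)
    rgb = isoluminant_colormap(values, palette)
    rgb[fmasked] = 0.0
    covered = np.zeros((h, w), dtype=bool)
    if mask is not None:
        if mask.palette != "black_transparent":
            raise ValueError(
                "color stimuli use a black_transparent mask, got "
                f"{mask.palette!r}"
            )
        covered = _sample_mask(mask, mask_transform, grid)
        rgb[covered] = 0.0
    return Frame(
        rgb=rgb,
        metadata={
            "t": float(t),
            "unmasked": ~(fmasked | covered),
            "figure_values": values,
        },
    )


def render_contrast_frame(
    figure,
    carrier,
    figure_transform: PlanarTransform | None = None,
    carrier_transform: PlanarTransform | None = None,
    shape: tuple[int, int] = (720, 1280),
    mean_level: float = 0.5,
    t: float = 0.0,
) -> Frame:
    """Second-order (texture-contrast modulated) figure.

    The black/white carrier's contrast about ``mean_level`` is scaled by the
    figure value: pixel = mean + value * (carrier - mean). Figure value 0
    gives a uniform gray, value 1 the full-contrast carrier.
    """
    if carrier.palette != "black_white":
        raise ValueError(
            f"contrast carrier must be black_white, got {carrier.palette!r}"
        )
    h, w = shape
    grid = pixel_grid(w, h)
    values, fmasked = evaluate_field(figure, grid, figure_transform)
    values = np.clip(values, 0.0, 1.0)
    dots = _sample_mask(carrier, carrier_transform, grid)
    carrier_lum = np.where(dots, 0.0, 1.0)
    gray = mean_level + values * (carrier_lum - mean_level)
    gray = np.where(fmasked, mean_level, gray)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    return Frame(
        rgb=rgb,
        metadata={"t": float(t), "unmasked": ~fmasked, "figure_values": values},
    )


def render_luminance_frame(
    figure,
    mask_palette: str = "black_transparent",
    mask=None,
    figure_transform: PlanarTransform | None = None,
    mask_transform: PlanarTransform | None = None,
    shape: tuple[int, int] = (720, 1280),
    t: float = 0.0,
) -> Frame:
    """Grayscale luminance figure under a black- or white-dot mask."""
    if mask_palette not in ("black_transparent", "white_transparent"):
        raise ValueError(f"unknown mask palette {mask_palette!r}")
    h, w = shape
    grid = pixel_grid(w, h)
    values, fmasked = evaluate_field(figure, grid, figure_transform)
    gray = np.clip(values, 0.0, 1.0)
    gray = np.where(fmasked, 0.0, gray)
    covered = np.zeros((h, w), dtype=bool)
    if mask is not None:
        covered = _sample_mask(mask, mask_transform, grid)
        level = 0.0 if mask_palette == "black_transparent" else 1.0
        gray = np.where(covered, level, gray)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    return Frame(
        rgb=rgb,
        metadata={
            "t": float(t),
            "unmasked": ~(fmasked | covered),
            "figure_values": np.clip(values, 0.0, 1.0),
        },
    )


MARKER_YELLOW = (1.0, 1.0, 0.0)


def add_markers(
    frame,
    marker_spec: list[dict] | None,
    figure_transform: PlanarTransform | None = None,
    radius: float | None = None,
):
    """Composite yellow marker disks onto a frame (in place; returns frame).

    Each marker is ``{"rho": px, "theta": radians, "attach": "figure"|"static"}``
    in polar coordinates about the frame center. Markers attached to the
    figure move under the figure transform and reveal the figure's physical
    motion; static markers reveal its stillness. Markers landing outside the
    frame are clipped with a warning.
    """
    if not marker_spec:
        return frame
    rgb = frame.rgb if hasattr(frame, "rgb") else frame
    h, w = rgb.shape[:2]
    if radius is None:
        radius = 0.01 * h
    grid = pixel_grid(w, h)
    for spec in marker_spec:
        rho, theta = float(spec["rho"]), float(spec["theta"])
        p = np.array([rho * np.cos(theta), rho * np.sin(theta)])
        if spec.get("attach", "figure") == "figure" and figure_transform is not None:
            p = figure_transform.apply(p)
        if abs(p[0]) > w / 2.0 or abs(p[1]) > h / 2.0:
            warnings.warn(f"marker at {p} outside frame, clipped", stacklevel=2)
        disk = np.hypot(grid[..., 0] - p[0], grid[..., 1] - p[1]) <= radius
        rgb[disk] = MARKER_YELLOW
    return frame
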