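"""Red-cyan anaglyph random-dot stereogram rendering.

The figure field is a depth map: its value at each output pixel sets a
horizontal binocular disparity, and the two eyes sample the depth-encoding
random-dot carrier at horizontally offset positions. The left view goes to
the red channel, the right view to the green and blue (cyan) channels.

The central device of these stimuli is that the figure (depth) transform and
the carrier (luminance) transform are independent: disparity is computed
after moving the figure, and the carrier is sampled after moving the carrier.
A rotating depth map under a static carrier ("standstill" paradigm) and a
static depth map under a rotating carrier ("capture" paradigm) therefore
differ only in which surface the motion is attached to.

Disparity is split symmetrically between the eyes (+/- d/2 each, which
halves the per-eye image distortion). The carrier's own transform is sampled
nearest-neighbor, preserving the binary dot statistics of the cyclopean
view; the horizontal eye shift is then applied with linear interpolation
along x, so the rendered pair encodes the smooth disparity field at
sub-pixel precision instead of quantizing it to whole pixels (a 1-px
disparity staircase would put a step edge inside nearly every correlation
window of the verification decoder).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import evaluate_field, pixel_grid
from .schedules import PlanarTransform

__all__ = [
    "StereoParams",
    "AnaglyphFrame",
    "depth_to_disparity",
    "render_anaglyph_frame",
    "render_carrier_view",
]


@dataclass(frozen=True)
class StereoParams:
    """Disparity mapping for a depth figure.

    ``d_max`` is the disparity (px) assigned to figure value 1;
    ``zero_plane`` is the figure value placed at the display plane (zero
    disparity). With the ``uncrossed`` sign convention, values above the zero
    plane lie behind the display plane; ``crossed`` flips the sign.
    """

    d_max: float = 8.0
    sign_convention: str = "uncrossed"
    zero_plane: float = 0.0

    def __post_init__(self):
        if self.d_max < 0:
            raise ValueError(f"d_max must be >= 0, got {self.d_max}")
        if self.sign_convention not in ("uncrossed", "crossed"):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        if not 0.0 <= self.zero_plane <= 1.0:
            raise ValueError(f"zero_plane must lie in [0, 1], got {self.zero_plane}")


@dataclass
class AnaglyphFrame:
    """Rendered anaglyph: (H, W, 3) linear-light RGB in [0, 1].

    The green and blue channels are identical by construction. ``metadata``
    carries the rendering-time ground truth (the disparity map actually
    applied and the figure mask), which the verification layer checks
    against a block-matching decode.
    """

    rgb: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    @property
    def left(self) -> np.ndarray:
        return self.rgb[..., 0]

    @property
    def right(self) -> np.ndarray:
        return self.rgb[..., 1]


def depth_to_disparity(figure_value, params: StereoParams):
    """Map figure values in [0, 1] to signed disparities in pixels."""
    v = np.asarray(figure_value, dtype=float)
    if np.any((v < -1e-9) | (v > 1.0 + 1e-9)):
        raise ValueError("figure value out of [0, 1]")
    d = params.d_max * (v - params.zero_plane)
    if params.sign_convention == "crossed":
        d = -d
    return d


def render_anaglyph_frame(
    figure,
    carrier,
    stereo_params: StereoParams | None = None,
    figure_transform: PlanarTransform | None = None,
    carrier_transform: PlanarTransform | None = None,
    shape: tuple[int, int] = (720, 1280),
    t: float = 0.0,
) -> AnaglyphFrame:
    """Render one anaglyph frame of ``shape`` (H, W).

    For each output pixel p the depth value is looked up through the inverse
    figure transform, converted to a disparity d, and the carrier view
    (sampled through the inverse carrier transform) is read at p + (d/2, 0)
    for the left eye and p - (d/2, 0) for the right. Inverse mapping
    guarantees every output pixel is defined. Figure-masked pixels render
    black in both eyes and are flagged in the metadata.
    """
    if stereo_params is None:
        stereo_params = StereoParams()
    if carrier.palette != "black_white":
        raise ValueError(
            "stereo carrier must use the black_white palette, got "
            f"{carrier.palette!r}"
        )
    h, w = shape
    if carrier.shape[0] < h or carrier.shape[1] < w:
        raise ValueError(
            f"carrier {carrier.shape} smaller than frame {(h, w)}"
        )
    grid = pixel_grid(w, h)
    values, masked = evaluate_field(figure, grid, figure_transform)
    values = np.clip(values, 0.0, 1.0)
    d = depth_to_disparity(values, stereo_params)

    # cyclopean carrier view (nearest-neighbor keeps dots binary) ...
    pts = grid
    if carrier_transform is not None:
        pts = carrier_transform.inverse().apply(pts)
    view = np.where(carrier.sample(pts), 0.0, 1.0)  # dots black on white

    # ... then the half-disparity eye shifts, linear along x
    xs = np.arange(w, dtype=float)

    def eye_view(offset_x):
        out = np.empty_like(view)
        for row in range(h):
            out[row] = np.interp(xs + offset_x[row], xs, view[row])
        return out

    left = eye_view(d / 2.0)
    right = eye_view(-d / 2.0)
    left = np.where(masked, 0.0, left)
    right = np.where(masked, 0.0, right)

    rgb = np.empty((h, w, 3), dtype=float)
    rgb[..., 0] = left
    rgb[..., 1] = right
    rgb[..., 2] = right
    return AnaglyphFrame(
        rgb=rgb,
        metadata={
            "t": float(t),
            "d_max": stereo_params.d_max,
            "disparity_true": d,
            "masked": masked,
            "figure_values": values,
        },
    )


def render_carrier_view(
    carrier,
    carrier_transform: PlanarTransform | None = None,
    shape: tuple[int, int] = (720, 1280),
) -> np.ndarray:
    """Cyclopean (zero-disparity) luminance view of the carrier alone."""
    h, w = shape
    pts = pixel_grid(w, h)
    if carrier_transform is not None:
        pts = carrier_transform.inverse().apply(pts)
    dots = carrier.sample(pts)
    return np.where(dots, 0.0, 1.0)
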