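"""Analytic figure fields.

A figure field is a continuous scalar map f(x, y) -> [0, 1] describing the
structure of the underlying surface of a motion-transparency stimulus: depth
for stereograms, hue phase for isoluminant color stimuli, a contrast envelope
for second-order stimuli, or brightness for plain luminance stimuli.

Coordinate conventions used throughout the package: the origin sits at the
image center, x grows rightward, y grows downward (raster convention), and the
polar angle ``theta = atan2(y, x)`` therefore increases clockwise on screen.
Lengths are in pixels of the target raster.

Every constructor returns a :class:`FigureField` whose geometry makes the
relevant motion an exact symmetry:

* ``sector_wheel`` with ``n`` sectors is invariant under rotation by ``2*pi/n``;
* ``ring_stack`` with ratio ``r`` is invariant under uniform scaling by ``r``
  (its profile is a sinusoid in log-radius, so ring radii follow the geometric
  sequence ``a * r**(n-1)``);
* ``spiral_bundle`` with pitch ``b`` turns rotation into scaling: rotating the
  sample points by ``dtheta`` equals scaling them by ``exp(b*dtheta)``.

These exact symmetries are what let the renderers loop the motion seamlessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "FigureField",
    "sector_wheel_field",
    "ring_field",
    "spiral_field",
    "grating_field",
    "uniform_field",
    "evaluate_field",
    "pixel_grid",
]


@dataclass(frozen=True)
class FigureField:
    """A scalar field on the plane with an optional masked region.

    Attributes
    ----------
    kind:
        One of ``sector_wheel``, ``flat_sectors``, ``ring_stack``,
        ``spiral_bundle``, ``linear_grating``, ``uniform``.
    params:
        The per-kind geometry parameters, kept for serialization.
    center:
        Field center in centered pixel coordinates.
    """

    kind: str
    params: dict
    value_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    mask_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    center: tuple[float, float] = (0.0, 0.0)

    def __call__(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate at an (..., 2) array of (x, y) points.

        Returns ``(values, masked)`` where ``masked`` is a boolean array
        flagging points inside occluded regions (values there are still
        defined but are not meant to be shown).
        """
        pts = np.asarray(points, dtype=float)
        x = pts[..., 0] - self.center[0]
        y = pts[..., 1] - self.center[1]
        values = self.value_fn(x, y)
        if self.mask_fn is None:
            masked = np.zeros(np.shape(values), dtype=bool)
        else:
            masked = self.mask_fn(x, y)
        return values, masked


def sector_wheel_field(
    n_sectors: int,
    profile: str = "sinusoidal",
    phase: float = 0.0,
    inner_radius: float = 0.0,
) -> FigureField:
    """Wheel of ``n_sectors`` angular sectors.

    ``sinusoidal`` gives ``(1 + cos(n*(theta - phase))) / 2`` over the polar
    angle, peaking at the sector centers; ``flat_alternating`` thresholds the
    same sinusoid at 1/2, producing two levels that switch every
    ``pi/n_sectors`` radians. ``inner_radius`` masks a central hub (the
    angular profile degenerates at the pole).
    """
    if n_sectors < 1:
        raise ValueError(f"n_sectors must be >= 1, got {n_sectors}")
    if profile not in ("sinusoidal", "flat_alternating"):
        raise ValueError(f"unknown sector profile {profile!r}")

    n = int(n_sectors)

    def value(x, y):
        theta = np.arctan2(y, x)
        c = np.cos(n * (theta - phase))
        if profile == "flat_alternating":
            return (c >= 0.0).astype(float)
        return 0.5 * (1.0 + c)

    mask = None
    if inner_radius > 0.0:
        r0 = float(inner_radius)

        def mask(x, y):  # noqa: F811 - intentional rebind
            return np.hypot(x, y) < r0

    kind = "flat_sectors" if profile == "flat_alternating" else "sector_wheel"
    return FigureField(
        kind=kind,
        params={
            "n_sectors": n,
            "profile": profile,
            "phase": float(phase),
            "inner_radius": float(inner_radius),
        },
        value_fn=value,
        mask_fn=mask,
    )


def ring_field(
    a: float,
    r: float,
    profile: str = "sinusoidal",
    n_visible: int = 8,
) -> FigureField:
    """Concentric rings whose radii follow the geometric sequence a*r**(n-1).

    The profile is a sinusoid in log-radius with period ``ln r``, so uniform
    scaling by ``r`` maps the field exactly onto itself; that symmetry is what
    the scaling stimuli exploit to wrap an unbounded expansion. The innermost
    annulus (inside ``a*r``) and everything outside ``a*r**(n_visible-1)`` are
    flagged masked, hiding the wrap seam.
    """
    if a <= 0:
        raise ValueError(f"initial radius a must be > 0, got {a}")
    if r <= 1:
        raise ValueError(f"common ratio r must be > 1, got {r}")
    if profile not in ("sinusoidal", "two_color"):
        raise ValueError(f"unknown ring profile {profile!r}")
    if n_visible < 2:
        raise ValueError(f"n_visible must be >= 2, got {n_visible}")

    log_a, log_r = np.log(a), np.log(r)
    inner = a * r
    outer = a * r ** (n_visible - 1)

    def value(x, y):
        rho = np.hypot(x, y)
        with np.errstate(divide="ignore"):
            u = (np.log(np.maximum(rho, 1e-300)) - log_a) / log_r
        v = 0.5 * (1.0 + np.cos(2.0 * np.pi * u))
        if profile == "two_color":
            return (np.cos(2.0 * np.pi * u) >= 0.0).astype(float)
        return v

    def mask(x, y):
        rho = np.hypot(x, y)
        return (rho < inner) | (rho > outer)

    return FigureField(
        kind="ring_stack",
        params={
            "a": float(a),
            "r": float(r),
            "profile": profile,
            "n_visible": int(n_visible),
        },
        value_fn=value,
        mask_fn=mask,
    )


def ring_radii(a: float, r: float, n: int) -> np.ndarray:
    """Radii of the first ``n`` rings, ``a * r**(k-1)`` for k = 1..n."""
    return a * r ** np.arange(n, dtype=float)


def spiral_field(
    n_arms: int,
    b: float,
    handedness: str = "right",
    a: float = 1.0,
    inner_radius: float = 0.0,
) -> FigureField:
    """Bundle of ``n_arms`` logarithmic spiral arms with pitch ``b``.

    The value is a sinusoid in the spiral phase
    ``psi = theta + ln(rho/a)/b`` (right-handed; the left-handed bundle flips
    the sign of the radial term), with ``n_arms`` cycles per turn. Because
    psi is constant along each arm, rotating the sample points by ``dtheta``
    is exactly equivalent to scaling them by ``exp(b*dtheta)`` — the property
    that makes rotation and expansion interchangeable for these stimuli.
    ``inner_radius`` masks a central hub, where the arm spacing collapses
    below pixel scale.
    """
    if n_arms < 1:
        raise ValueError(f"n_arms must be >= 1, got {n_arms}")
    if b == 0:
        raise ValueError("pitch b must be non-zero (b=0 degenerates to a wheel)")
    if handedness not in ("right", "left"):
        raise ValueError(f"handedness must be 'right' or 'left', got {handedness!r}")

    n = int(n_arms)
    sgn = 1.0 if handedness == "right" else -1.0
    log_a = np.log(a)

    def value(x, y):
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        with np.errstate(divide="ignore"):
            psi = theta + sgn * (np.log(np.maximum(rho, 1e-300)) - log_a) / b
        return 0.5 * (1.0 + np.cos(n * psi))

    mask = None
    if inner_radius > 0.0:
        r0 = float(inner_radius)

        def mask(x, y):  # noqa: F811 - intentional rebind
            return np.hypot(x, y) < r0

    return FigureField(
        kind="spiral_bundle",
        params={
            "n_arms": n,
            "b": float(b),
            "handedness": handedness,
            "a": float(a),
            "inner_radius": float(inner_radius),
        },
        value_fn=value,
        mask_fn=mask,
    )


def grating_field(
    period: float,
    waveform: str = "sinusoidal",
    orientation: float = 0.0,
    phase: float = 0.0,
) -> FigureField:
    """Linear grating of the given spatial period (px) and orientation (rad).

    ``value = (1 + cos(2*pi*u/period + phase)) / 2`` along the axis
    ``u = x*cos(orientation) + y*sin(orientation)``; the square waveform
    thresholds at 1/2 and takes exactly two values.
    """
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period}")
    if waveform not in ("sinusoidal", "square"):
        raise ValueError(f"unknown waveform {waveform!r}")
    cx, cy = np.cos(orientation), np.sin(orientation)

    def value(x, y):
        u = x * cx + y * cy
        c = np.cos(2.0 * np.pi * u / period + phase)
        if waveform == "square":
            return (c >= 0.0).astype(float)
        return 0.5 * (1.0 + c)

    return FigureField(
        kind="linear_grating",
        params={
            "period": float(period),
            "waveform": waveform,
            "orientation": float(orientation),
            "phase": float(phase),
        },
        value_fn=value,
    )


def uniform_field(value: float = 0.5) -> FigureField:
    """Constant field (flat depth / single color)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"uniform value must lie in [0, 1], got {value}")
    v = float(value)
    return FigureField(
        kind="uniform",
        params={"value": v},
        value_fn=lambda x, y: np.full(np.shape(x), v, dtype=float),
    )


def evaluate_field(field, points, transform=None):
    """Evaluate ``field`` at ``points`` moved by ``transform`` (inverse map).

    The transform describes the motion of the *field*; each output point p is
    therefore looked up at ``transform^{-1}(p)``, the shader-style inverse
    mapping that leaves no holes. Returns ``(values, masked)``.
    """
    pts = np.asarray(points, dtype=float)
    if transform is not None:
        pts = transform.inverse().apply(pts)
    return field(pts)


def pixel_grid(width: int, height: int) -> np.ndarray:
    """(H, W, 2) array of pixel-center coordinates, origin at image center."""
    xs = np.arange(width, dtype=float) - (width - 1) / 2.0
    ys = np.arange(height, dtype=float) - (height - 1) / 2.0
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx, gy], axis=-1)


# registry used by the config layer
FIELD_KINDS: dict[str, Callable] = {
    "sector_wheel": sector_wheel_field,
    "ring_stack": ring_field,
    "spiral_bundle": spiral_field,
    "linear_grating": grating_field,
    "uniform": uniform_field,
}
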