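"""Time-parameterized planar transforms for stimulus surfaces.

A :class:`MotionSchedule` maps time (seconds) to a :class:`PlanarTransform`
for one surface — the figure, the depth-encoding carrier, or the overlaid
mask. The five motion classes are the components of planar optic flow:
rotation, scaling (looming), pure shear (area-conserving), spiraling
(rotation + scaling), and translation.

Direction reversal ("back and forth") uses triangle-wave time integration:
the surface moves at constant speed and reverses instantaneously every
``reversal_period`` seconds, so after two periods it is back at its start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "PlanarTransform",
    "MotionSchedule",
    "rotation_schedule",
    "scaling_schedule",
    "shear_schedule",
    "spiral_schedule",
    "translation_schedule",
    "static_schedule",
    "wrap_scale",
    "triangle_time",
]


@dataclass(frozen=True)
class PlanarTransform:
    """Affine map p -> A p + t with an invertible 2x2 linear part A."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        o = np.asarray(self.offset, dtype=float).reshape(2)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", o)
        if abs(float(np.linalg.det(m))) < 1e-12:
            raise ValueError("singular transform (|det| < 1e-12)")

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_linear(cls, matrix, center=(0.0, 0.0)) -> "PlanarTransform":
        """Linear map applied about a fixed point ``center``."""
        m = np.asarray(matrix, dtype=float).reshape(2, 2)
        c = np.asarray(center, dtype=float).reshape(2)
        return cls(m, c - m @ c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        # elementwise rather than matmul: identical bit patterns regardless
        # of the batch shape (BLAS kernels vary with operand shape)
        pts = np.asarray(points, dtype=float)
        x, y = pts[..., 0], pts[..., 1]
        m, o = self.matrix, self.offset
        return np.stack(
            [m[0, 0] * x + m[0, 1] * y + o[0], m[1, 0] * x + m[1, 1] * y + o[1]],
            axis=-1,
        )

    def inverse(self) -> "PlanarTransform":
        inv = np.linalg.inv(self.matrix)
        return PlanarTransform(inv, -inv @ self.offset)

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return PlanarTransform(
            self.matrix @ other.matrix, self.matrix @ other.offset + self.offset
        )

    __matmul__ = compose

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.matrix, np.eye(2), atol=tol)
            and np.allclose(self.offset, 0.0, atol=tol)
        )


def triangle_time(t: float, reversal_period: float | None) -> float:
    """Signed elapsed motion time under back-and-forth reversal.

    Integrates a +/-1 square wave of half-period ``reversal_period``:
    the result ramps 0 -> T over the first period, back to 0 over the
    second, and repeats. ``None`` means no reversal (tau = t).
    """
    if reversal_period is None:
        return float(t)
    T = float(reversal_period)
    tm = math.fmod(float(t), 2.0 * T)
    if tm < 0:
        tm += 2.0 * T
    return tm if tm <= T else 2.0 * T - tm


@dataclass(frozen=True)
class MotionSchedule:
    """Time -> PlanarTransform for one surface."""

    kind: str  # rotation | scaling | shear | spiral | translation | static
    rate: dict = dc_field(default_factory=dict)
    reversal_period: float | None = None
    center: tuple[float, float] = (0.0, 0.0)

    def transform_at(self, t: float) -> PlanarTransform:
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        tau = triangle_time(t, self.reversal_period)
        c = self.center
        if self.kind == "static":
            return PlanarTransform.identity()
        if self.kind == "rotation":
            ang = math.radians(self.rate["omega"] * tau)
            m = _rot(ang)
            return PlanarTransform.from_linear(m, c)
        if self.kind == "scaling":
            s = self.rate["sigma"] ** tau
            return PlanarTransform.from_linear(np.eye(2) * s, c)
        if self.kind == "spiral":
            ang = math.radians(self.rate["omega"] * tau)
            s = self.rate["sigma"] ** tau
            return PlanarTransform.from_linear(_rot(ang) * s, c)
        if self.kind == "shear":
            # log-sinusoidal oscillation of the axis factor: s(0)=1, s at the
            # half-cycle peak equals axis_factor, det == 1 throughout.
            f = self.rate["frequency"]
            amp = self.rate["axis_factor"]
            s = amp ** (0.5 * (1.0 - math.cos(2.0 * math.pi * f * float(t))))
            return PlanarTransform.from_linear(np.diag([s, 1.0 / s]), c)
        if self.kind == "translation":
            v = np.asarray(self.rate["velocity"], dtype=float)
            return PlanarTransform(np.eye(2), v * tau)
        raise ValueError(f"unknown schedule kind {self.kind!r}")

    @property
    def is_static(self) -> bool:
        if self.kind == "static":
            return True
        if self.kind == "rotation":
            return self.rate["omega"] == 0
        if self.kind == "scaling":
            return self.rate["sigma"] == 1
        if self.kind == "spiral":
            return self.rate["omega"] == 0 and self.rate["sigma"] == 1
        if self.kind == "shear":
            return self.rate["axis_factor"] == 1
        if self.kind == "translation":
            return not np.any(np.asarray(self.rate["velocity"]))
        return False


def _rot(angle_rad: float) -> np.ndarray:
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    # positive angle rotates clockwise on screen (y grows downward)
    return np.array([[ca, -sa], [sa, ca]])


def rotation_schedule(
    omega: float, reversal_period: float | None = None, center=(0.0, 0.0)
) -> MotionSchedule:
    """Constant rotation at ``omega`` deg/s (positive = clockwise on screen)."""
    return MotionSchedule(
        "rotation", {"omega": float(omega)}, reversal_period, tuple(center)
    )


def scaling_schedule(
    sigma: float, reversal_period: float | None = None, center=(0.0, 0.0)
) -> MotionSchedule:
    """Exponential scaling: scale(t) = sigma**t (sigma is the factor per second)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return MotionSchedule(
        "scaling", {"sigma": float(sigma)}, reversal_period, tuple(center)
    )


def shear_schedule(
    axis_factor: float, frequency: float, center=(0.0, 0.0)
) -> MotionSchedule:
    """Pure shear: diag(s(t), 1/s(t)) with s oscillating between 1 and
    ``axis_factor`` at ``frequency`` Hz. Area is conserved by construction
    (det == 1). ``axis_factor`` is the horizontal factor reached at the
    half-cycle peak; factors < 1 describe horizontal compression."""
    if axis_factor <= 0:
        raise ValueError(f"axis_factor must be > 0, got {axis_factor}")
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    return MotionSchedule(
        "shear",
        {"axis_factor": float(axis_factor), "frequency": float(frequency)},
        None,
        tuple(center),
    )


def spiral_schedule(
    omega: float,
    sigma: float,
    reversal_period: float | None = None,
    center=(0.0, 0.0),
) -> MotionSchedule:
    """Rotation at ``omega`` deg/s composed with scaling at ``sigma`` per second
    about a common center."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return MotionSchedule(
        "spiral",
        {"omega": float(omega), "sigma": float(sigma)},
        reversal_period,
        tuple(center),
    )


def translation_schedule(
    velocity, reversal_period: float | None = None
) -> MotionSchedule:
    """Uniform translation at ``velocity`` px/s (vx, vy)."""
    v = np.asarray(velocity, dtype=float).reshape(2)
    return MotionSchedule("translation", {"velocity": tuple(v)}, reversal_period)


def static_schedule() -> MotionSchedule:
    return MotionSchedule("static")


def wrap_scale(scale: float, ratio: float) -> float:
    """Canonical scale in [1, ratio) equivalent to ``scale`` on a log-periodic
    ring stack of common ratio ``ratio``.

    Returns ``scale * ratio**(-k)`` for the unique integer k that lands the
    result in [1, ratio); rendering at the wrapped scale is pixel-identical
    outside the masked annuli, which is how an unbounded expansion loops.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if ratio <= 1:
        raise ValueError(f"ratio must be > 1, got {ratio}")
    k = math.floor(math.log(scale) / math.log(ratio))
    w = scale * ratio ** (-k)
    # guard against boundary rounding
    if w >= ratio:
        w /= ratio
    elif w < 1.0:
        w *= ratio
    return w
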