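"""Motion schedules: reversal integration, group structure, area conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionstill import (
    rotation_schedule,
    scaling_schedule,
    shear_schedule,
    spiral_schedule,
    static_schedule,
    translation_schedule,
    wrap_scale,
)
from motionstill.schedules import PlanarTransform, triangle_time


def test_all_schedules_start_at_identity():
    schedules = [
        rotation_schedule(12.0),
        scaling_schedule(1.176),
        shear_schedule(1.2, 0.2),
        spiral_schedule(9.0, 1.079),
        translation_schedule((16.3, 0.0)),
        static_schedule(),
    ]
    for s in schedules:
        assert s.transform_at(0.0).is_identity(tol=1e-12)


def test_rotation_rate_and_reversal():
    s = rotation_schedule(12.0)
    T = s.transform_at(1.0)
    ang = math.degrees(math.atan2(T.matrix[1, 0], T.matrix[0, 0]))
    assert ang == pytest.approx(12.0, abs=1e-9)
    # back and forth at 6 deg/s with 5 s reversal: net zero after 10 s
    s = rotation_schedule(6.0, reversal_period=5.0)
    assert s.transform_at(10.0).is_identity(tol=1e-9)
    assert rotation_schedule(0.0).transform_at(3.0).is_identity()


def test_scaling_rate_examples():
    assert scaling_schedule(1.176).transform_at(1.0).matrix[0, 0] == pytest.approx(
        1.176
    )
    # 107.9 %/s compounds to ~146% over the 5 s half-cycle
    s5 = scaling_schedule(1.079).transform_at(5.0).matrix[0, 0]
    assert s5 == pytest.approx(1.079**5)
    assert s5 == pytest.approx(1.4626, abs=2e-4)
    assert scaling_schedule(1.0).transform_at(7.0).is_identity()
    with pytest.raises(ValueError):
        scaling_schedule(0.0)


def test_rotation_and_scaling_compose_as_groups(rng):
    center = (3.0, -2.0)
    for sched in (
        rotation_schedule(12.0, center=center),
        scaling_schedule(1.176, center=center),
        spiral_schedule(9.0, 1.079, center=center),
    ):
        for _ in range(20):
            t1, t2 = rng.uniform(0.0, 5.0, size=2)
            lhs = sched.transform_at(t1 + t2)
            rhs = sched.transform_at(t1) @ sched.transform_at(t2)
            assert np.abs(lhs.matrix - rhs.matrix).max() < 1e-9
            assert np.abs(lhs.offset - rhs.offset).max() < 1e-9


def test_shear_conserves_area_and_cycles(rng):
    s = shear_schedule(1.2, 0.2)
    for t in rng.uniform(0.0, 30.0, size=1000):
        assert abs(s.transform_at(t).det - 1.0) < 1e-9
    # vertical factor at max shear is the reciprocal
    peak = s.transform_at(2.5)  # half-cycle of 0.2 Hz
    assert peak.matrix[0, 0] == pytest.approx(1.2, abs=1e-9)
    assert peak.matrix[1, 1] == pytest.approx(1.0 / 1.2, abs=1e-9)
    assert s.transform_at(5.0).is_identity(tol=1e-9)  # full cycle


def test_shear_preserves_polygon_area(rng):
    s = shear_schedule(1.2, 0.2)
    pts = rng.uniform(-100, 100, size=(12, 2))
    hull = pts[np.argsort(np.arctan2(pts[:, 1], pts[:, 0]))]

    def area(p):
        x, y = p[:, 0], p[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    a0 = area(hull)
    for t in rng.uniform(0.0, 10.0, size=50):
        assert area(s.transform_at(t).apply(hull)) == pytest.approx(a0, rel=1e-6)


def test_spiral_schedule_reduces_to_components():
    t = 2.3
    rot = spiral_schedule(9.0, 1.0).transform_at(t)
    assert np.allclose(rot.matrix, rotation_schedule(9.0).transform_at(t).matrix)
    scl = spiral_schedule(0.0, 1.079).transform_at(t)
    assert np.allclose(scl.matrix, scaling_schedule(1.079).transform_at(t).matrix)
    # 9 deg/s for 5 s with scale(5 s) = 1.46: 45 deg plus 1.46x
    sched = spiral_schedule(9.0, 1.46 ** (1.0 / 5.0))
    T = sched.transform_at(5.0)
    scale = math.hypot(T.matrix[0, 0], T.matrix[1, 0])
    ang = math.degrees(math.atan2(T.matrix[1, 0], T.matrix[0, 0]))
    assert scale == pytest.approx(1.46, rel=1e-9)
    assert ang == pytest.approx(45.0, abs=1e-9)


def test_translation_offsets_and_reversal():
    s = translation_schedule((16.3, 0.0))
    assert np.allclose(s.transform_at(1.0).offset, [16.3, 0.0])
    s = translation_schedule((256.0, 0.0), reversal_period=5.0)
    assert np.allclose(s.transform_at(10.0).offset, 0.0)
    # 256 px/s over a 256-px grating period: one cycle per second
    assert translation_schedule((256.0, 0.0)).transform_at(1.0).offset[0] == 256.0


def test_transform_round_trip_precision(rng):
    T = spiral_schedule(13.0, 1.1, center=(5.0, 7.0)).transform_at(3.3)
    pts = rng.uniform(-500, 500, size=(200, 2))
    back = T.inverse().apply(T.apply(pts))
    assert np.abs(back - pts).max() < 1e-9


def test_rotation_full_turn_is_field_identity():
    T = rotation_schedule(12.0).transform_at(30.0)  # 360 degrees
    assert T.is_identity(tol=1e-9)


def test_transform_matches_explicit_trig_oracle():
    omega, t = 12.0, 2.1
    T = rotation_schedule(omega).transform_at(t)
    a = math.radians(omega * t)
    oracle = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    assert np.abs(T.matrix - oracle).max() < 1e-12


def test_wrap_scale_examples_and_oracle():
    assert wrap_scale(2.25, 1.5) == pytest.approx(1.0)
    assert wrap_scale(1.0, 1.5) == 1.0
    # brute force over k for 0.9: 0.9 * 1.5 = 1.35 is the canonical value
    assert wrap_scale(0.9, 1.5) == pytest.approx(1.35)


@settings(deadline=None, max_examples=200)
@given(
    scale=st.floats(1e-3, 1e3),
    ratio=st.floats(1.01, 4.0),
)
def test_wrap_scale_properties(scale, ratio):
    w = wrap_scale(scale, ratio)
    assert 1.0 <= w < ratio
    # w differs from scale by an exact power of the ratio
    k = math.log(scale / w) / math.log(ratio)
    assert abs(k - round(k)) < 1e-6


@settings(deadline=None, max_examples=100)
@given(t=st.floats(0.0, 100.0), period=st.floats(0.5, 20.0))
def test_triangle_time_bounds_and_period(t, period):
    tau = triangle_time(t, period)
    assert 0.0 <= tau <= period
    assert triangle_time(t + 2.0 * period, period) == pytest.approx(tau, abs=1e-6)
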