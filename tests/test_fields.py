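"""Figure-field geometry: ranges, exact symmetries, inverse-map evaluation."""

import math

import numpy as np
import pytest

from motionstill import (
    evaluate_field,
    grating_field,
    ring_field,
    sector_wheel_field,
    spiral_field,
    uniform_field,
)
from motionstill.fields import pixel_grid, ring_radii
from motionstill.schedules import PlanarTransform, rotation_schedule

from conftest import rotation_matrix


ALL_FIELDS = [
    sector_wheel_field(8),
    sector_wheel_field(12, profile="flat_alternating"),
    ring_field(a=40.0, r=1.5),
    spiral_field(12, b=0.5),
    grating_field(256.0),
    grating_field(64.0, waveform="square", orientation=0.3),
    uniform_field(0.25),
]


@pytest.mark.parametrize("field", ALL_FIELDS, ids=lambda f: f.kind)
def test_values_stay_in_unit_interval(field, rng):
    pts = rng.uniform(-1000.0, 1000.0, size=(1_000_000, 2))
    values, _ = field(pts)
    assert values.min() >= 0.0
    assert values.max() <= 1.0


def test_sector_wheel_peaks_at_sector_centers():
    field = sector_wheel_field(8, profile="sinusoidal", phase=0.0)
    v, _ = field(np.array([[100.0, 0.0]]))  # theta = 0: cosine peak
    assert v[0] == pytest.approx(1.0, abs=1e-12)
    # trough mid-sector
    t = math.pi / 8
    v, _ = field(np.array([[100 * math.cos(t), 100 * math.sin(t)]]))
    assert v[0] == pytest.approx(0.0, abs=1e-12)


def test_sector_wheel_rotation_symmetry(points):
    field = sector_wheel_field(8)
    R = rotation_matrix(2.0 * math.pi / 8)
    v1, _ = field(points)
    v2, _ = field(points @ R.T)
    assert np.abs(v1 - v2).max() < 1e-9


def test_flat_sectors_are_two_valued_and_symmetric(points):
    field = sector_wheel_field(12, profile="flat_alternating")
    v, _ = field(points)
    assert set(np.unique(v)) <= {0.0, 1.0}
    R = rotation_matrix(2.0 * math.pi / 12)
    v2, _ = field(points @ R.T)
    assert np.abs(v - v2).max() < 1e-9
    # value switches every pi/12: rotating by half that flips the parity of
    # points at sector centers
    centers = np.array(
        [[50 * math.cos(k * math.pi / 6), 50 * math.sin(k * math.pi / 6)]
         for k in range(12)]
    )
    vc, _ = field(centers)
    vs, _ = field(centers @ rotation_matrix(math.pi / 12).T)
    assert not np.array_equal(vc, vs)


def test_ring_radii_follow_geometric_sequence():
    assert np.allclose(ring_radii(0.1, 1.5, 3), [0.1, 0.15, 0.225])


def test_ring_field_scale_symmetry_and_masking(points):
    field = ring_field(a=40.0, r=1.5, n_visible=8)
    v1, m1 = field(points)
    v2, m2 = field(points * 1.5)
    # log-periodicity: scaling by r is exact on values everywhere
    assert np.abs(v1 - v2).max() < 1e-9
    # innermost/outermost annuli flagged
    rho = np.hypot(points[:, 0], points[:, 1])
    inner = rho < 40.0 * 1.5
    assert np.array_equal(m1, inner | (rho > 40.0 * 1.5**7))


def test_ring_two_color_profile_is_binary():
    field = ring_field(a=40.0, r=1.5, profile="two_color")
    v, _ = field(pixel_grid(64, 64))
    assert set(np.unique(v)) <= {0.0, 1.0}


@pytest.mark.parametrize("handedness,sign", [("right", 1.0), ("left", -1.0)])
def test_spiral_rotation_equals_scaling(points, handedness, sign):
    b = 0.5
    field = spiral_field(12, b=b, handedness=handedness)
    dtheta = math.radians(10.0)
    v_rot, _ = field(points @ rotation_matrix(dtheta).T)
    v_scl, _ = field(points * math.exp(sign * b * dtheta))
    assert np.abs(v_rot - v_scl).max() < 1e-9


def test_spiral_pitch_for_350_percent_per_quarter_turn():
    # e^{b*pi/2} = 3.5 -> b = 2 ln 3.5 / pi
    b = 2.0 * math.log(3.5) / math.pi
    assert math.exp(b * math.pi / 2.0) == pytest.approx(3.5, rel=1e-12)


def test_grating_periodicity_and_square_levels(rng):
    g = grating_field(256.0)
    x = rng.uniform(-500, 500, size=(500, 2))
    v1, _ = g(x)
    v2, _ = g(x + [256.0, 0.0])
    assert np.abs(v1 - v2).max() < 1e-9
    v, _ = g(np.array([[0.0, 0.0]]))
    assert v[0] == pytest.approx(1.0)
    sq = grating_field(64.0, waveform="square")
    vs, _ = sq(rng.uniform(-500, 500, size=(2000, 2)))
    assert set(np.unique(vs)) == {0.0, 1.0}


def test_field_constructor_validation():
    with pytest.raises(ValueError):
        sector_wheel_field(0)
    with pytest.raises(ValueError):
        ring_field(a=1.0, r=0.9)
    with pytest.raises(ValueError):
        spiral_field(12, b=0.0)
    with pytest.raises(ValueError):
        grating_field(-1.0)


def test_evaluate_field_matches_per_point_oracle(points):
    field = sector_wheel_field(8)
    T = rotation_schedule(12.0).transform_at(1.7)
    values, _ = evaluate_field(field, points, T)
    inv = T.inverse()
    for p, v in zip(points[:100], values[:100]):
        q = inv.apply(p)
        v_single, _ = field(q[None, :])
        assert v_single[0] == v  # bit-for-bit


def test_evaluate_field_identity_and_symmetry(points):
    field = sector_wheel_field(8)
    direct, _ = field(points)
    via_eval, _ = evaluate_field(field, points, PlanarTransform.identity())
    assert np.array_equal(direct, via_eval)
    T = rotation_schedule(45.0).transform_at(1.0)  # 45 deg = 2 pi / 8
    rotated, _ = evaluate_field(field, points, T)
    assert np.abs(direct - rotated).max() < 1e-9


def test_uniform_field_constant_under_any_transform(points):
    field = uniform_field(0.3)
    T = PlanarTransform(np.array([[1.2, 0.3], [0.1, 0.9]]), np.array([5.0, -2.0]))
    v, _ = evaluate_field(field, points, T)
    assert np.all(v == 0.3)


def test_singular_transform_rejected():
    with pytest.raises(ValueError, match="singular"):
        PlanarTransform(np.array([[1.0, 0.0], [2.0, 0.0]]), np.zeros(2))
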