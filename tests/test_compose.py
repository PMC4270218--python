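"""Composition: presets, paradigms, determinism, partial masking."""

import numpy as np
import pytest

from motionstill import build_preset, compose_stimulus, partial_mask, render_frame
from motionstill.compose import build_carrier, build_figure
from motionstill.config import StimulusConfig
from motionstill.presets import list_presets
from motionstill.verify import warp_similarity

SMALL = dict(resolution=(160, 120), duration=0.2, fps=10.0, seed=3)


def test_build_preset_examples():
    cfg = build_preset("stereo_rotation_standstill")
    assert cfg.figure_motion["omega"] == 12.0
    assert cfg.carrier_motion["omega"] == 0.0
    assert cfg.paradigm == "standstill"
    cfg = build_preset("color_scaling_capture")
    assert cfg.figure_motion["sigma"] == 1.0
    assert cfg.carrier_motion["sigma"] == pytest.approx(1.079)
    assert cfg.paradigm == "capture"
    cfg = build_preset("contrast_rotation")
    assert cfg.figure_motion["omega"] == 4.0
    assert cfg.carrier_motion["omega"] == 4.0
    assert cfg.paradigm == "joint"
    with pytest.raises(KeyError):
        build_preset("no_such_preset")


def test_every_preset_composes_a_frame():
    for name in list_presets():
        cfg = build_preset(name, **SMALL)
        frame = render_frame(cfg, 0.1)
        assert frame.rgb.shape == (120, 160, 3)
        assert np.isfinite(frame.rgb).all()


def test_frame_count_and_shape():
    cfg = build_preset("color_rotation", resolution=(80, 60), duration=1.0,
                       fps=10.0)
    stack = compose_stimulus(cfg)
    assert stack.n_frames == 10
    assert stack.frames.shape == (10, 60, 80, 3)
    assert len(stack.metadata["transforms"]) == 10


def test_same_seed_bit_identical_stack():
    a = compose_stimulus(build_preset("stereo_rotation_standstill", **SMALL))
    b = compose_stimulus(build_preset("stereo_rotation_standstill", **SMALL))
    assert np.array_equal(a.frames, b.frames)


def test_standstill_keeps_carrier_transform_identity():
    cfg = build_preset("stereo_rotation_standstill", **SMALL)
    stack = compose_stimulus(cfg)
    for rec in stack.metadata["transforms"]:
        assert np.allclose(rec["carrier_matrix"], np.eye(2))
        assert np.allclose(rec["carrier_offset"], 0.0)
    # figure transforms do vary
    mats = [rec["figure_matrix"] for rec in stack.metadata["transforms"]]
    assert not np.allclose(mats[0], mats[-1])


def test_paradigm_invariants_enforced():
    cfg = build_preset("stereo_rotation_standstill", **SMALL)
    cfg.carrier_motion = {"kind": "rotation", "omega": 5.0}
    with pytest.raises(ValueError, match="standstill"):
        compose_stimulus(cfg)
    cfg = build_preset("stereo_rotation_capture", **SMALL)
    cfg.figure_motion = {"kind": "rotation", "omega": 5.0}
    with pytest.raises(ValueError, match="capture"):
        compose_stimulus(cfg)
    cfg = build_preset("stereo_rotation", **SMALL)
    cfg.carrier_motion = {"kind": "rotation", "omega": 13.0,
                          "reversal_period": 5.0}
    with pytest.raises(ValueError, match="joint"):
        compose_stimulus(cfg)


def test_flicker_paradigm_regenerates_mask():
    cfg = build_preset("color_rotation_standstill_slow", **SMALL)
    cfg.paradigm = "flicker"
    stack = compose_stimulus(cfg)
    assert not np.array_equal(stack.frames[0], stack.frames[1])
    # same seed still reproduces the whole flickering stack
    again = compose_stimulus(cfg)
    assert np.array_equal(stack.frames, again.frames)


def test_flicker_legacy_jitter_mode():
    cfg = build_preset("color_rotation_standstill_slow", **SMALL)
    cfg.paradigm = "flicker"
    cfg.flicker_mode = "legacy_jitter"
    stack = compose_stimulus(cfg)
    assert not np.array_equal(stack.frames[0], stack.frames[1])
    assert np.array_equal(stack.frames, compose_stimulus(cfg).frames)


def test_standstill_and_capture_share_disparity_statistics():
    """Rotating the depth map vs rotating the carrier yields different
    frames but the same disparity content when the rotation equals the
    wheel's sector period (45 deg at 12 deg/s -> t = 3.75 s)."""
    small = dict(resolution=(200, 200), seed=3)
    stand = build_preset("stereo_rotation_standstill", **small)
    capt = build_preset("stereo_rotation_capture", **small)
    f_stand = render_frame(stand, 3.75)
    f_capt = render_frame(capt, 3.75)
    assert not np.array_equal(f_stand.rgb, f_capt.rgb)
    bins = np.linspace(0.0, 8.0, 33)
    h_stand = np.histogram(
        f_stand.metadata["disparity_true"][~f_stand.metadata["masked"]], bins
    )[0]
    h_capt = np.histogram(
        f_capt.metadata["disparity_true"][~f_capt.metadata["masked"]], bins
    )[0]
    assert np.array_equal(h_stand, h_capt)


def test_joint_frame_is_warp_of_initial_frame():
    """Moving figure and mask together is a rigid rotation of the frame."""
    cfg = build_preset("color_rotation", resolution=(240, 240), seed=5)
    fig = build_figure(cfg)
    car = build_carrier(cfg)
    f0 = render_frame(cfg, 0.0, figure=fig, carrier=car)
    f1 = render_frame(cfg, 1.0, figure=fig, carrier=car)  # 6 deg later
    warped = warp_similarity(f0.rgb.mean(axis=-1), 6.0, 1.0)
    target = f1.rgb.mean(axis=-1)
    valid = ~np.isnan(warped)
    # keep away from the mask-dot edges' resampling disagreements: compare
    # MSE against the MSE of the unwarped frame, which must be much larger
    mse_warp = float(np.mean((warped[valid] - target[valid]) ** 2))
    mse_raw = float(np.mean((f0.rgb.mean(axis=-1)[valid] - target[valid]) ** 2))
    assert mse_warp < 0.25 * mse_raw


def test_partial_mask_radius_zero_is_standstill_everywhere():
    cfg = build_preset("color_rotation_capture_slow", **SMALL)
    masked = partial_mask(cfg, 0.0)
    f_masked = render_frame(masked, 0.15)
    static_cfg = build_preset("color_rotation_capture_slow", **SMALL)
    static_cfg.carrier_motion = {"kind": "static"}
    static_cfg.paradigm = "flicker"  # bypass capture invariant for reference
    f_static = render_frame(static_cfg, 0.15)
    assert np.array_equal(f_masked.rgb, f_static.rgb)


def test_partial_mask_large_radius_is_full_capture():
    cfg = build_preset("color_rotation_capture_slow", **SMALL)
    big = partial_mask(cfg, 250.0)
    f_big = render_frame(big, 0.15)
    f_plain = render_frame(cfg, 0.15)
    assert np.array_equal(f_big.rgb, f_plain.rgb)
    with pytest.raises(ValueError):
        partial_mask(cfg, -1.0)


def test_partial_mask_splits_inner_and_outer():
    cfg = build_preset("color_rotation_capture_slow", resolution=(200, 200),
                       duration=0.2, fps=10.0, seed=3)
    split = partial_mask(cfg, 50.0)
    f_split = render_frame(split, 0.15)
    f_move = render_frame(cfg, 0.15)
    cfg_static = build_preset("color_rotation_capture_slow",
                              resolution=(200, 200), duration=0.2, fps=10.0,
                              seed=3)
    cfg_static.carrier_motion = {"kind": "static"}
    cfg_static.paradigm = "flicker"
    f_static = render_frame(cfg_static, 0.15)
    gy, gx = np.mgrid[0:200, 0:200]
    rho = np.hypot(gx - 99.5, gy - 99.5)
    inner = rho <= 50.0
    assert np.array_equal(f_split.rgb[inner], f_move.rgb[inner])
    assert np.array_equal(f_split.rgb[~inner], f_static.rgb[~inner])


def test_config_validation_errors():
    with pytest.raises(ValueError, match="family"):
        StimulusConfig(family="holograms")
    with pytest.raises(ValueError, match="paradigm"):
        StimulusConfig(paradigm="hover")
    with pytest.raises(ValueError, match="fps"):
        StimulusConfig(fps=0.0)
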