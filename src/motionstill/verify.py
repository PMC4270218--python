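"""Quantitative verification of rendered stimuli.

These routines are the package's measurement instruments: they recover, from
rendered frames alone, the properties the renderers claim to construct —
the disparity map of an anaglyph pair (windowed normalized cross-correlation
block matching with parabolic sub-pixel refinement), the luma uniformity of
isoluminant color frames, and the rotation/scale relating two frames
(exhaustive grid-search registration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter
from skimage.transform import AffineTransform, warp

__all__ = [
    "DisparityMap",
    "decode_disparity",
    "luma_stats",
    "estimate_similarity",
    "scaling_rotation_equivalence",
    "transform_area_ratio",
    "warp_similarity",
]

_EPS = 1e-12


@dataclass
class DisparityMap:
    """Per-pixel horizontal disparity estimates.

    ``disparity`` includes parabolic sub-pixel refinement;
    ``integer_disparity`` is the raw argmax over the shift grid.
    ``confidence`` is the peak normalized cross-correlation clipped to
    [0, 1]; pixels whose correlation window lacks texture, or that sit
    within the search range of the left/right border, are flagged masked.
    """

    disparity: np.ndarray
    integer_disparity: np.ndarray
    confidence: np.ndarray
    masked: np.ndarray
    search: int
    window: int


def decode_disparity(
    left_view: np.ndarray,
    right_view: np.ndarray,
    window: int = 9,
    search: int = 10,
    subpixel: bool = True,
    passes: int = 1,
) -> DisparityMap:
    """Block-matching disparity between two views.

    For every pixel, the shift s in [-search, search] maximizing the
    windowed normalized cross-correlation between ``left(x, y)`` and
    ``right(x + s, y)`` is taken as the disparity; a parabola through the
    correlation peak and its neighbors refines it to sub-pixel precision.
    The convention matches the renderer: a feature in front of (behind) the
    carrier plane separates the eye views horizontally, and swapping the
    views negates the sign.

    With ``passes=2`` a coarse-to-fine refinement follows: the right view is
    warped by a median-smoothed copy of the first-pass field and re-matched
    over a +/-2 px residual search. On smoothly varying disparity fields
    this removes the bias a single pass picks up from the disparity gradient
    across the correlation window. ``integer_disparity`` always reports the
    first pass so the exhaustive-search contract stays exact.
    """
    L = np.asarray(left_view, dtype=float)
    R = np.asarray(right_view, dtype=float)
    if L.shape != R.shape:
        raise ValueError(f"view shapes differ: {L.shape} vs {R.shape}")
    h, w = L.shape
    if window > min(h, w):
        raise ValueError(f"window {window} larger than image {L.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if passes not in (1, 2):
        raise ValueError(f"passes must be 1 or 2, got {passes}")

    d, d_int, c0, flat = _ncc_pass(L, R, window, search, subpixel)

    if passes == 2:
        coarse = median_filter(d, size=5)
        xs = np.arange(w, dtype=float)
        Rw = np.empty_like(R)
        for row in range(h):
            Rw[row] = np.interp(xs + coarse[row], xs, R[row])
        resid, _, c0, flat2 = _ncc_pass(L, Rw, window, 2, subpixel)
        d = coarse + resid
        flat |= flat2

    cols = np.arange(w)
    border = (cols < search) | (cols >= w - search)
    masked = flat | border[None, :]
    return DisparityMap(
        disparity=d,
        integer_disparity=d_int,
        confidence=np.clip(c0, 0.0, 1.0),
        masked=masked,
        search=search,
        window=window,
    )


def _ncc_pass(L, R, window, search, subpixel):
    """One exhaustive NCC sweep; returns (disparity, integer, peak, flat)."""
    h, w = L.shape
    shifts = np.arange(-search, search + 1)
    size = (window, window)
    mu_L = uniform_filter(L, size, mode="nearest")
    var_L = uniform_filter(L * L, size, mode="nearest") - mu_L**2

    ncc = np.empty((len(shifts), h, w), dtype=np.float64)
    for i, s in enumerate(shifts):
        Rs = np.roll(R, -s, axis=1)  # Rs(x) = R(x + s)
        mu_R = uniform_filter(Rs, size, mode="nearest")
        var_R = uniform_filter(Rs * Rs, size, mode="nearest") - mu_R**2
        cov = uniform_filter(L * Rs, size, mode="nearest") - mu_L * mu_R
        denom = np.sqrt(np.maximum(var_L, 0.0) * np.maximum(var_R, 0.0))
        ncc[i] = np.where(denom > _EPS, cov / np.maximum(denom, _EPS), 0.0)

    best = np.argmax(ncc, axis=0)  # first max wins on ties
    d_int = shifts[best]
    c0 = np.take_along_axis(ncc, best[None], axis=0)[0]

    d = d_int.astype(float)
    if subpixel:
        # a perfect correlation peak is already exact; the parabola would
        # only add noise from the unrelated neighboring-shift correlations
        interior = (best > 0) & (best < len(shifts) - 1) & (c0 < 1.0 - 1e-9)
        cm = np.take_along_axis(ncc, np.maximum(best - 1, 0)[None], axis=0)[0]
        cp = np.take_along_axis(
            ncc, np.minimum(best + 1, len(shifts) - 1)[None], axis=0
        )[0]
        denom = cm - 2.0 * c0 + cp
        safe = np.where(np.abs(denom) > _EPS, denom, 1.0)
        delta = np.where(np.abs(denom) > _EPS, 0.5 * (cm - cp) / safe, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        d = d + np.where(interior, delta, 0.0)

    flat = var_L <= _EPS
    return d, d_int, c0, flat


def luma_stats(frame, region=None, coefficients=(0.2126, 0.7152, 0.0722)) -> dict:
    """Mean and coefficient of variation of linear-light luma over a region.

    ``frame`` is linear RGB (an (H, W, 3) array or an object with ``.rgb``);
    ``region`` is a boolean mask (default: the frame's own unmasked flags if
    present, else everything).
    """
    rgb = frame.rgb if hasattr(frame, "rgb") else np.asarray(frame, dtype=float)
    if region is None:
        meta = getattr(frame, "metadata", None)
        region = meta.get("unmasked") if meta else None
    if region is None:
        region = np.ones(rgb.shape[:2], dtype=bool)
    if not np.any(region):
        raise ValueError("empty region")
    luma = rgb @ np.asarray(coefficients, dtype=float)
    vals = luma[region]
    mean = float(vals.mean())
    cv = float(vals.std() / mean) if mean > _EPS else float("inf")
    return {"mean": mean, "cv": cv, "n": int(vals.size)}


def _as_gray(frame) -> np.ndarray:
    a = frame.rgb if hasattr(frame, "rgb") else np.asarray(frame, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=-1)
    return np.asarray(a, dtype=float)


def warp_similarity(
    image: np.ndarray, angle_deg: float = 0.0, scale: float = 1.0
) -> np.ndarray:
    """Rotate (clockwise on screen) and scale an image about its center.

    Bilinear interpolation; pixels pulled from outside the source are NaN so
    that comparisons can mask them out.
    """
    img = _as_gray(image)
    h, w = img.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ang = np.radians(angle_deg)
    # forward map about the center: p_dst = scale * R(ang) (p_src - c) + c;
    # warp() wants the inverse, p_src = R(-ang)/scale (p_dst - c) + c
    ca, sa = np.cos(ang), np.sin(ang)
    m = np.array([[ca, -sa], [sa, ca]]) * scale
    inv = np.linalg.inv(m)
    tf = AffineTransform(
        matrix=np.array(
            [
                [inv[0, 0], inv[0, 1], cx - inv[0, 0] * cx - inv[0, 1] * cy],
                [inv[1, 0], inv[1, 1], cy - inv[1, 0] * cx - inv[1, 1] * cy],
                [0, 0, 1],
            ]
        )
    )
    return warp(img, tf, order=1, cval=np.nan, preserve_range=True)


def estimate_similarity(
    frame_a,
    frame_b,
    angle_grid=None,
    scale_grid=None,
    valid_mask: np.ndarray | None = None,
) -> dict:
    """Exhaustive rotation x scale registration of ``frame_a`` onto ``frame_b``.

    Every (angle, scale) on the grids warps ``frame_a`` and is scored by the
    mean squared error against ``frame_b`` over valid (non-NaN, optionally
    externally masked) pixels. Ties within numerical noise are broken toward
    the smaller |angle|. Brute force is chosen over log-polar phase
    correlation for robustness at desk scale.
    """
    a = _as_gray(frame_a)
    b = _as_gray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    angle_grid = np.atleast_1d(
        np.asarray([0.0] if angle_grid is None else angle_grid, dtype=float)
    )
    scale_grid = np.atleast_1d(
        np.asarray([1.0] if scale_grid is None else scale_grid, dtype=float)
    )
    if angle_grid.size == 0 or scale_grid.size == 0:
        raise ValueError("empty search grid")

    results = []
    for s in scale_grid:
        for ang in angle_grid:
            wa = warp_similarity(a, ang, s)
            valid = ~np.isnan(wa) & ~np.isnan(b)
            if valid_mask is not None:
                valid &= valid_mask
            if not np.any(valid):
                raise ValueError(
                    f"empty overlap after warp (angle={ang}, scale={s})"
                )
            mse = float(np.mean((wa[valid] - b[valid]) ** 2))
            results.append((mse, abs(ang), float(ang), float(s)))

    best_mse = min(r[0] for r in results)
    tol = max(1e-12, 1e-9 * best_mse)
    ties = [r for r in results if r[0] <= best_mse + tol]
    ties.sort(key=lambda r: (r[1], r[0]))
    mse, _, ang, s = ties[0]
    return {"best_angle": ang, "best_scale": s, "mse": mse}


def scaling_rotation_equivalence(
    image,
    total_scale: float,
    n_steps: int = 6,
    angle_step: float = 0.5,
    symmetry_period: float = 30.0,
    valid_mask: np.ndarray | None = None,
) -> dict:
    """Total rotation equivalent to a uniform scaling of a log-spiral image.

    On a logarithmic-spiral figure, scaling and rotation produce the same
    image motion, but an n-arm bundle is also invariant under rotation by its
    symmetry period (360/n degrees), so a single static registration of the
    fully scaled frame only determines the equivalent rotation modulo that
    period. The motion equivalence is recovered by continuity: the scaling is
    factored into ``n_steps`` equal sub-scalings, each small enough that its
    best-matching rotation lies strictly inside one symmetry period, the
    per-step rotation is found by brute-force search on an ``angle_step``
    grid over [0, symmetry_period), and the increments are summed.
    """
    if total_scale <= 1.0:
        raise ValueError(f"total_scale must be > 1, got {total_scale}")
    q = total_scale ** (1.0 / n_steps)
    grid = np.arange(0.0, symmetry_period, angle_step)
    base = _as_gray(image)
    increments = []
    prev = base
    for _ in range(n_steps):
        nxt = warp_similarity(prev, 0.0, q)
        res = estimate_similarity(
            prev, nxt, angle_grid=grid, valid_mask=valid_mask
        )
        increments.append(res["best_angle"])
        prev = nxt
    return {
        "total_angle": float(np.sum(increments)),
        "per_step": increments,
        "step_scale": q,
    }


def stereo_roundtrip(config, times=None, window=17, passes=2) -> dict:
    """Disparity round-trip check for a stereo stimulus configuration.

    Renders the anaglyph at three times (default: start, a quarter of the
    run — where the 0.2 Hz shear cycle and the 5 s reversal schedules are at
    full excursion — and near the end), decodes each pair, and reports the
    RMS error against the disparity field the renderer actually applied,
    over pixels that are neither figure-masked nor decoder-flagged. The
    17-px window accommodates the coarse peripheral dots of the
    eccentricity carriers.
    """
    from .compose import build_carrier, build_figure, render_frame

    if config.family != "stereo":
        raise ValueError(f"{config.name} is not a stereo configuration")
    if times is None:
        times = (
            0.0,
            config.duration / 4.0,
            0.92 * config.duration,
        )
    figure = build_figure(config)
    carrier = build_carrier(config)
    out = []
    for t in times:
        frame = render_frame(config, t, figure=figure, carrier=carrier)
        d_max = frame.metadata["d_max"]
        dm = decode_disparity(
            frame.left,
            frame.right,
            window=window,
            search=int(np.ceil(d_max)) + 2,
            passes=passes,
        )
        ok = ~frame.metadata["masked"] & ~dm.masked
        err = dm.disparity[ok] - frame.metadata["disparity_true"][ok]
        out.append(
            {
                "t": float(t),
                "rms_px": float(np.sqrt(np.mean(err**2))),
                "n_px": int(ok.sum()),
            }
        )
    return {"preset": config.name, "d_max": float(d_max), "roundtrip": out}


def transform_area_ratio(transform) -> float:
    """|det| of the linear part: the factor by which the transform scales area."""
    return abs(transform.det)
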