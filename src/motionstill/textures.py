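"""Seeded random-dot carrier and mask textures.

The carrier is the Julesz-style random-dot raster through which the figure is
seen: half of its cells are opaque dots and half transparent (or half black
and half white for the depth-encoding stereo carrier). Dots are square cells
of ``dot_size`` px with no anti-aliasing, matching the blocky appearance of
classic random-dot stereograms and keeping the dot statistics exact.

For scaling (looming) stimuli a special carrier is used whose dot size grows
as a power function of eccentricity; such a texture is statistically
self-similar, so uniform scaling does not change its appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "CarrierTexture",
    "random_dot_texture",
    "eccentricity_texture",
    "flicker_sequence",
    "dot_statistics",
]

PALETTES = ("black_transparent", "white_transparent", "black_white")


@dataclass(frozen=True)
class CarrierTexture:
    """A random-dot raster plus its palette and generation parameters.

    ``dots`` is an (H, W) boolean array; True marks a dot cell. The palette
    says how dots render: ``black_transparent`` / ``white_transparent`` masks
    show black/white dots over the figure, ``black_white`` paints dots black
    and the rest white (the stereo depth-encoding carrier).
    """

    dots: np.ndarray
    palette: str
    density: float
    dot_size: int
    seed: int
    params: dict = dc_field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dots.shape

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Nearest-neighbor dot lookup at centered (x, y) coordinates.

        Coordinates are wrapped (the texture tiles), so transformed sampling
        never runs out of carrier.
        """
        pts = np.asarray(points, dtype=float)
        h, w = self.dots.shape
        col = np.rint(pts[..., 0] + (w - 1) / 2.0).astype(np.int64) % w
        row = np.rint(pts[..., 1] + (h - 1) / 2.0).astype(np.int64) % h
        return self.dots[row, col]


def _check_size(width: int, height: int) -> None:
    if width < 1 or height < 1:
        raise ValueError(f"degenerate texture size {width}x{height}")


def random_dot_texture(
    width: int,
    height: int,
    palette: str = "black_transparent",
    density: float = 0.5,
    dot_size: int = 1,
    seed: int = 0,
) -> CarrierTexture:
    """Uniform random-dot texture: independent Bernoulli(density) cells.

    The raster is bit-reproducible from ``seed`` (PCG64 integer draws).
    """
    _check_size(width, height)
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    if dot_size < 1:
        raise ValueError(f"dot_size must be >= 1, got {dot_size}")
    if palette not in PALETTES:
        raise ValueError(f"unknown palette {palette!r}")

    rng = np.random.default_rng(int(seed))
    ch = -(-height // dot_size)
    cw = -(-width // dot_size)
    # integer threshold draw keeps the generation path exact
    thresh = int(round(density * 2**32))
    cells = rng.integers(0, 2**32, size=(ch, cw), dtype=np.uint64) < thresh
    dots = np.repeat(np.repeat(cells, dot_size, axis=0), dot_size, axis=1)
    dots = dots[:height, :width]
    return CarrierTexture(
        dots=dots,
        palette=palette,
        density=float(density),
        dot_size=int(dot_size),
        seed=int(seed),
        params={"kind": "uniform", "width": width, "height": height},
    )


def _hash_cells(seed: int, *indices: np.ndarray) -> np.ndarray:
    """SplitMix64-style integer hash of (seed, i, j, ...) -> uint64."""
    mults = (
        np.uint64(0x9E3779B97F4A7C15),
        np.uint64(0xBF58476D1CE4E5B9),
        np.uint64(0x94D049BB133111EB),
    )
    with np.errstate(over="ignore"):
        z = np.uint64(seed)
        for idx, mult in zip(indices, mults):
            z = z + mult * (idx.astype(np.uint64) + np.uint64(1))
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z


def eccentricity_texture(
    width: int,
    height: int,
    exponent: float,
    base_size: float = 4.0,
    seed: int = 0,
    palette: str = "black_white",
    density: float = 0.5,
    e_ref: float = 60.0,
) -> CarrierTexture:
    """Random-dot texture whose cell size grows as a power of eccentricity.

    The target cell diameter at eccentricity ``e`` px is
    ``base_size * (1 + e/e_ref)**exponent`` — ``base_size`` at the center,
    growing with the power law at the ``e_ref`` eccentricity scale (so
    ``exponent == 0`` reduces to a uniform texture of cell size
    ``base_size``, and ``exponent == 1`` makes the texture asymptotically
    scale-invariant, the property the looming stimuli need). The raster is
    built from concentric *bands* of square-cell random grids: within a band
    the cell size is the integer nearest the target size at that
    eccentricity (band edges follow a geometric size progression), which
    keeps the dots blocky and isotropic everywhere while their size steps up
    with eccentricity. Cell occupancy comes from a deterministic integer
    hash of (seed, band, cell index), so the raster is platform-independent
    and reproducible.
    """
    _check_size(width, height)
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    if base_size < 1:
        raise ValueError(f"base_size must be >= 1, got {base_size}")
    if palette not in PALETTES:
        raise ValueError(f"unknown palette {palette!r}")

    beta = float(exponent)
    s0 = float(base_size)
    er = float(e_ref)
    growth = 1.5  # size ratio between adjacent bands

    xs = np.arange(width, dtype=float) - (width - 1) / 2.0
    ys = np.arange(height, dtype=float) - (height - 1) / 2.0
    gx, gy = np.meshgrid(xs, ys)
    rho = np.hypot(gx, gy)

    target = s0 * (1.0 + rho / er) ** beta
    band = np.rint(np.log(target / s0) / np.log(growth)).astype(np.int64)
    band = np.maximum(band, 0)
    size = np.maximum(1, np.rint(s0 * growth ** band.astype(float))).astype(
        np.int64
    )
    ci = np.floor_divide(np.rint(gx + (width - 1) / 2.0).astype(np.int64), size)
    cj = np.floor_divide(np.rint(gy + (height - 1) / 2.0).astype(np.int64), size)

    z = _hash_cells(int(seed), band, ci, cj)
    thresh = np.uint64(int(round(density * 2**64)) - 1)
    dots = z <= thresh
    return CarrierTexture(
        dots=dots,
        palette=palette,
        density=float(density),
        dot_size=int(round(s0)),
        seed=int(seed),
        params={
            "kind": "eccentricity",
            "width": width,
            "height": height,
            "exponent": beta,
            "base_size": s0,
            "e_ref": er,
        },
    )


def flicker_sequence(
    texture_params: dict,
    n_frames: int,
    mode: str = "regenerate",
    seed: int = 0,
) -> list[CarrierTexture]:
    """A per-frame carrier sequence for dynamic-noise ("flicker") masks.

    ``regenerate`` draws a fresh texture each frame (true dynamic noise: the
    dot pattern is renewed at every frame change, leaving no coherent carrier
    motion). ``legacy_jitter`` reproduces the cheaper real-time trick of
    irregularly shifting, rotating and scaling one base texture on each frame;
    jitter amplitudes are at most one dot of shift, 2 degrees of rotation and
    2% of scale.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if mode not in ("regenerate", "legacy_jitter"):
        raise ValueError(f"unknown flicker mode {mode!r}")

    params = dict(texture_params)
    kind = params.pop("kind", "uniform")
    maker = random_dot_texture if kind == "uniform" else eccentricity_texture

    if mode == "regenerate":
        frames = []
        for i in range(n_frames):
            frames.append(maker(**params, seed=int(seed) + i))
        return frames

    base = maker(**params, seed=int(seed))
    rng = np.random.default_rng(int(seed) ^ 0x5EED)
    h, w = base.shape
    xs = np.arange(w, dtype=float) - (w - 1) / 2.0
    ys = np.arange(h, dtype=float) - (h - 1) / 2.0
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx, gy], axis=-1)

    frames = []
    amp = float(base.dot_size)
    for i in range(n_frames):
        shift = rng.uniform(-amp, amp, size=2)
        ang = np.radians(rng.uniform(-2.0, 2.0))
        sc = rng.uniform(0.98, 1.02)
        ca, sa = np.cos(ang), np.sin(ang)
        m = np.array([[ca, -sa], [sa, ca]]) * sc
        inv = np.linalg.inv(m)
        src = (pts - shift) @ inv.T
        dots = base.sample(src)
        frames.append(
            CarrierTexture(
                dots=dots,
                palette=base.palette,
                density=base.density,
                dot_size=base.dot_size,
                seed=int(seed),
                params={
                    **base.params,
                    "jitter": {
                        "frame": i,
                        "shift": tuple(shift),
                        "angle_deg": float(np.degrees(ang)),
                        "scale": float(sc),
                    },
                },
            )
        )
    return frames


def dot_statistics(texture: CarrierTexture, n_annuli: int = 8) -> dict:
    """Exact raster statistics: opaque fraction and a dot-size profile.

    The size profile reports, per eccentricity annulus, the mean length of
    maximal horizontal runs of dot pixels — a granulometry proxy for the dot
    diameter that needs nothing but the raster.
    """
    dots = texture.dots
    h, w = dots.shape
    frac = float(dots.sum()) / dots.size

    ys = np.arange(h, dtype=float) - (h - 1) / 2.0
    xs = np.arange(w, dtype=float) - (w - 1) / 2.0
    gx, gy = np.meshgrid(xs, ys)
    rho = np.hypot(gx, gy)
    rmax = rho.max() + 1e-9
    edges = np.linspace(0.0, rmax, n_annuli + 1)

    # maximal horizontal runs of True
    padded = np.zeros((h, w + 2), dtype=bool)
    padded[:, 1:-1] = dots
    diff = np.diff(padded.astype(np.int8), axis=1)
    starts = np.argwhere(diff == 1)
    ends = np.argwhere(diff == -1)
    # argwhere preserves row-major order, so starts/ends pair up per row
    run_rows = starts[:, 0]
    run_mid_col = (starts[:, 1] + ends[:, 1] - 1) / 2.0
    run_len = (ends[:, 1] - starts[:, 1]).astype(float)
    run_rho = np.hypot(run_mid_col - (w - 1) / 2.0, run_rows - (h - 1) / 2.0)

    mean_run = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (run_rho >= lo) & (run_rho < hi)
        mean_run.append(float(run_len[sel].mean()) if sel.any() else float("nan"))

    return {
        "opaque_fraction": frac,
        "annulus_edges": edges.tolist(),
        "mean_run_length": mean_run,
    }
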