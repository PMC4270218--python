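"""Frame and metadata output.

PNG is the canonical, bit-exact export: frames written and re-read round-trip
exactly, and the JSON manifest records per-frame SHA-256 checksums plus the
fully resolved configuration, which is sufficient to re-render the run
bit-identically. MP4 export is a convenience with no exactness contract (the
manifest flags it as such).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "srgb_encode",
    "srgb_decode",
    "write_frames",
    "read_frames",
]

log = logging.getLogger("motionstill")


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear-light [0, 1] -> 8-bit sRGB."""
    a = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    srgb = np.where(
        a <= 0.0031308, 12.92 * a, 1.055 * np.power(a, 1.0 / 2.4) - 0.055
    )
    return np.rint(srgb * 255.0).astype(np.uint8)


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    """8-bit sRGB -> linear-light float in [0, 1]."""
    a = np.asarray(encoded, dtype=float) / 255.0
    return np.where(a <= 0.04045, a / 12.92, np.power((a + 0.055) / 1.055, 2.4))


def write_frames(stack, out_dir, fmt: str = "png") -> dict:
    """Write a FrameStack as numbered PNGs (or a best-effort MP4) + manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt not in ("png", "mp4"):
        raise ValueError(f"unknown format {fmt!r}")

    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = srgb_encode(frames)

    entries = []
    if fmt == "png":
        pad = max(4, len(str(stack.n_frames)))
        for i in range(stack.n_frames):
            name = f"frame_{i:0{pad}d}.png"
            iio.imwrite(out / name, frames[i])
            digest = hashlib.sha256(frames[i].tobytes()).hexdigest()
            entries.append({"file": name, "sha256": digest})
        exact = True
    else:
        name = "stimulus.mp4"
        try:
            iio.imwrite(out / name, frames, fps=stack.fps, extension=".mp4")
        except Exception as exc:  # missing encoder
            raise RuntimeError(f"mp4 export failed (encoder unavailable?): {exc}")
        entries.append({"file": name, "sha256": None})
        exact = False

    manifest = {
        "format": fmt,
        "bit_exact": exact,
        "fps": stack.fps,
        "n_frames": int(stack.n_frames),
        "shape": list(stack.frames.shape[1:]),
        "frames": entries,
        "metadata": _jsonable(stack.metadata),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("wrote %d %s frame(s) to %s", stack.n_frames, fmt, out)
    return manifest


def read_frames(out_dir) -> np.ndarray:
    """Re-read PNG frames written by :func:`write_frames`, in order."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest["format"] != "png":
        raise ValueError("only the png format is bit-exact re-readable")
    return np.stack(
        [iio.imread(out / e["file"]) for e in manifest["frames"]], axis=0
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
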