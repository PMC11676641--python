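"""Reading and writing recordings and derived images.

Recordings are stored as grayscale TIFF - either a single multi-page file
or a numbered single-page sequence (``frame_0000.tif`` ...) - accompanied
by a JSON sidecar holding the exact frame rate and pixel scale, which the
analysis requires and TIFF does not reliably carry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import ImageStack
from .tracking import MotionHistoryImage

__all__ = ["write_stack", "read_stack", "write_mhi"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix else path / "meta.json"


def write_stack(
    stack: ImageStack,
    path: str | Path,
    mode: str = "multipage",
    bit_depth: int = 8,
) -> Path:
    """Write a stack as TIFF plus a metadata sidecar.

    ``mode="multipage"`` writes one multi-page file at ``path``;
    ``mode="sequence"`` writes numbered single-page TIFFs into the
    directory ``path``.  Intensities are clipped and cast to the requested
    unsigned bit depth (8 or 16).
    """
    path = Path(path)
    if bit_depth == 8:
        data = np.clip(stack.frames, 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.clip(stack.frames, 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "pixel_size_um": stack.pixel_size,
        "n_frames": stack.n_frames,
        "bit_depth": bit_depth,
    }
    if mode == "multipage":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = _sidecar_path(path)
    elif mode == "sequence":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(data.shape[0]):
            tifffile.imwrite(path / f"frame_{i:04d}.tif", data[i], photometric="minisblack")
        sidecar = path / "meta.json"
    else:
        raise ValueError("mode must be 'multipage' or 'sequence'")
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    return sidecar


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF or a numbered TIFF sequence plus its sidecar."""
    path = Path(path)
    if path.is_dir():
        sidecar = path / "meta.json"
        files = sorted(path.glob("frame_*.tif"))
        if not files:
            raise FileNotFoundError(f"no frame_*.tif files in {path}")
        frames = np.stack([tifffile.imread(f) for f in files])
    else:
        sidecar = _sidecar_path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar} not found (frame rate and pixel size are required)"
        )
    meta = json.loads(sidecar.read_text())
    return ImageStack(
        frames=frames.astype(np.float32),
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_size=float(meta["pixel_size_um"]),
    )


def write_mhi(mhi: MotionHistoryImage, path: str | Path) -> None:
    """Write a motion history image as a float32 TIFF (seconds per pixel)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mhi.values.astype(np.float32))
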