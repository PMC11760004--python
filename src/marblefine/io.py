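"""Reading and writing images, ROI masks, and tabular artifacts.

Images are PNG/TIFF/JPEG, 8-bit RGB or grayscale (16-bit rescaled). An ROI
may be a binary image of identical dimensions or a plain-text polygon file
with one ``x,y`` vertex per line (0-based pixel coordinates, implicitly
closed), rasterized by even-odd fill.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as draw_polygon

from .segmentation import MarblingMask, _as_uint8


def load_image(path: str | Path) -> np.ndarray:
    """Read an image as uint8, keeping its (H, W) or (H, W, 3) layout."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return _as_uint8(arr)


def load_polygon(path: str | Path) -> np.ndarray:
    """Vertices of a polygon ROI file as an (n, 2) float array of (x, y)."""
    verts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y = line.split(",")
        verts.append((float(x), float(y)))
    if len(verts) < 3:
        raise ValueError(f"polygon file {path} needs >= 3 vertices")
    return np.asarray(verts)


def rasterize_polygon(verts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a polygon given as (x, y) vertices into a boolean mask."""
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def load_roi(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load an ROI as a boolean mask, from a binary image or a polygon file.

    A ``.txt``/``.csv``/``.poly`` path is parsed as a vertex list; anything
    else is read as an image whose nonzero pixels are the ROI.
    """
    path = Path(path)
    if path.suffix.lower() in {".txt", ".csv", ".poly"}:
        return rasterize_polygon(load_polygon(path), shape)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.shape != shape:
        raise ValueError(
            f"ROI mask {path} has shape {arr.shape}, expected {shape}"
        )
    return arr > 0


def save_mask(mask: MarblingMask, path: str | Path) -> None:
    """Write a fat mask as binary PNG (fat=255) plus a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, (mask.fat.astype(np.uint8) * 255))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "threshold_used": mask.threshold_used,
                "fat_pixel_count": mask.fat_pixel_count,
            },
            indent=2,
        )
        + "\n"
    )


def load_mask(path: str | Path) -> MarblingMask:
    """Read a binary fat-mask PNG, recovering the threshold from the sidecar."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    threshold = -1
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        threshold = json.loads(sidecar.read_text()).get("threshold_used", -1)
    return MarblingMask(fat=arr > 0, threshold_used=threshold)
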