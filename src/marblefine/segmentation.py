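"""Otsu segmentation of intramuscular fat from sirloin cross-section images.

The marbling particles are the bright ("white") structures inside the muscle
region of interest (ROI); lean muscle is dark. A per-image Otsu threshold is
computed on the 256-bin intensity histogram of ROI pixels only — background
outside the ROI is excluded so it cannot bias the between-class variance —
and the fat mask is the bright class above the threshold, intersected with
the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogram

#: ITU-R BT.601 luminance weights used to collapse RGB to a single channel.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Thresholding algorithms the config accepts. Only Otsu is implemented;
#: the enum exists so alternative algorithms can be slotted in later.
THRESHOLD_METHODS = ("otsu",)


@dataclass(frozen=True)
class MarblingMask:
    """Binary fat/lean mask restricted to an ROI.

    Attributes
    ----------
    fat : (H, W) bool ndarray
        True on marbling (fat) pixels. Always a subset of the ROI.
    threshold_used : int
        The Otsu threshold that produced the mask (0-254), or -1 when the
        mask was supplied pre-binarized.
    """

    fat: np.ndarray
    threshold_used: int = -1

    @property
    def fat_pixel_count(self) -> int:
        return int(np.count_nonzero(self.fat))


def _as_uint8(arr: np.ndarray) -> np.ndarray:
    """Coerce an intensity array to 8-bit, rescaling 16-bit input."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)  # 65535 -> 255
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return np.clip(arr, 0, 255).astype(np.uint8)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to 8-bit luminance.

    Uses round(0.299 R + 0.587 G + 0.114 B) per pixel. Grayscale input
    (2-D array) is passed through after dtype coercion.

    Parameters
    ----------
    img : (H, W, 3) or (H, W) ndarray
        8-bit (or 16-bit, rescaled) image.

    Returns
    -------
    (H, W) uint8 ndarray
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return _as_uint8(img)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = _as_uint8(img[..., :3]).astype(np.float64)
        lum = rgb @ np.asarray(GRAY_WEIGHTS)
        return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    raise ValueError(f"expected (H,W) or (H,W,3) image, got shape {img.shape}")


def otsu_threshold(gray: np.ndarray, roi: np.ndarray) -> int:
    """Otsu threshold of the ROI-restricted intensity histogram.

    Builds the 256-bin histogram from ROI pixels only and returns the
    threshold t in [0, 254] maximizing the between-class variance
    w0(t) * w1(t) * (mu0(t) - mu1(t))^2 of the classes {intensity <= t}
    and {intensity > t}. Ties are broken toward the smallest t.

    Raises
    ------
    DegenerateHistogram
        If all ROI pixels share a single intensity value.
    """
    gray = _as_uint8(np.asarray(gray))
    roi = np.asarray(roi, dtype=bool)
    values = gray[roi]
    if values.size == 0:
        raise DegenerateHistogram("ROI contains no pixels")
    counts = np.bincount(values.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogram(
            "all ROI pixels share one intensity; Otsu threshold undefined"
        )
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts)[:255]
    w1 = counts.sum() - w0
    cum_moment = np.cumsum(counts * levels)[:255]
    total_moment = float((counts * levels).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_moment / w0
        mu1 = (total_moment - cum_moment) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) max


def binarize(gray: np.ndarray, roi: np.ndarray, t: int) -> MarblingMask:
    """Threshold the grayscale image at t inside the ROI.

    Fat is the bright class: fat(x) = roi(x) AND gray(x) > t.
    """
    if not 0 <= t <= 254:
        raise ValueError(f"threshold must be in [0, 254], got {t}")
    gray = _as_uint8(np.asarray(gray))
    roi = np.asarray(roi, dtype=bool)
    return MarblingMask(fat=roi & (gray > t), threshold_used=int(t))


def segment(img: np.ndarray, roi: np.ndarray, method: str = "otsu") -> MarblingMask:
    """Full segmentation: grayscale -> ROI-restricted Otsu -> binarize."""
    if method not in THRESHOLD_METHODS:
        raise ValueError(
            f"unknown threshold method {method!r}; available: {THRESHOLD_METHODS}"
        )
    gray = to_grayscale(img)
    t = otsu_threshold(gray, roi)
    return binarize(gray, roi, t)
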