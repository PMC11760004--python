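"""Synthetic sirloin-like images with controlled marbling fineness.

Marbling is emulated as a Boolean blob model: overlapping deformed disks
(random radius, mild random elongation) are dropped uniformly inside an
elliptical muscle ROI until the fat-pixel fraction first reaches the
target; the last blob is trimmed so every image realizes the same
intramuscular-fat fraction. Fineness is controlled purely by the blob
radius — many small blobs (fine) vs. few large ones (coarse) at matched
total fat — which isolates the spatial-distribution signal from the
fat-amount signal.

Rendering assigns a bright mean intensity to fat and a dark one to lean,
adds Gaussian noise, and clips to 8 bits, so Otsu segmentation is
exercised end-to-end. Everything is reproducible from a single seed.

Default study conditions: 560x560 images, a 480x400 elliptical ROI, fat
fraction 0.35, fat/lean intensities 200/80, noise SD 8; radius presets
fine = 2 px, medium = 6 px, coarse = 12 px.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import UnreachableFraction
from .segmentation import MarblingMask


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one synthetic marbling image."""

    image_size: tuple[int, int] = (560, 560)
    roi_semi_axes: tuple[int, int] = (200, 240)  # (row, col): 400 x 480 px ellipse
    target_imf_fraction: float = 0.35
    particle_radius_mean: float = 6.0
    particle_radius_sd: float = 1.5
    shape_irregularity: float = 0.3
    fat_intensity_mean: int = 200
    lean_intensity_mean: int = 80
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.target_imf_fraction < 1:
            raise ValueError("target_imf_fraction must be in (0, 1)")
        if self.fat_intensity_mean <= self.lean_intensity_mean:
            raise ValueError("fat must be brighter than lean")


@dataclass(frozen=True)
class SyntheticImage:
    """A rendered image plus its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    roi: np.ndarray  # (H, W) bool
    truth_mask: MarblingMask
    truth_label: str
    realized_imf: float
    seed: int


#: Radius presets for the three fineness groups (pixels).
PRESETS = {
    "fine": {"particle_radius_mean": 2.0, "particle_radius_sd": 0.5},
    "medium": {"particle_radius_mean": 6.0, "particle_radius_sd": 1.5},
    "coarse": {"particle_radius_mean": 12.0, "particle_radius_sd": 3.0},
}


def preset_spec(label: str, **overrides) -> SyntheticSpec:
    """The default spec for a fineness group, with optional overrides."""
    if label not in PRESETS:
        raise ValueError(f"unknown preset {label!r}; choose from {list(PRESETS)}")
    return SyntheticSpec(**{**PRESETS[label], **overrides})


def elliptical_roi(
    image_size: tuple[int, int], semi_axes: tuple[int, int]
) -> np.ndarray:
    """Centered elliptical ROI mask."""
    h, w = image_size
    rr, cc = np.ogrid[:h, :w]
    ar, ac = semi_axes
    return ((rr - h / 2) / ar) ** 2 + ((cc - w / 2) / ac) ** 2 <= 1.0


def _truth_mask(spec: SyntheticSpec, rng: np.random.Generator,
                roi: np.ndarray) -> tuple[np.ndarray, float]:
    """Drop blobs until the ROI fat fraction reaches the target, then trim."""
    if spec.particle_radius_mean >= min(spec.roi_semi_axes):
        raise UnreachableFraction("blob radius exceeds ROI capacity")
    h, w = spec.image_size
    roi_rows, roi_cols = np.nonzero(roi)
    roi_count = roi_rows.size
    target_px = int(round(spec.target_imf_fraction * roi_count))
    fat = np.zeros((h, w), dtype=bool)
    fat_count = 0
    last_new: tuple[np.ndarray, np.ndarray] | None = None
    max_blobs = 200 * max(1, target_px // max(1, int(spec.particle_radius_mean**2)))
    blobs = 0
    while fat_count < target_px:
        if blobs >= max_blobs:
            raise UnreachableFraction("could not reach target fat fraction")
        radius = max(1.0, rng.normal(spec.particle_radius_mean,
                                     spec.particle_radius_sd))
        j = rng.integers(0, roi_count)
        cr, cc_ = roi_rows[j], roi_cols[j]
        elong = 1.0 + spec.shape_irregularity * abs(rng.normal())
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cr, cc_, radius * elong, max(1.0, radius / elong),
                              shape=(h, w), rotation=theta)
        new = roi[rr, cc] & ~fat[rr, cc]
        rr, cc = rr[new], cc[new]
        fat[rr, cc] = True
        fat_count += rr.size
        last_new = (rr, cc)
        blobs += 1
    # trim the overshoot of the last blob so realized == target exactly
    excess = fat_count - target_px
    if excess > 0 and last_new is not None:
        rr, cc = last_new
        drop = rng.permutation(rr.size)[:excess]
        fat[rr[drop], cc[drop]] = False
        fat_count -= excess
    return fat, fat_count / roi_count


def generate_image(spec: SyntheticSpec, seed: int,
                   label: str = "synthetic") -> SyntheticImage:
    """Render one synthetic marbling image, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    roi = elliptical_roi(spec.image_size, spec.roi_semi_axes)
    fat, realized = _truth_mask(spec, rng, roi)
    canvas = np.zeros(spec.image_size, dtype=np.float64)
    canvas[roi] = spec.lean_intensity_mean
    canvas[fat] = spec.fat_intensity_mean
    canvas += rng.normal(0.0, spec.noise_sd, size=spec.image_size)
    gray = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = np.repeat(gray[..., None], 3, axis=2)
    return SyntheticImage(
        image=image,
        roi=roi,
        truth_mask=MarblingMask(fat=fat),
        truth_label=label,
        realized_imf=realized,
        seed=seed,
    )


def generate_panel(
    n_per_group: int,
    base_seed: int,
    specs: dict[str, SyntheticSpec] | None = None,
) -> list[SyntheticImage]:
    """n_per_group images for each fineness label, seeded base_seed + index.

    ``specs`` maps labels to generator specs; the default is the three
    fine/medium/coarse presets at matched fat fraction.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if specs is None:
        specs = {label: preset_spec(label) for label in PRESETS}
    sizes = {s.image_size for s in specs.values()}
    fracs = {s.target_imf_fraction for s in specs.values()}
    if len(sizes) > 1 or len(fracs) > 1:
        raise ValueError("panel specs must share image size and fat fraction")
    panel = []
    idx = 0
    for label, spec in specs.items():
        for _ in range(n_per_group):
            panel.append(generate_image(spec, seed=base_seed + idx, label=label))
            idx += 1
    return panel


def scaled_spec(spec: SyntheticSpec, factor: float) -> SyntheticSpec:
    """Shrink a spec (image, ROI, radii) by a linear factor, for fast runs."""
    return replace(
        spec,
        image_size=(int(spec.image_size[0] * factor),
                    int(spec.image_size[1] * factor)),
        roi_semi_axes=(int(spec.roi_semi_axes[0] * factor),
                       int(spec.roi_semi_axes[1] * factor)),
        particle_radius_mean=max(1.0, spec.particle_radius_mean * factor),
        particle_radius_sd=spec.particle_radius_sd * factor,
    )
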