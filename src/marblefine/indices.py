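"""Marbling fineness index candidates F1a-F8 plus the Kuchida index.

The index family summarizes one binary marbling mask:

==========  ==========================================================
F1a         number of particles, n
F1b         total fat area A_total (px)
F2a / F2b   A50 and A50/A_total
F3a / F3b   P50 and P50/P_total
F4          number of smallest particles with cumulative area < 50%
F5          mean of p_i^2 / a_i over particles (shape compactness)
F6          A50 * P50
F7          sample SD of per-tile fat-area ratios on a step x step grid
F8          F2b / F7
==========  ==========================================================

F7 is the central fineness statistic: the ROI bounding box is split into
step x step tiles, each sufficiently-covered tile contributes its fat
fraction x_i, and F7 = sqrt(sum (x_i - xbar)^2 / (n_tiles - 1)). Evenly
distributed (fine) marbling gives uniform tile ratios and a low F7; a few
large streaks (coarse) concentrate fat in some tiles and raise it.

The Kuchida fineness index — the count of particles sized 0.01 to 0.5 cm^2
divided by the loin-eye (ROI) area in cm^2 — runs in the opposite
direction (higher = finer) and needs a pixels-per-cm calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import (
    EmptyMarbling,
    InsufficientTiles,
    InvalidStepSize,
    MissingScale,
    NoTilesIncluded,
    UndefinedRatio,
)
from .particles import CumulativeStats, ParticleTable, cumulative_stats, label_particles
from .segmentation import MarblingMask, segment

#: Optimal tiles-per-axis count (default step size).
DEFAULT_STEP = 70
#: Minimum fraction of a tile that must be ROI for the tile to count.
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class TileGrid:
    """step x step partition of the ROI bounding box with per-tile fat ratios.

    Tile boundaries are floor(k * extent / step), half-open, so tiles cover
    the bounding box exactly. A tile is included when its ROI coverage
    (ROI pixels / tile pixels) reaches ``min_coverage``; for included tiles
    x_i = fat pixels / ROI pixels in the tile, so partially covered border
    tiles are normalized by their meat portion rather than their full area.
    """

    step: int
    row_bounds: np.ndarray  # (step+1,) absolute pixel rows
    col_bounds: np.ndarray
    roi_px: np.ndarray  # (step, step)
    fat_px: np.ndarray  # (step, step)
    included: np.ndarray  # (step, step) bool
    min_coverage: float

    @property
    def n_tiles(self) -> int:
        return int(np.count_nonzero(self.included))

    @property
    def x(self) -> np.ndarray:
        """Fat-area ratios x_i of the included tiles (1-D, row-major order)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = self.fat_px / self.roi_px
        return ratios[self.included]

    @property
    def x_bar(self) -> float:
        return float(self.x.mean())


@dataclass
class IndexVector:
    """All fineness index candidates for one image."""

    f1a: int
    f1b: int
    f2a: int
    f2b: float
    f3a: int
    f3b: float
    f4: int
    f5: float
    f6: int
    f7: float = np.nan
    f8: float = np.nan
    kuchida: float = np.nan
    step: int = DEFAULT_STEP
    threshold_used: int = -1

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ScaleCalibration:
    """Image scale: pixels per centimetre (needed by the Kuchida index)."""

    pixels_per_cm: float

    def __post_init__(self) -> None:
        if not self.pixels_per_cm > 0:
            raise ValueError("pixels_per_cm must be positive")


@dataclass
class PipelineConfig:
    """Knobs of the image -> IndexVector pipeline."""

    step: int = DEFAULT_STEP
    min_coverage: float = DEFAULT_MIN_COVERAGE
    connectivity: int = 8
    min_area: int = 1
    pixels_per_cm: float | None = None
    threshold_method: str = "otsu"


def basic_indices(table: ParticleTable, stats: CumulativeStats) -> IndexVector:
    """F1a-F6 from particle geometry and cumulative statistics.

    F5 pairs each particle's own perimeter and area (mean of p_i^2/a_i);
    the pairing matters, so it uses the table rows, not the two
    independently sorted sequences.
    """
    if table.n == 0:
        raise EmptyMarbling("no marbling particles")
    p = table.perimeters.astype(np.float64)
    a = table.areas.astype(np.float64)
    return IndexVector(
        f1a=table.n,
        f1b=stats.a_total,
        f2a=stats.a50,
        f2b=stats.a50 / stats.a_total,
        f3a=stats.p50,
        f3b=stats.p50 / stats.p_total,
        f4=stats.f4,
        f5=float(np.mean(p * p / a)),
        f6=stats.a50 * stats.p50,
    )


def roi_bbox(roi: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open (r0, r1, c0, c1) bounding box of the true region."""
    rows = np.flatnonzero(roi.any(axis=1))
    cols = np.flatnonzero(roi.any(axis=0))
    if rows.size == 0:
        raise ValueError("ROI is empty")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def build_tile_grid(
    mask: MarblingMask | np.ndarray,
    roi: np.ndarray,
    step: int = DEFAULT_STEP,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> TileGrid:
    """Partition the ROI bounding box into step x step tiles.

    Raises
    ------
    InvalidStepSize
        If either bounding-box dimension is smaller than ``step``
        (tiles would be sub-pixel).
    NoTilesIncluded
        If no tile reaches ``min_coverage`` ROI coverage.
    """
    fat = mask.fat if isinstance(mask, MarblingMask) else np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    if step < 2:
        raise ValueError("step must be >= 2")
    r0, r1, c0, c1 = roi_bbox(roi)
    ext_r, ext_c = r1 - r0, c1 - c0
    if ext_r < step or ext_c < step:
        raise InvalidStepSize(
            f"ROI bounding box {ext_r}x{ext_c} px cannot hold {step} tiles per axis"
        )
    k = np.arange(step + 1, dtype=np.int64)
    row_bounds = r0 + (k * ext_r) // step
    col_bounds = c0 + (k * ext_c) // step
    # tile index of every bbox pixel row/column
    row_idx = np.repeat(np.arange(step), np.diff(row_bounds))
    col_idx = np.repeat(np.arange(step), np.diff(col_bounds))
    tid = row_idx[:, None] * step + col_idx[None, :]
    roi_b = roi[r0:r1, c0:c1]
    fat_b = fat[r0:r1, c0:c1]
    roi_px = np.bincount(tid[roi_b], minlength=step * step).reshape(step, step)
    fat_px = np.bincount(tid[fat_b & roi_b], minlength=step * step).reshape(step, step)
    tile_px = np.outer(np.diff(row_bounds), np.diff(col_bounds))
    included = roi_px >= min_coverage * tile_px
    if not included.any():
        raise NoTilesIncluded(f"no tile reaches ROI coverage {min_coverage}")
    return TileGrid(
        step=step,
        row_bounds=row_bounds,
        col_bounds=col_bounds,
        roi_px=roi_px,
        fat_px=fat_px,
        included=included,
        min_coverage=min_coverage,
    )


def compute_f7(grid: TileGrid) -> float:
    """Sample standard deviation of the included tile fat ratios.

    F7 = sqrt( sum_i (x_i - xbar)^2 / (n_tiles - 1) ).

    Raises
    ------
    InsufficientTiles
        If fewer than two tiles are included (n - 1 = 0).
    """
    if grid.n_tiles < 2:
        raise InsufficientTiles(f"need >= 2 included tiles, have {grid.n_tiles}")
    return float(np.std(grid.x, ddof=1))


def compute_f8(f2b: float, f7: float) -> float:
    """F8 = F2b / F7; undefined when F7 is zero."""
    if f7 == 0:
        raise UndefinedRatio("F8 undefined: F7 is zero")
    return f2b / f7


def kuchida_index(
    table: ParticleTable,
    roi: np.ndarray,
    scale: ScaleCalibration | None,
) -> float:
    """Count of particles sized 0.01-0.5 cm^2 per cm^2 of loin-eye area.

    Raises
    ------
    MissingScale
        If no pixels-per-cm calibration is supplied.
    """
    if scale is None:
        raise MissingScale("Kuchida index requires a pixels_per_cm calibration")
    px_per_cm2 = scale.pixels_per_cm**2
    areas_cm2 = table.areas / px_per_cm2
    count = int(np.count_nonzero((areas_cm2 >= 0.01) & (areas_cm2 <= 0.5)))
    roi_cm2 = np.count_nonzero(np.asarray(roi, dtype=bool)) / px_per_cm2
    return count / roi_cm2


def indices_from_mask(
    mask: MarblingMask,
    roi: np.ndarray,
    config: PipelineConfig | None = None,
) -> IndexVector:
    """All indices from a pre-binarized marbling mask."""
    config = config or PipelineConfig()
    table = label_particles(mask, connectivity=config.connectivity,
                            min_area=config.min_area)
    if table.n == 0:
        raise EmptyMarbling("no marbling particles in ROI")
    stats = cumulative_stats(table)
    vec = basic_indices(table, stats)
    grid = build_tile_grid(mask, roi, step=config.step,
                           min_coverage=config.min_coverage)
    vec.f7 = compute_f7(grid)
    vec.f8 = compute_f8(vec.f2b, vec.f7) if vec.f7 > 0 else np.nan
    if config.pixels_per_cm is not None:
        vec.kuchida = kuchida_index(
            table, roi, ScaleCalibration(config.pixels_per_cm)
        )
    vec.step = config.step
    vec.threshold_used = mask.threshold_used
    return vec


def compute_all(
    img: np.ndarray,
    roi: np.ndarray,
    config: PipelineConfig | None = None,
) -> IndexVector:
    """End-to-end: RGB image + ROI -> segmentation -> IndexVector."""
    config = config or PipelineConfig()
    mask = segment(img, roi, method=config.threshold_method)
    return indices_from_mask(mask, roi, config)
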