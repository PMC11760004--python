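"""Connected-component morphometry of marbling particles.

Each maximal connected component of fat pixels is one marbling particle
(8-connectivity by default, so diagonal fat streaks stay one fleck). Area is
the pixel count a_i; perimeter p_i is the number of unit pixel edges exposed
to a non-fat or out-of-image pixel, so a single pixel has p = 4 and a solid
2x2 block has p = 8.

Cumulative statistics follow the ascending-sorted convention: A50 is the
area of the particle at which the ascending cumulative area first reaches
50% of A_total, and P50 is its perimeter analogue on the perimeter-sorted
sequence. With integer areas the cumulative fraction generically never
equals 0.5 exactly, so "first rank with cumulative fraction >= 0.5" is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMarbling
from .segmentation import MarblingMask

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class ParticleTable:
    """Per-particle geometry, sorted ascending by area (ties by label id).

    Attributes
    ----------
    ids : (n,) int ndarray
        Original row-major component labels (1-based), in sorted order.
    areas : (n,) int ndarray
        Pixel counts a_i, ascending.
    perimeters : (n,) int ndarray
        Exposed-edge counts p_i, aligned with ``areas`` per particle.
    centroids : (n, 2) float ndarray
        (row, col) centroids.
    bboxes : (n, 4) int ndarray
        (r0, c0, r1, c1) half-open bounding boxes.
    connectivity : int
        4 or 8.
    """

    ids: np.ndarray
    areas: np.ndarray
    perimeters: np.ndarray
    centroids: np.ndarray
    bboxes: np.ndarray
    connectivity: int = 8

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "area_px": self.areas,
                "perimeter_px": self.perimeters,
                "centroid_row": self.centroids[:, 0],
                "centroid_col": self.centroids[:, 1],
                "bbox_r0": self.bboxes[:, 0],
                "bbox_c0": self.bboxes[:, 1],
                "bbox_r1": self.bboxes[:, 2],
                "bbox_c1": self.bboxes[:, 3],
            }
        )


@dataclass(frozen=True)
class CumulativeStats:
    """A_total, P_total and the 50%-cumulation particle statistics."""

    a_total: int
    p_total: int
    a50: int
    p50: int
    i_a50: int  # 1-based rank in the area-sorted sequence
    i_p50: int  # 1-based rank in the perimeter-sorted sequence
    f4: int = field(default=0)  # count of smallest particles with cum fraction < 0.5


def _edge_exposure(labels: np.ndarray, n: int) -> np.ndarray:
    """Perimeter per label as the count of exposed unit pixel edges."""
    fat = labels > 0
    per = np.zeros(n + 1, dtype=np.int64)
    shifts = (
        (slice(None, -1), slice(None), slice(1, None), slice(None)),  # below
        (slice(1, None), slice(None), slice(None, -1), slice(None)),  # above
        (slice(None), slice(None, -1), slice(None), slice(1, None)),  # right
        (slice(None), slice(1, None), slice(None), slice(None, -1)),  # left
    )
    for dst_r, dst_c, src_r, src_c in shifts:
        nb = np.zeros_like(fat)
        nb[dst_r, dst_c] = fat[src_r, src_c]
        exposed = fat & ~nb
        per += np.bincount(labels[exposed], minlength=n + 1)
    return per


def label_particles(
    mask: MarblingMask | np.ndarray,
    connectivity: int = 8,
    min_area: int = 1,
) -> ParticleTable:
    """Label connected fat components and measure their geometry.

    Parameters
    ----------
    mask : MarblingMask or (H, W) bool ndarray
        The fat mask.
    connectivity : {4, 8}
        Pixel adjacency defining a particle. Default 8.
    min_area : int
        Particles below this pixel count are dropped (noise suppression);
        default 1 keeps everything.

    Returns
    -------
    ParticleTable sorted ascending by area, ties broken by the row-major
    first-encounter label id. An empty mask yields an empty table (n = 0).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    fat = mask.fat if isinstance(mask, MarblingMask) else np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(fat, structure=_STRUCTURES[connectivity])
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return ParticleTable(
            ids=empty,
            areas=empty,
            perimeters=empty,
            centroids=np.empty((0, 2)),
            bboxes=np.empty((0, 4), dtype=np.int64),
            connectivity=connectivity,
        )
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n + 1)[1:]
    perimeters = _edge_exposure(labels, n)[1:]
    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    sum_r = np.bincount(lab, weights=rows, minlength=n + 1)[1:]
    sum_c = np.bincount(lab, weights=cols, minlength=n + 1)[1:]
    centroids = np.stack([sum_r / areas, sum_c / areas], axis=1)
    slices = ndimage.find_objects(labels)
    bboxes = np.array(
        [(s[0].start, s[1].start, s[0].stop, s[1].stop) for s in slices],
        dtype=np.int64,
    )
    ids = np.arange(1, n + 1, dtype=np.int64)

    if min_area > 1:
        keep = areas >= min_area
        ids, areas, perimeters = ids[keep], areas[keep], perimeters[keep]
        centroids, bboxes = centroids[keep], bboxes[keep]

    order = np.lexsort((ids, areas))  # ascending area, ties by label id
    return ParticleTable(
        ids=ids[order],
        areas=areas[order].astype(np.int64),
        perimeters=perimeters[order].astype(np.int64),
        centroids=centroids[order],
        bboxes=bboxes[order],
        connectivity=connectivity,
    )


def _first_half_rank(sorted_values: np.ndarray) -> int:
    """0-based index of the first element whose cumulative sum reaches half."""
    cum = np.cumsum(sorted_values, dtype=np.int64)
    total = int(cum[-1])
    return int(np.searchsorted(cum, 0.5 * total, side="left"))


def cumulative_stats(table: ParticleTable) -> CumulativeStats:
    """A_total, P_total, A50, P50 and the F4 count from a particle table.

    A50 is a_k for the smallest rank k (areas ascending) whose cumulative
    area fraction reaches 0.5; P50 is the perimeter analogue on the
    perimeter-sorted sequence. F4 counts the smallest particles whose
    cumulative area fraction stays strictly below 0.5 (i.e. k - 1).

    Raises
    ------
    EmptyMarbling
        If the table has no particles.
    """
    if table.n == 0:
        raise EmptyMarbling("no marbling particles in mask")
    areas = np.asarray(table.areas, dtype=np.int64)  # already ascending
    perims_sorted = np.sort(np.asarray(table.perimeters, dtype=np.int64))
    k_a = _first_half_rank(areas)
    k_p = _first_half_rank(perims_sorted)
    return CumulativeStats(
        a_total=int(areas.sum()),
        p_total=int(perims_sorted.sum()),
        a50=int(areas[k_a]),
        p50=int(perims_sorted[k_p]),
        i_a50=k_a + 1,
        i_p50=k_p + 1,
        f4=k_a,
    )
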