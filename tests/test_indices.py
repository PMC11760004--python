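"""The fineness index family F1a-F8, tile grids, and the Kuchida index."""

import numpy as np
import pytest

import marblefine as mf
from marblefine.errors import (
    EmptyMarbling,
    InsufficientTiles,
    InvalidStepSize,
    MissingScale,
    UndefinedRatio,
)
from marblefine.indices import roi_bbox

from test_particles import _table_from_areas


def test_basic_indices_single_pixel_particle():
    """One 1-px particle: a=1, p=4, so F5 = 16 and F6 = 1*4 = 4."""
    m = np.zeros((5, 5), bool)
    m[2, 2] = True
    table = mf.label_particles(m)
    vec = mf.basic_indices(table, mf.cumulative_stats(table))
    assert (vec.f1a, vec.f1b, vec.f2a) == (1, 1, 1)
    assert vec.f2b == 1.0
    assert (vec.f3a, vec.f3b) == (4, 1.0)
    assert vec.f4 == 0
    assert vec.f5 == 16.0
    assert vec.f6 == 4


def test_basic_indices_area_multiset():
    """Areas [1,2,3,4]: A50 = 3 so F2b = 0.3 and F4 = 2."""
    table = _table_from_areas([1, 2, 3, 4])
    vec = mf.basic_indices(table, mf.cumulative_stats(table))
    assert vec.f2a == 3
    assert vec.f2b == pytest.approx(0.3)
    assert vec.f4 == 2
    assert vec.f6 == vec.f2a * vec.f3a


def test_basic_indices_empty_raises():
    table = mf.label_particles(np.zeros((4, 4), bool))
    with pytest.raises(EmptyMarbling):
        mf.cumulative_stats(table)


def _rect_roi(h, w, pad=5):
    roi = np.zeros((h + 2 * pad, w + 2 * pad), bool)
    roi[pad:pad + h, pad:pad + w] = True
    return roi


def test_tile_grid_140px_bbox_step_70():
    """A 140x140 bounding box at 70 tiles/axis gives 4900 tiles of 2x2 px."""
    roi = _rect_roi(140, 140)
    grid = mf.build_tile_grid(np.zeros_like(roi), roi, step=70,
                              min_coverage=1.0)
    assert grid.n_tiles == 70 * 70 == 4900
    assert np.all(grid.roi_px == 4)
    assert np.all(np.diff(grid.row_bounds) == 2)


def test_tile_grid_rejects_undersized_bbox():
    roi = _rect_roi(50, 200)
    with pytest.raises(InvalidStepSize):
        mf.build_tile_grid(np.zeros_like(roi), roi, step=70)


def test_tile_grid_partial_coverage_inclusion():
    """Border tiles below min_coverage are excluded; x_i is normalized by
    the ROI (meat) portion of the tile, not the full tile area."""
    roi = np.zeros((20, 20), bool)
    roi[0:10, 0:20] = True
    roi[10:20, 0:5] = True  # bottom-right of bbox mostly outside ROI
    fat = np.zeros_like(roi)
    fat[0:10, 0:10] = True
    grid = mf.build_tile_grid(fat, roi, step=2, min_coverage=0.5)
    # tiles: 10x10 px each; coverage: 1, 1, 0.5, 0 -> three included
    assert grid.included.tolist() == [[True, True], [True, False]]
    x = grid.fat_px / np.where(grid.roi_px, grid.roi_px, 1)
    assert x[0, 0] == 1.0 and x[0, 1] == 0.0 and x[1, 0] == 0.0


@pytest.mark.parametrize(
    "pattern, expected",
    [
        ("equal", 0.0),
        ("half", np.sqrt(4 * 0.25 / 3)),  # x = (0,0,1,1): 0.57735...
    ],
)
def test_f7_closed_forms(pattern, expected):
    roi = _rect_roi(8, 8, pad=0)
    fat = np.zeros_like(roi)
    if pattern == "equal":
        fat[::2, ::2] = True  # same ratio in every tile
    else:
        fat[:, 4:] = True  # two tiles all fat, two all lean
    grid = mf.build_tile_grid(fat, roi, step=2, min_coverage=1.0)
    assert mf.compute_f7(grid) == pytest.approx(expected, abs=1e-12)


def test_f7_insufficient_tiles():
    roi = np.zeros((8, 8), bool)
    roi[0:4, 0:4] = True  # one fully covered tile
    roi[7, 7] = True      # stretches the bbox without covering its tile
    grid = mf.build_tile_grid(np.zeros_like(roi), roi, step=2,
                              min_coverage=1.0)
    assert grid.n_tiles == 1
    with pytest.raises(InsufficientTiles):
        mf.compute_f7(grid)


def test_f7_upper_bound_and_zero_iff_equal():
    """F7 <= 0.5*sqrt(n/(n-1)) for ratios in [0,1]; 0 iff all equal."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        roi = _rect_roi(60, 60)
        fat = roi & (rng.random(roi.shape) < rng.uniform(0.05, 0.9))
        grid = mf.build_tile_grid(fat, roi, step=6, min_coverage=1.0)
        f7 = mf.compute_f7(grid)
        n = grid.n_tiles
        assert 0.0 <= f7 <= 0.5 * np.sqrt(n / (n - 1)) + 1e-12
        assert (f7 == 0.0) == bool(np.all(grid.x == grid.x[0]))


def test_f8_ratio_and_undefined():
    assert mf.compute_f8(0.3, np.sqrt(1 / 3)) == pytest.approx(0.51962, abs=1e-5)
    assert mf.compute_f8(1.0, 1.0) == 1.0
    with pytest.raises(UndefinedRatio):
        mf.compute_f8(0.3, 0.0)


def test_kuchida_index_size_window():
    """Only particles sized 0.01-0.5 cm^2 count, over the ROI cm^2 area."""
    ppc = 100.0  # 1 cm^2 = 10,000 px
    areas_px = [50, 200, 3000, 7000]  # 0.005, 0.02, 0.3, 0.7 cm^2
    table = _table_from_areas(areas_px)
    roi = np.ones((1000, 1000), bool)  # 100 cm^2
    k = mf.kuchida_index(table, roi, mf.ScaleCalibration(ppc))
    assert k == pytest.approx(2 / 100)
    empty = _table_from_areas([7000, 9000])
    assert mf.kuchida_index(empty, roi, mf.ScaleCalibration(ppc)) == 0.0
    with pytest.raises(MissingScale):
        mf.kuchida_index(table, roi, None)


def test_compute_all_equals_stagewise_composition():
    syn = mf.generate_image(
        mf.preset_spec("medium", image_size=(240, 240), roi_semi_axes=(90, 100)),
        seed=31,
    )
    cfg = mf.PipelineConfig(step=40, pixels_per_cm=20.0)
    vec = mf.compute_all(syn.image, syn.roi, cfg)

    mask = mf.segment(syn.image, syn.roi)
    table = mf.label_particles(mask, connectivity=cfg.connectivity)
    stats = mf.cumulative_stats(table)
    ref = mf.basic_indices(table, stats)
    grid = mf.build_tile_grid(mask, syn.roi, step=cfg.step,
                              min_coverage=cfg.min_coverage)
    assert vec.f7 == mf.compute_f7(grid)
    assert vec.f8 == mf.compute_f8(ref.f2b, vec.f7)
    assert vec.kuchida == mf.kuchida_index(
        table, syn.roi, mf.ScaleCalibration(20.0)
    )
    for name in ("f1a", "f1b", "f2a", "f2b", "f3a", "f3b", "f4", "f5", "f6"):
        assert getattr(vec, name) == getattr(ref, name)
    assert vec.threshold_used == mask.threshold_used


def test_compute_all_all_lean_roi_raises():
    """A single speck below the min-area filter leaves no particles."""
    img = np.full((120, 120, 3), 80, dtype=np.uint8)  # all lean
    roi = _rect_roi(100, 100, pad=10)
    img[60, 60] = 200  # lone bright speck inside the ROI
    with pytest.raises(EmptyMarbling):
        mf.compute_all(img, roi, mf.PipelineConfig(step=10, min_area=2))


def test_f7_invariant_under_aligned_pixel_replication():
    """x2 upscaling with tile-aligned boundaries (140 -> 280 px, step 70)
    leaves every tile ratio, and hence F7, exactly unchanged."""
    rng = np.random.default_rng(41)
    roi = _rect_roi(140, 140, pad=3)
    fat = roi & (rng.random(roi.shape) < 0.3)
    big_roi = np.kron(roi, np.ones((2, 2), bool))
    big_fat = np.kron(fat, np.ones((2, 2), bool))
    f7_small = mf.compute_f7(mf.build_tile_grid(fat, roi, step=70))
    f7_big = mf.compute_f7(mf.build_tile_grid(big_fat, big_roi, step=70))
    assert f7_big == pytest.approx(f7_small, abs=1e-15)


def test_roi_bbox_half_open():
    roi = np.zeros((10, 10), bool)
    roi[2:5, 3:9] = True
    assert roi_bbox(roi) == (2, 5, 3, 9)
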