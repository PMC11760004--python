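"""Shared fixtures: the synthetic three-group study panel.

The panel mirrors the study design: n images per fineness group
(fine / medium / coarse radius presets) at matched intramuscular-fat
fraction 0.35 on 560x560 images, segmented end-to-end through Otsu.
Session-scoped because generation and segmentation dominate test cost.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import marblefine as mf

PANEL_SEED = 1234
N_PER_GROUP = 20


@pytest.fixture(scope="session")
def three_group_panel():
    """Generated panel images with segmented masks and F7 at step 70."""
    panel = mf.generate_panel(N_PER_GROUP, base_seed=PANEL_SEED)
    masks = [mf.segment(s.image, s.roi) for s in panel]
    f7_70 = np.array([
        mf.compute_f7(mf.build_tile_grid(m, s.roi, step=70))
        for m, s in zip(masks, panel)
    ])
    return {
        "images": panel,
        "masks": masks,
        "labels": [s.truth_label for s in panel],
        "f7_70": f7_70,
    }
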