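"""End-to-end batch pipeline: paired images + ROIs -> CSV artifacts.

The run is fully deterministic given inputs, configuration, and seed:
per-image masks, particle tables, an ``indices.csv`` panel table,
group comparisons, and (optionally) the step-size sweep. A degenerate
image is logged and skipped rather than killing the whole panel; the exit
status distinguishes full success, partial success, and config errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ConfigError, MarbleFineError, PairingError
from .group_stats import (
    DEFAULT_SWEEP_STEPS,
    one_way_anova,
    step_size_sweep,
    welch_t,
)
from .indices import PipelineConfig, indices_from_mask
from .particles import label_particles
from .segmentation import segment

logger = logging.getLogger("marblefine")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

INDEX_COLUMNS = [
    "image_id", "group", "bms",
    "f1a", "f1b", "f2a", "f2b", "f3a", "f3b", "f4", "f5", "f6",
    "f7", "f8", "kuchida", "step", "threshold_used",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    images: Path
    rois: Path
    out: Path
    step: int = 70
    min_coverage: float = 0.5
    connectivity: int = 8
    min_area: int = 1
    pixels_per_cm: float | None = None
    sweep_steps: tuple[int, ...] = ()
    bootstrap_b: int = 1000
    seed: int = 0
    manifest: Path | None = None  # optional CSV: image_id, group, bms

    def validate(self) -> None:
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if not 0 < self.min_coverage <= 1:
            raise ConfigError("min_coverage must be in (0, 1]")
        if self.step < 2:
            raise ConfigError("step must be >= 2")
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def pair_inputs(images_dir: Path, rois_dir: Path) -> list[tuple[str, Path, Path]]:
    """Match images to ROI files by stem; every image must have an ROI."""
    images = sorted(
        p for p in Path(images_dir).iterdir()
        if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not images:
        raise PairingError(f"no images found in {images_dir}")
    rois = {p.stem: p for p in Path(rois_dir).iterdir() if p.is_file()}
    pairs = []
    for img in images:
        roi = rois.get(img.stem) or rois.get(img.stem + "_roi")
        if roi is None:
            raise PairingError(f"no ROI file for image {img.name}")
        pairs.append((img.stem, img, roi))
    return pairs


def run_pipeline(config: RunConfig) -> int:
    """Execute the full workflow; returns exit status 0/1/2.

    0 = all images processed, 1 = some images skipped, 2 = config error.
    """
    try:
        config.validate()
        pairs = pair_inputs(config.images, config.rois)
    except (ConfigError, PairingError) as exc:
        logger.error("%s", exc)
        return 2
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "particles").mkdir(exist_ok=True)

    groups: dict[str, tuple[str, int | None]] = {}
    if config.manifest is not None:
        mf = pd.read_csv(config.manifest)
        for _, row in mf.iterrows():
            groups[str(row["image_id"])] = (
                str(row.get("group", "")), row.get("bms"),
            )

    pcfg = PipelineConfig(
        step=config.step, min_coverage=config.min_coverage,
        connectivity=config.connectivity, min_area=config.min_area,
        pixels_per_cm=config.pixels_per_cm,
    )
    rows, masks, rois, labels, failed = [], [], [], [], []
    log_lines = [f"config_hash={config.digest()} seed={config.seed}"]
    for image_id, img_path, roi_path in pairs:
        try:
            img = mio.load_image(img_path)
            shape = img.shape[:2]
            roi = mio.load_roi(roi_path, shape)
            mask = segment(img, roi)
            mio.save_mask(mask, out / "masks" / f"{image_id}_mask.png")
            table = label_particles(mask, connectivity=config.connectivity,
                                    min_area=config.min_area)
            table.to_dataframe().to_csv(
                out / "particles" / f"{image_id}.csv", index=False
            )
            vec = indices_from_mask(mask, roi, pcfg)
        except MarbleFineError as exc:
            logger.warning("skipping %s: %s", image_id, exc)
            failed.append(image_id)
            log_lines.append(f"{image_id} SKIPPED {type(exc).__name__}: {exc}")
            continue
        group, bms = groups.get(image_id, ("", None))
        rows.append({"image_id": image_id, "group": group, "bms": bms,
                     **vec.as_dict()})
        masks.append(mask)
        rois.append(roi)
        labels.append(group)
        log_lines.append(
            f"{image_id} threshold={vec.threshold_used} f7={vec.f7:.6f}"
        )

    if not rows:
        logger.error("all images failed")
        return 2
    indices_df = pd.DataFrame(rows)[INDEX_COLUMNS]
    indices_df.to_csv(out / "indices.csv", index=False)

    label_set = [l for l in ("fine", "medium", "coarse") if l in labels]
    if "fine" in labels and "coarse" in labels:
        comparisons = []
        f7 = indices_df.set_index("image_id")["f7"]
        by_label = {
            l: indices_df.loc[indices_df["group"] == l, "f7"].to_numpy()
            for l in label_set
        }
        if all(v.size >= 2 for v in (by_label.get("fine"), by_label.get("coarse"))):
            res = welch_t(by_label["fine"], by_label["coarse"])
            comparisons.append({
                "test": "welch_t", "contrast": "fine_vs_coarse",
                "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            })
        if len(label_set) >= 2 and all(v.size >= 2 for v in by_label.values()):
            res = one_way_anova(by_label)
            comparisons.append({
                "test": "anova", "contrast": "|".join(label_set),
                "statistic": res.statistic, "df": str(res.df),
                "p_value": res.p_value,
            })
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)
        del f7

    if config.sweep_steps:
        sweep = step_size_sweep(masks, rois, labels, steps=config.sweep_steps,
                                min_coverage=config.min_coverage)
        pd.DataFrame({"step": sweep.steps, "p_value": sweep.p_values}).to_csv(
            out / "sweep.csv", index=False
        )
        log_lines.append(f"optimal_step={sweep.optimal_step}")

    # long-format boxplot data: one row per (image, index)
    long = indices_df.melt(
        id_vars=["image_id", "group", "bms"],
        value_vars=["f1a", "f1b", "f2a", "f2b", "f3a", "f3b",
                    "f4", "f5", "f6", "f7", "f8"],
        var_name="index", value_name="value",
    )
    long.to_csv(out / "boxplot_data.tsv", sep="\t", index=False)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return 1 if failed else 0
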