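"""Three-stage segmentation pipeline: standardize -> segment -> visualize.

For every B0 input image the pipeline writes (a) an indexed-mask PNG with
raw class ids 0..8, (b) an RGB overlay of the colored ROIs on the input,
and (c), when a co-registered FA map is available, a CSV table of the
mean FA over each predicted ROI — the quantity clinicians read off for
tract-wise DTI analysis.  Visualization never alters the stored mask.

Input pairing convention: ``<stem>_b0.png`` is segmented; an FA map named
``<stem>_fa.png`` in the same directory is used for the FA table.  Plain
``<name>.png`` files (no ``_fa``/``_mask``/pipeline-output suffix) are
also accepted as B0 inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import io_data
from .model import SCSNet, load_checkpoint
from .phantom import N_CLASSES, ROI_NAMES
from .training import logger

#: Default ROI palette: left/right pairs share a hue at different
#: saturation (dorsal blue, lateral green, ventral orange, GM magenta);
#: background stays transparent in overlays.
DEFAULT_COLOR_MAP = {
    1: (90, 140, 255), 5: (0, 60, 200),      # dorsal
    2: (120, 230, 120), 6: (0, 150, 0),      # lateral
    3: (255, 190, 100), 7: (230, 120, 0),    # ventral
    4: (255, 130, 220), 8: (190, 0, 160),    # gray matter
}

_RESERVED_SUFFIXES = ("_fa", "_mask", "_predmask", "_overlay")


@dataclass
class PipelineConfig:
    model_checkpoint: str
    input_dir: str
    output_dir: str
    color_map: dict[int, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_MAP))
    report_fa: bool = True
    target_size: int = 128

    def validate(self) -> "PipelineConfig":
        if sorted(self.color_map) != list(range(1, N_CLASSES)):
            raise ValueError("color_map must cover the 8 ROI classes")
        if len({tuple(c) for c in self.color_map.values()}) != 8:
            raise ValueError("ROI colors must be distinct")
        return self


def make_overlay(image: np.ndarray, mask: np.ndarray,
                 color_map: dict[int, tuple] = DEFAULT_COLOR_MAP,
                 alpha: float = 0.55) -> np.ndarray:
    """RGB uint8 overlay; background pixels show the image unchanged."""
    base = np.clip(image, 0.0, 1.0)
    rgb = np.stack([base] * 3, axis=-1) * 255.0
    for cls, color in color_map.items():
        sel = mask == cls
        rgb[sel] = (1 - alpha) * rgb[sel] + alpha * np.asarray(color, float)
    return np.round(rgb).astype(np.uint8)


def roi_mean_fa_table(mask: np.ndarray, fa_map: np.ndarray) -> pd.DataFrame:
    """Mean FA over each predicted ROI, as shown in the visualization step."""
    rows = []
    for cls in range(1, N_CLASSES):
        sel = mask == cls
        rows.append({"roi": ROI_NAMES[cls], "pixel_count": int(sel.sum()),
                     "mean_fa": fa_map[sel].mean() if sel.any() else np.nan})
    return pd.DataFrame(rows)


def find_inputs(input_dir) -> list[Path]:
    paths = []
    for p in sorted(Path(input_dir).glob("*.png")):
        if p.stem.endswith(_RESERVED_SUFFIXES):
            continue
        paths.append(p)
    return paths


def _fa_path_for(b0_path: Path) -> Path:
    stem = b0_path.stem
    base = stem[:-3] if stem.endswith("_b0") else stem
    return b0_path.with_name(f"{base}_fa.png")


def run_pipeline(config: PipelineConfig,
                 model: SCSNet | None = None) -> list[dict]:
    """Segment every input image; returns one record of paths per slice."""
    config.validate()
    if model is None:
        model = load_checkpoint(config.model_checkpoint)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = find_inputs(config.input_dir)
    if not inputs:
        raise ValueError(f"no input PNGs found in {config.input_dir}")
    records = []
    for path in inputs:
        try:
            image = io_data.read_b0(path)
        except Exception as exc:               # unreadable input: skip
            logger.warning("skipping unreadable image %s (%s)", path, exc)
            continue
        image = io_data.standardize_image(image, target=config.target_size)
        mask = model.predict_mask(image)
        base = path.stem[:-3] if path.stem.endswith("_b0") else path.stem
        mask_path = out_dir / f"{base}_predmask.png"
        overlay_path = out_dir / f"{base}_overlay.png"
        Image.fromarray(mask, mode="L").save(mask_path)
        overlay = make_overlay(image, mask, config.color_map)
        Image.fromarray(overlay, mode="RGB").save(overlay_path)
        record = {"input": str(path), "mask": str(mask_path),
                  "overlay": str(overlay_path), "fa_table": None}
        if config.report_fa:
            fa_path = _fa_path_for(path)
            if fa_path.exists():
                fa_map = io_data.standardize_image(
                    io_data.read_fa(fa_path), target=config.target_size)
                table = roi_mean_fa_table(mask, fa_map)
                table_path = out_dir / f"{base}_fa_means.csv"
                table.to_csv(table_path, index=False)
                record["fa_table"] = str(table_path)
            else:
                logger.warning("no FA map for %s; mask/overlay only", path)
        records.append(record)
    return records
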