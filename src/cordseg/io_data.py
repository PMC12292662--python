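"""File I/O, dataset splitting, and input standardization.

Storage formats (all PNG, lossless):

* B0 image  — 8-bit grayscale, value = round(255 * b0)
* FA map    — 16-bit grayscale, value = round(10000 * fa), preserving
  four decimal places of the dimensionless FA scalar
* label mask — 8-bit single-channel with raw class indices 0..8

Dataset splitting follows the slice-level random-sampling protocol:
pooled slice ids are permuted under a seed and partitioned 81% / 9% / 10%
into train / validation / test with largest-remainder rounding.  Because
the split unit is the slice (not the patient), slices of one subject can
land in different partitions; see the methods note for the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .phantom import PhantomSample

FA_SCALE = 10000
DEFAULT_FRACTIONS = (0.81, 0.09, 0.10)


# ---------------------------------------------------------------------------
# Sample read/write
# ---------------------------------------------------------------------------

def write_sample(sample: PhantomSample, path_b0, path_fa, path_mask) -> None:
    sample.validate()
    b0 = np.round(sample.b0 * 255.0).astype(np.uint8)
    Image.fromarray(b0, mode="L").save(path_b0)
    fa = np.round(sample.fa * FA_SCALE).astype(np.uint16)
    Image.fromarray(fa).save(path_fa)      # 16-bit grayscale PNG
    Image.fromarray(sample.mask.astype(np.uint8), mode="L").save(path_mask)


def read_b0(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "L":
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.float64) / 255.0
    return arr


def read_fa(path) -> np.ndarray:
    img = Image.open(path)
    arr = np.asarray(img, dtype=np.float64)
    if img.mode == "L":           # tolerate 8-bit FA maps
        arr /= 255.0
    else:
        arr /= FA_SCALE
    if arr.max() > 1.0:
        raise ValueError(f"FA values above 1 in {path}")
    return arr


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel")
    if arr.min() < 0 or arr.max() > 8:
        raise ValueError(f"mask {path} has values outside 0..8")
    return arr.astype(np.uint8)


def read_sample(path_b0, path_fa, path_mask) -> PhantomSample:
    """Load a triplet; enforces dimension agreement and value ranges."""
    b0, fa, mask = read_b0(path_b0), read_fa(path_fa), read_mask(path_mask)
    if not (b0.shape == fa.shape == mask.shape):
        raise ValueError("b0/fa/mask dimension mismatch on disk")
    return PhantomSample(b0=b0, fa=fa, mask=mask,
                         meta={"path_b0": str(path_b0)}).validate()


def load_manifest(data_dir) -> pd.DataFrame:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    for col in ("path_b0", "path_fa", "path_mask"):
        manifest[col] = [str(data_dir / p) for p in manifest[col]]
    return manifest


def load_samples(manifest: pd.DataFrame) -> list[PhantomSample]:
    return [read_sample(r.path_b0, r.path_fa, r.path_mask)
            for r in manifest.itertuples()]


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    seed: int

    def validate(self) -> "DatasetSplit":
        parts = [self.train, self.val, self.test]
        ids = [i for p in parts for i in p]
        if len(ids) != len(set(ids)):
            raise ValueError("split parts are not disjoint")
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, name) for name, part in
                (("train", self.train), ("val", self.val), ("test", self.test))
                for i in part]
        return pd.DataFrame(rows, columns=["id", "split"])


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Integer part sizes summing to n, largest fractional remainder first."""
    exact = [f * n for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    rema = [e - s for e, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        k = int(np.argmax(rema))
        sizes[k] += 1
        rema[k] = -1.0
    return sizes


def split_dataset(ids, fractions=DEFAULT_FRACTIONS, seed: int = 0
                  ) -> DatasetSplit:
    """Random 81/9/10 train/val/test partition of pooled slice ids."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 ids to split")
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_train, n_val, n_test = largest_remainder_sizes(len(ids), fractions)
    return DatasetSplit(train=shuffled[:n_train],
                        val=shuffled[n_train:n_train + n_val],
                        test=shuffled[n_train + n_val:],
                        seed=seed).validate()


# ---------------------------------------------------------------------------
# Standardization of arbitrary-size inputs
# ---------------------------------------------------------------------------

def standardize_image(image: np.ndarray, target: int = 128,
                      interpolation: str = "bilinear") -> np.ndarray:
    """Central square crop, then isotropic rescale to ``target x target``.

    ``interpolation='nearest'`` must be used for label masks so no mixed
    labels are invented at region boundaries.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    h, w = image.shape
    m = min(h, w)
    top, left = (h - m) // 2, (w - m) // 2
    crop = image[top:top + m, left:left + m]
    if m == target:
        return crop.copy()
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    out = resize(crop.astype(np.float64), (target, target), order=order,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    if interpolation == "nearest":
        out = out.astype(image.dtype)
    return out


def crop_offsets(shape: tuple[int, int]) -> tuple[int, int]:
    """(top, left) of the central square crop used by standardize_image."""
    h, w = shape
    m = min(h, w)
    return (h - m) // 2, (w - m) // 2
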