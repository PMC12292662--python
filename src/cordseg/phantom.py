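"""Synthetic cervical spinal-cord phantom: B0 image, FA map, 9-class mask.

Each phantom slice is an elliptical cord on a dark background whose
interior is partitioned into a butterfly-shaped gray-matter core and six
white-matter columns (dorsal / lateral / ventral, each split left/right),
i.e. the eight anatomical ROIs of tract-wise cord DTI analysis plus
background.  Per-region mean FA values default to the magnitudes typical
of healthy cervical white and gray matter (dorsal/lateral/ventral columns
around 0.54-0.60, gray matter around 0.54, background around 0.18); pixel
FA is region mean + clipped Gaussian noise.  The B0 channel uses three
grayscale levels (dark background, bright white matter, intermediate gray
matter) so tissue boundaries are visibly delineated, plus noise.

Left/right convention: "left" means the lower column index in image
coordinates.  Class ids::

    0 background
    1 left dorsal     5 right dorsal
    2 left lateral    6 right lateral
    3 left ventral    7 right ventral
    4 left gray matter 8 right gray matter

Geometry is defined analytically in cord-normalised coordinates
(u, v) = ((x - cx)/rx, (y - cy)/ry): the cord is u^2+v^2 <= 1, gray
matter is the mirrored half-butterfly polygon ``GM_HALF_POLYGON`` tested
on (|u|, v), and white matter is divided into dorsal/lateral/ventral
wedges by the angle from the dorsal (top) direction.  Mirroring the
membership test on |u| makes the unjittered phantom exactly symmetric
about the vertical midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath

N_CLASSES = 9

ROI_NAMES = {
    0: "background",
    1: "left_dorsal", 2: "left_lateral", 3: "left_ventral",
    4: "left_gray_matter",
    5: "right_dorsal", 6: "right_lateral", 7: "right_ventral",
    8: "right_gray_matter",
}
ROI_IDS = tuple(range(1, 9))
#: left-class id -> right-class id (and back)
MIRROR_PAIRS = {1: 5, 2: 6, 3: 7, 4: 8, 5: 1, 6: 2, 7: 3, 8: 4}

#: Table of per-region mean FA defaults (dimensionless).
DEFAULT_FA_MEANS = {
    1: 0.5950, 2: 0.6033, 3: 0.5674, 4: 0.5442,
    5: 0.5894, 6: 0.5418, 7: 0.5833, 8: 0.5429,
}
DEFAULT_BACKGROUND_FA = 0.1812

#: B0 grayscale means per tissue group.
DEFAULT_B0_CONTRAST = {"background": 0.05, "white_matter": 0.75,
                       "gray_matter": 0.55}

#: Half-butterfly gray-matter outline (right side) in normalised (u, v);
#: v grows downward, so negative v is dorsal.  Slender dorsal horn,
#: broader ventral horn, thin medial bridge at u ~ 0.
GM_HALF_POLYGON = [
    (0.00, -0.12), (0.10, -0.18), (0.16, -0.38), (0.30, -0.62),
    (0.42, -0.55), (0.33, -0.30), (0.26, -0.05), (0.44, 0.18),
    (0.50, 0.42), (0.32, 0.55), (0.12, 0.34), (0.00, 0.20),
]

#: Wedge limits (radians from the dorsal direction) separating the
#: dorsal / lateral / ventral white-matter columns.
DORSAL_LIMIT_RAD = np.deg2rad(55.0)
VENTRAL_LIMIT_RAD = np.deg2rad(125.0)


@dataclass
class PhantomConfig:
    image_size: int = 128
    cord_radii: tuple[float, float] | None = None   # (semi-x, semi-y) px
    region_fa_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FA_MEANS))
    background_fa_mean: float = DEFAULT_BACKGROUND_FA
    fa_noise_sd: float = 0.05
    b0_contrast: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_B0_CONTRAST))
    b0_noise_sd: float = 0.03
    jitter: float = 1.0
    seed: int = 0

    def radii(self) -> tuple[float, float]:
        if self.cord_radii is not None:
            return self.cord_radii
        return 0.32 * self.image_size, 0.25 * self.image_size

    def validate(self) -> "PhantomConfig":
        fas = list(self.region_fa_means.values()) + [self.background_fa_mean]
        if not all(0.0 < f < 1.0 for f in fas):
            raise ValueError("all FA means must lie in (0, 1)")
        if sorted(self.region_fa_means) != list(ROI_IDS):
            raise ValueError("region_fa_means must cover classes 1..8")
        if self.fa_noise_sd < 0 or self.b0_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        rx, ry = self.radii()
        reach = max(rx, ry) * (1.0 + 0.05 * self.jitter) + 3.0 * self.jitter
        if reach > self.image_size / 2.0 - 4.0:
            raise ValueError("cord does not fit with a 4 px background margin")
        return self


@dataclass
class JitterParams:
    """Per-sample affine perturbation of the cord geometry."""
    rotation: float = 0.0        # radians
    shift: tuple[float, float] = (0.0, 0.0)   # (dx, dy) pixels
    scale: tuple[float, float] = (1.0, 1.0)   # (sx, sy)


@dataclass
class PhantomSample:
    b0: np.ndarray          # [S, S] float in [0, 1]
    fa: np.ndarray          # [S, S] float in [0, 1]
    mask: np.ndarray        # [S, S] uint8 in 0..8
    meta: dict

    def validate(self) -> "PhantomSample":
        if not (self.b0.shape == self.fa.shape == self.mask.shape):
            raise ValueError("b0/fa/mask dimension mismatch")
        if self.mask.min() < 0 or self.mask.max() > 8:
            raise ValueError("mask values outside 0..8")
        return self


def draw_jitter(rng: np.random.Generator, jitter: float) -> JitterParams:
    """Draw the affine perturbation; consumes 5 uniforms even at jitter=0."""
    u = rng.uniform(-1.0, 1.0, size=5)
    return JitterParams(
        rotation=0.06 * jitter * u[0],
        shift=(3.0 * jitter * u[1], 3.0 * jitter * u[2]),
        scale=(1.0 + 0.05 * jitter * u[3], 1.0 + 0.05 * jitter * u[4]),
    )


def normalized_coords(config: PhantomConfig, jp: JitterParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) cord-normalised coordinates of every pixel center."""
    s = config.image_size
    rx, ry = config.radii()
    cx = (s - 1) / 2.0 + jp.shift[0]
    cy = (s - 1) / 2.0 + jp.shift[1]
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    c, sn = np.cos(jp.rotation), np.sin(jp.rotation)
    ur = c * dx + sn * dy
    vr = -sn * dx + c * dy
    return ur / (rx * jp.scale[0]), vr / (ry * jp.scale[1])


def classify_points(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised region classification of normalised coordinates."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    mask = np.zeros(u.shape, dtype=np.uint8)
    inside = u * u + v * v <= 1.0
    pts = np.column_stack([np.abs(u[inside]), v[inside]])
    gm = MplPath(GM_HALF_POLYGON).contains_points(pts)
    right = u[inside] > 0.0
    beta = np.arctan2(np.abs(u[inside]), -v[inside])
    wm = np.where(beta < DORSAL_LIMIT_RAD, 1,
                  np.where(beta < VENTRAL_LIMIT_RAD, 2, 3))
    cls = np.where(gm, 4, wm) + np.where(right, 4, 0)
    mask[inside] = cls.astype(np.uint8)
    return mask


def rasterize_mask(config: PhantomConfig, jp: JitterParams) -> np.ndarray:
    u, v = normalized_coords(config, jp)
    return classify_points(u, v)


def build_roi_geometry(config: PhantomConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Label mask for one sample; raises if any ROI rasterises empty."""
    config.validate()
    mask = rasterize_mask(config, draw_jitter(rng, config.jitter))
    counts = np.bincount(mask.ravel(), minlength=N_CLASSES)
    if (counts == 0).any():
        empty = [ROI_NAMES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"empty region(s) after jitter: {empty}")
    return mask


def generate_phantom(config: PhantomConfig, seed: int | None = None
                     ) -> PhantomSample:
    """One deterministic B0/FA/mask triplet for (config, seed).

    FA and B0 values are quantised to their PNG storage grids (1/10000
    and 1/255) so that writing and re-reading a sample is lossless.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mask = build_roi_geometry(config, rng)

    fa_means = np.empty(N_CLASSES)
    fa_means[0] = config.background_fa_mean
    for i in ROI_IDS:
        fa_means[i] = config.region_fa_means[i]
    fa = fa_means[mask] + rng.normal(0.0, 1.0, mask.shape) * config.fa_noise_sd
    fa = np.round(np.clip(fa, 0.0, 1.0) * 10000.0) / 10000.0

    b0_means = np.empty(N_CLASSES)
    b0_means[0] = config.b0_contrast["background"]
    for i in ROI_IDS:
        group = "gray_matter" if i in (4, 8) else "white_matter"
        b0_means[i] = config.b0_contrast[group]
    b0 = b0_means[mask] + rng.normal(0.0, 1.0, mask.shape) * config.b0_noise_sd
    b0 = np.round(np.clip(b0, 0.0, 1.0) * 255.0) / 255.0

    meta = {"seed": int(seed), "image_size": config.image_size,
            "jitter": config.jitter}
    return PhantomSample(b0=b0, fa=fa, mask=mask, meta=meta).validate()


def generate_dataset(config: PhantomConfig, n_slices: int, out_dir,
                     seed: int = 0):
    """Write ``n_slices`` phantom triplets as PNGs plus a CSV manifest.

    Per-slice seeds derive deterministically from the master seed.
    Returns the manifest as a pandas DataFrame with columns
    path_b0 / path_fa / path_mask / seed (paths relative to ``out_dir``).
    """
    import pandas as pd

    from . import io_data

    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    config.validate()
    out_dir = FsPath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slice_seeds = (np.random.SeedSequence(seed).generate_state(n_slices)
                   & 0x7FFFFFFF)
    rows = []
    for idx, s in enumerate(slice_seeds):
        sample = generate_phantom(config, int(s))
        names = {k: f"slice_{idx:04d}_{k}.png" for k in ("b0", "fa", "mask")}
        io_data.write_sample(sample, out_dir / names["b0"],
                             out_dir / names["fa"], out_dir / names["mask"])
        rows.append({"path_b0": names["b0"], "path_fa": names["fa"],
                     "path_mask": names["mask"], "seed": int(s)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
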