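"""Modality-specific image preprocessing.

Radiograph arm: bounding-box ROI extraction, resampling to a fixed input
size, and per-crop intensity standardization. Histology arm: Reinhard-style
stain normalization in LAB space, saturation/brightness tissue masking, and
non-overlapping fixed-size tiling with a tissue-fraction keep rule.

Coordinates are 0-based, half-open pixel intervals throughout; bounding
boxes are (x, y, width, height) as exported by the VIA annotator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color
from skimage.transform import resize

from .errors import AnnotationError, ConfigError

DEFAULT_TILE_SIZE = 256
DEFAULT_TISSUE_THRESHOLD = 0.5
DEFAULT_SATURATION_MIN = 0.08
DEFAULT_BRIGHTNESS_MAX = 0.95


@dataclass(frozen=True)
class RoiAnnotation:
    """Axis-aligned bounding box on a named image (top-left origin)."""

    image_id: str
    x: int
    y: int
    width: int
    height: int

    def validate_against(self, image: np.ndarray) -> None:
        h, w = image.shape[:2]
        if (self.width <= 0 or self.height <= 0 or self.x < 0 or self.y < 0
                or self.x + self.width > w or self.y + self.height > h):
            raise AnnotationError(
                f"annotation for {self.image_id!r}: box ({self.x},{self.y},"
                f"{self.width},{self.height}) outside {h}x{w} image")


@dataclass
class TileGrid:
    """Candidate tiles of a slide with tissue fractions and keep flags."""

    tile_size: int
    tiles: list  # (row, col, tissue_fraction, keep)

    @property
    def kept(self) -> list:
        return [t for t in self.tiles if t[3]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tiles, columns=["row", "col", "tissue_fraction", "kept"])


def extract_roi(image: np.ndarray, ann: RoiAnnotation, target_size: int) -> np.ndarray:
    """Crop the annotated box, resample to target_size^2, and standardize.

    The crop is z-scored over its own pixels (zero mean, unit variance);
    constant crops map to all zeros.
    """
    if target_size < 8:
        raise ConfigError(f"target_size must be >= 8, got {target_size}")
    ann.validate_against(image)
    crop = np.asarray(image, dtype=float)[ann.y:ann.y + ann.height, ann.x:ann.x + ann.width]
    if crop.shape != (target_size, target_size):
        crop = resize(crop, (target_size, target_size), order=1, mode="reflect",
                      anti_aliasing=True, preserve_range=True)
    sd = crop.std()
    if sd < 1e-12:
        return np.zeros_like(crop)
    return (crop - crop.mean()) / sd


@dataclass(frozen=True)
class StainStats:
    """Per-channel mean and sd in LAB space; the Reinhard reference."""

    means: tuple
    sds: tuple

    def validate(self) -> None:
        arr = np.asarray(self.means + self.sds, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ConfigError("stain reference statistics must be finite")
        if any(s <= 0 for s in self.sds):
            raise ConfigError("stain reference sds must be positive")


def compute_stain_stats(patch: np.ndarray) -> StainStats:
    """LAB channel means/sds of an RGB patch (unit-scale RGB in [0, 1])."""
    lab = color.rgb2lab(np.clip(patch, 0.0, 1.0))
    means = tuple(float(lab[..., c].mean()) for c in range(3))
    sds = tuple(float(lab[..., c].std()) for c in range(3))
    return StainStats(means=means, sds=sds)


def stain_normalize(patch: np.ndarray, reference: StainStats) -> np.ndarray:
    """Reinhard statistics transfer: recenter/rescale LAB channels to reference.

    A zero-variance source channel is shifted to the reference mean without
    rescaling. Output is clipped back to valid RGB range, so normalizing a
    patch to its own statistics is the identity up to clipping/rounding.
    """
    reference.validate()
    lab = color.rgb2lab(np.clip(np.asarray(patch, dtype=float), 0.0, 1.0))
    out = np.empty_like(lab)
    for c in range(3):
        ch = lab[..., c]
        mu, sd = ch.mean(), ch.std()
        if sd < 1e-8:
            out[..., c] = ch - mu + reference.means[c]
        else:
            out[..., c] = (ch - mu) / sd * reference.sds[c] + reference.means[c]
    return np.clip(color.lab2rgb(out), 0.0, 1.0)


def tissue_mask(slide: np.ndarray, s_min: float = DEFAULT_SATURATION_MIN,
                v_max: float = DEFAULT_BRIGHTNESS_MAX) -> np.ndarray:
    """Boolean mask: tissue iff saturation >= s_min and brightness <= v_max.

    White background and blown-out artifacts fail both rules.
    """
    hsv = color.rgb2hsv(np.clip(np.asarray(slide, dtype=float), 0.0, 1.0))
    return (hsv[..., 1] >= s_min) & (hsv[..., 2] <= v_max)


def tile_slide(slide: np.ndarray, mask: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE,
               tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD) -> TileGrid:
    """Non-overlapping tiling anchored at (0, 0); remainder strips dropped.

    A tile is kept iff its masked tissue fraction reaches tissue_threshold.
    A tile_size exceeding either slide dimension yields an empty grid.
    """
    if not (0 < tissue_threshold <= 1):
        raise ConfigError(f"tissue_threshold must be in (0, 1], got {tissue_threshold}")
    h, w = mask.shape[:2]
    if slide.shape[:2] != (h, w):
        raise ConfigError(f"mask shape {mask.shape[:2]} does not match slide {slide.shape[:2]}")
    tiles = []
    for row in range(h // tile_size):
        for col in range(w // tile_size):
            sub = mask[row * tile_size:(row + 1) * tile_size,
                       col * tile_size:(col + 1) * tile_size]
            frac = float(sub.mean())
            tiles.append((row, col, frac, frac >= tissue_threshold))
    return TileGrid(tile_size=tile_size, tiles=tiles)


def extract_kept_patches(slide: np.ndarray, grid: TileGrid) -> list:
    """Pixel data of the kept tiles, row-major order."""
    t = grid.tile_size
    return [slide[r * t:(r + 1) * t, c * t:(c + 1) * t] for r, c, _, keep in grid.tiles if keep]


def read_via_annotations(csv_path) -> list[RoiAnnotation]:
    """Parse a VIA-annotator region CSV into RoiAnnotation records.

    Expects columns ``filename`` and ``region_shape_attributes`` (a JSON
    object with x/y/width/height for rectangular regions).
    """
    df = pd.read_csv(csv_path)
    anns = []
    for _, row in df.iterrows():
        attrs = json.loads(row["region_shape_attributes"])
        if not attrs:
            continue
        anns.append(RoiAnnotation(image_id=str(row["filename"]),
                                  x=int(attrs["x"]), y=int(attrs["y"]),
                                  width=int(attrs["width"]), height=int(attrs["height"])))
    return anns
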