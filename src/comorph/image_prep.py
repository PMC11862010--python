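"""Well-image preprocessing: FOV merging, illumination correction,
percentile intensity normalization.

Mirrors the preprocessing applied to the raw screen: the four overlapping
camera fields of view are stacked horizontally in pairs and then vertically
into one well-level image per channel; a smooth per-channel illumination
surface estimated across wells divides out uneven lighting; and before
feature extraction each channel is rescaled by its 99th-percentile intensity
onto [0, 255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import MultiChannelImage

__all__ = [
    "IlluminationProfile",
    "merge_fovs",
    "estimate_illumination",
    "apply_illumination",
    "percentile_normalize",
    "read_image_tiff",
    "write_image_tiff",
    "read_mask_tiff",
    "write_mask_tiff",
]

logger = logging.getLogger(__name__)


@dataclass
class IlluminationProfile:
    """Per-channel smooth correction surface, strictly positive, mean 1."""

    surfaces: np.ndarray  # (3, H, W)

    def __post_init__(self) -> None:
        self.surfaces = np.asarray(self.surfaces, dtype=np.float64)
        if self.surfaces.ndim != 3 or self.surfaces.shape[0] != 3:
            raise ValueError("illumination profile must be (3, H, W)")
        if self.surfaces.min() <= 0:
            raise ValueError("illumination profile must be strictly positive")
        means = self.surfaces.mean(axis=(1, 2))
        if np.any(np.abs(means - 1.0) > 1e-6):
            raise ValueError("illumination profile channels must have mean 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.surfaces.shape[1:]


def merge_fovs(
    tiles: Sequence[MultiChannelImage], overlap_px: int
) -> MultiChannelImage:
    """Merge four FOV tiles (tl, tr, bl, br) into one well image.

    Output side is ``2 * tile_side - overlap_px`` per axis.  In overlap
    regions the pixel from the earlier (top/left) tile wins: the trailing
    ``overlap_px`` rows/columns of the later tile are cropped.  Exact inverse
    of :func:`comorph.synthetic.split_into_fovs`.
    """
    if len(tiles) != 4:
        raise ValueError("merge_fovs expects exactly four tiles")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"tiles must share one shape, got {sorted(shapes)}")
    th, tw = tiles[0].shape
    if th != tw:
        raise ValueError("tiles must be square")
    if not (0 <= overlap_px < th):
        raise ValueError("overlap_px must satisfy 0 <= overlap < tile side")

    t = th
    side = 2 * t - overlap_px
    o = overlap_px
    out = np.empty((3, side, side))
    tl, tr, bl, br = (tile.pixels for tile in tiles)
    out[:, :t, :t] = tl
    out[:, :t, t:] = tr[:, :, o:]
    out[:, t:, :t] = bl[:, o:, :]
    out[:, t:, t:] = br[:, o:, o:]
    return MultiChannelImage(out)


def estimate_illumination(
    images: Sequence[MultiChannelImage],
    smoothing_scale: float | None = None,
) -> IlluminationProfile:
    """Estimate a retrospective flat-field profile from a set of well images.

    The per-channel mean image across wells is Gaussian-smoothed at a large
    scale (default: a quarter of the image side) and rescaled to mean 1.
    A single image is allowed: its own smoothed field is returned.
    """
    if len(images) == 0:
        raise ValueError("estimate_illumination requires at least one image")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("all images must share one shape")
    h, w = images[0].shape
    if smoothing_scale is None:
        smoothing_scale = min(h, w) / 4.0

    mean = np.mean([im.pixels for im in images], axis=0)
    smooth = np.stack(
        [gaussian_filter(mean[c], sigma=smoothing_scale, mode="nearest") for c in range(3)]
    )
    # guard against an all-dark channel; the profile must stay positive
    floor = 1e-9 * max(smooth.max(), 1.0)
    smooth = np.maximum(smooth, floor)
    smooth = smooth / smooth.mean(axis=(1, 2), keepdims=True)
    return IlluminationProfile(smooth)


def apply_illumination(
    image: MultiChannelImage, profile: IlluminationProfile
) -> MultiChannelImage:
    """Divide each channel by its illumination surface (divisive correction)."""
    if image.shape != profile.shape:
        raise ValueError(
            f"image shape {image.shape} != profile shape {profile.shape}"
        )
    return MultiChannelImage(image.pixels / profile.surfaces)


def percentile_normalize(
    channel: np.ndarray, q: float = 99.0, out_max: float = 255.0
) -> np.ndarray:
    """Rescale one channel by its q-th percentile onto [0, out_max].

    ``out = clip(pixels / percentile_q * out_max, 0, out_max)``, so a
    constant channel maps to ``out_max`` everywhere and any pixel above the
    q-th percentile clips to ``out_max`` exactly.  Percentiles use linear
    interpolation between order statistics.  An all-zero channel (percentile
    0) is returned unchanged with a warning rather than dividing by zero.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("channel must be non-empty")
    if not (0 < q <= 100):
        raise ValueError("q must lie in (0, 100]")
    ref = float(np.percentile(channel, q))
    if ref == 0.0:
        logger.warning("percentile_normalize: %g-th percentile is 0; returning zeros", q)
        return np.zeros_like(channel)
    return np.clip(channel / ref * out_max, 0.0, out_max)


# --- TIFF I/O -------------------------------------------------------------

def write_image_tiff(path, image: MultiChannelImage) -> None:
    """Write a multi-channel image as a 3-page float32 TIFF."""
    import tifffile

    tifffile.imwrite(
        path,
        image.pixels.astype(np.float32),
        photometric="minisblack",
        planarconfig="separate",
    )


def read_image_tiff(path) -> MultiChannelImage:
    import tifffile

    return MultiChannelImage(tifffile.imread(path))


def write_mask_tiff(path, mask: np.ndarray) -> None:
    """Write a label mask as 16-bit integer TIFF."""
    import tifffile

    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels exceed 16-bit range")
    tifffile.imwrite(path, mask.astype(np.uint16))


def read_mask_tiff(path) -> np.ndarray:
    import tifffile

    from .containers import validate_label_mask

    return validate_label_mask(tifffile.imread(path).astype(np.int64))
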