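"""Single-cell extraction: regions from label masks, fixed-size crops,
handcrafted features, and embedding-extractor plumbing.

Bounding boxes are square, centred at the floored object centroid, and
follow the half-open convention ``[r0, r0 + box)`` with
``r0 = floor(centroid_row) - box // 2`` (same for columns).  Cells whose box
does not fit inside the image are excluded and counted.  In masked mode
every pixel that does not belong to the cell's own label is zeroed in all
three channels, isolating the cell from neighbours and background.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
from skimage.measure import regionprops

from .containers import (
    CellRegion,
    MultiChannelImage,
    SingleCellCrop,
    validate_label_mask,
)

__all__ = [
    "FEATURE_NAMES",
    "regions_from_mask",
    "crop_cells",
    "handcrafted_features",
    "handcrafted_feature_table",
    "embed_features",
    "MockExtractor",
]

logger = logging.getLogger(__name__)

_SHAPE_FEATURES = ("area", "perimeter", "eccentricity", "solidity", "extent")
_INTENSITY_STATS = ("mean", "sd", "median", "p10", "p90", "integrated")

#: Fixed feature ordering: five shape features, then six intensity
#: statistics per channel in (ck818, vimentin, hoechst) order.
FEATURE_NAMES: tuple[str, ...] = _SHAPE_FEATURES + tuple(
    f"{ch}_{stat}"
    for ch in ("ck818", "vimentin", "hoechst")
    for stat in _INTENSITY_STATS
)


def regions_from_mask(mask: np.ndarray) -> list[CellRegion]:
    """One :class:`CellRegion` per distinct positive label, ascending label.

    Centroid is the mean of member pixel coordinates; eccentricity comes
    from the second-central-moment ellipse (0 = round, →1 = line).  A
    single-pixel region has eccentricity 0 by that convention.
    """
    mask = validate_label_mask(mask)
    out = []
    for rp in regionprops(mask):
        out.append(
            CellRegion(
                label=int(rp.label),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=int(rp.area),
                eccentricity=float(min(rp.eccentricity, np.nextafter(1.0, 0.0))),
                bbox=tuple(int(v) for v in rp.bbox),
            )
        )
    return out


def crop_cells(
    image: MultiChannelImage,
    mask: np.ndarray,
    box_size: int = 50,
    masked: bool = False,
    plate_id: str = "",
    well_id: str = "",
) -> tuple[list[SingleCellCrop], int]:
    """Extract a fixed-size crop per labelled cell.

    Returns ``(crops, n_excluded)`` where ``n_excluded`` counts edge cells
    whose full box did not fit inside the image; thus
    ``len(crops) + n_excluded`` equals the number of labels in the mask.
    """
    mask = validate_label_mask(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if box_size < 1:
        raise ValueError("box_size must be >= 1")
    h, w = image.shape
    half = box_size // 2

    crops: list[SingleCellCrop] = []
    n_excluded = 0
    for region in regions_from_mask(mask):
        r0 = int(np.floor(region.centroid[0])) - half
        c0 = int(np.floor(region.centroid[1])) - half
        if r0 < 0 or c0 < 0 or r0 + box_size > h or c0 + box_size > w:
            n_excluded += 1
            continue
        block = image.pixels[:, r0 : r0 + box_size, c0 : c0 + box_size].copy()
        if masked:
            keep = mask[r0 : r0 + box_size, c0 : c0 + box_size] == region.label
            block *= keep[None, :, :]
        crops.append(
            SingleCellCrop(
                pixels=block,
                label=region.label,
                masked=masked,
                plate_id=plate_id,
                well_id=well_id,
            )
        )
    if n_excluded:
        logger.info(
            "crop_cells: excluded %d edge cell(s) in %s/%s (box %d)",
            n_excluded, plate_id or "?", well_id or "?", box_size,
        )
    return crops, n_excluded


def handcrafted_features(
    image: MultiChannelImage, region: CellRegion, mask: np.ndarray
) -> np.ndarray:
    """Shape + per-channel intensity feature vector for one cell.

    Ordering is :data:`FEATURE_NAMES`: area, perimeter, eccentricity,
    solidity, extent, then (mean, sd, median, p10, p90, integrated
    intensity) over the cell's labelled pixels for each channel.  Perimeter
    uses the regionprops contour approximation, under which a single-pixel
    region has perimeter 0; sd is the population standard deviation.
    """
    mask = validate_label_mask(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    r0, c0, r1, c1 = region.bbox
    sub = mask[r0:r1, c0:c1] == region.label
    if not sub.any():
        raise ValueError(f"label {region.label} absent from mask")
    rp = regionprops(sub.astype(np.uint8))[0]
    shape_part = [
        float(region.area),
        float(rp.perimeter),
        float(region.eccentricity),
        float(rp.solidity),
        float(rp.extent),
    ]
    member = mask == region.label
    intensity_part = []
    for c in range(3):
        vals = image.pixels[c][member]
        intensity_part.extend(
            [
                float(vals.mean()),
                float(vals.std()),
                float(np.median(vals)),
                float(np.percentile(vals, 10)),
                float(np.percentile(vals, 90)),
                float(vals.sum()),
            ]
        )
    return np.array(shape_part + intensity_part)


def handcrafted_feature_table(
    image: MultiChannelImage,
    mask: np.ndarray,
    plate_id: str = "",
    well_id: str = "",
) -> "pd.DataFrame":
    """Handcrafted features for every cell in a mask, one row per label."""
    import pandas as pd

    regions = regions_from_mask(mask)
    rows = []
    for region in regions:
        vec = handcrafted_features(image, region, mask)
        row = {"plate_id": plate_id, "well_id": well_id, "cell_label": region.label}
        row.update(dict(zip(FEATURE_NAMES, vec)))
        rows.append(row)
    cols = ["plate_id", "well_id", "cell_label", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


class MockExtractor:
    """Deterministic stand-in for a CNN embedding extractor.

    Pools simple per-channel statistics from the crop (mean, sd, and three
    quantiles per channel, plus the nonzero-pixel fraction) and applies a
    fixed seeded random projection to ``dim`` outputs.  Identical crops map
    to identical embeddings; any intensity change perturbs the pooled
    statistics and hence the embedding.
    """

    _N_POOLED = 16

    def __init__(self, dim: int = 32, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((dim, self._N_POOLED)) / np.sqrt(
            self._N_POOLED
        )

    def _pool(self, pixels: np.ndarray) -> np.ndarray:
        stats = []
        for c in range(3):
            ch = pixels[c]
            stats.extend(
                [
                    ch.mean(),
                    ch.std(),
                    np.percentile(ch, 10),
                    np.percentile(ch, 50),
                    np.percentile(ch, 90),
                ]
            )
        stats.append((pixels != 0).mean())
        return np.asarray(stats)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim != 3 or pixels.shape[0] != 3:
            raise ValueError("extractor input must be (3, box, box)")
        return self._projection @ self._pool(pixels)


def embed_features(
    crops: Sequence[SingleCellCrop],
    extractor: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Apply an opaque embedding extractor to each crop; rows are cells.

    The extractor maps a ``(3, box, box)`` block to a fixed-length vector;
    inconsistent output lengths raise.  Returns an ``(n_crops, dim)`` array
    (``(0, 0)`` for no crops).
    """
    rows = []
    dim = None
    for i, crop in enumerate(crops):
        vec = np.asarray(extractor(crop.pixels), dtype=np.float64).ravel()
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(
                f"extractor returned length {vec.size} for crop {i}, expected {dim}"
            )
        rows.append(vec)
    if not rows:
        return np.empty((0, 0))
    return np.vstack(rows)
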