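"""Shared domain containers for the co-culture profiling pipeline.

Conventions used throughout the package:

* images are channel-first ``float`` arrays of shape ``(3, H, W)`` with the
  fixed channel order ``(ck818, vimentin, hoechst)`` — cancer cytokeratin,
  fibroblast vimentin, and nuclear stain;
* label masks are ``(H, W)`` non-negative integer arrays where 0 is
  background and each positive value identifies one segmented cancer cell;
* pixel coordinates are 0-based ``(row, col)``, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fixed channel order used everywhere in the package.
CHANNEL_NAMES: tuple[str, str, str] = ("ck818", "vimentin", "hoechst")

#: Well roles recognised in plate layouts.
ROLES = ("negative_control", "positive_control", "treated")


@dataclass(frozen=True)
class WellAnnotation:
    """Metadata for one well of a plate.

    ``compound_id``, ``concentration_index`` and ``moa_label`` are ``None``
    for control wells; treated wells must carry all three.
    """

    well_id: str
    row: int
    col: int
    role: str
    compound_id: str | None = None
    concentration_index: int | None = None
    moa_label: str | None = None
    coculture: str = "KB"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == "treated":
            if self.compound_id is None or self.moa_label is None:
                raise ValueError(
                    f"treated well {self.well_id} must carry compound_id and moa_label"
                )
            if self.concentration_index is None or self.concentration_index < 1:
                raise ValueError(
                    f"treated well {self.well_id}: concentration_index must be >= 1"
                )


@dataclass(frozen=True)
class PlateLayout:
    """A plate's worth of annotated wells."""

    plate_id: str
    wells: tuple[WellAnnotation, ...]

    def __post_init__(self) -> None:
        coords = [(w.row, w.col) for w in self.wells]
        if len(set(coords)) != len(coords):
            raise ValueError(f"duplicate well coordinates on plate {self.plate_id}")

    def wells_by_role(self, role: str) -> tuple[WellAnnotation, ...]:
        return tuple(w for w in self.wells if w.role == role)

    @property
    def n_wells(self) -> int:
        return len(self.wells)


@dataclass
class MultiChannelImage:
    """Three-channel fluorescence image, channel-first ``(3, H, W)``."""

    pixels: np.ndarray
    channel_names: tuple[str, str, str] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError(
                f"expected (3, H, W) pixel array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channel_names.index(name)]


def validate_label_mask(mask: np.ndarray) -> np.ndarray:
    """Check label-mask conventions and return the mask as an integer array."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.allclose(mask, np.round(mask)):
            raise ValueError("label mask must contain integers")
        mask = mask.astype(np.int64)
    if mask.min() < 0:
        raise ValueError("label mask must be non-negative")
    return mask


@dataclass(frozen=True)
class CellRegion:
    """Geometry of one labelled object, regionprops conventions.

    ``bbox`` is half-open ``(min_row, min_col, max_row, max_col)``;
    ``eccentricity`` follows the second-central-moment ellipse convention
    (0 = circle, →1 = line segment).
    """

    label: int
    centroid: tuple[float, float]
    area: int
    eccentricity: float
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("region area must be >= 1")
        if not (0.0 <= self.eccentricity < 1.0 + 1e-12):
            raise ValueError("eccentricity must lie in [0, 1)")


@dataclass
class SingleCellCrop:
    """Fixed-size per-cell image block, channel-first ``(3, box, box)``.

    In masked mode every pixel whose mask label differs from ``label`` is
    exactly zero in all three channels.
    """

    pixels: np.ndarray
    label: int
    masked: bool
    plate_id: str = ""
    well_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError("crop must be (3, box, box)")
        if self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError("crop must be square")

    @property
    def box_size(self) -> int:
        return self.pixels.shape[1]


def layout_to_frame(layouts: Sequence[PlateLayout]) -> "pd.DataFrame":
    """Flatten one or more plate layouts to a tidy table."""
    import pandas as pd

    nan = float("nan")
    rows = []
    for layout in layouts:
        for w in layout.wells:
            rows.append(
                {
                    "plate_id": layout.plate_id,
                    "well_id": w.well_id,
                    "row": w.row,
                    "col": w.col,
                    "role": w.role,
                    "compound_id": w.compound_id if w.compound_id is not None else nan,
                    "concentration_index": (
                        w.concentration_index if w.concentration_index is not None else nan
                    ),
                    "moa_label": w.moa_label if w.moa_label is not None else nan,
                    "coculture": w.coculture,
                }
            )
    return pd.DataFrame(rows)
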