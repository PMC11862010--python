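"""Table schemas, configuration, and file I/O for the pipeline.

Tables travel as CSV or Parquet (chosen by extension).  The layout schema
is: plate_id, well_id, row, col, role, compound_id, concentration_index,
moa_label, coculture.  Unknown columns are tolerated with a warning and
preserved on passthrough; missing required columns are an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "LAYOUT_REQUIRED_COLUMNS",
    "read_layout",
    "write_layout",
    "read_table",
    "write_table",
    "layouts_from_frame",
]

LAYOUT_REQUIRED_COLUMNS = (
    "plate_id",
    "well_id",
    "role",
    "compound_id",
    "concentration_index",
    "moa_label",
)


@dataclass
class PipelineConfig:
    """Declarative configuration for an end-to-end run.

    Synthetic-mode defaults mirror the package's default screen scale:
    2 plates of 4 compounds x 5 concentrations plus 12+12 control wells,
    ~50 cells per well.
    """

    # paths (None = synthetic mode for inputs)
    images_dir: str | None = None
    masks_dir: str | None = None
    layout_path: str | None = None
    output_dir: str = "comorph_out"

    # synthetic scale
    n_plates: int = 2
    n_compounds: int = 4
    n_conc: int = 5
    n_moas: int = 2
    n_features: int = 8
    controls_per_role: int = 12
    cells_per_well: float = 50.0
    effect_size: float = 2.0
    cell_noise_sd: float = 1.0
    plate_sd: float = 0.5
    n_image_wells: int = 2
    write_images: bool = False

    # preprocessing
    overlap_px: int = 5
    smoothing_scale: float | None = None
    percentile: float = 99.0
    box_size: int = 50
    masked: bool = False

    # profiling
    mad_scale: bool = False
    min_cells: int = 1

    # enrichment
    alpha: float = 0.05
    n_perm: int = 1000
    metric: str = "pearson"
    leave_compound_out: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.box_size < 1:
            raise ValueError("box_size must be >= 1")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must lie in (0, 100]")
        if self.overlap_px < 0:
            raise ValueError("overlap_px must be >= 0")
        if self.metric not in ("pearson", "spearman"):
            raise ValueError("metric must be 'pearson' or 'spearman'")
        if self.n_conc < 1 or self.n_compounds < 1 or self.n_plates < 1:
            raise ValueError("synthetic scale parameters must be >= 1")
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a table as CSV or Parquet depending on the file extension."""
    path = Path(path)
    if path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported table format: {path.suffix!r}")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    raise ValueError(f"unsupported table format: {path.suffix!r}")


def write_layout(layout_frame: pd.DataFrame, path) -> None:
    missing = [c for c in LAYOUT_REQUIRED_COLUMNS if c not in layout_frame.columns]
    if missing:
        raise ValueError(f"layout missing required columns: {missing}")
    write_table(layout_frame, path)


def read_layout(path) -> pd.DataFrame:
    """Read and validate a layout table; unknown columns warn, missing raise."""
    frame = read_table(path)
    missing = [c for c in LAYOUT_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"layout at {path} missing required columns: {missing}")
    known = set(LAYOUT_REQUIRED_COLUMNS) | {"row", "col", "coculture"}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        logger.warning("read_layout: tolerating unknown columns %s", unknown)
    return frame


def layouts_from_frame(frame: pd.DataFrame):
    """Rebuild :class:`PlateLayout` objects from a tidy layout table."""
    from .containers import PlateLayout, WellAnnotation

    def _coords(rec) -> tuple[int, int]:
        row, col = getattr(rec, "row", None), getattr(rec, "col", None)
        if row is not None and col is not None and not pd.isna(row):
            return int(row), int(col)
        # fall back to parsing well ids like "A01"
        wid = str(rec.well_id)
        return ord(wid[0].upper()) - ord("A"), int(wid[1:]) - 1

    layouts = []
    for plate_id, sub in frame.groupby("plate_id", sort=True):
        wells = []
        for r in sub.itertuples(index=False):
            conc = r.concentration_index
            row, col = _coords(r)
            wells.append(
                WellAnnotation(
                    well_id=r.well_id,
                    row=row,
                    col=col,
                    role=r.role,
                    compound_id=None if pd.isna(r.compound_id) else str(r.compound_id),
                    concentration_index=None if pd.isna(conc) else int(conc),
                    moa_label=None if pd.isna(r.moa_label) else str(r.moa_label),
                    coculture=str(getattr(r, "coculture", "KB")),
                )
            )
        layouts.append(PlateLayout(plate_id=str(plate_id), wells=tuple(wells)))
    return layouts
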