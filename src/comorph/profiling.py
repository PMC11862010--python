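"""Well-level profiling: mean aggregation of cell features, per-plate robust
normalization against DMSO controls, and Z' plate quality scores.

A well profile is the mean of its cells' feature vectors.  Profiles are
normalized per plate and feature as

    z = (x - median(DMSO wells)) / MAD(DMSO wells)

with the raw (unscaled) median absolute deviation by default; the 1.4826
normal-consistency factor is available behind a flag.  Plate quality is
summarised by the Z' factor between positive (toxic) and negative (vehicle)
controls; Z' > 0.5 indicates adequate separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellProfiles",
    "NormalizationStats",
    "aggregate_well",
    "robust_normalize",
    "zprime",
    "plate_zprime",
    "ZPRIME_THRESHOLD",
    "MAD_CONSISTENCY",
]

logger = logging.getLogger(__name__)

#: Z' above this indicates adequate control separation.
ZPRIME_THRESHOLD = 0.5
#: Consistency factor making MAD estimate the normal sigma.
MAD_CONSISTENCY = 1.4826

_KEY_COLUMNS = ["plate_id", "well_id"]
_ANNOTATION_COLUMNS = [
    "role",
    "compound_id",
    "concentration_index",
    "moa_label",
    "coculture",
]


@dataclass
class WellProfiles:
    """Well-by-feature matrix with cell counts and layout annotations.

    ``frame`` has one row per well keyed by (plate_id, well_id), the
    annotation columns that were available, a ``cell_count`` column, and one
    column per feature (``feature_columns``).  Wells with no cells carry
    ``cell_count == 0`` and NaN features; they are flagged missing rather
    than zero-filled and are excluded from control statistics and ranking.
    """

    frame: pd.DataFrame
    feature_columns: list[str]

    def __post_init__(self) -> None:
        for col in _KEY_COLUMNS + ["cell_count"]:
            if col not in self.frame.columns:
                raise ValueError(f"WellProfiles frame missing column {col!r}")
        missing = [c for c in self.feature_columns if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature columns absent from frame: {missing}")

    @property
    def is_missing(self) -> pd.Series:
        return self.frame["cell_count"] == 0

    def values(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def drop_missing(self) -> "WellProfiles":
        return WellProfiles(
            self.frame.loc[~self.is_missing].reset_index(drop=True).copy(),
            list(self.feature_columns),
        )


def _infer_feature_columns(cells: pd.DataFrame) -> list[str]:
    cols = [c for c in cells.columns if c.startswith("f_")]
    if not cols:
        raise ValueError("no feature columns (f_*) found in cell table")
    return cols


def aggregate_well(
    cells: pd.DataFrame,
    feature_columns: list[str] | None = None,
    layout: pd.DataFrame | None = None,
) -> WellProfiles:
    """Mean-aggregate cell features to one profile per well.

    ``cells`` must carry plate_id and well_id on every row.  If ``layout``
    (a tidy layout table) is given, wells present in the layout but absent
    from the cell table are appended with ``cell_count = 0`` and NaN
    features (flagged missing), and annotation columns are taken from the
    layout; otherwise annotations are carried through from the cell table
    when present.
    """
    for col in _KEY_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table missing key column {col!r}")
    if feature_columns is None:
        feature_columns = _infer_feature_columns(cells)

    grouped = cells.groupby(_KEY_COLUMNS, sort=True)
    means = grouped[feature_columns].mean()
    counts = grouped.size().rename("cell_count")
    frame = pd.concat([counts, means], axis=1).reset_index()

    ann_cols = [c for c in _ANNOTATION_COLUMNS if c in cells.columns]
    if ann_cols:
        ann = grouped[ann_cols].first().reset_index()
        frame = ann.merge(frame, on=_KEY_COLUMNS, validate="1:1")

    if layout is not None:
        ann_cols = [c for c in _ANNOTATION_COLUMNS if c in layout.columns]
        keyed = layout[_KEY_COLUMNS + ann_cols].drop_duplicates(_KEY_COLUMNS)
        frame = keyed.merge(
            frame[_KEY_COLUMNS + ["cell_count"] + feature_columns],
            on=_KEY_COLUMNS,
            how="left",
            validate="1:1",
        )
        n_missing = int(frame["cell_count"].isna().sum())
        if n_missing:
            logger.info("aggregate_well: %d layout well(s) had no cells", n_missing)
        frame["cell_count"] = frame["cell_count"].fillna(0).astype(int)

    return WellProfiles(frame.reset_index(drop=True), list(feature_columns))


@dataclass
class NormalizationStats:
    """Per-plate, per-feature DMSO medians and MADs used for normalization."""

    medians: pd.DataFrame  # index plate_id, columns features
    mads: pd.DataFrame
    dropped_features: list[str] = field(default_factory=list)
    mad_scaled: bool = False


def robust_normalize(
    profiles: WellProfiles,
    mad_scale: bool = False,
    zero_mad_policy: str = "drop",
    epsilon: float = 1e-9,
) -> tuple[WellProfiles, NormalizationStats]:
    """Normalize each well against its own plate's DMSO control statistics.

    Every feature value becomes ``(x - median) / MAD`` with median and MAD
    computed over the plate's non-missing negative-control wells, so control
    wells end with per-plate median exactly 0.  With ``mad_scale`` the MAD
    is multiplied by 1.4826.  A feature whose control MAD is zero on any
    plate is dropped from the output (default) or floored at ``epsilon``
    when ``zero_mad_policy == "floor"``.

    Raises if any plate has fewer than two control wells with profiles.
    """
    if zero_mad_policy not in ("drop", "floor"):
        raise ValueError("zero_mad_policy must be 'drop' or 'floor'")
    frame = profiles.frame
    if "role" not in frame.columns:
        raise ValueError("profiles must carry a 'role' annotation column")
    feats = list(profiles.feature_columns)
    usable = frame.loc[~profiles.is_missing]
    controls = usable.loc[usable["role"] == "negative_control"]

    medians, mads = {}, {}
    for plate, sub in controls.groupby("plate_id"):
        if len(sub) < 2:
            raise ValueError(
                f"plate {plate}: need >= 2 negative-control wells, got {len(sub)}"
            )
        x = sub[feats].to_numpy(dtype=float)
        med = np.median(x, axis=0)
        mad = np.median(np.abs(x - med), axis=0)
        if mad_scale:
            mad = mad * MAD_CONSISTENCY
        medians[plate] = med
        mads[plate] = mad
    plates_in_data = set(frame["plate_id"].unique())
    if plates_in_data - set(medians):
        raise ValueError(
            f"plates without negative controls: {sorted(plates_in_data - set(medians))}"
        )

    med_df = pd.DataFrame(medians, index=feats).T
    mad_df = pd.DataFrame(mads, index=feats).T

    zero_mask = (mad_df == 0).any(axis=0)
    dropped: list[str] = []
    if zero_mask.any():
        if zero_mad_policy == "drop":
            dropped = list(mad_df.columns[zero_mask])
            logger.warning(
                "robust_normalize: dropping %d feature(s) with zero control MAD: %s",
                len(dropped), dropped,
            )
            feats = [f for f in feats if f not in dropped]
            med_df = med_df[feats]
            mad_df = mad_df[feats]
        else:
            mad_df = mad_df.mask(mad_df == 0, epsilon)

    out = frame.drop(columns=dropped).copy()
    for plate in med_df.index:
        rows = out["plate_id"] == plate
        x = out.loc[rows, feats].to_numpy(dtype=float)
        out.loc[rows, feats] = (x - med_df.loc[plate].to_numpy()) / mad_df.loc[
            plate
        ].to_numpy()

    stats = NormalizationStats(
        medians=med_df, mads=mad_df, dropped_features=dropped, mad_scaled=mad_scale
    )
    return WellProfiles(out, feats), stats


def zprime(positive_values, negative_values) -> float:
    """Z' factor: ``1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|``.

    Sample standard deviations (ddof=1).  Equal arm means make the statistic
    undefined; ``-inf`` is returned with a warning.  Zero variance in both
    arms with distinct means gives the ideal score 1.
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each control arm needs at least two values")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        logger.warning("zprime: control means are equal; returning -inf")
        return float("-inf")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta)


def plate_zprime(
    profiles: WellProfiles, readout: str = "cell_count"
) -> pd.DataFrame:
    """Per-plate Z' between positive and negative controls.

    The default readout is the per-well cancer cell count.  Returns a table
    with plate_id, zprime and a pass flag at the 0.5 threshold.
    """
    frame = profiles.frame
    if readout not in frame.columns:
        raise ValueError(f"readout column {readout!r} not present")
    rows = []
    for plate, sub in frame.groupby("plate_id"):
        pos = sub.loc[sub["role"] == "positive_control", readout]
        neg = sub.loc[sub["role"] == "negative_control", readout]
        z = zprime(pos, neg)
        rows.append({"plate_id": plate, "zprime": z, "passed": z > ZPRIME_THRESHOLD})
    return pd.DataFrame(rows)
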