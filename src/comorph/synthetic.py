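"""Synthetic screen generator: plate layouts, rendered wells, feature tables.

The generator stands in for a 384-well co-culture imaging screen so the whole
pipeline is testable without the deposited images.  It emulates the study
conditions: 384-well plates carrying 12 DMSO (negative) and 12 BzCl
(positive) control wells, compounds at five concentrations annotated with a
mechanism of action (MOA), two morphologically distinct cell populations
(round-ish cancer cells, elongated fibroblasts), smooth illumination
gradients, and 2x2 field-of-view tiling with edge overlap.

Every function is a pure function of its arguments and seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .containers import (
    CHANNEL_NAMES,
    MultiChannelImage,
    PlateLayout,
    WellAnnotation,
)

__all__ = [
    "EffectModel",
    "CellSpec",
    "SceneSpec",
    "PlateCapacityError",
    "generate_plate_layout",
    "random_scene",
    "render_well_image",
    "split_into_fovs",
    "simulate_feature_table",
]

#: Default synthetic scale: 2 plates x (4 compounds x 5 conc + 24 controls).
DEFAULT_N_COMPOUNDS = 4
DEFAULT_N_CONC = 5
DEFAULT_CONTROLS_PER_ROLE = 12
DEFAULT_CELLS_PER_WELL = ("poisson", 50)

#: Default dose-response multipliers: weak effects at the two lowest
#: concentrations, saturated at the top three.
DEFAULT_CONC_MULTIPLIERS = (0.25, 0.5, 1.0, 1.0, 1.0)


class PlateCapacityError(ValueError):
    """Requested layout does not fit on the plate."""


@dataclass(frozen=True)
class EffectModel:
    """Statistical model of drug-induced feature shifts.

    Cell-level features are drawn as

        baseline + moa_effect[moa] * conc_multiplier[c] + plate_effect + noise

    where ``plate_effect ~ N(0, plate_sd)`` per plate and feature, and
    ``noise ~ N(0, cell_noise_sd)`` per cell and feature.  Negative-control
    wells receive zero effect; positive-control wells receive
    ``positive_control_effect`` (a strong, MOA-independent shift emulating
    the toxic BzCl phenotype).
    """

    moa_effects: Mapping[str, tuple[float, ...]]
    conc_multipliers: tuple[float, ...] = DEFAULT_CONC_MULTIPLIERS
    cell_noise_sd: float = 1.0
    plate_sd: float = 0.5
    baseline: tuple[float, ...] | None = None
    positive_control_effect: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        dims = {len(v) for v in self.moa_effects.values()}
        if len(dims) > 1:
            raise ValueError("all MOA effect vectors must share one length")
        if self.n_features < 2:
            raise ValueError("feature dimension must be >= 2")
        if any(m < 0 for m in self.conc_multipliers):
            raise ValueError("concentration multipliers must be non-negative")
        for name in ("baseline", "positive_control_effect"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_features:
                raise ValueError(f"{name} length must equal feature dimension")

    @property
    def n_features(self) -> int:
        return len(next(iter(self.moa_effects.values())))

    def effect_for(self, moa: str, concentration_index: int) -> np.ndarray:
        mult = self.conc_multipliers[concentration_index - 1]
        return np.asarray(self.moa_effects[moa], dtype=float) * mult

    @classmethod
    def null(cls, moas: Sequence[str], n_features: int = 8, **kwargs) -> "EffectModel":
        """All-zero effects: treated wells distributed like DMSO wells."""
        zero = tuple(0.0 for _ in range(n_features))
        return cls(moa_effects={m: zero for m in moas}, **kwargs)

    @classmethod
    def with_target(
        cls,
        moas: Sequence[str],
        target_moa: str,
        shift: float,
        n_features: int = 8,
        **kwargs,
    ) -> "EffectModel":
        """Zero effects except ``target_moa``, shifted by ``shift`` on the
        first half of the feature axes (a shared, direction-consistent
        phenotype for that MOA)."""
        if target_moa not in moas:
            raise ValueError(f"{target_moa!r} not among MOAs")
        zero = tuple(0.0 for _ in range(n_features))
        vec = tuple(shift if i < max(1, n_features // 2) else 0.0 for i in range(n_features))
        effects = {m: (vec if m == target_moa else zero) for m in moas}
        return cls(moa_effects=effects, **kwargs)


def _well_id(row: int, col: int) -> str:
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def generate_plate_layout(
    n_compounds: int,
    n_conc: int,
    moa_assignment: Mapping[str, str],
    controls_per_role: int = DEFAULT_CONTROLS_PER_ROLE,
    seed: int = 0,
    plate_id: str = "P1",
    coculture: str = "KB",
    plate_shape: tuple[int, int] = (16, 24),
) -> PlateLayout:
    """Lay out controls and a compound x concentration grid on one plate.

    Wells are placed at seeded-random coordinates; every compound appears at
    every concentration index 1..n_conc exactly once.  ``moa_assignment``
    maps each compound id to its MOA label and must cover all compounds.

    Raises
    ------
    PlateCapacityError
        If the requested wells exceed the plate capacity.
    """
    if n_conc < 1:
        raise ValueError("n_conc must be >= 1")
    compounds = [f"C{i + 1:03d}" for i in range(n_compounds)]
    missing = [c for c in compounds if c not in moa_assignment]
    if missing:
        raise ValueError(f"moa_assignment missing compounds: {missing}")

    n_rows, n_cols = plate_shape
    capacity = n_rows * n_cols
    needed = n_compounds * n_conc + 2 * controls_per_role
    if needed > capacity:
        raise PlateCapacityError(
            f"layout needs {needed} wells but plate holds {capacity}"
        )

    rng = np.random.default_rng(seed)
    coords = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    order = rng.permutation(len(coords))[:needed]
    picked = [coords[i] for i in order]

    wells: list[WellAnnotation] = []
    it = iter(picked)
    for role in ("negative_control", "positive_control"):
        for _ in range(controls_per_role):
            r, c = next(it)
            wells.append(
                WellAnnotation(_well_id(r, c), r, c, role, coculture=coculture)
            )
    for compound in compounds:
        for conc in range(1, n_conc + 1):
            r, c = next(it)
            wells.append(
                WellAnnotation(
                    _well_id(r, c),
                    r,
                    c,
                    "treated",
                    compound_id=compound,
                    concentration_index=conc,
                    moa_label=moa_assignment[compound],
                    coculture=coculture,
                )
            )
    return PlateLayout(plate_id=plate_id, wells=tuple(wells))


@dataclass(frozen=True)
class CellSpec:
    """One simulated cell: population, position and ellipse geometry."""

    population: str  # "cancer" | "fibroblast"
    centroid: tuple[float, float]
    size: float  # equivalent radius, pixels
    orientation: float = 0.0  # radians
    eccentricity: float = 0.0

    def __post_init__(self) -> None:
        if self.population not in ("cancer", "fibroblast"):
            raise ValueError(f"unknown population {self.population!r}")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ValueError("eccentricity must lie in [0, 1)")
        if self.size <= 0:
            raise ValueError("cell size must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """The cells to render in one well image."""

    cells: tuple[CellSpec, ...] = ()

    @property
    def n_cancer(self) -> int:
        return sum(1 for c in self.cells if c.population == "cancer")

    @property
    def n_fibroblast(self) -> int:
        return sum(1 for c in self.cells if c.population == "fibroblast")


def random_scene(
    n_cancer: int,
    n_fibroblast: int,
    image_size: tuple[int, int] = (195, 195),
    seed: int = 0,
    margin: int = 15,
    min_separation: float = 18.0,
) -> SceneSpec:
    """Sample a non-overlapping scene.

    Cancer cells are near-round (eccentricity ~U[0, 0.4]); fibroblasts are
    elongated (eccentricity ~U[0.85, 0.97]).  Centroids are rejection-sampled
    with a minimum pairwise separation so labels stay distinct.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    placed: list[tuple[float, float]] = []

    def place() -> tuple[float, float]:
        for _ in range(10_000):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation**2 for pr, pc in placed):
                placed.append((r, c))
                return (r, c)
        raise RuntimeError("could not place cell without overlap; reduce density")

    cells: list[CellSpec] = []
    for _ in range(n_cancer):
        cells.append(
            CellSpec(
                "cancer",
                place(),
                size=rng.uniform(5.0, 8.0),
                orientation=rng.uniform(0, np.pi),
                eccentricity=rng.uniform(0.0, 0.4),
            )
        )
    for _ in range(n_fibroblast):
        cells.append(
            CellSpec(
                "fibroblast",
                place(),
                size=rng.uniform(6.0, 9.0),
                orientation=rng.uniform(0, np.pi),
                eccentricity=rng.uniform(0.85, 0.97),
            )
        )
    return SceneSpec(cells=tuple(cells))


def _ellipse_axes(size: float, eccentricity: float) -> tuple[float, float]:
    # equivalent radius r: a*b = r^2, with e^2 = 1 - (b/a)^2
    ratio = np.sqrt(1.0 - eccentricity**2)  # b/a
    a = size / ratio**0.5
    return a, a * ratio


def _make_illumination(
    illumination, image_size: tuple[int, int]
) -> np.ndarray:
    """Resolve an illumination spec to a positive (H, W) multiplier field.

    Accepted specs: ``None`` (flat), an ``(H, W)`` array, or a tuple
    ``("linear", axis, strength)`` giving a mean-1 linear ramp along
    ``axis`` spanning ``1 - strength`` .. ``1 + strength``.
    """
    h, w = image_size
    if illumination is None:
        return np.ones((h, w))
    if isinstance(illumination, np.ndarray):
        if illumination.shape != (h, w):
            raise ValueError("illumination field shape mismatch")
        if illumination.min() <= 0:
            raise ValueError("illumination field must be strictly positive")
        return illumination
    kind, axis, strength = illumination
    if kind != "linear":
        raise ValueError(f"unknown illumination spec {kind!r}")
    if not (0 <= strength < 1):
        raise ValueError("gradient strength must lie in [0, 1)")
    n = h if axis == 0 else w
    ramp = 1.0 + strength * (2.0 * np.arange(n) / max(n - 1, 1) - 1.0)
    field_ = ramp[:, None] * np.ones((1, w)) if axis == 0 else np.ones((h, 1)) * ramp[None, :]
    return field_


def render_well_image(
    scene: SceneSpec,
    image_size: tuple[int, int] = (195, 195),
    illumination=None,
    noise_sd: float = 2.0,
    seed: int = 0,
    background: float = 5.0,
    cell_intensity: float = 100.0,
    nucleus_intensity: float = 80.0,
) -> tuple[MultiChannelImage, np.ndarray]:
    """Render a three-channel well image plus its cancer label mask.

    Cells are anisotropic ellipses: cancer bodies light up the CK8/18
    channel, fibroblast bodies the vimentin channel, and a half-size nuclear
    ellipse at each centroid lights up the Hoechst channel.  The label mask
    covers cancer objects only, background 0, labels consecutive from 1 in
    scene order.  An illumination gradient multiplies all channels, then
    zero-mean Gaussian noise is added and the result clipped at 0.
    """
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError("image_size must be positive")
    rng = np.random.default_rng(seed)
    body = np.zeros((3, h, w))
    mask = np.zeros((h, w), dtype=np.int32)

    next_label = 1
    for cell in scene.cells:
        a, b = _ellipse_axes(cell.size, cell.eccentricity)
        rr, cc = draw_ellipse(
            cell.centroid[0], cell.centroid[1], a, b,
            shape=(h, w), rotation=cell.orientation,
        )
        chan = 0 if cell.population == "cancer" else 1
        body[chan, rr, cc] = cell_intensity
        if cell.population == "cancer":
            mask[rr, cc] = next_label
            next_label += 1
        nr, nc = draw_ellipse(
            cell.centroid[0], cell.centroid[1], a / 2.0, b / 2.0,
            shape=(h, w), rotation=cell.orientation,
        )
        body[2, nr, nc] = nucleus_intensity

    # overlap between cancer cells can swallow an earlier label entirely;
    # relabel so labels are consecutive from 1
    present = np.unique(mask[mask > 0])
    relabel = np.zeros(int(mask.max()) + 1, dtype=np.int32)
    relabel[present] = np.arange(1, len(present) + 1)
    mask = relabel[mask]

    field_ = _make_illumination(illumination, image_size)
    pixels = (background + body) * field_[None, :, :]
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, None)
    return MultiChannelImage(pixels), mask


def split_into_fovs(
    image: MultiChannelImage, overlap_px: int
) -> tuple[MultiChannelImage, MultiChannelImage, MultiChannelImage, MultiChannelImage]:
    """Split a square well image into four overlapping 2x2 tiles.

    Adjacent tiles share ``overlap_px`` rows/columns of identical pixels
    (copied from the parent image, never re-noised), so
    ``merge_fovs(split_into_fovs(img, o), o)`` is bit-identical to ``img``.
    Tiles are returned in (top-left, top-right, bottom-left, bottom-right)
    order.
    """
    h, w = image.shape
    if h != w:
        raise ValueError("split_into_fovs requires a square image")
    if overlap_px < 0:
        raise ValueError("overlap_px must be >= 0")
    if (h + overlap_px) % 2 != 0:
        raise ValueError(
            f"side {h} with overlap {overlap_px} does not split into equal tiles"
        )
    t = (h + overlap_px) // 2
    if overlap_px >= t:
        raise ValueError("overlap must be smaller than the tile side")
    px = image.pixels
    o = t - overlap_px
    tiles = (
        px[:, :t, :t],
        px[:, :t, o:],
        px[:, o:, :t],
        px[:, o:, o:],
    )
    return tuple(MultiChannelImage(p.copy()) for p in tiles)  # type: ignore[return-value]


def simulate_feature_table(
    layouts: PlateLayout | Sequence[PlateLayout],
    effects: EffectModel,
    cells_per_well=DEFAULT_CELLS_PER_WELL,
    seed: int = 0,
    positive_control_count_factor: float = 0.1,
) -> "pd.DataFrame":
    """Draw a cell-level feature table for one or more plates.

    ``cells_per_well`` is either an int (fixed count) or ``("poisson", mean)``.
    Positive-control wells get their expected cell count scaled by
    ``positive_control_count_factor`` (the toxic-control phenotype that the
    cell-count Z' readout relies on).  Columns: plate_id, well_id, role,
    compound_id, concentration_index, moa_label, coculture, cell_id,
    f_0..f_{d-1}.  Deterministic given the seed.
    """
    import pandas as pd

    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    d = effects.n_features
    baseline = (
        np.zeros(d) if effects.baseline is None else np.asarray(effects.baseline, float)
    )
    pos_effect = (
        np.full(d, 5.0) * effects.cell_noise_sd
        if effects.positive_control_effect is None
        else np.asarray(effects.positive_control_effect, float)
    )
    rng = np.random.default_rng(seed)

    records = []
    feats = []
    for layout in layouts:
        plate_effect = rng.normal(0.0, effects.plate_sd, size=d)
        for well in layout.wells:
            if isinstance(cells_per_well, int):
                mean_n = float(cells_per_well)
            else:
                kind, mean_n = cells_per_well
                if kind != "poisson":
                    raise ValueError(f"unknown cell-count spec {kind!r}")
            if well.role == "positive_control":
                mean_n *= positive_control_count_factor
            n_cells = (
                int(round(mean_n))
                if isinstance(cells_per_well, int)
                else int(rng.poisson(mean_n))
            )
            if well.role == "negative_control":
                shift = np.zeros(d)
            elif well.role == "positive_control":
                shift = pos_effect
            else:
                shift = effects.effect_for(well.moa_label, well.concentration_index)
            mu = baseline + shift + plate_effect
            x = mu[None, :] + rng.normal(0.0, effects.cell_noise_sd, size=(n_cells, d))
            feats.append(x)
            for i in range(n_cells):
                records.append(
                    (
                        layout.plate_id,
                        well.well_id,
                        well.role,
                        well.compound_id,
                        well.concentration_index,
                        well.moa_label,
                        well.coculture,
                        i + 1,
                    )
                )
    meta = pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "well_id",
            "role",
            "compound_id",
            "concentration_index",
            "moa_label",
            "coculture",
            "cell_id",
        ],
    )
    values = (
        np.concatenate(feats, axis=0) if feats else np.empty((0, d))
    )
    for j in range(d):
        meta[f"f_{j}"] = values[:, j]
    return meta
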