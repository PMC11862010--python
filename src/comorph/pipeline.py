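"""End-to-end orchestration: synthetic screen → profiles → MOA enrichment.

``run_pipeline`` ties the stages together and writes every intermediate
table plus a manifest (config, hash, master seed, package versions) into an
output directory.  All randomness flows from the single master seed in the
config, so a fixed config reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .containers import MultiChannelImage, PlateLayout, layout_to_frame
from .enrichment import moa_enrichment_scan, percent_enriched, results_to_frame
from .image_prep import (
    apply_illumination,
    estimate_illumination,
    merge_fovs,
    percentile_normalize,
    write_image_tiff,
    write_mask_tiff,
)
from .io import PipelineConfig, read_layout, write_table
from .profiling import WellProfiles, aggregate_well, plate_zprime, robust_normalize
from .single_cell import crop_cells, handcrafted_feature_table
from .synthetic import (
    EffectModel,
    generate_plate_layout,
    random_scene,
    render_well_image,
    simulate_feature_table,
    split_into_fovs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "default_moa_names",
    "default_moa_assignment",
    "default_effect_model",
    "synthetic_layouts",
    "apply_min_cells",
    "run_pipeline",
]

#: MOA vocabulary used for synthetic screens (drug target classes).
MOA_NAMES = (
    "PARP",
    "MEK1/2",
    "HDAC",
    "Topoisomerase",
    "EGFR",
    "CDK",
    "PI3K",
    "VEGFR",
    "BET",
    "Mitotic",
)


def default_moa_names(n_moas: int) -> tuple[str, ...]:
    if n_moas <= len(MOA_NAMES):
        return MOA_NAMES[:n_moas]
    return MOA_NAMES + tuple(f"MOA_{i}" for i in range(len(MOA_NAMES), n_moas))


def default_moa_assignment(n_compounds: int, n_moas: int) -> dict[str, str]:
    """Round-robin compound→MOA map over a drug-target vocabulary."""
    moas = default_moa_names(n_moas)
    return {f"C{i + 1:03d}": moas[i % n_moas] for i in range(n_compounds)}


def default_effect_model(
    moas: Sequence[str],
    n_features: int,
    effect_size: float,
    seed: int,
    cell_noise_sd: float = 1.0,
    plate_sd: float = 0.5,
) -> EffectModel:
    """One random unit direction per MOA, scaled to ``effect_size``.

    Compounds sharing a MOA therefore share a phenotypic direction, which is
    what the enrichment statistic is designed to detect.
    """
    rng = np.random.default_rng(seed)
    effects = {}
    for moa in moas:
        v = rng.standard_normal(n_features)
        v *= effect_size / np.linalg.norm(v)
        effects[moa] = tuple(v)
    return EffectModel(
        moa_effects=effects, cell_noise_sd=cell_noise_sd, plate_sd=plate_sd
    )


def synthetic_layouts(config: PipelineConfig) -> list[PlateLayout]:
    assignment = default_moa_assignment(config.n_compounds, config.n_moas)
    return [
        generate_plate_layout(
            config.n_compounds,
            config.n_conc,
            assignment,
            controls_per_role=config.controls_per_role,
            seed=config.seed + i,
            plate_id=f"P{i + 1}",
        )
        for i in range(config.n_plates)
    ]


def apply_min_cells(profiles: WellProfiles, min_cells: int) -> WellProfiles:
    """Drop wells with fewer than ``min_cells`` cells (logged)."""
    if min_cells <= 0:
        return profiles
    keep = profiles.frame["cell_count"] >= min_cells
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("apply_min_cells: dropping %d well(s) below %d cells", n_drop, min_cells)
    return WellProfiles(
        profiles.frame.loc[keep].reset_index(drop=True).copy(),
        list(profiles.feature_columns),
    )


def _image_stage(
    config: PipelineConfig, layouts: Sequence[PlateLayout], outdir: Path
) -> pd.DataFrame:
    """Render a few wells, run the image preprocessing path, and extract
    handcrafted features — exercises the full image pipeline at small scale."""
    layout = layouts[0]
    wells = [w for w in layout.wells if w.role == "treated"][: config.n_image_wells]
    tables = []
    merged_images = []
    scenes_masks = []
    for i, well in enumerate(wells):
        scene = random_scene(
            n_cancer=12, n_fibroblast=8, seed=config.seed + 1000 + i
        )
        image, mask = render_well_image(
            scene,
            illumination=("linear", 1, 0.2),
            noise_sd=2.0,
            seed=config.seed + 2000 + i,
        )
        # tile and re-merge, as the raw screen's 4-FOV acquisition would
        tiles = split_into_fovs(image, config.overlap_px)
        merged = merge_fovs(tiles, config.overlap_px)
        merged_images.append(merged)
        scenes_masks.append((well, merged, mask))

    profile = estimate_illumination(merged_images, config.smoothing_scale)
    for well, merged, mask in scenes_masks:
        corrected = apply_illumination(merged, profile)
        normed = MultiChannelImage(
            np.stack(
                [
                    percentile_normalize(corrected.pixels[c], q=config.percentile)
                    for c in range(3)
                ]
            )
        )
        crops, n_excl = crop_cells(
            normed, mask, box_size=config.box_size, masked=config.masked,
            plate_id=layout.plate_id, well_id=well.well_id,
        )
        logger.info(
            "image stage %s/%s: %d crops, %d excluded",
            layout.plate_id, well.well_id, len(crops), n_excl,
        )
        table = handcrafted_feature_table(
            normed, mask, plate_id=layout.plate_id, well_id=well.well_id
        )
        tables.append(table)
        if config.write_images:
            imdir = outdir / "images"
            imdir.mkdir(exist_ok=True)
            write_image_tiff(imdir / f"{layout.plate_id}_{well.well_id}.tif", normed)
            write_mask_tiff(imdir / f"{layout.plate_id}_{well.well_id}_mask.tif", mask)
    return (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame()
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline per the config; returns the output directory.

    In synthetic mode (no layout path) the screen is generated from the
    config's scale parameters.  Outputs: layout.csv, cell_features.csv,
    image_cell_features.csv, well_profiles.csv, normalized_profiles.csv,
    zprime.csv, enrichment_results.csv, moa_summary.csv, manifest.json.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.layout_path is not None:
        layout_frame = read_layout(config.layout_path)
        from .io import layouts_from_frame

        layouts = layouts_from_frame(layout_frame)
    else:
        layouts = synthetic_layouts(config)
        layout_frame = layout_to_frame(layouts)
    write_table(layout_frame, outdir / "layout.csv")

    moas = sorted(
        {w.moa_label for lay in layouts for w in lay.wells if w.moa_label is not None}
    )
    effects = default_effect_model(
        moas,
        config.n_features,
        config.effect_size,
        seed=config.seed + 7,
        cell_noise_sd=config.cell_noise_sd,
        plate_sd=config.plate_sd,
    )
    cells = simulate_feature_table(
        layouts,
        effects,
        cells_per_well=("poisson", config.cells_per_well),
        seed=config.seed + 11,
    )
    write_table(cells, outdir / "cell_features.csv")

    image_cells = _image_stage(config, layouts, outdir)
    write_table(image_cells, outdir / "image_cell_features.csv")

    profiles = aggregate_well(cells, layout=layout_frame)
    write_table(profiles.frame, outdir / "well_profiles.csv")

    zp = plate_zprime(profiles, readout="cell_count")
    write_table(zp, outdir / "zprime.csv")

    profiles = apply_min_cells(profiles, config.min_cells)
    normalized, stats = robust_normalize(profiles, mad_scale=config.mad_scale)
    write_table(normalized.frame, outdir / "normalized_profiles.csv")

    results = moa_enrichment_scan(
        normalized,
        alpha=config.alpha,
        n_perm=config.n_perm,
        leave_compound_out=config.leave_compound_out,
        metric=config.metric,
        seed=config.seed,
    )
    write_table(results_to_frame(results), outdir / "enrichment_results.csv")
    summary = percent_enriched(results)
    write_table(summary, outdir / "moa_summary.csv")

    manifest = {
        "package": "comorph",
        "version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "n_wells": int(len(layout_frame)),
        "n_cells_simulated": int(len(cells)),
        "dropped_features": stats.dropped_features,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
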