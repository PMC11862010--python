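"""Simulation studies: type-I calibration and MOA recovery.

These run the full statistical path — synthetic screen → well aggregation →
per-plate robust normalization → MOA enrichment scan — under controlled
effect models, and summarise the operating characteristics of the
enrichment statistic:

* under a null effect model (no drug induces any morphological change) the
  fraction of query wells called enriched at level alpha estimates the
  type-I error of the permutation test;
* with one MOA given a strong shared phenotype, that MOA's percent-enriched
  measures recovery power while the untouched MOAs measure specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import layout_to_frame
from .enrichment import moa_enrichment_scan, percent_enriched, results_to_frame
from .pipeline import default_moa_assignment, default_moa_names
from .profiling import aggregate_well, plate_zprime, robust_normalize
from .synthetic import EffectModel, generate_plate_layout, simulate_feature_table

__all__ = ["StudyResult", "run_enrichment_study", "type_one_error_study", "moa_recovery_study"]


@dataclass
class StudyResult:
    """Outputs of one simulation study."""

    results_frame: pd.DataFrame
    summary: pd.DataFrame
    enriched_fraction: float
    n_queries: int
    zprime: pd.DataFrame


def run_enrichment_study(
    effects: EffectModel,
    n_plates: int,
    n_compounds: int,
    n_conc: int,
    moa_assignment: dict[str, str],
    seed: int,
    alpha: float = 0.05,
    n_perm: int = 1000,
    cells_per_well: float = 50.0,
    leave_compound_out: bool = False,
) -> StudyResult:
    """Simulate a screen under ``effects`` and scan every treated well."""
    layouts = [
        generate_plate_layout(
            n_compounds, n_conc, moa_assignment,
            seed=seed + i, plate_id=f"P{i + 1}",
        )
        for i in range(n_plates)
    ]
    layout_frame = layout_to_frame(layouts)
    cells = simulate_feature_table(
        layouts, effects, cells_per_well=("poisson", cells_per_well), seed=seed + 101
    )
    profiles = aggregate_well(cells, layout=layout_frame)
    zp = plate_zprime(profiles)
    normalized, _ = robust_normalize(profiles)
    results = moa_enrichment_scan(
        normalized, alpha=alpha, n_perm=n_perm,
        leave_compound_out=leave_compound_out, seed=seed,
    )
    frame = results_to_frame(results)
    computable = frame.loc[frame["computable"]]
    frac = float(computable["enriched"].mean()) if len(computable) else float("nan")
    return StudyResult(
        results_frame=frame,
        summary=percent_enriched(results),
        enriched_fraction=frac,
        n_queries=int(len(computable)),
        zprime=zp,
    )


def type_one_error_study(
    seed: int = 0,
    n_plates: int = 10,
    n_moas: int = 8,
    compounds_per_moa: int = 3,
    n_conc: int = 5,
    n_features: int = 8,
    alpha: float = 0.05,
    n_perm: int = 1000,
) -> StudyResult:
    """Enrichment scan under the null effect model (zero effects everywhere).

    Default scale gives 10 plates x 24 compounds x 5 concentrations = 1200
    query wells.  The enriched fraction should sit near ``alpha``.
    """
    n_compounds = n_moas * compounds_per_moa
    assignment = default_moa_assignment(n_compounds, n_moas)
    effects = EffectModel.null(default_moa_names(n_moas), n_features=n_features)
    return run_enrichment_study(
        effects, n_plates, n_compounds, n_conc, assignment,
        seed=seed, alpha=alpha, n_perm=n_perm,
    )


def moa_recovery_study(
    seed: int = 0,
    target_moa: str = "PARP",
    shift: float = 3.0,
    n_plates: int = 2,
    n_moas: int = 8,
    compounds_per_moa: int = 3,
    n_conc: int = 5,
    n_features: int = 8,
    alpha: float = 0.05,
    n_perm: int = 1000,
    leave_compound_out: bool = False,
) -> StudyResult:
    """One MOA carries a shared phenotypic shift; the rest are null.

    The target MOA's effect is ``shift`` cell-level noise sd per affected
    feature, scaled by the dose curve (0.25, 0.5, 1, 1, 1), so the top three
    concentrations see the full shift.
    """
    n_compounds = n_moas * compounds_per_moa
    assignment = default_moa_assignment(n_compounds, n_moas)
    moas = default_moa_names(n_moas)
    effects = EffectModel.with_target(moas, target_moa, shift, n_features=n_features)
    return run_enrichment_study(
        effects, n_plates, n_compounds, n_conc, assignment,
        seed=seed, alpha=alpha, n_perm=n_perm,
        leave_compound_out=leave_compound_out,
    )
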