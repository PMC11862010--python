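"""Mechanism-of-action (MOA) enrichment over correlation-ranked well profiles.

For a query well, all eligible treated wells are ranked by the correlation
of their normalized profiles with the query (descending, query first at
self-correlation 1).  A running sum walks down the ranking: +1/N_hit at
wells sharing the query's MOA, -1/N_miss otherwise (the unweighted
Kolmogorov-Smirnov scheme, so the curve ends at exactly 0 and the maximum —
the enrichment score *es* — lies in [0, 1]).  Significance comes from a
permutation null: the MOA labels at ranks 2..N are shuffled (rank 1 stays
fixed), es is recomputed per shuffle, and the p-value is the proportion of
shuffled scores strictly greater than the observed one.  A well is called
enriched when p < alpha.

The leave-compound-out variant removes the query compound's other wells
from the ranking before scoring, so enrichment cannot be driven by the
query compound's own sibling concentrations.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiling import WellProfiles

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "correlation_ranking",
    "running_enrichment_score",
    "permutation_pvalue",
    "moa_enrichment_scan",
    "percent_enriched",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

#: Tie guard for comparing enrichment scores.  Distinct es values on a
#: ranked list differ by at least 1/(N_hit * N_miss), far above this, while
#: cumsum rounding can perturb mathematically equal scores by ~1e-16; the
#: guard keeps "strictly greater" meaning strictly greater in exact
#: arithmetic.
ES_TIE_TOL = 1e-9


def well_key(plate_id: str, well_id: str) -> str:
    """Canonical string key for a well."""
    return f"{plate_id}:{well_id}"


@dataclass
class RankedList:
    """Correlation-ranked wells for one query.

    ``correlations`` is non-increasing; ties are broken by well key so the
    ordering is reproducible.  When the query is included it sits at rank 1
    with self-correlation 1.
    """

    well_keys: tuple[str, ...]
    correlations: np.ndarray
    moa_labels: tuple[str, ...]
    query_key: str
    query_moa: str

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if not (
            len(self.well_keys) == self.correlations.size == len(self.moa_labels)
        ):
            raise ValueError("ranked list fields must share one length")
        if np.any(np.diff(self.correlations) > 1e-12):
            raise ValueError("correlations must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.well_keys)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise average ranks (for Spearman)."""
    from scipy.stats import rankdata

    return rankdata(x, axis=1)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and scale each row to unit norm; zero-variance rows -> NaN."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / norms


def correlation_ranking(
    query_key: str,
    profiles: WellProfiles,
    metric: str = "pearson",
    exclusions: Iterable[str] = (),
    include_controls: bool = False,
) -> RankedList:
    """Rank eligible wells by profile correlation with the query well.

    Controls are excluded by default; wells in ``exclusions`` (canonical
    keys) are removed; the query itself is kept unless explicitly excluded.
    Wells with zero profile variance have undefined correlation and are
    dropped with a warning.
    """
    if metric not in ("pearson", "spearman"):
        raise ValueError("metric must be 'pearson' or 'spearman'")
    frame = profiles.frame.loc[~profiles.is_missing]
    keys = [well_key(p, w) for p, w in zip(frame["plate_id"], frame["well_id"])]
    frame = frame.assign(_key=keys)
    if not include_controls and "role" in frame.columns:
        keep = (frame["role"] == "treated") | (frame["_key"] == query_key)
        frame = frame.loc[keep]
    excl = set(exclusions)
    frame = frame.loc[~frame["_key"].isin(excl)]
    if query_key not in set(frame["_key"]):
        raise KeyError(f"query well {query_key!r} not among eligible profiles")

    x = frame[profiles.feature_columns].to_numpy(dtype=float)
    if metric == "spearman":
        x = _rank_rows(x)
    z = _standardize_rows(x)
    valid = ~np.isnan(z).any(axis=1)
    if not valid.all():
        dropped = list(frame["_key"].to_numpy()[~valid])
        logger.warning(
            "correlation_ranking: dropping %d zero-variance profile(s): %s",
            len(dropped), dropped[:5],
        )
        frame = frame.loc[valid]
        z = z[valid]
    keys_arr = frame["_key"].to_numpy()
    if query_key not in keys_arr:
        raise ValueError(f"query well {query_key!r} has a zero-variance profile")
    if len(keys_arr) < 2:
        raise ValueError("need at least two wells after exclusions")

    qi = int(np.flatnonzero(keys_arr == query_key)[0])
    corr = z @ z[qi]
    corr[qi] = 1.0  # exact self-correlation

    order = np.lexsort((keys_arr, -corr))
    moas = frame["moa_label"].fillna("").to_numpy()
    query_moa = str(moas[qi])
    return RankedList(
        well_keys=tuple(keys_arr[order]),
        correlations=corr[order],
        moa_labels=tuple(str(m) for m in moas[order]),
        query_key=query_key,
        query_moa=query_moa,
    )


def _labels_of(ranked) -> Sequence[str]:
    return ranked.moa_labels if isinstance(ranked, RankedList) else ranked


def _hit_increments(hits: np.ndarray) -> tuple[float, float]:
    n_hit = int(hits.sum())
    n_miss = hits.size - n_hit
    if n_hit == 0:
        raise ValueError("category absent from ranked list")
    if n_miss == 0:
        raise ValueError("category covers the whole ranked list")
    return 1.0 / n_hit, -1.0 / n_miss


def running_enrichment_score(ranked, category: str) -> tuple[float, np.ndarray]:
    """Enrichment score and running curve for one MOA category.

    Walking the ranking top-down, the running sum gains ``+1/N_hit`` at
    category matches and ``-1/N_miss`` at non-matches; es is the curve
    maximum.  The increments sum to zero, so the curve always ends at 0 and
    es is in [0, 1].  The statistic depends only on the label order, not on
    the correlation magnitudes.
    """
    labels = np.asarray(_labels_of(ranked))
    if labels.size == 0:
        raise ValueError("ranked list is empty")
    hits = labels == category
    up, down = _hit_increments(hits)
    curve = np.cumsum(np.where(hits, up, down))
    return float(curve.max()), curve


def _permuted_es(
    hits: np.ndarray, n_perm: int, rng: np.random.Generator, fix_first: bool
) -> np.ndarray:
    """es for ``n_perm`` label shuffles, vectorized over permutations."""
    up, down = _hit_increments(hits)
    start = 1 if fix_first else 0
    sub = hits[start:]
    idx = np.argsort(rng.random((n_perm, sub.size)), axis=1)
    perm = sub[idx]
    if fix_first:
        head = np.full((n_perm, 1), hits[0])
        perm = np.concatenate([head, perm], axis=1)
    curves = np.cumsum(np.where(perm, up, down), axis=1)
    return curves.max(axis=1)


def permutation_pvalue(
    ranked,
    category: str,
    n_perm: int = 1000,
    fix_first: bool = True,
    seed: int = 0,
    smoothed: bool = False,
) -> float:
    """Permutation p-value for the enrichment score.

    Labels at ranks 2..N are shuffled uniformly (rank-1 label fixed when
    ``fix_first``); p is the proportion of shuffled es values *strictly
    greater* than the observed es.  ``smoothed`` switches to the
    conservative ``(k + 1) / (n_perm + 1)`` estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(_labels_of(ranked))
    hits = labels == category
    es_obs, _ = running_enrichment_score(labels, category)
    rng = np.random.default_rng(seed)
    es_perm = _permuted_es(hits, n_perm, rng, fix_first)
    k = int(np.sum(es_perm > es_obs + ES_TIE_TOL))
    if smoothed:
        return (k + 1) / (n_perm + 1)
    return k / n_perm


@dataclass
class EnrichmentResult:
    """Per-query enrichment outcome."""

    query_key: str
    compound_id: str
    concentration_index: int
    moa: str
    coculture: str
    es: float
    p_value: float
    enriched: bool
    computable: bool
    n_permutations: int
    seed: int
    running_curve: np.ndarray | None = None


def _child_seed(master_seed: int, key: str) -> int:
    """Deterministic per-query seed below 2**31."""
    return int(
        np.random.SeedSequence(
            [int(master_seed), zlib.crc32(key.encode()) & 0x7FFFFFFF]
        ).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def moa_enrichment_scan(
    profiles: WellProfiles,
    alpha: float = 0.05,
    n_perm: int = 1000,
    leave_compound_out: bool = False,
    metric: str = "pearson",
    seed: int = 0,
    store_curves: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment of each treated well's own MOA across the whole screen.

    One result per treated, non-missing query well.  With
    ``leave_compound_out`` every other well of the query's compound is
    excluded from the ranking before scoring (the query itself remains).  A
    query is flagged not-computable when its MOA has fewer than two eligible
    wells or covers the entire ranking.  Per-query seeds derive
    deterministically from ``seed`` and the well key.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    frame = profiles.frame.loc[~profiles.is_missing]
    for col in ("role", "compound_id", "moa_label"):
        if col not in frame.columns:
            raise ValueError(f"profiles missing annotation column {col!r}")
    treated = frame.loc[frame["role"] == "treated"]
    if treated["moa_label"].isna().any() or treated["compound_id"].isna().any():
        raise ValueError("every treated well must carry compound_id and moa_label")

    results: list[EnrichmentResult] = []
    for row in treated.itertuples(index=False):
        qkey = well_key(row.plate_id, row.well_id)
        exclusions: set[str] = set()
        if leave_compound_out:
            sib = treated.loc[
                (treated["compound_id"] == row.compound_id)
            ]
            exclusions = {
                well_key(p, w) for p, w in zip(sib["plate_id"], sib["well_id"])
            } - {qkey}
        ranked = correlation_ranking(
            qkey, profiles, metric=metric, exclusions=exclusions
        )
        labels = np.asarray(ranked.moa_labels)
        hits = labels == ranked.query_moa
        n_hit = int(hits.sum())
        computable = 2 <= n_hit < labels.size
        coculture = getattr(row, "coculture", "")
        qseed = _child_seed(seed, qkey)
        if not computable:
            results.append(
                EnrichmentResult(
                    qkey, row.compound_id, int(row.concentration_index),
                    ranked.query_moa, coculture,
                    es=float("nan"), p_value=float("nan"), enriched=False,
                    computable=False, n_permutations=n_perm, seed=qseed,
                )
            )
            continue
        es, curve = running_enrichment_score(labels, ranked.query_moa)
        rng = np.random.default_rng(qseed)
        es_perm = _permuted_es(hits, n_perm, rng, fix_first=True)
        p = float(np.sum(es_perm > es + ES_TIE_TOL)) / n_perm
        results.append(
            EnrichmentResult(
                qkey, row.compound_id, int(row.concentration_index),
                ranked.query_moa, coculture,
                es=es, p_value=p, enriched=bool(p < alpha),
                computable=True, n_permutations=n_perm, seed=qseed,
                running_curve=curve if store_curves else None,
            )
        )
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (curves omitted)."""
    return pd.DataFrame(
        [
            {
                "query_key": r.query_key,
                "compound_id": r.compound_id,
                "concentration_index": r.concentration_index,
                "moa_label": r.moa,
                "coculture": r.coculture,
                "es": r.es,
                "p_value": r.p_value,
                "enriched": r.enriched,
                "computable": r.computable,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )


def percent_enriched(
    results: Sequence[EnrichmentResult],
    group_by: tuple[str, str] = ("coculture", "moa_label"),
) -> pd.DataFrame:
    """Percent of computable query wells enriched, per (co-culture, MOA).

    ``percent_enriched = 100 * n_enriched / n_total`` where ``n_total`` is
    the number of computable query results in the group; empty groups are
    omitted.
    """
    if len(results) == 0:
        raise ValueError("no enrichment results to summarise")
    frame = results_to_frame(results)
    frame = frame.loc[frame["computable"]]
    rows = []
    for keys, sub in frame.groupby(list(group_by), sort=True):
        n_total = len(sub)
        n_enriched = int(sub["enriched"].sum())
        rec = dict(zip(group_by, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(
            n_enriched=n_enriched,
            n_total=n_total,
            percent_enriched=100.0 * n_enriched / n_total,
        )
        rows.append(rec)
    return pd.DataFrame(rows)
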