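"""Correlation ranking, running enrichment score, permutation p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorph.enrichment import (
    EnrichmentResult,
    correlation_ranking,
    moa_enrichment_scan,
    percent_enriched,
    permutation_pvalue,
    results_to_frame,
    running_enrichment_score,
    well_key,
)
from comorph.profiling import WellProfiles


# --- independent oracles ---------------------------------------------------

def es_prefix_max_oracle(labels, category):
    """Brute-force running sum in pure Python: prefix max of KS increments."""
    n_hit = sum(1 for l in labels if l == category)
    n_miss = len(labels) - n_hit
    running, best = 0.0, -np.inf
    for l in labels:
        running += 1.0 / n_hit if l == category else -1.0 / n_miss
        best = max(best, running)
    return best


def exhaustive_pvalue_oracle(labels, category):
    """p over the full enumeration of non-first label permutations."""
    es_obs = es_prefix_max_oracle(labels, category)
    perms = list(itertools.permutations(labels[1:]))
    exceed = sum(
        1
        for perm in perms
        if es_prefix_max_oracle([labels[0], *perm], category) > es_obs + 1e-12
    )
    return exceed / len(perms)


def _profiles_from_matrix(x, moas, roles=None, compounds=None, concs=None):
    n = x.shape[0]
    frame = pd.DataFrame(
        {
            "plate_id": "P1",
            "well_id": [f"W{i:02d}" for i in range(n)],
            "role": roles or ["treated"] * n,
            "compound_id": compounds or [f"C{i:03d}" for i in range(n)],
            "concentration_index": concs or [1] * n,
            "moa_label": moas,
            "coculture": "KB",
            "cell_count": 10,
        }
    )
    feats = [f"f_{j}" for j in range(x.shape[1])]
    for j, f in enumerate(feats):
        frame[f] = x[:, j]
    return WellProfiles(frame, feats)


class TestCorrelationRanking:
    def test_query_ranks_first_with_self_correlation_one(self):
        rng = np.random.default_rng(0)
        profiles = _profiles_from_matrix(rng.normal(size=(6, 5)), ["A"] * 3 + ["B"] * 3)
        ranked = correlation_ranking("P1:W02", profiles)
        assert ranked.well_keys[0] == "P1:W02"
        assert ranked.correlations[0] == 1.0

    def test_exact_negation_ranks_last(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 6))
        x[4] = -x[0]
        profiles = _profiles_from_matrix(x, ["A", "B", "A", "B", "B"])
        ranked = correlation_ranking("P1:W00", profiles)
        assert ranked.well_keys[-1] == "P1:W04"
        assert ranked.correlations[-1] == pytest.approx(-1.0)

    def test_pearson_matches_brute_force_on_five_wells(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 7))
        profiles = _profiles_from_matrix(x, ["A", "B", "A", "B", "B"])
        ranked = correlation_ranking("P1:W01", profiles)
        for key, corr in zip(ranked.well_keys, ranked.correlations):
            i = int(key.split("W")[1])
            a, b = x[1], x[i]
            cov = np.mean((a - a.mean()) * (b - b.mean()))
            oracle = cov / (a.std() * b.std())
            assert corr == pytest.approx(oracle, abs=1e-12)

    def test_spearman_is_rank_based(self):
        # monotone but nonlinear relation: spearman 1, pearson < 1
        x = np.vstack([np.arange(1.0, 7.0), np.arange(1.0, 7.0) ** 5])
        profiles = _profiles_from_matrix(x, ["A", "B"])
        pear = correlation_ranking("P1:W00", profiles, metric="pearson")
        spear = correlation_ranking("P1:W00", profiles, metric="spearman")
        assert spear.correlations[1] == pytest.approx(1.0)
        assert pear.correlations[1] < 1.0 - 1e-6

    def test_controls_excluded_by_default(self):
        rng = np.random.default_rng(3)
        roles = ["treated"] * 4 + ["negative_control", "positive_control"]
        profiles = _profiles_from_matrix(
            rng.normal(size=(6, 5)), ["A", "B", "A", "B", "", ""], roles=roles
        )
        ranked = correlation_ranking("P1:W00", profiles)
        assert len(ranked) == 4

    def test_zero_variance_profile_dropped(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 5))
        x[3] = 2.5  # constant profile: correlation undefined
        profiles = _profiles_from_matrix(x, ["A", "B", "A", "B", "B"])
        ranked = correlation_ranking("P1:W00", profiles)
        assert "P1:W03" not in ranked.well_keys
        assert len(ranked) == 4

    def test_exclusions_removed(self):
        rng = np.random.default_rng(5)
        profiles = _profiles_from_matrix(rng.normal(size=(5, 5)), ["A"] * 5)
        ranked = correlation_ranking("P1:W00", profiles, exclusions={"P1:W01"})
        assert "P1:W01" not in ranked.well_keys


class TestRunningEnrichmentScore:
    @pytest.mark.parametrize(
        "labels, expected_es, expected_curve",
        [
            (["A", "A", "B", "B"], 1.0, [0.5, 1.0, 0.5, 0.0]),
            (["B", "B", "A", "A"], 0.0, [-0.5, -1.0, -0.5, 0.0]),
            (["A", "B", "A", "B"], 0.5, [0.5, 0.0, 0.5, 0.0]),
        ],
    )
    def test_hand_computed_cases(self, labels, expected_es, expected_curve):
        es, curve = running_enrichment_score(labels, "A")
        assert es == expected_es
        np.testing.assert_allclose(curve, expected_curve)

    def test_category_absent_or_universal_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            running_enrichment_score(["B", "B"], "A")
        with pytest.raises(ValueError, match="whole"):
            running_enrichment_score(["A", "A"], "A")

    @given(
        st.lists(st.sampled_from(["A", "B"]), min_size=2, max_size=30).filter(
            lambda ls: len(set(ls)) == 2
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_curve_ends_at_zero_and_es_in_unit_interval(self, labels):
        es, curve = running_enrichment_score(labels, "A")
        assert curve[-1] == pytest.approx(0.0, abs=1e-12)
        assert -1e-12 <= es <= 1.0 + 1e-12
        assert es == pytest.approx(curve.max())

    @given(
        st.lists(st.sampled_from(["A", "B"]), min_size=2, max_size=15).filter(
            lambda ls: len(set(ls)) == 2
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_prefix_max_oracle(self, labels):
        es, _ = running_enrichment_score(labels, "A")
        assert es == pytest.approx(es_prefix_max_oracle(labels, "A"), abs=1e-12)

    def test_depends_only_on_label_order(self):
        # es is a function of the ranked labels alone: two ranked lists with
        # identical label order but monotonically transformed correlation
        # values give the same score
        from comorph.enrichment import RankedList

        labels = ("A", "B", "A", "B", "B", "A")
        corr = np.array([1.0, 0.8, 0.5, 0.1, -0.2, -0.9])
        keys = tuple(f"P1:W{i:02d}" for i in range(6))
        r1 = RankedList(keys, corr, labels, "P1:W00", "A")
        r2 = RankedList(keys, np.tanh(3 * corr), labels, "P1:W00", "A")
        es1, _ = running_enrichment_score(r1, "A")
        es2, _ = running_enrichment_score(r2, "A")
        assert es1 == es2


class TestPermutationPvalue:
    def test_exhaustive_three_labels(self):
        # [A, A, B]: shuffling ranks 2-3 gives permuted es in {1.0, 0.5};
        # observed es 1.0 -> no shuffle strictly exceeds -> p = 0
        p = permutation_pvalue(["A", "A", "B"], "A", n_perm=200, seed=0)
        assert p == 0.0
        assert exhaustive_pvalue_oracle(["A", "A", "B"], "A") == 0.0

    def test_degenerate_tail_gives_zero(self):
        # all non-first labels identical: every shuffle reproduces the list
        p = permutation_pvalue(["A", "B", "B", "B"], "A", n_perm=100, seed=1)
        assert p == 0.0

    def test_deterministic_given_seed(self):
        labels = ["B", "A", "B", "A", "B", "B", "A"]
        p1 = permutation_pvalue(labels, "A", n_perm=500, seed=42)
        p2 = permutation_pvalue(labels, "A", n_perm=500, seed=42)
        assert p1 == p2

    def test_matches_exhaustive_enumeration_within_mc_error(self):
        labels = ["B", "A", "B", "A", "B", "A"]
        exact = exhaustive_pvalue_oracle(labels, "A")
        n_perm = 2000
        mc = permutation_pvalue(labels, "A", n_perm=n_perm, seed=3)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) <= 3 * se + 1e-12

    def test_smoothed_estimator(self):
        p = permutation_pvalue(["A", "A", "B"], "A", n_perm=99, seed=0, smoothed=True)
        assert p == pytest.approx(1.0 / 100.0)

    def test_fix_first_keeps_rank_one_label(self):
        # with the top label fixed and one hit total, the hit never moves:
        # every permuted es equals the observed es, p stays 0
        labels = ["A", "B", "B", "B", "B"]
        assert permutation_pvalue(labels, "A", n_perm=300, seed=5) == 0.0


class TestMoaEnrichmentScan:
    def _signal_profiles(self, seed=0, n_per_moa=6, d=6, shift=4.0):
        rng = np.random.default_rng(seed)
        moas, rows = [], []
        direction = np.zeros(d)
        direction[: d // 2] = 1.0
        for i in range(2 * n_per_moa):
            moa = "A" if i < n_per_moa else "B"
            x = rng.normal(size=d)
            if moa == "A":
                x = x + shift * direction
            rows.append(x)
            moas.append(moa)
        return _profiles_from_matrix(np.vstack(rows), moas)

    def test_shared_shift_enriches_target_moa(self):
        profiles = self._signal_profiles()
        results = moa_enrichment_scan(profiles, n_perm=500, seed=0)
        summary = percent_enriched(results)
        row = summary.set_index("moa_label")
        assert row.loc["A", "percent_enriched"] > 60.0

    def test_one_result_per_treated_query(self):
        profiles = self._signal_profiles()
        results = moa_enrichment_scan(profiles, n_perm=100, seed=0)
        assert len(results) == 12
        assert all(r.computable for r in results)

    def test_leave_compound_out_excludes_siblings(self, small_layout_frame):
        # single plate, 5 concentrations: each query's ranking loses
        # exactly n_conc - 1 = 4 sibling wells
        rng = np.random.default_rng(6)
        treated = small_layout_frame.loc[small_layout_frame["role"] == "treated"]
        x = rng.normal(size=(len(treated), 5))
        profiles = _profiles_from_matrix(
            x,
            list(treated["moa_label"]),
            compounds=list(treated["compound_id"]),
            concs=list(treated["concentration_index"]),
        )
        query = "P1:W00"
        full = correlation_ranking(query, profiles)
        siblings = {
            well_key("P1", f"W{i:02d}")
            for i, c in enumerate(profiles.frame["compound_id"])
            if c == profiles.frame["compound_id"].iloc[0]
        } - {query}
        assert len(siblings) == 4
        reduced = correlation_ranking(query, profiles, exclusions=siblings)
        assert len(full) - len(reduced) == 4
        assert query in reduced.well_keys

    def test_single_member_moa_not_computable(self):
        rng = np.random.default_rng(7)
        profiles = _profiles_from_matrix(
            rng.normal(size=(5, 5)), ["A", "B", "B", "B", "B"]
        )
        results = moa_enrichment_scan(profiles, n_perm=50, seed=0)
        by_moa = {r.moa: r for r in results}
        assert not by_moa["A"].computable
        assert np.isnan(by_moa["A"].p_value)

    def test_deterministic_given_master_seed(self):
        profiles = self._signal_profiles(seed=2)
        a = results_to_frame(moa_enrichment_scan(profiles, n_perm=200, seed=9))
        b = results_to_frame(moa_enrichment_scan(profiles, n_perm=200, seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestPercentEnriched:
    def _result(self, moa, enriched, computable=True, coculture="KB"):
        return EnrichmentResult(
            query_key="P1:W00", compound_id="C001", concentration_index=1,
            moa=moa, coculture=coculture, es=0.5,
            p_value=0.01 if enriched else 0.5, enriched=enriched,
            computable=computable, n_permutations=100, seed=0,
        )

    def test_three_of_five(self):
        results = [self._result("A", i < 3) for i in range(5)]
        summary = percent_enriched(results)
        assert summary["percent_enriched"].iloc[0] == 60.0

    def test_bounds(self):
        none = percent_enriched([self._result("A", False) for _ in range(4)])
        full = percent_enriched([self._result("A", True) for _ in range(4)])
        assert none["percent_enriched"].iloc[0] == 0.0
        assert full["percent_enriched"].iloc[0] == 100.0

    def test_totals_partition_computable_results(self):
        results = (
            [self._result("A", True) for _ in range(3)]
            + [self._result("B", False) for _ in range(2)]
            + [self._result("C", False, computable=False)]
        )
        summary = percent_enriched(results)
        assert summary["n_total"].sum() == 5  # non-computable excluded

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_enriched([])
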