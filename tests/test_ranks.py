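"""Rank engine: reference groups, relative rank, weighted rank, and the
comparator-counting invariants, checked against an O(n^2) brute-force
oracle."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ranknorms as rn
from tests.conftest import make_group


def brute_force_counts(values, idx):
    """O(n) pairwise comparator counting for member idx (the oracle)."""
    me = values[idx]
    below = sum(1 for j, v in enumerate(values) if j != idx and v < me)
    above = sum(1 for j, v in enumerate(values) if j != idx and v > me)
    return below, above


class TestReferenceGroups:
    def test_eight_groups_from_two_by_four(self, pool):
        groups = rn.build_reference_groups(pool)
        assert len(groups) == 8
        assert sum(g.n for g in groups.values()) == len(pool)
        assert set(groups) == {(g, l) for g in ("M", "F") for l in (1, 2, 3, 4)}

    def test_single_stratum_pool(self):
        df = pd.DataFrame(
            {"id": ["a", "b", "c"], "gender": "M", "location": 1,
             "brac_ug_per_100ml": [1.0, 2.0, 3.0]}
        )
        groups = rn.build_reference_groups(df)
        assert len(groups) == 1
        assert groups[("M", 1)].n == 3

    def test_missing_gender_rejected_with_log(self, caplog):
        df = pd.DataFrame(
            {"id": ["a", "b"], "gender": ["M", None], "location": [1, 1],
             "brac_ug_per_100ml": [1.0, 2.0]}
        )
        with caplog.at_level(logging.WARNING):
            groups = rn.build_reference_groups(df)
        assert groups[("M", 1)].n == 1
        assert "b" in caplog.text

    def test_mean_comparison_set_size_partition_invariant(self):
        """Any partition of 1,862 people into 8 groups averages (n_g - 1)
        to (1862 - 8)/8 = 231.75."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            cuts = np.sort(rng.choice(np.arange(1, 1862), size=7, replace=False))
            sizes = np.diff(np.concatenate([[0], cuts, [1862]]))
            groups = [make_group(np.arange(s), location=i) for i, s in enumerate(sizes)]
            assert rn.mean_comparison_set_size(groups) == pytest.approx(231.75)


class TestRelativeRank:
    def test_middle_of_five(self):
        g = make_group([10, 20, 30, 40, 50])
        assert rn.relative_rank(30, g) == pytest.approx(0.5)

    def test_unique_minimum_and_maximum(self):
        g = make_group([5, 10, 20, 40])
        assert rn.relative_rank(5, g) == 0.0
        assert rn.relative_rank(40, g) == 1.0

    def test_all_tied_group_is_half(self):
        g = make_group([7.0] * 6)
        assert rn.relative_rank(7.0, g) == 0.5
        assert rn.weighted_rank(7.0, g, eta=0.3) == 0.5

    def test_singleton_group_rank_missing(self, caplog):
        g = make_group([12.0])
        with caplog.at_level(logging.WARNING):
            assert np.isnan(rn.relative_rank(12.0, g))
            assert np.isnan(rn.weighted_rank(12.0, g, eta=1.0))

    def test_midrank_tie_mode(self):
        # values 10,20,20,20,30: a "20" has below=1, above=1, 2 ties
        g = make_group([10, 20, 20, 20, 30])
        assert rn.relative_rank(20, g) == pytest.approx(1 / 4)
        assert rn.relative_rank(20, g, ties="midrank") == pytest.approx((1 + 1.0) / 4)
        with pytest.raises(rn.RankParameterError):
            rn.relative_rank(20, g, ties="nearest")


class TestWeightedRank:
    def test_eta_one_identity_on_random_instances(self):
        """SR(eta=1) == R to 1e-12 over 1,000 random (below, above) pairs."""
        rng = np.random.default_rng(1)
        n = rng.integers(2, 300, size=1000)
        below = np.array([rng.integers(0, m) for m in n])
        above = np.array([rng.integers(0, m - b) for m, b in zip(n, below)])
        sr = rn.weighted_rank_from_counts(below, above, 1.0)
        with np.errstate(invalid="ignore"):
            r = np.where((below == 0) & (above == 0), 0.5, below / (below + above))
        # R uses below/(n-1); comparing against below/(below+above) is only
        # valid when there are no ties, so restrict to tie-free instances
        tie_free = below + above == n - 1
        np.testing.assert_allclose(sr[tie_free], (below / (n - 1))[tie_free], atol=1e-12)
        np.testing.assert_allclose(sr, r, atol=1e-12)

    def test_extremes_for_any_eta(self):
        g = make_group([1, 2, 3, 4, 5, 6])
        for eta in (0.01, 0.5, 1.0, 2.0, 5.0):
            assert rn.weighted_rank(1, g, eta) == pytest.approx(0.0, abs=1e-15)
            assert rn.weighted_rank(6, g, eta) == pytest.approx(1.0, abs=1e-15)

    def test_nondecreasing_in_brac_within_group(self):
        rng = np.random.default_rng(2)
        values = rng.normal(50, 30, 80)
        g = make_group(values)
        for eta in (0.14, 0.7, 1.0, 3.0):
            srs = [rn.weighted_rank(v, g, eta) for v in np.sort(values)]
            assert all(b >= a - 1e-15 for a, b in zip(srs, srs[1:]))

    def test_strictly_decreasing_in_eta_for_interior_members(self):
        """More weight on those above lowers perceived standing: SR falls
        strictly as eta grows whenever below > 0 and above > 0."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            below = int(rng.integers(1, 100))
            above = int(rng.integers(1, 100))
            etas = np.sort(rng.uniform(0.01, 5, 10))
            srs = [float(rn.weighted_rank_from_counts(below, above, e)) for e in etas]
            assert all(b < a for a, b in zip(srs, srs[1:]))

    def test_eta_must_be_positive(self):
        with pytest.raises(rn.RankParameterError):
            rn.weighted_rank_from_counts(3, 4, 0.0)

    @given(
        st.lists(st.integers(0, 60), min_size=2, max_size=200),
        st.floats(0.01, 5.0),
        st.integers(0, 10**6),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracle(self, values, eta, seed):
        """below/above/R/SR agree exactly with O(n^2) pairwise counting,
        on integer-valued groups (ties frequent by construction)."""
        values = [float(v) for v in values]
        idx = seed % len(values)
        g = make_group(values)
        below, above = brute_force_counts(values, idx)
        got_b, got_a = rn.comparator_counts(values[idx], g)
        assert (got_b, got_a) == (below, above)
        n = len(values)
        expect_r = 0.5 if below == above == 0 else below / (n - 1)
        assert rn.relative_rank(values[idx], g) == pytest.approx(expect_r, abs=1e-15)
        denom = below + eta * above
        expect_sr = 0.5 if denom == 0 else 0.5 + (below - eta * above) / (2 * denom)
        assert rn.weighted_rank(values[idx], g, eta) == pytest.approx(expect_sr, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(50, 30, 60)
        g1 = make_group(values)
        g2 = make_group(rng.permutation(values))
        for v in values[:10]:
            assert rn.relative_rank(v, g1) == rn.relative_rank(v, g2)
            assert rn.weighted_rank(v, g1, 0.7) == rn.weighted_rank(v, g2, 0.7)


class TestAssignRanks:
    def test_subsample_ranked_within_pool_groups(self, pool, judgements):
        """Judgment respondents are ranked against the full pool, so their
        comparator counts sum to (pool group size - 1 - ties)."""
        ranked = rn.assign_ranks(judgements.head(50), pool)
        groups = rn.build_reference_groups(pool)
        for _, row in ranked.iterrows():
            grp = groups[(row["gender"], int(row["location"]))]
            assert row["n_group"] == grp.n
            assert row["below"] + row["above"] <= grp.n - 1
            b, a = brute_force_counts(list(grp.brac_sorted),
                                      int(np.searchsorted(grp.brac_sorted, row["brac_ug_per_100ml"])))
            assert (row["below"], row["above"]) == (b, a)
            assert row["R"] == pytest.approx(row["below"] / (grp.n - 1))
            assert row["group_mean"] == pytest.approx(grp.mean_brac)

    def test_eta_column_matches_scalar_weighted_rank(self, pool, judgements):
        ranked = rn.assign_ranks(judgements.head(30), pool, eta=0.7)
        groups = rn.build_reference_groups(pool)
        for _, row in ranked.iterrows():
            grp = groups[(row["gender"], int(row["location"]))]
            assert row["SR"] == pytest.approx(
                rn.weighted_rank(row["brac_ug_per_100ml"], grp, 0.7), abs=1e-12
            )

    def test_rank_bounds(self, pool, judgements):
        ranked = rn.assign_ranks(judgements, pool, eta=0.37)
        assert ranked["R"].between(0, 1).all()
        assert ranked["SR"].between(0, 1).all()


class TestEligibility:
    def test_zero_brac_never_eligible(self):
        resp = {"brac_ug_per_100ml": 0.0, **{c: 5 for c in rn.RATING_COLUMNS}}
        assert not rn.judgement_eligible(resp)

    def test_partial_ratings_eligible_per_outcome(self):
        resp = {"brac_ug_per_100ml": 40.0, **{c: 5 for c in rn.RATING_COLUMNS}}
        resp["judge_extreme"] = np.nan
        assert not rn.judgement_eligible(resp)  # all four required
        assert rn.judgement_eligible(resp, outcome="judge_drunk")
        assert not rn.judgement_eligible(resp, outcome="judge_extreme")

    def test_covariate_requirement_for_model4(self):
        resp = {
            "brac_ug_per_100ml": 40.0, "gender": "M",
            "session_duration_h": 5.0, "survey_after_23h": 1,
            "fast_score": 6, "age_years": 25.0,
            **{c: 5 for c in rn.RATING_COLUMNS},
        }
        assert rn.judgement_eligible(resp, require_covariates=True)
        resp["fast_score"] = np.nan
        assert rn.judgement_eligible(resp)
        assert not rn.judgement_eligible(resp, require_covariates=True)
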