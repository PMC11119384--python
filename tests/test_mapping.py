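import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhkit.core import (
    BinaryMask,
    DegenerateInputError,
    InvalidSpecError,
    ProbabilityMap,
)
from wmhkit.mapping import (
    LABEL_A,
    LABEL_B,
    MatchSpec,
    build_probability_map,
    fdr_correct,
    match_samples,
    percent_voxels_different,
    standardized_mean_difference,
    threshold_difference_map,
    voxel_test_with_fdr,
    voxelwise_rank_test,
)
from wmhkit.synthetic import CohortSpec, generate_cohort, generate_mask_population


def masks_from(arrays):
    return [BinaryMask(np.asarray(a, dtype=bool)) for a in arrays]


class TestProbabilityMap:
    def test_identical_masks_reproduce_the_mask(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        pm = build_probability_map(masks_from([m] * 10))
        np.testing.assert_array_equal(pm.values, m.astype(float))
        assert pm.n == 10

    def test_fraction_arithmetic(self):
        shape = (4, 4, 4)
        on = [np.ones(shape)] * 73 + [np.zeros(shape)] * 73
        pm = build_probability_map(masks_from(on))
        assert np.all(pm.values == 0.5)

    def test_values_are_multiples_of_one_over_n(self, rng):
        masks = [rng.random((5, 5, 5)) < 0.5 for _ in range(7)]
        pm = build_probability_map(masks_from(masks))
        np.testing.assert_allclose(pm.values * 7, np.round(pm.values * 7), atol=1e-12)

    def test_binomial_recovery(self):
        pm_true = ProbabilityMap(np.full((8, 8, 8), 0.3), 1)
        masks = generate_mask_population(pm_true, 200, seed=3)
        pm = build_probability_map(masks)
        bound = 3 * np.sqrt(0.3 * 0.7 / 200)
        assert np.mean(np.abs(pm.values - 0.3) <= bound) >= 0.99

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_probability_map([])


class TestMatching:
    def test_identical_groups_fully_matched(self):
        df = generate_cohort(CohortSpec(n_lis=40, n_dich=0, seed=2))
        twin = df.copy()
        twin["phenotype"] = "dICH"
        both = pd.concat([df, twin], ignore_index=True)
        res = match_samples(both, "phenotype", MatchSpec(seed=0))
        assert res.n_pairs == 40
        assert res.pairs["distance"].max() == 0.0

    def test_caliper_excludes_distant_pair(self):
        """A {50, 60} vs B {51, 70} with a 5-year caliper: only (50, 51)
        is feasible (verified by exhausting the 2×2 assignments)."""
        df = pd.DataFrame({"g": ["A", "A", "B", "B"], "age": [50, 60, 51, 70]})
        spec = MatchSpec(exact_vars=(), continuous_vars=(("age", 5.0),), seed=9)
        res = match_samples(df, "g", spec)
        assert res.n_pairs == 1
        pair_ages = (
            df.loc[res.pairs["index_a"], "age"].iloc[0],
            df.loc[res.pairs["index_b"], "age"].iloc[0],
        )
        assert sorted(pair_ages) == [50, 51]

    def test_deterministic_under_seed(self, small_cohort):
        a = match_samples(small_cohort, "phenotype", MatchSpec(seed=5))
        b = match_samples(small_cohort, "phenotype", MatchSpec(seed=5))
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_matched_sample_is_balanced(self):
        """Post-matching standardized mean differences stay below 0.1 for
        every matched covariate."""
        cohort = generate_cohort(CohortSpec(seed=21))
        spec = MatchSpec(seed=1)
        res = match_samples(cohort, "phenotype", spec)
        assert res.n_pairs >= 100
        for var in spec.exact_vars + ("age",):
            assert standardized_mean_difference(cohort, res, var) < 0.1, var

    def test_infeasible_matching_warns_not_raises(self):
        df = pd.DataFrame({"g": ["A", "B"], "age": [20, 90], "sex": [0, 1]})
        spec = MatchSpec(exact_vars=("sex",), continuous_vars=(("age", 5.0),))
        with pytest.warns(UserWarning):
            res = match_samples(df, "g", spec)
        assert res.n_pairs == 0


def exact_permutation_p(a: int, b: int, n_a: int, n_b: int) -> float:
    """Exact two-sided permutation p of the rank-sum statistic for binary
    samples, via hypergeometric grouping over the count landing in group A."""
    N = n_a + n_b
    ones = a + b
    zeros = N - ones
    r0, r1 = (zeros + 1) / 2, zeros + (ones + 1) / 2
    expect = n_a * (N + 1) / 2
    ks = np.arange(max(0, ones - n_b), min(n_a, ones) + 1)
    w = (n_a - ks) * r0 + ks * r1
    pmf = stats.hypergeom.pmf(ks, N, ones, n_a)
    t_obs = abs(((n_a - a) * r0 + a * r1) - expect)
    return float(pmf[np.abs(w - expect) >= t_obs - 1e-9].sum())


class TestVoxelRankTest:
    def test_identical_groups_give_p_one(self, rng):
        masks = masks_from([rng.random((5, 5, 5)) < 0.5 for _ in range(6)])
        p, _ = voxelwise_rank_test(masks, masks)
        assert np.all(p == 1.0)

    def test_matches_scipy_tie_corrected_rank_sum(self):
        """At a voxel with 9/10 presence vs 1/10, the vectorized p must
        equal scipy's tie-corrected rank-sum p on the same 0/1 samples."""
        shape = (2, 2, 2)
        ga = masks_from([np.ones(shape)] * 9 + [np.zeros(shape)])
        gb = masks_from([np.ones(shape)] + [np.zeros(shape)] * 9)
        p, _ = voxelwise_rank_test(
            ga, gb, analysis_mask=BinaryMask(np.ones(shape, dtype=bool))
        )
        x = np.array([1.0] * 9 + [0.0])
        y = np.array([1.0] + [0.0] * 9)
        expected = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert p[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("a,b,n_a,n_b", [(9, 1, 10, 10), (5, 0, 10, 6), (3, 4, 10, 8)])
    def test_permutation_grouping_matches_label_enumeration(self, a, b, n_a, n_b):
        """The hypergeometric grouping used as oracle equals a literal
        enumeration of all label assignments."""
        data = np.concatenate(
            [np.ones(a), np.zeros(n_a - a), np.ones(b), np.zeros(n_b - b)]
        )
        ranks = stats.rankdata(data)
        expect = n_a * (n_a + n_b + 1) / 2
        t_obs = abs(ranks[:n_a].sum() - expect)
        hits = total = 0
        for comb in itertools.combinations(range(n_a + n_b), n_a):
            total += 1
            if abs(ranks[list(comb)].sum() - expect) >= t_obs - 1e-9:
                hits += 1
        assert exact_permutation_p(a, b, n_a, n_b) == pytest.approx(hits / total)

    @pytest.mark.parametrize("a,b", [(20, 10), (25, 8), (30, 12)])
    def test_normal_approximation_close_to_exact_at_n50(self, a, b):
        """In the significant tail at n = 50 per group the tie-corrected
        normal approximation tracks the exact permutation p closely."""
        shape = (1, 1, 1)
        ga = masks_from([np.ones(shape)] * a + [np.zeros(shape)] * (50 - a))
        gb = masks_from([np.ones(shape)] * b + [np.zeros(shape)] * (50 - b))
        p, _ = voxelwise_rank_test(
            ga, gb, analysis_mask=BinaryMask(np.ones(shape, dtype=bool))
        )
        assert p[0, 0, 0] == pytest.approx(exact_permutation_p(a, b, 50, 50), abs=0.02)

    def test_group_swap_symmetry(self, rng):
        ga = masks_from([rng.random((4, 4, 4)) < 0.5 for _ in range(8)])
        gb = masks_from([rng.random((4, 4, 4)) < 0.3 for _ in range(8)])
        full = BinaryMask(np.ones((4, 4, 4), dtype=bool))
        p_ab, _ = voxelwise_rank_test(ga, gb, analysis_mask=full)
        p_ba, _ = voxelwise_rank_test(gb, ga, analysis_mask=full)
        np.testing.assert_allclose(p_ab, p_ba, rtol=1e-12)

    def test_three_groups_use_kruskal_wallis(self, rng):
        shape = (1, 1, 1)
        groups = [
            masks_from([np.ones(shape)] * k + [np.zeros(shape)] * (8 - k))
            for k in (1, 4, 7)
        ]
        full = BinaryMask(np.ones(shape, dtype=bool))
        p, _ = voxelwise_rank_test(*groups, analysis_mask=full)
        samples = [
            np.array([1.0] * k + [0.0] * (8 - k)) for k in (1, 4, 7)
        ]
        expected = stats.kruskal(*samples).pvalue
        assert p[0, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_small_group_rejected(self, rng):
        m = masks_from([rng.random((3, 3, 3)) < 0.5])
        with pytest.raises(InvalidSpecError):
            voxelwise_rank_test(m, m)

    def test_type_one_error_calibrated(self):
        """Two independent populations from the same Bernoulli(0.3) map:
        the p < 0.05 fraction sits near the nominal rate and BH flags
        almost nothing."""
        pm = ProbabilityMap(np.full((20, 20, 20), 0.3), 1)
        ga = generate_mask_population(pm, 50, seed=41)
        gb = generate_mask_population(pm, 50, seed=42)
        full = BinaryMask(np.ones((20, 20, 20), dtype=bool))
        vt = voxel_test_with_fdr(ga, gb, analysis_mask=full, q=0.05)
        frac = float((vt.p_map < 0.05).mean())
        assert 0.02 <= frac <= 0.08
        assert vt.significant.n_voxels / 20**3 <= 0.01


class TestFdr:
    def test_hand_computed_bh_thresholds(self):
        """p = [.01, .02, .03, .04, .2] at q = .05: BH thresholds i/m·q are
        .01, .02, .03, .04, .05, so the first four are significant."""
        adj, flags = fdr_correct([0.01, 0.02, 0.03, 0.04, 0.2], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, True, True, False])
        np.testing.assert_allclose(adj[:4], [0.05, 0.05, 0.05, 0.05])
        assert adj[4] == pytest.approx(0.2)

    def test_all_tiny_p_all_flagged(self):
        adj, flags = fdr_correct([0.001] * 100, q=0.05)
        assert flags.all()

    def test_empty_input(self):
        adj, flags = fdr_correct([])
        assert adj.size == 0 and flags.size == 0

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(200)
        adj, _ = fdr_correct(p)
        assert np.all(adj >= p - 1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        adj, flags = fdr_correct(p, q=0.05)
        sm_flags, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, rtol=1e-10)
        np.testing.assert_array_equal(flags, sm_flags)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            fdr_correct([0.5, 1.2])

    def test_false_discovery_proportion_controlled(self, rng):
        """Average false-discovery proportion over 500 repetitions stays
        at or below q (within Monte-Carlo error) with uniform nulls and a
        block of genuine signals."""
        q = 0.05
        m0, m1 = 80, 20
        fdps = []
        for _ in range(500):
            p = np.concatenate([
                rng.random(m0),
                rng.beta(0.05, 10.0, m1) * 1e-2,
            ])
            _, flags = fdr_correct(p, q=q)
            n_rej = flags.sum()
            fdps.append(flags[:m0].sum() / n_rej if n_rej else 0.0)
        assert np.mean(fdps) <= q + 0.01


class TestDifferenceMap:
    def _pm(self, arr):
        return ProbabilityMap(np.asarray(arr, dtype=float), 10)

    def test_equal_maps_give_no_labels(self, rng):
        vals = rng.random((4, 4, 4))
        labels = threshold_difference_map(self._pm(vals), self._pm(vals))
        assert np.all(labels == 0)

    def test_forced_label(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a[0, 0, 0], b[0, 0, 0] = 0.8, 0.1
        labels = threshold_difference_map(self._pm(a), self._pm(b))
        assert labels[0, 0, 0] == LABEL_A

    def test_matches_brute_force_rule(self, rng):
        a = rng.random((10, 10, 10))
        b = rng.random((10, 10, 10))
        labels = threshold_difference_map(self._pm(a), self._pm(b), 0.75, 0.60)
        for idx in np.ndindex(3, 3, 3):  # spot-check a sub-block exhaustively
            va, vb = a[idx], b[idx]
            if va >= 0.75 and va > vb:
                assert labels[idx] == LABEL_A
            elif vb >= 0.60 and vb > va:
                assert labels[idx] == LABEL_B
            else:
                assert labels[idx] == 0

    def test_swap_mirrors_labels(self, rng):
        a, b = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        fwd = threshold_difference_map(self._pm(a), self._pm(b), 0.6, 0.6)
        rev = threshold_difference_map(self._pm(b), self._pm(a), 0.6, 0.6)
        np.testing.assert_array_equal(fwd == LABEL_A, rev == LABEL_B)
        np.testing.assert_array_equal(fwd == LABEL_B, rev == LABEL_A)

    def test_bad_threshold_rejected(self, rng):
        pm = self._pm(rng.random((3, 3, 3)))
        with pytest.raises(InvalidSpecError):
            threshold_difference_map(pm, pm, thrA=1.5)


class TestPercentDifferent:
    def test_full_overlap_is_hundred(self, rng):
        m = BinaryMask(rng.random((5, 5, 5)) < 0.5)
        assert percent_voxels_different(m, m) == pytest.approx(100.0)

    def test_fraction_arithmetic(self):
        union = np.zeros((5, 5, 5), dtype=bool)
        union.ravel()[:100] = True
        sig = np.zeros((5, 5, 5), dtype=bool)
        sig.ravel()[:8] = True
        got = percent_voxels_different(BinaryMask(sig), BinaryMask(union))
        assert got == pytest.approx(8.0)

    def test_empty_union_rejected(self):
        empty = BinaryMask(np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(DegenerateInputError):
            percent_voxels_different(empty, empty)

    def test_planted_fraction_recovered(self):
        """With a group difference planted in a known sub-region, the
        recovered percentage of different voxels lands within 3 points of
        the planted fraction."""
        base = np.full((10, 10, 10), 0.4)
        pa, pb = base.copy(), base.copy()
        pa[:5, :5, :5] = 0.85
        pb[:5, :5, :5] = 0.15
        ga = generate_mask_population(ProbabilityMap(pa, 1), 100, seed=7)
        gb = generate_mask_population(ProbabilityMap(pb, 1), 100, seed=8)
        full = BinaryMask(np.ones((10, 10, 10), dtype=bool))
        vt = voxel_test_with_fdr(ga, gb, analysis_mask=full, q=0.05)
        got = percent_voxels_different(vt.significant, full)
        assert got == pytest.approx(12.5, abs=3.0)
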