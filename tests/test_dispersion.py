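"""MPD/MNTD, randomization nulls, and the dispersion-test classifier."""

import itertools

import numpy as np
import pytest

from camipy import (
    AssemblyParams,
    assemble_local,
    classify_by_dispersion,
    mntd,
    mpd,
    null_distribution,
    pairwise_distance_matrix,
    simulate_regional_pool,
    dispersion_test,
)
from camipy.dispersion import classify_all, null_mntd, null_mpd, random_subsets


class TestDistances:
    def test_tiny_tree_path_sums(self, tiny_pool):
        D = pairwise_distance_matrix(tiny_pool.phylogeny)
        assert D[0, 1] == pytest.approx(2.0)
        assert D[0, 2] == pytest.approx(4.0)
        assert D[1, 2] == pytest.approx(4.0)

    def test_trait_distance_absolute_difference(self, tiny_pool):
        D = pairwise_distance_matrix(tiny_pool.traits, ["A", "C"])
        assert D[0, 1] == pytest.approx(3.0)

    def test_symmetry_zero_diagonal(self, six_tip_pool):
        for D in (
            pairwise_distance_matrix(six_tip_pool.phylogeny),
            pairwise_distance_matrix(six_tip_pool.traits, six_tip_pool.phylogeny.labels),
        ):
            assert np.allclose(D, D.T)
            assert np.all(np.diag(D) == 0)


class TestMetrics:
    def test_three_member_hand_values(self):
        D = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        assert mpd(D) == pytest.approx(10 / 3)
        assert mntd(D) == pytest.approx((2 + 2 + 4) / 3)

    def test_two_members_equal(self):
        D = np.array([[0.0, 1.7], [1.7, 0.0]])
        assert mpd(D) == mntd(D) == pytest.approx(1.7)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            mpd(np.zeros((1, 1)))

    def test_exhaustive_enumeration_on_six_tips(self, six_tip_pool):
        """MPD/MNTD and null machinery vs. brute force over all subsets."""
        for D in (six_tip_pool.phylo_distances, six_tip_pool.trait_distances):
            for size in (2, 3, 4):
                for combo in itertools.combinations(range(6), size):
                    sub = D[np.ix_(combo, combo)]
                    pairs = [sub[i, j] for i in range(size) for j in range(size) if i < j]
                    assert mpd(sub) == pytest.approx(float(np.mean(pairs)), abs=1e-12)
                    nn = [
                        min(sub[i, j] for j in range(size) if j != i) for i in range(size)
                    ]
                    assert mntd(sub) == pytest.approx(float(np.mean(nn)), abs=1e-12)

    def test_vectorized_nulls_equal_direct_metrics(self, six_tip_pool):
        D = six_tip_pool.phylo_distances
        rng = np.random.default_rng(0)
        subsets = random_subsets(rng, 6, 3, 200)
        v_mpd = null_mpd(D, subsets)
        v_mntd = null_mntd(D, subsets)
        for r in range(200):
            sub = D[np.ix_(subsets[r], subsets[r])]
            assert v_mpd[r] == pytest.approx(mpd(sub), rel=1e-5)
            assert v_mntd[r] == pytest.approx(mntd(sub), abs=1e-12)


class TestNullDistribution:
    def test_n_equals_N_degenerate(self, six_tip_pool):
        null = null_distribution(six_tip_pool, "phylo", "mpd", n=6, reps=99, seed=0)
        assert np.allclose(null, null[0])

    def test_deterministic_under_seed(self, six_tip_pool):
        a = null_distribution(six_tip_pool, "trait", "mntd", n=3, reps=999, seed=42)
        b = null_distribution(six_tip_pool, "trait", "mntd", n=3, reps=999, seed=42)
        assert np.array_equal(a, b)

    def test_null_mean_matches_exhaustive_expectation(self, six_tip_pool):
        # all C(6,3)=20 subsets enumerable
        D = six_tip_pool.phylo_distances
        exact = np.array(
            [mpd(D[np.ix_(c, c)]) for c in itertools.combinations(range(6), 3)]
        )
        null = null_distribution(six_tip_pool, "phylo", "mpd", n=3, reps=999, seed=7)
        se = exact.std() / np.sqrt(999)
        assert abs(null.mean() - exact.mean()) < 3 * se + 1e-12

    def test_full_pool_test_degenerate_null_raises(self, six_tip_pool):
        # the full pool against its own single-subset null has sd 0
        with pytest.raises(ValueError, match="degenerate"):
            dispersion_test(
                six_tip_pool, six_tip_pool.phylogeny.labels, "phylo", "mpd",
                reps=99, seed=0,
            )

    def test_n_larger_than_pool_rejected(self, six_tip_pool):
        with pytest.raises(ValueError):
            null_distribution(six_tip_pool, "phylo", "mpd", n=7, reps=99, seed=0)


class TestClassifier:
    def test_median_observed_is_neutral(self):
        null = np.linspace(0, 1, 999)
        assert classify_by_dispersion(0.5, null) == "neutral"

    def test_extremes(self):
        null = np.linspace(1.0, 2.0, 999)
        assert classify_by_dispersion(0.5, null) == "filtering"
        assert classify_by_dispersion(2.5, null) == "competition"

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError):
            classify_by_dispersion(1.0, np.ones(999))

    def test_affine_rescaling_invariance(self, medium_pool, medium_local):
        res_a = dispersion_test(
            medium_pool, medium_local.members, "phylo", "mpd", reps=999, seed=3
        )
        # rescale all branch lengths (hence all distances) by 3.7
        scaled = simulate_regional_pool(1.0, 0.2, 60, "BM", 1.0, seed=2024)
        scaled.phylogeny.blen *= 3.7
        scaled.phylogeny._cache.clear()
        res_b = dispersion_test(
            scaled, medium_local.members, "phylo", "mpd", reps=999, seed=3
        )
        assert res_b.classification == res_a.classification
        # single-precision nulls: invariance holds to ~1e-5
        assert res_b.ses == pytest.approx(res_a.ses, rel=1e-4)

    def test_ses_sign_convention(self, medium_pool, medium_local):
        res = dispersion_test(medium_pool, medium_local.members, "phylo", "mpd", seed=0)
        assert res.ses == pytest.approx(
            -(res.observed - res.null_mean) / res.null_sd
        )
        assert res.p_low + res.p_high >= 1.0

    def test_size_of_neutral_test_is_alpha(self):
        """Neutral data should be called non-neutral ~5% of the time.

        1,000 neutral simulations from one pool, independent streams per
        trial; 99% binomial CI around 0.05.
        """
        pool = simulate_regional_pool(1.0, 0.0, 40, "BM", 1.0, seed=5)
        n_sims = 1000
        wrong = 0
        for ch in np.random.SeedSequence(777).spawn(n_sims):
            rng = np.random.default_rng(ch)
            local = assemble_local(pool, AssemblyParams(model="neutral", n=20), seed=rng)
            calls = classify_all(pool, local.member_idx, reps=999, seed=rng)
            wrong += calls["phylo_mpd"] != "neutral"
        rate = wrong / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 2.58 * se
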