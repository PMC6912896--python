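"""The 30 summary statistics, standardization, and statistic selection."""

import numpy as np
import pytest

from camipy import (
    AssemblyParams,
    RegionalPool,
    TraitSet,
    assemble_local,
    compute_summaries,
    select_top_stats,
    simulate_regional_pool,
    standardize_reference,
)
from camipy.assembly import LocalCommunity
from camipy.summaries import STAT_NAMES, SummaryVector, blomberg_k, pagel_lambda


def _local_from_labels(pool, labels):
    idx = pool.phylogeny.indices_of(labels)
    return LocalCommunity(
        members=list(labels),
        member_idx=idx,
        local_tree=pool.phylogeny.induced(labels),
        local_traits={m: pool.traits.values[m] for m in labels},
    )


class TestCanonicalVector:
    def test_exactly_thirty_frozen_names(self):
        assert len(STAT_NAMES) == 30
        assert len(set(STAT_NAMES)) == 30

    def test_vector_enforces_order(self):
        vals = {k: 0.0 for k in reversed(STAT_NAMES)}
        with pytest.raises(ValueError):
            SummaryVector(vals)

    def test_requires_four_members(self, six_tip_pool):
        local = _local_from_labels(six_tip_pool, ["A", "B", "C"])
        with pytest.raises(ValueError, match=">= 4"):
            compute_summaries(six_tip_pool, local)


class TestIdentityAndDegenerateCases:
    def test_local_equals_regional(self, medium_pool):
        labels = medium_pool.phylogeny.labels
        local = _local_from_labels(medium_pool, labels)
        sv = compute_summaries(medium_pool, local, seed=0)
        assert sv["richness_ratio"] == 1.0
        assert sv["nltt_distance"] == 0.0
        assert sv["pd_ratio"] == 1.0
        assert sv["trait_shift"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_traits_flagged(self, medium_pool):
        traits = TraitSet(
            {lab: 1.0 for lab in medium_pool.phylogeny.labels}, "BM", sigma2=1.0
        )
        pool = RegionalPool(medium_pool.phylogeny, traits, {})
        local = _local_from_labels(pool, pool.phylogeny.labels[:10])
        sv = compute_summaries(pool, local, seed=0)
        assert sv["trait_var_local"] == 0.0
        assert sv["mpd_trait"] == 0.0
        assert "blomberg_k" in sv.flags
        assert "trait_skew_local" in sv.flags


class TestInvariances:
    def test_label_permutation_invariance(self, medium_pool):
        """Relabeling species must not change any statistic."""
        params = AssemblyParams(model="filtering", n=20, tE=2.0, zE=0.0)
        local = assemble_local(medium_pool, params, seed=4)
        sv1 = compute_summaries(medium_pool, local, seed=11)

        perm_names = {lab: f"sp_{lab}" for lab in medium_pool.phylogeny.labels}
        tree2 = medium_pool.phylogeny
        from camipy import Phylogeny

        tree2 = Phylogeny(
            tree2.parent.copy(), tree2.blen.copy(), [perm_names[x] for x in tree2.labels]
        )
        traits2 = TraitSet(
            {perm_names[k]: v for k, v in medium_pool.traits.values.items()},
            "BM",
            sigma2=1.0,
        )
        pool2 = RegionalPool(tree2, traits2, {})
        local2 = _local_from_labels(pool2, [perm_names[m] for m in local.members])
        sv2 = compute_summaries(pool2, local2, seed=11)
        for k in STAT_NAMES:
            assert sv2[k] == pytest.approx(sv1[k], abs=1e-12), k

    def test_ses_reproducible_bit_for_bit(self, medium_pool, medium_local):
        a = compute_summaries(medium_pool, medium_local, seed=13)
        b = compute_summaries(medium_pool, medium_local, seed=13)
        assert a.values == b.values

    def test_ses_centered_under_neutral_assembly(self):
        """SES statistics have ~0 mean when the local community is a
        uniform random subset (the SES's own null)."""
        pool = simulate_regional_pool(1.0, 0.0, 30, "BM", 1.0, seed=31)
        ses = {k: [] for k in ("mpd_phylo_ses", "mntd_phylo_ses", "mpd_trait_ses", "mntd_trait_ses")}
        for s in range(1000):
            local = assemble_local(pool, AssemblyParams(model="neutral", n=10), seed=s)
            sv = compute_summaries(pool, local, null_reps=199, seed=50_000 + s)
            for k in ses:
                ses[k].append(sv[k])
        for k, vals in ses.items():
            assert abs(np.mean(vals)) < 0.15, k


class TestPhylogeneticSignal:
    def test_k_and_lambda_match_independent_implementation(self):
        """Frozen oracle values from R phytools::phylosig on this dataset:
        K = 1.51511, lambda = 1.00014 (unbounded; we cap at 1)."""
        pool = simulate_regional_pool(1.0, 0.0, 30, "BM", 1.5, seed=42)
        C = pool.phylogeny.mrca_depths()
        z = pool.trait_array
        assert blomberg_k(C, z) == pytest.approx(1.51511, abs=1e-4)
        assert pagel_lambda(C, z) == pytest.approx(1.0, abs=1e-3)

    def test_lambda_zero_for_shuffled_traits(self):
        pool = simulate_regional_pool(1.0, 0.0, 64, "BM", 1.0, seed=9)
        C = pool.phylogeny.mrca_depths()
        rng = np.random.default_rng(0)
        z = rng.permutation(pool.trait_array)
        assert pagel_lambda(C, z) < 0.3

    def test_blomberg_k_near_one_under_bm(self):
        """K averages ~1 on BM-simulated traits (N=128, 200 replicates)."""
        from camipy import evolve_traits_bm, simulate_bd_tree

        tree = simulate_bd_tree(1.0, 0.0, 128, 500)
        C = tree.mrca_depths()
        ks = []
        for s in range(200):
            ts = evolve_traits_bm(tree, 1.0, 0.0, seed=s)
            ks.append(blomberg_k(C, ts.array_for(tree.labels)))
        assert 0.8 < np.mean(ks) < 1.2


class TestStandardization:
    def test_constant_column_flagged_zeroed(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        Z, rec = standardize_reference(X)
        assert np.all(Z[:, 0] == 0)
        assert rec.zero_mad[0] and not rec.zero_mad[1]

    def test_hand_median_mad(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Z, rec = standardize_reference(X)
        assert rec.center[0] == 2.0 and rec.scale[0] == 1.0
        assert Z.ravel().tolist() == [-1.0, 0.0, 1.0]

    def test_reapplication_is_exact(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 7))
        Z, rec = standardize_reference(X)
        assert np.array_equal(rec.apply(X), Z)


class TestSelection:
    def test_tie_break_by_canonical_order(self):
        imp = {k: 1.0 for k in STAT_NAMES}
        assert select_top_stats(imp, 10) == list(STAT_NAMES[:10])

    def test_max_score_wins(self):
        imp = {k: 0.0 for k in STAT_NAMES}
        imp["pagel_lambda"] = 5.0
        assert select_top_stats(imp, 1) == ["pagel_lambda"]

    def test_sorted_selection(self):
        imp = {"gamma_regional": 3.0, "gamma_local": 1.0, "colless_regional": 2.0}
        assert select_top_stats(imp, 2) == ["gamma_regional", "colless_regional"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            select_top_stats({"gamma_regional": 1.0}, 0)
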