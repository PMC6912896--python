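"""Random-forest and ABC model selection / parameter estimation."""

import numpy as np
import pandas as pd
import pytest

from camipy import (
    abc_cross_validate,
    abc_estimate_strength,
    abc_model_select,
    rf_predict,
    train_rf,
)
from camipy.inference import REF_PARAM_COLS
from camipy.summaries import STAT_NAMES


def _make_ref(rows_per_model, fill, models=("neutral", "filtering", "competition"), seed=0):
    """Synthetic reference table; ``fill(rng, model, i)`` -> 30-vector."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in models:
        for i in range(rows_per_model):
            row = {c: np.nan for c in REF_PARAM_COLS}
            row.update({"model": m, "trait_model": "BM", "N": 100, "n": 50, "seed": i})
            row.update(dict(zip(STAT_NAMES, fill(rng, m, i))))
            rows.append(row)
    return pd.DataFrame(rows)


def _noise_fill(rng, m, i):
    return rng.normal(size=30)


def _separated_fill(rng, m, i):
    x = rng.normal(size=30)
    # statistic 0 has disjoint support per model
    x[0] = {"neutral": 0.0, "filtering": 10.0, "competition": 20.0}[m] + rng.random() * 0.5
    return x


class TestRandomForest:
    def test_chance_level_on_identical_distributions(self):
        ref = _make_ref(1000, _noise_fill, models=("neutral", "filtering"))
        _, report = train_rf(ref, n_trees=300, seed=1)
        assert report.oob_error_overall == pytest.approx(0.5, abs=0.05)

    def test_perfect_separator_found_and_ranked(self):
        ref = _make_ref(300, _separated_fill)
        forest, report = train_rf(ref, n_trees=300, seed=1, compute_mda=True, mda_repeats=2)
        assert report.oob_error_overall < 0.01
        gini_top = max(report.importance_gini, key=report.importance_gini.get)
        mda_top = max(report.importance_mda, key=report.importance_mda.get)
        assert gini_top == STAT_NAMES[0]
        assert mda_top == STAT_NAMES[0]

    def test_vote_fractions_normalized_and_confident(self):
        def fill(rng, m, i):
            x = rng.normal(size=30)
            # several redundant separating statistics -> near-unanimous votes
            x[:5] = {"neutral": 0.0, "filtering": 10.0, "competition": 20.0}[m]
            x[:5] += rng.random(5) * 0.5
            return x

        ref = _make_ref(200, fill)
        forest, _ = train_rf(ref, n_trees=200, seed=2)
        # a training row from the cleanly separable filtering class
        row = ref[ref["model"] == "filtering"].iloc[0]
        obs = {k: float(row[k]) for k in STAT_NAMES}
        votes = rf_predict(forest, obs)
        assert sum(votes.values()) == pytest.approx(1.0, abs=1e-9)
        assert votes["filtering"] > 0.9

    def test_single_class_rejected(self):
        ref = _make_ref(100, _noise_fill, models=("neutral",))
        with pytest.raises(ValueError):
            train_rf(ref)

    def test_persisted_forest_round_trips_and_guards_manifest(self, tmp_path):
        from camipy.inference import load_forest, save_forest

        ref = _make_ref(100, _separated_fill)
        forest, _ = train_rf(ref, n_trees=50, seed=3)
        row = {k: float(ref.iloc[0][k]) for k in STAT_NAMES}
        path = tmp_path / "forest.joblib"
        save_forest(forest, path)
        back = load_forest(path)
        assert rf_predict(back, row) == rf_predict(forest, row)
        back._camipy_stat_names = ("not", "the", "same")
        with pytest.raises(ValueError, match="refusing"):
            rf_predict(back, row)

    def test_oob_reproducible(self):
        ref = _make_ref(100, _separated_fill)
        _, a = train_rf(ref, n_trees=100, seed=9)
        _, b = train_rf(ref, n_trees=100, seed=9)
        assert a.oob_error_overall == b.oob_error_overall


class TestABCModelSelect:
    def test_observed_equal_to_reference_row(self):
        ref = _make_ref(50, _noise_fill)
        obs = {k: ref.iloc[17][k] for k in STAT_NAMES}
        res = abc_model_select(obs, ref, STAT_NAMES, tolerance=1 / len(ref))
        assert res.accepted[0] == 17
        assert res.model_posterior[ref.iloc[17]["model"]] == 1.0

    def test_tolerance_one_recovers_reference_frequencies(self):
        ref = _make_ref(40, _noise_fill)
        obs = dict(zip(STAT_NAMES, np.zeros(30)))
        res = abc_model_select(obs, ref, STAT_NAMES[:5], tolerance=1.0)
        for m in ("neutral", "filtering", "competition"):
            assert res.model_posterior[m] == pytest.approx(1 / 3)

    def test_distances_match_naive_double_loop(self):
        """Euclidean distances agree with a brute-force recomputation."""
        from camipy.summaries import standardize_reference

        ref = _make_ref(34, _noise_fill)
        subset = list(STAT_NAMES[:7])
        rng = np.random.default_rng(8)
        obs_vec = rng.normal(size=7)
        obs = dict(zip(subset, obs_vec))
        res = abc_model_select(obs, ref, subset, tolerance=1.0)

        X = ref[subset].to_numpy()
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        mad[mad == 0] = 1.0
        expected = []
        for r in range(len(ref)):
            s = 0.0
            for j in range(7):
                d = (X[r, j] - med[j]) / mad[j] - (obs_vec[j] - med[j]) / mad[j]
                s += d * d
            expected.append(np.sqrt(s))
        expected = np.asarray(expected)
        order = np.argsort(expected, kind="stable")
        assert np.allclose(res.distances, expected[order], atol=1e-12)

    def test_too_small_tolerance_rejected(self):
        ref = _make_ref(10, _noise_fill)
        with pytest.raises(ValueError, match="tolerance"):
            abc_model_select(dict(zip(STAT_NAMES, np.zeros(30))), ref, STAT_NAMES, tolerance=0)


class TestABCCrossValidation:
    def test_perfect_information(self):
        ref = _make_ref(60, _separated_fill)
        cv = abc_cross_validate(ref, [STAT_NAMES[0]], tolerance=0.05, seed=0)
        assert cv["overall_error"] == pytest.approx(0.0, abs=0.02)

    def test_chance_level(self):
        ref = _make_ref(300, _noise_fill, models=("neutral", "filtering"))
        cv = abc_cross_validate(ref, list(STAT_NAMES[:10]), tolerance=0.05, seed=0)
        assert cv["overall_error"] == pytest.approx(0.5, abs=0.05)

    def test_reproducible(self):
        ref = _make_ref(80, _noise_fill)
        a = abc_cross_validate(ref, list(STAT_NAMES[:10]), tolerance=0.1, seed=5)
        b = abc_cross_validate(ref, list(STAT_NAMES[:10]), tolerance=0.1, seed=5)
        assert a["overall_error"] == b["overall_error"]


class TestStrengthEstimation:
    def test_nearest_neighbor_recovery(self):
        """If statistic 0 encodes tE exactly, the posterior concentrates
        near the observed value."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(500):
            tE = rng.uniform(1, 60)
            row = {c: np.nan for c in REF_PARAM_COLS}
            row.update({"model": "filtering", "trait_model": "BM", "tE": tE, "seed": i})
            x = rng.normal(size=30)
            x[0] = tE
            row.update(dict(zip(STAT_NAMES, x)))
            rows.append(row)
        ref = pd.DataFrame(rows)
        obs = dict(zip(STAT_NAMES, np.zeros(30)))
        obs[STAT_NAMES[0]] = 20.0
        res = abc_estimate_strength(obs, ref, [STAT_NAMES[0]], tolerance=0.02)
        assert res.point_estimate == pytest.approx(20.0, abs=2.0)
        assert np.all((res.posterior_draws >= 1) & (res.posterior_draws <= 60))

    def test_constant_strength_reference(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(50):
            row = {c: np.nan for c in REF_PARAM_COLS}
            row.update({"model": "competition", "trait_model": "BM", "tC": 7.0, "seed": i})
            row.update(dict(zip(STAT_NAMES, rng.normal(size=30))))
            rows.append(row)
        ref = pd.DataFrame(rows)
        obs = dict(zip(STAT_NAMES, np.zeros(30)))
        res = abc_estimate_strength(obs, ref, list(STAT_NAMES[:5]), tolerance=0.2)
        assert res.point_estimate == 7.0

    def test_mixed_model_reference_rejected(self):
        ref = _make_ref(60, _noise_fill)
        obs = dict(zip(STAT_NAMES, np.zeros(30)))
        with pytest.raises(ValueError):
            abc_estimate_strength(obs, ref, list(STAT_NAMES[:5]))


class TestRobustnessToNoiseStatistics:
    def test_rf_tolerates_added_noise_stats(self):
        """Extra label-independent statistics barely hurt RF accuracy, on a
        cleanly separable reference."""

        def informative(rng, m, i):
            x = rng.normal(size=30)
            x[5] = {"neutral": 0.0, "filtering": 4.0, "competition": 8.0}[m] + rng.normal(0, 0.4)
            return x

        def clean(rng, m, i):
            x = np.zeros(30)
            x[5] = {"neutral": 0.0, "filtering": 4.0, "competition": 8.0}[m] + rng.normal(0, 0.4)
            return x

        ref_clean = _make_ref(200, clean, seed=4)
        ref_noisy = _make_ref(200, informative, seed=4)
        _, rep_clean = train_rf(ref_clean, n_trees=300, seed=0)
        _, rep_noisy = train_rf(ref_noisy, n_trees=300, seed=0)
        assert rep_noisy.oob_error_overall <= rep_clean.oob_error_overall + 0.02

    def test_abc_degrades_with_noise_subset(self):
        def informative(rng, m, i):
            x = rng.normal(size=30)
            x[5] = {"neutral": 0.0, "filtering": 4.0, "competition": 8.0}[m] + rng.normal(0, 0.4)
            return x

        ref = _make_ref(150, informative, seed=4)
        cv_good = abc_cross_validate(ref, [STAT_NAMES[5]], tolerance=0.05, seed=0)
        cv_noisy = abc_cross_validate(ref, list(STAT_NAMES), tolerance=0.05, seed=0)
        assert cv_noisy["overall_error"] > cv_good["overall_error"]
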