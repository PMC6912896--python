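"""Model selection and strength-parameter estimation.

Two inference engines consume the same reference table of simulated
summary statistics:

* a random-forest classifier (500 trees, sqrt-features per split) trained
  on all 30 statistics, evaluated by its out-of-bag (OoB) error and
  reporting variable importances (Gini always; permutation-based MDA on
  request);
* ABC rejection: Euclidean distance between median/MAD-standardized
  statistics (a selected subset, typically the RF top 10), accepting the
  ``ceil(tolerance * rows)`` nearest reference simulations.  Model support
  is the per-model share of accepted rows; parameter posteriors are the
  accepted rows' strength values, summarized by the median.

Reference tables are pandas DataFrames with columns ``model, trait_model,
lambda, mu, sigma2, alpha, tE, tC, zE, N, n, seed`` followed by the 30
statistic columns (see :mod:`camipy.summaries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .regional_sim import _as_rng
from .summaries import STAT_NAMES, SummaryVector, StandardScale, standardize_reference

__all__ = [
    "REF_PARAM_COLS",
    "RFReport",
    "ABCResult",
    "train_rf",
    "rf_predict",
    "abc_model_select",
    "abc_cross_validate",
    "abc_estimate_strength",
]

REF_PARAM_COLS = ("model", "trait_model", "lambda", "mu", "sigma2", "alpha",
                  "tE", "tC", "zE", "N", "n", "seed")


def _stat_matrix(ref: pd.DataFrame, stat_names: Sequence[str] = STAT_NAMES) -> np.ndarray:
    missing = [s for s in stat_names if s not in ref.columns]
    if missing:
        raise KeyError(f"reference table is missing statistic columns: {missing}")
    return ref.loc[:, list(stat_names)].to_numpy(dtype=np.float64)


def _obs_vector(observed, stat_names: Sequence[str]) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        return np.array([observed.values[s] for s in stat_names])
    if isinstance(observed, dict):
        return np.array([observed[s] for s in stat_names])
    arr = np.asarray(observed, dtype=np.float64).ravel()
    if arr.shape[0] != len(stat_names):
        raise ValueError("observed vector length does not match the statistic set")
    return arr


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------


@dataclass
class RFReport:
    oob_error_overall: float
    oob_error_per_model: dict[str, float]
    confusion: pd.DataFrame  # rows: true model, cols: OoB-predicted model
    importance_gini: dict[str, float]
    importance_mda: dict[str, float] = field(default_factory=dict)
    classes: tuple[str, ...] = ()


def train_rf(
    ref: pd.DataFrame,
    labels: Sequence[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    compute_mda: bool = False,
    mda_repeats: int = 5,
) -> tuple[RandomForestClassifier, RFReport]:
    """Train a random forest on the 30 statistics and report OoB error.

    ``labels`` defaults to the reference's ``model`` column; pass e.g.
    ``ref["model"] + "_" + ref["trait_model"]`` for the six-way joint
    classification.  MDA (permutation importance) is optional because it
    costs ~30 forest predictions.
    """
    y = np.asarray(ref["model"] if labels is None else labels)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    counts = pd.Series(y).value_counts()
    if counts.min() < 50:
        raise ValueError(f"need >= 50 rows per class; smallest class has {counts.min()}")
    X = _stat_matrix(ref)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    proba = forest.oob_decision_function_
    # rows never left out of bag (possible at tiny n_trees) count as errors
    valid = proba.sum(axis=1) > 0
    pred = np.asarray(forest.classes_)[np.argmax(proba, axis=1)]
    correct = valid & (pred == y)
    per_model = {
        c: float(1.0 - correct[y == c].mean()) for c in classes
    }
    conf = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=forest.classes_, fill_value=0)
    gini = dict(zip(STAT_NAMES, forest.feature_importances_.astype(float)))
    mda: dict[str, float] = {}
    if compute_mda:
        pi = permutation_importance(
            forest, X, y, n_repeats=mda_repeats, random_state=int(seed), n_jobs=1
        )
        mda = dict(zip(STAT_NAMES, pi.importances_mean.astype(float)))
    report = RFReport(
        oob_error_overall=float(1.0 - correct.mean()),
        oob_error_per_model=per_model,
        confusion=conf,
        importance_gini=gini,
        importance_mda=mda,
        classes=tuple(classes),
    )
    return forest, report


def rf_predict(forest: RandomForestClassifier, observed) -> dict[str, float]:
    """Per-model vote fractions for one observed SummaryVector."""
    manifest = getattr(forest, "_camipy_stat_names", tuple(STAT_NAMES))
    if tuple(manifest) != tuple(STAT_NAMES):
        raise ValueError(
            "forest was trained on a different statistic set; refusing to predict"
        )
    x = _obs_vector(observed, STAT_NAMES)[None, :]
    proba = forest.predict_proba(x)[0]
    return {c: float(p) for c, p in zip(forest.classes_, proba)}


def save_forest(forest: RandomForestClassifier, path) -> None:
    """Persist a trained forest with an embedded statistic-name manifest."""
    import joblib

    from . import __version__

    joblib.dump(
        {"version": __version__, "stat_names": tuple(STAT_NAMES), "forest": forest},
        path,
    )


def load_forest(path) -> RandomForestClassifier:
    """Load a persisted forest; the manifest travels with it and
    :func:`rf_predict` refuses mismatched statistic sets."""
    import joblib

    payload = joblib.load(path)
    forest = payload["forest"]
    forest._camipy_stat_names = tuple(payload["stat_names"])
    return forest


# ---------------------------------------------------------------------------
# ABC rejection
# ---------------------------------------------------------------------------


@dataclass
class ABCResult:
    accepted: np.ndarray  # row positions into the reference
    model_posterior: dict[str, float]
    tolerance: float
    distances: np.ndarray  # distances of accepted rows, ascending
    stat_subset: tuple[str, ...]
    posterior_draws: np.ndarray | None = None
    point_estimate: float | None = None


def _n_accept(tolerance: float, rows: int) -> int:
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    k = int(np.ceil(tolerance * rows))
    if k < 1:
        raise ValueError(
            "tolerance * rows < 1: enlarge the reference table or the tolerance"
        )
    return k


def abc_model_select(
    observed,
    ref: pd.DataFrame,
    stat_subset: Sequence[str],
    tolerance: float = 0.001,
) -> ABCResult:
    """ABC rejection over Euclidean distance on standardized statistics.

    Columns are standardized (median/MAD) over the reference rows; flagged
    statistics in the observed vector should be excluded from
    ``stat_subset`` by the caller.  Accepts the ``ceil(tolerance * rows)``
    nearest rows; model support is each model's share of accepted rows.
    """
    stat_subset = tuple(stat_subset)
    unknown = set(stat_subset) - set(STAT_NAMES)
    if unknown:
        raise KeyError(f"unknown statistics in subset: {sorted(unknown)}")
    if isinstance(observed, SummaryVector) and observed.flags & set(stat_subset):
        raise ValueError(
            f"observed vector has undefined statistics in the ABC subset: "
            f"{sorted(observed.flags & set(stat_subset))}"
        )
    X = _stat_matrix(ref, stat_subset)
    Z, scale = standardize_reference(X)
    zobs = scale.apply(_obs_vector(observed, stat_subset))[0]
    d = np.sqrt(((Z - zobs) ** 2).sum(axis=1))
    k = _n_accept(tolerance, len(ref))
    nearest = np.argsort(d, kind="stable")[:k]
    models = ref["model"].to_numpy()
    post = {m: float(np.mean(models[nearest] == m)) for m in np.unique(models)}
    return ABCResult(
        accepted=nearest,
        model_posterior=post,
        tolerance=tolerance,
        distances=d[nearest],
        stat_subset=stat_subset,
    )


def abc_cross_validate(
    ref: pd.DataFrame,
    stat_subset: Sequence[str],
    tolerance: float = 0.001,
    n_eval: int | None = None,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> dict:
    """Leave-one-out ABC model choice over held-out reference rows.

    Each evaluated row is classified to the max-posterior model among the
    remaining rows (posterior ties broken uniformly at random, seeded).
    Standardization is fit once on the full table; the held-out row is
    always excluded from acceptance.  Returns overall and per-model
    misclassification rates and the confusion table.
    """
    rng = _as_rng(seed)
    y = np.asarray(ref["model"] if labels is None else labels)
    R = len(ref)
    X = _stat_matrix(ref, tuple(stat_subset))
    Z, _ = standardize_reference(X)
    k = _n_accept(tolerance, R - 1)
    if n_eval is None:
        eval_rows = np.arange(R)
    else:
        if n_eval > R:
            raise ValueError("n_eval exceeds the number of reference rows")
        eval_rows = rng.choice(R, size=n_eval, replace=False)
        eval_rows.sort()

    classes = np.unique(y)
    pred = np.empty(eval_rows.shape[0], dtype=y.dtype)
    sq = np.einsum("ij,ij->i", Z, Z)
    # pairwise squared distances in blocks to bound memory
    block = max(1, int(2e7) // max(R, 1))
    for s in range(0, eval_rows.shape[0], block):
        rows = eval_rows[s : s + block]
        d2 = sq[rows, None] + sq[None, :] - 2.0 * (Z[rows] @ Z.T)
        d2[np.arange(rows.shape[0]), rows] = np.inf  # leave self out
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        for i, r in enumerate(rows):
            votes = pd.Series(y[part[i]]).value_counts()
            top = votes[votes == votes.max()].index.to_numpy()
            pred[s + i] = top[0] if top.shape[0] == 1 else top[rng.integers(top.shape[0])]
    truth = y[eval_rows]
    overall = float(np.mean(pred != truth))
    per_model = {c: float(np.mean(pred[truth == c] != c)) for c in classes}
    conf = pd.crosstab(pd.Series(truth, name="true"), pd.Series(pred, name="predicted"))
    return {
        "overall_error": overall,
        "per_model_error": per_model,
        "confusion": conf,
        "n_eval": int(eval_rows.shape[0]),
        "n_accept": k,
    }


def abc_estimate_strength(
    observed,
    ref_one_model: pd.DataFrame,
    stat_subset: Sequence[str],
    tolerance: float = 0.001,
) -> ABCResult:
    """ABC rejection posterior for the strength parameter tE or tC.

    ``ref_one_model`` must contain rows from a single non-neutral model
    with the relevant strength column recorded; the accepted rows' values
    form the posterior sample and the point estimate is its median.
    """
    models = ref_one_model["model"].unique()
    if models.shape[0] != 1 or models[0] not in ("filtering", "competition"):
        raise ValueError("reference must hold exactly one non-neutral model's rows")
    col = "tE" if models[0] == "filtering" else "tC"
    vals = ref_one_model[col].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"reference has missing {col} values")
    res = abc_model_select(observed, ref_one_model, stat_subset, tolerance)
    draws = vals[res.accepted]
    res.posterior_draws = draws
    res.point_estimate = float(np.median(draws))
    return res
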