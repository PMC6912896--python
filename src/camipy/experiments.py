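"""Simulation studies: power analyses and strength-parameter recovery.

``run_power_analysis`` scores six model-identification approaches on data
simulated under the three assembly models (optionally crossed with the two
trait models into six joint labels) over a grid of regional community
sizes, local richness always half the regional:

* four dispersion hypothesis tests ({phylogenetic, trait} x {MPD, MNTD},
  two-tailed randomization at alpha);
* a random forest on the 30 summary statistics, scored by OoB error;
* ABC rejection on the RF-selected top-10 statistics, scored by
  leave-one-out cross-validation.

``run_parameter_recovery`` measures how well ABC rejection recovers the
true filtering/competition strength (tE/tC) from its posterior median,
across a grid of true values and community sizes.

Every dataset gets its own child seed spawned from the experiment seed, so
each cell is regenerable bit-for-bit.  Default priors (documented
substitutes spanning mild-to-strong regimes, configurable via
:class:`PriorSpec`): lambda ~ U(0.05, 2), mu = eps*lambda with
eps ~ U(0, 0.9), sigma2 ~ U(1, 5), alpha ~ U(0.01, 0.1),
tE, tC ~ U(1, 60), trees rescaled to crown age 15; the environmental optimum zE is a uniform draw among
the regional tip trait values; BM and OU are equiprobable (assigned in
strict alternation, so per-(model x trait) counts are exactly balanced).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assembly import MODELS, AssemblyParams, assemble_local
from .dispersion import classify_all
from .inference import abc_cross_validate, train_rf
from .regional_sim import simulate_regional_pool
from .summaries import STAT_NAMES, compute_summaries, select_top_stats

__all__ = [
    "PriorSpec",
    "PowerResult",
    "simulate_dataset",
    "build_reference_table",
    "run_power_analysis",
    "run_parameter_recovery",
    "DEFAULT_TRUE_VALUES",
]

DISPERSION_APPROACHES = ("phylo_mpd", "phylo_mntd", "trait_mpd", "trait_mntd")

# 1 to 56 in steps of 5, plus the prior's upper bound
DEFAULT_TRUE_VALUES = tuple(range(1, 57, 5)) + (60,)


@dataclass
class PriorSpec:
    """Uniform prior bounds for the generating parameters."""

    lambda_range: tuple[float, float] = (0.05, 2.0)
    mu_frac_range: tuple[float, float] = (0.0, 0.9)  # mu = frac * lambda
    sigma2_range: tuple[float, float] = (1.0, 5.0)
    alpha_range: tuple[float, float] = (0.01, 0.1)
    tE_range: tuple[float, float] = (1.0, 60.0)
    tC_range: tuple[float, float] = (1.0, 60.0)
    # Regional trees are rescaled to this crown age before traits evolve.
    # Together with the sigma2 bounds this puts regional trait variances at
    # ~15-60 squared-trait units, the scale on which the strength priors
    # U(1, 60) realize strong-to-mild filtering and competition (a filter
    # binds when variance >~ tE/2; a competitive exclusion zone is
    # detectable when variance <~ 2 tC).  The alpha bounds give OU
    # phylogenetic half-lives ln2/alpha between ~T/3 and ~3.5T: a mild-to-
    # strong selective pull that remains a distinct trait model rather
    # than collapsing into BM.
    crown_age: float = 15.0

    def __post_init__(self):
        for name in ("lambda_range", "sigma2_range", "alpha_range", "tE_range", "tC_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive with lo <= hi")
        lo, hi = self.mu_frac_range
        if lo < 0 or hi >= 1:
            raise ValueError("mu_frac_range must sit in [0, 1) so that mu < lambda")

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        lam = rng.uniform(*self.lambda_range)
        return {
            "lambda": lam,
            "mu": rng.uniform(*self.mu_frac_range) * lam,
            "sigma2": rng.uniform(*self.sigma2_range),
            "alpha": rng.uniform(*self.alpha_range),
            "tE": rng.uniform(*self.tE_range),
            "tC": rng.uniform(*self.tC_range),
        }


def simulate_dataset(
    model: str,
    trait_model: str,
    N: int,
    n: int,
    priors: PriorSpec,
    seed,
    null_reps: int = 999,
    attempt_cap: int = 200_000,
    max_redraws: int = 400,
    overrides: dict | None = None,
    compute_stats: bool = True,
):
    """Simulate one (regional pool, local community) dataset and summarize.

    Draws parameters from ``priors`` (``overrides`` pins any of them, e.g.
    a fixed true tE for recovery studies), simulates the pool, draws zE
    among the regional trait values (filtering only), and runs assembly.
    If assembly exceeds ``attempt_cap`` the parameter draw is rejected and
    redrawn from the same stream (counted in the returned row as
    ``redraws``).  Strong-filter settings (small tE) are only assemblable
    when the nuisance draws cooperate (moderate sigma2, central zE), so
    the redraw loop implicitly truncates to feasible parameter
    combinations -- the same truncation any rejection-algorithm
    implementation imposes.

    Returns ``(row, pool, local)`` where ``row`` is a flat dict of the
    parameter record plus (if ``compute_stats``) the 30 statistics.
    """
    rng = np.random.default_rng(seed)
    overrides = overrides or {}
    for attempt in range(max_redraws):
        p = priors.sample(rng)
        p.update(overrides)
        pool = simulate_regional_pool(
            lam=p["lambda"],
            mu=p["mu"],
            N=N,
            trait_model=trait_model,
            sigma2=p["sigma2"],
            alpha=p["alpha"] if trait_model == "OU" else 0.0,
            seed=rng,
            rescale_crown_age=priors.crown_age,
        )
        zE = float(rng.choice(pool.trait_array)) if model == "filtering" else np.nan
        if "zE" in overrides:
            zE = overrides["zE"]
        params = AssemblyParams(
            model=model,
            n=n,
            tE=p["tE"] if model == "filtering" else None,
            tC=p["tC"] if model == "competition" else None,
            zE=zE if model == "filtering" else None,
        )
        try:
            local = assemble_local(pool, params, rng, attempt_cap=attempt_cap)
        except RuntimeError:
            continue
        row = {
            "model": model,
            "trait_model": trait_model,
            "lambda": p["lambda"],
            "mu": p["mu"],
            "sigma2": p["sigma2"],
            "alpha": p["alpha"] if trait_model == "OU" else 0.0,
            "tE": p["tE"] if model == "filtering" else np.nan,
            "tC": p["tC"] if model == "competition" else np.nan,
            "zE": zE,
            "N": N,
            "n": n,
            "redraws": attempt,
        }
        if compute_stats:
            sv = compute_summaries(pool, local, null_reps=null_reps, seed=rng)
            row.update(sv.values)
            row["undefined_stats"] = ";".join(sorted(sv.flags))
        return row, pool, local
    raise RuntimeError(
        f"assembly failed for {max_redraws} successive parameter draws "
        f"(model={model}, N={N}, n={n})"
    )


def build_reference_table(
    N: int,
    n: int,
    reps_per_combo: int,
    priors: PriorSpec | None = None,
    seed: int = 0,
    models: Sequence[str] = MODELS,
    trait_models: Sequence[str] = ("BM", "OU"),
    null_reps: int = 999,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Reference table with ``reps_per_combo`` rows per (model x trait model)."""
    priors = priors or PriorSpec()
    ss = np.random.SeedSequence(seed)
    rows = []
    combos = [(m, t) for m in models for t in trait_models]
    children = ss.spawn(len(combos) * reps_per_combo)
    i = 0
    for m, t in combos:
        for _ in range(reps_per_combo):
            row, _, _ = simulate_dataset(
                m, t, N, n, priors, children[i], null_reps=null_reps, overrides=overrides
            )
            row["seed"] = i
            rows.append(row)
            i += 1
    df = pd.DataFrame(rows)
    cols = ["model", "trait_model", "lambda", "mu", "sigma2", "alpha", "tE", "tC",
            "zE", "N", "n", "seed", "redraws"] + list(STAT_NAMES) + ["undefined_stats"]
    return df.loc[:, cols]


@dataclass
class PowerResult:
    """Misclassification grid plus the artifacts behind it."""

    rates: pd.DataFrame  # columns: approach, size, model, error, n_datasets
    reference_tables: dict[int, pd.DataFrame]
    rf_reports: dict[int, object]
    abc_reports: dict[int, dict]
    rf6_reports: dict[int, object] = field(default_factory=dict)
    abc6_reports: dict[int, dict] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def mean_error(self, approaches, models=None, sizes=None) -> float:
        """Average misclassification over the selected cells (percent)."""
        if isinstance(approaches, str):
            approaches = [approaches]
        t = self.rates[self.rates["approach"].isin(approaches)]
        if models is not None:
            t = t[t["model"].isin([models] if isinstance(models, str) else models)]
        if sizes is not None:
            t = t[t["size"].isin([sizes] if isinstance(sizes, int) else sizes)]
        if t.empty:
            raise ValueError("no matching cells")
        return float(t["error"].mean()) * 100.0


def run_power_analysis(
    sizes: Sequence[int],
    reps_per_model: int,
    seed: int = 0,
    six_model: bool = False,
    disp_reps: int | None = None,
    alpha: float = 0.05,
    null_reps: int = 999,
    disp_null_reps: int = 999,
    priors: PriorSpec | None = None,
    n_trees: int = 500,
    abc_tolerance: float = 0.001,
    abc_min_accept: int = 50,
    dispersion_only: bool = False,
    progress: bool = False,
) -> PowerResult:
    """Score all approaches on simulated data over a community-size grid.

    ``sizes`` are regional richnesses N (local n = N/2).  ``reps_per_model``
    datasets are simulated per assembly model and size, split evenly
    between BM and OU traits.  Dispersion tests are scored on the first
    ``disp_reps`` datasets per model (default: all of them); RF by OoB
    error; ABC by leave-one-out cross-validation with the RF top-10
    statistics and an acceptance count of at least ``abc_min_accept``.
    With ``six_model=True`` RF and ABC are additionally scored on the
    six-way (assembly x trait) label.  ``dispersion_only=True`` skips the
    summary statistics and the RF/ABC scoring entirely (and simulates only
    the datasets the dispersion tests need).
    """
    if reps_per_model < 2 or reps_per_model % 2:
        raise ValueError("reps_per_model must be a positive even number (BM/OU balanced)")
    for N in sizes:
        if not 4 <= N:
            raise ValueError("regional sizes must be >= 4")
    priors = priors or PriorSpec()
    per_combo = reps_per_model // 2
    disp_reps = reps_per_model if disp_reps is None else min(disp_reps, reps_per_model)

    ss = np.random.SeedSequence(seed)
    records = []
    ref_tables: dict[int, pd.DataFrame] = {}
    rf_reports: dict[int, object] = {}
    abc_reports: dict[int, dict] = {}
    rf6_reports: dict[int, object] = {}
    abc6_reports: dict[int, dict] = {}

    for N in sizes:
        n = N // 2
        size_ss, disp_ss, infer_ss = ss.spawn(3)
        children = size_ss.spawn(len(MODELS) * 2 * per_combo)
        disp_children = disp_ss.spawn(len(MODELS) * 2 * per_combo)
        rows = []
        disp_calls: dict[str, list] = {a: [] for a in DISPERSION_APPROACHES}
        disp_truth: list[str] = []
        i = 0
        for m in MODELS:
            for t in ("BM", "OU"):
                for r in range(per_combo):
                    if dispersion_only and r >= (disp_reps + 1) // 2:
                        i += 1
                        continue
                    row, pool, local = simulate_dataset(
                        m, t, N, n, priors, children[i], null_reps=null_reps,
                        compute_stats=not dispersion_only,
                    )
                    row["seed"] = i
                    rows.append(row)
                    # dispersion on the first disp_reps/2 of each trait half
                    if r < (disp_reps + 1) // 2:
                        calls = classify_all(
                            pool, local.member_idx, reps=disp_null_reps, alpha=alpha,
                            seed=np.random.default_rng(disp_children[i]),
                        )
                        for a in DISPERSION_APPROACHES:
                            disp_calls[a].append(calls[a])
                        disp_truth.append(m)
                    i += 1
            if progress:  # pragma: no cover
                print(f"size {N}: simulated {m}", flush=True)
        truth = np.asarray(disp_truth)
        if disp_reps > 0:
            for a in DISPERSION_APPROACHES:
                calls = np.asarray(disp_calls[a])
                for m in MODELS:
                    sel = truth == m
                    records.append({
                        "approach": a, "size": N, "model": m,
                        "error": float(np.mean(calls[sel] != m)),
                        "n_datasets": int(sel.sum()),
                    })
        if dispersion_only:
            if progress:  # pragma: no cover
                print(f"size {N}: done", flush=True)
            continue

        ref = pd.DataFrame(rows)
        cols = ["model", "trait_model", "lambda", "mu", "sigma2", "alpha", "tE", "tC",
                "zE", "N", "n", "seed", "redraws"] + list(STAT_NAMES) + ["undefined_stats"]
        ref = ref.loc[:, cols]
        ref_tables[N] = ref

        rf_seed, abc_seed, rf6_seed, abc6_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in infer_ss.spawn(4)
        ]
        _, report = train_rf(ref, n_trees=n_trees, seed=rf_seed)
        rf_reports[N] = report
        for m in MODELS:
            records.append({
                "approach": "rf", "size": N, "model": m,
                "error": report.oob_error_per_model[m],
                "n_datasets": reps_per_model,
            })
        top10 = select_top_stats(report.importance_gini, k=10)
        tol = max(abc_tolerance, abc_min_accept / (len(ref) - 1))
        cv = abc_cross_validate(ref, top10, tolerance=tol, seed=abc_seed)
        cv["stat_subset"] = top10
        abc_reports[N] = cv
        for m in MODELS:
            records.append({
                "approach": "abc", "size": N, "model": m,
                "error": cv["per_model_error"][m],
                "n_datasets": reps_per_model,
            })

        if six_model:
            labels6 = (ref["model"] + "_" + ref["trait_model"]).to_numpy()
            _, rep6 = train_rf(ref, labels=labels6, n_trees=n_trees, seed=rf6_seed)
            rf6_reports[N] = rep6
            for lab, err in rep6.oob_error_per_model.items():
                records.append({
                    "approach": "rf6", "size": N, "model": lab,
                    "error": err, "n_datasets": per_combo,
                })
            top10_6 = select_top_stats(rep6.importance_gini, k=10)
            cv6 = abc_cross_validate(ref, top10_6, tolerance=tol, seed=abc6_seed, labels=labels6)
            cv6["stat_subset"] = top10_6
            abc6_reports[N] = cv6
            for lab, err in cv6["per_model_error"].items():
                records.append({
                    "approach": "abc6", "size": N, "model": lab,
                    "error": err, "n_datasets": per_combo,
                })
        if progress:  # pragma: no cover
            print(f"size {N}: done", flush=True)

    rates = pd.DataFrame(records)
    return PowerResult(
        rates=rates,
        reference_tables=ref_tables,
        rf_reports=rf_reports,
        abc_reports=abc_reports,
        rf6_reports=rf6_reports,
        abc6_reports=abc6_reports,
        config={
            "sizes": list(sizes), "reps_per_model": reps_per_model, "seed": seed,
            "six_model": six_model, "disp_reps": disp_reps, "alpha": alpha,
            "null_reps": null_reps, "disp_null_reps": disp_null_reps,
            "priors": asdict(priors), "n_trees": n_trees,
            "abc_tolerance": abc_tolerance, "abc_min_accept": abc_min_accept,
        },
    )


def run_parameter_recovery(
    model: str,
    trait_model: str,
    sizes: Sequence[tuple[int, int]] = ((200, 100), (800, 400)),
    true_values: Sequence[float] = DEFAULT_TRUE_VALUES,
    reps: int = 100,
    ref_rows: int = 50_000,
    seed: int = 0,
    priors: PriorSpec | None = None,
    null_reps: int = 999,
    tolerance: float = 0.001,
    min_accept: int = 50,
    stat_subset: Sequence[str] | None = None,
    selection_rows_per_combo: int = 100,
    progress: bool = False,
) -> pd.DataFrame:
    """ABC recovery of the strength parameter over a grid of true values.

    For each community size pair (N, n): build a one-model reference of
    ``ref_rows`` rows with the strength drawn from its prior, then for
    each true value simulate ``reps`` observed datasets at that pinned
    strength and record the ABC posterior median.  The statistic subset
    defaults to the top 10 by Gini importance of a small three-model RF
    trained at the first size (the same selection rule as model choice).

    Returns a tidy frame: model, trait_model, N, n, true_value, rep,
    estimate, n_accepted.
    """
    if model not in ("filtering", "competition"):
        raise ValueError("recovery applies to the non-neutral models")
    priors = priors or PriorSpec()
    strength_col = "tE" if model == "filtering" else "tC"
    ss = np.random.SeedSequence(seed)
    sel_ss, *size_ss = ss.spawn(1 + len(sizes))

    if stat_subset is None:
        sel_seed = int(sel_ss.generate_state(1)[0] % (2**31))
        sel_table = build_reference_table(
            sizes[0][0], sizes[0][1], selection_rows_per_combo,
            priors=priors, seed=sel_seed, null_reps=null_reps,
        )
        _, sel_report = train_rf(ref=sel_table, seed=sel_seed)
        stat_subset = select_top_stats(sel_report.importance_gini, k=10)

    out = []
    for (N, n), sss in zip(sizes, size_ss):
        ref_ss, obs_ss = sss.spawn(2)
        ref_seed = int(ref_ss.generate_state(1)[0] % (2**31))
        per_combo = int(np.ceil(ref_rows / 1))
        ref = build_reference_table(
            N, n, per_combo, priors=priors, seed=ref_seed,
            models=(model,), trait_models=(trait_model,), null_reps=null_reps,
        )
        tol = max(tolerance, min_accept / len(ref))
        children = obs_ss.spawn(len(true_values) * reps)
        i = 0
        from .inference import abc_estimate_strength  # local import: cycle-free

        for tv in true_values:
            for r in range(reps):
                row, _, _ = simulate_dataset(
                    model, trait_model, N, n, priors, children[i],
                    null_reps=null_reps, overrides={strength_col: float(tv)},
                )
                obs = {k: row[k] for k in STAT_NAMES}
                res = abc_estimate_strength(obs, ref, stat_subset, tolerance=tol)
                out.append({
                    "model": model, "trait_model": trait_model, "N": N, "n": n,
                    "true_value": float(tv), "rep": r,
                    "estimate": res.point_estimate,
                    "n_accepted": int(res.accepted.shape[0]),
                })
                i += 1
            if progress:  # pragma: no cover
                print(f"recovery N={N}: true={tv} done", flush=True)
    return pd.DataFrame(out)
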