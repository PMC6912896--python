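"""The 30-statistic summary of a (regional, local) community dataset.

These statistics are the feature space for random-forest model selection
and the candidate statistic set for ABC.  They cover four families:

* tree shape — Pybus-Harvey gamma and normalized Colless imbalance of the
  regional and local trees, mean branch lengths, the normalized
  lineage-through-time (nLTT) distance between the two trees, and the
  richness ratio n/N;
* trait moments — mean, variance, skewness, excess kurtosis of regional
  and local trait values, the local trait range and its ratio to the
  regional range, and the standardized shift of the local trait mean;
* dispersion — MPD and MNTD of the local members on phylogenetic and on
  trait distances, raw and as standardized effect sizes (SES) against
  uniform random same-size subsets of the regional pool;
* phylogenetic signal — Blomberg's K and Pagel's lambda of the local
  traits on the local tree.

The canonical order and names in ``STAT_NAMES`` are frozen; a
:class:`SummaryVector` always carries all 30 values.  A statistic that is
undefined for a degenerate input (e.g. zero trait variance) is recorded as
0.0 and its name added to ``flags``; flagged statistics are meant to be
imputed for random forests but excluded from ABC distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import linalg, optimize

from .assembly import LocalCommunity
from .dispersion import mntd, mpd, null_mntd, null_mpd, random_subsets
from .regional_sim import RegionalPool, _as_rng
from .trees import colless_index, gamma_statistic, nltt_distance

__all__ = [
    "STAT_NAMES",
    "SummaryVector",
    "compute_summaries",
    "standardize_reference",
    "StandardScale",
    "select_top_stats",
    "blomberg_k",
    "pagel_lambda",
]

STAT_NAMES: tuple[str, ...] = (
    "gamma_regional",
    "gamma_local",
    "colless_regional",
    "colless_local",
    "mean_branch_length_regional",
    "mean_branch_length_local",
    "nltt_distance",
    "richness_ratio",
    "trait_mean_regional",
    "trait_var_regional",
    "trait_skew_regional",
    "trait_kurt_regional",
    "trait_mean_local",
    "trait_var_local",
    "trait_skew_local",
    "trait_kurt_local",
    "trait_range_local",
    "trait_range_ratio",
    "mpd_phylo",
    "mpd_phylo_ses",
    "mntd_phylo",
    "mntd_phylo_ses",
    "mpd_trait",
    "mpd_trait_ses",
    "mntd_trait",
    "mntd_trait_ses",
    "blomberg_k",
    "pagel_lambda",
    "pd_ratio",
    "trait_shift",
)


@dataclass
class SummaryVector:
    """Ordered map of the 30 named statistics (+ undefined-value flags)."""

    values: dict[str, float]
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if tuple(self.values) != STAT_NAMES:
            raise ValueError("SummaryVector must hold exactly the 30 canonical statistics in order")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in STAT_NAMES])

    def __getitem__(self, key: str) -> float:
        return self.values[key]


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------


def _phylo_mean_and_mse(C: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """GLS phylogenetic mean, MSE0 (raw) and MSE (phylo-corrected)."""
    n = z.shape[0]
    cf = linalg.cho_factor(C, lower=True, check_finite=False)
    Ci1 = linalg.cho_solve(cf, np.ones(n), check_finite=False)
    a = float(Ci1 @ z) / float(Ci1.sum())
    r = z - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ linalg.cho_solve(cf, r, check_finite=False)) / (n - 1)
    return a, mse0, mse


def blomberg_k(C: np.ndarray, z: np.ndarray) -> float:
    """Blomberg's K: observed MSE0/MSE scaled by its Brownian expectation.

    ``C`` is the phylogenetic covariance (shared path length) matrix of the
    community tree; K ~ 1 under Brownian motion, < 1 for less signal than
    BM, > 1 for more.
    """
    n = z.shape[0]
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    _, mse0, mse = _phylo_mean_and_mse(C, z)
    if mse == 0:
        raise FloatingPointError("zero phylogenetic MSE (constant traits)")
    cf = linalg.cho_factor(C, lower=True, check_finite=False)
    inv1 = linalg.cho_solve(cf, np.ones(n), check_finite=False)
    expected = (np.trace(C) - n / float(inv1.sum())) / (n - 1)
    return float((mse0 / mse) / expected)


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _lambda_negloglik(lam: float, C: np.ndarray, z: np.ndarray) -> float:
    n = z.shape[0]
    Cl = _lambda_transform(C, lam)
    try:
        cf = linalg.cho_factor(Cl, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Ci1 = linalg.cho_solve(cf, np.ones(n), check_finite=False)
    a = float(Ci1 @ z) / float(Ci1.sum())
    r = z - a
    s2 = float(r @ linalg.cho_solve(cf, r, check_finite=False)) / n
    if s2 <= 0:
        return np.inf
    return 0.5 * (n * np.log(s2) + logdet + n * (1.0 + np.log(2 * np.pi)))


def pagel_lambda(C: np.ndarray, z: np.ndarray, xatol: float = 1e-6) -> float:
    """ML estimate of Pagel's lambda over [0, 1] (bounded 1-D search).

    lambda scales the off-diagonal (shared-history) entries of the
    phylogenetic covariance: 0 = no signal (star phylogeny), 1 = Brownian
    motion.
    """
    if z.shape[0] < 4:
        raise ValueError("Pagel's lambda needs at least 4 tips")
    if np.var(z) == 0:
        raise FloatingPointError("constant traits: lambda undefined")
    res = optimize.minimize_scalar(
        _lambda_negloglik,
        bounds=(0.0, 1.0),
        args=(C, z),
        method="bounded",
        options={"xatol": xatol},
    )
    # the bounded optimizer can sit inside the interval at a flat optimum;
    # compare with the endpoints explicitly
    cands = [0.0, 1.0, float(res.x)]
    vals = [_lambda_negloglik(c, C, z) for c in cands]
    return float(cands[int(np.argmin(vals))]) if min(vals) < np.inf else float(res.x)


# ---------------------------------------------------------------------------
# the 30 statistics
# ---------------------------------------------------------------------------


def compute_summaries(
    pool: RegionalPool,
    local: LocalCommunity,
    null_reps: int = 999,
    seed=None,
) -> SummaryVector:
    """Reduce a (regional, local) pair to the canonical SummaryVector.

    ``null_reps`` controls the SES randomization null size; the SES values
    are reproducible bit-for-bit for a fixed ``seed``.  Requires local
    richness >= 4 (the signal statistics are meaningless below that).
    """
    n = local.n
    N = pool.N
    if n < 4:
        raise ValueError("summary statistics require local richness >= 4")
    idx = np.asarray(local.member_idx)
    if np.any(idx < 0) or np.any(idx >= N):
        raise ValueError("local member indices do not match the regional pool")
    rng = _as_rng(seed)

    tree = pool.phylogeny
    ltree = local.local_tree if local.local_tree is not None else tree.induced(local.members)
    z_reg = pool.trait_array
    z_loc = z_reg[idx]

    flags: set[str] = set()
    v: dict[str, float] = {}

    def moments(z, prefix):
        # biased sample skewness / excess kurtosis (Fisher), as in
        # scipy.stats.skew / kurtosis defaults
        mu = z.mean()
        d = z - mu
        m2 = float(np.mean(d * d))
        v[f"trait_mean_{prefix}"] = float(mu)
        v[f"trait_var_{prefix}"] = float(z.var(ddof=1))
        if m2 == 0:
            v[f"trait_skew_{prefix}"] = 0.0
            v[f"trait_kurt_{prefix}"] = 0.0
            flags.update({f"trait_skew_{prefix}", f"trait_kurt_{prefix}"})
        else:
            v[f"trait_skew_{prefix}"] = float(np.mean(d**3) / m2**1.5)
            v[f"trait_kurt_{prefix}"] = float(np.mean(d**4) / m2**2 - 3.0)

    # tree shape
    v["gamma_regional"] = gamma_statistic(tree)
    v["gamma_local"] = gamma_statistic(ltree)
    v["colless_regional"] = colless_index(tree)
    v["colless_local"] = colless_index(ltree)
    v["mean_branch_length_regional"] = float(tree.blen.sum() / (tree.nnodes - 1))
    v["mean_branch_length_local"] = float(ltree.blen.sum() / (ltree.nnodes - 1))
    v["nltt_distance"] = 0.0 if n == N else nltt_distance(tree, ltree)
    v["richness_ratio"] = n / N

    # trait moments
    moments(z_reg, "regional")
    moments(z_loc, "local")
    v["trait_range_local"] = float(z_loc.max() - z_loc.min())
    reg_range = float(z_reg.max() - z_reg.min())
    if reg_range == 0:
        v["trait_range_ratio"] = 0.0
        flags.add("trait_range_ratio")
    else:
        v["trait_range_ratio"] = v["trait_range_local"] / reg_range

    # dispersion, raw + SES against shared random subsets
    subsets = random_subsets(rng, N, n, null_reps)
    for source, D in (("phylo", pool.phylo_distances), ("trait", pool.trait_distances)):
        sub = D[np.ix_(idx, idx)]
        order = np.argsort(D, axis=1)
        for metric, fn, null in (
            ("mpd", mpd, null_mpd(D, subsets)),
            ("mntd", mntd, null_mntd(D, subsets, order)),
        ):
            obs = fn(sub)
            v[f"{metric}_{source}"] = obs
            sd = float(null.std(ddof=1))
            if sd <= 1e-12 * max(1.0, abs(float(null.mean()))):
                v[f"{metric}_{source}_ses"] = 0.0
                flags.add(f"{metric}_{source}_ses")
            else:
                v[f"{metric}_{source}_ses"] = (obs - float(null.mean())) / sd

    # phylogenetic signal on the local tree
    mrca = tree.mrca_depths()
    root_depth = float(tree.crown_age - ltree.crown_age)
    C = mrca[np.ix_(idx, idx)] - root_depth
    np.fill_diagonal(C, np.diag(mrca)[idx] - root_depth)
    try:
        v["blomberg_k"] = blomberg_k(C, z_loc)
    except (FloatingPointError, linalg.LinAlgError):
        v["blomberg_k"] = 0.0
        flags.add("blomberg_k")
    try:
        v["pagel_lambda"] = pagel_lambda(C, z_loc)
    except (FloatingPointError, linalg.LinAlgError):
        v["pagel_lambda"] = 0.0
        flags.add("pagel_lambda")

    # Faith's PD of the local members relative to the regional tree
    v["pd_ratio"] = 1.0 if n == N else ltree.total_branch_length / tree.total_branch_length

    sd_reg = float(z_reg.std(ddof=1))
    if sd_reg == 0:
        v["trait_shift"] = 0.0
        flags.add("trait_shift")
    else:
        v["trait_shift"] = abs(float(z_loc.mean()) - float(z_reg.mean())) / sd_reg

    ordered = {k: float(v[k]) for k in STAT_NAMES}
    return SummaryVector(ordered, frozenset(flags))


# ---------------------------------------------------------------------------
# standardization + statistic selection
# ---------------------------------------------------------------------------


@dataclass
class StandardScale:
    """Reapplicable median/MAD column scale fit on a reference table."""

    center: np.ndarray
    scale: np.ndarray
    zero_mad: np.ndarray  # boolean: columns whose MAD was 0 (scale set to 1)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.center) / self.scale


def standardize_reference(stats_matrix: np.ndarray) -> tuple[np.ndarray, StandardScale]:
    """Center columns by median, scale by median absolute deviation.

    Zero-MAD columns are scaled by 1 and flagged.  Robust scaling keeps a
    handful of extreme simulations from dominating Euclidean ABC
    distances.
    """
    X = np.asarray(stats_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    center = np.median(X, axis=0)
    mad = np.median(np.abs(X - center), axis=0)
    zero = mad == 0
    scale = np.where(zero, 1.0, mad)
    rec = StandardScale(center=center, scale=scale, zero_mad=zero)
    return rec.apply(X), rec


def select_top_stats(importance: Mapping[str, float], k: int = 10) -> list[str]:
    """The ``k`` statistic names with highest importance.

    Ties are broken by canonical ``STAT_NAMES`` order; unknown names are
    rejected.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(importance):
        raise ValueError("k exceeds the number of scored statistics")
    unknown = set(importance) - set(STAT_NAMES)
    if unknown:
        raise KeyError(f"unknown statistic names: {sorted(unknown)}")
    canon = {name: i for i, name in enumerate(STAT_NAMES)}
    ranked = sorted(importance.items(), key=lambda kv: (-kv[1], canon[kv[0]]))
    return [name for name, _ in ranked[:k]]
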