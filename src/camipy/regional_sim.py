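"""Regional species pool simulation.

A regional pool is a constant-rate birth--death phylogeny grown until it
holds ``N`` extant species, with one continuous trait per species evolved
along the tree under Brownian motion (BM) or an Ornstein--Uhlenbeck (OU)
process.

Birth--death conditioning.  The tree is grown forward in time (Gillespie)
from a crown pair of lineages; if the whole clade dies the simulation
restarts.  On the first moment the extant count reaches ``N`` the pendant
edges are extended by an Exp(N(lambda+mu)) waiting time -- the classic
simple-sampling stop rule.  Without that extension the youngest internode
interval would be exactly zero, which noticeably inflates the Pybus--Harvey
gamma of pure-birth trees (E[gamma] should be 0).  Extinct lineages are
pruned afterwards, so returned trees are ultrametric with exactly ``N``
tips labeled ``t1..tN`` in birth order.

RNG discipline: each public operation takes an integer seed (or an existing
``numpy.random.Generator``) and draws from a single stream; in composite
simulations the tree is drawn first, then the traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .trees import Phylogeny

__all__ = [
    "TraitSet",
    "RegionalPool",
    "simulate_bd_tree",
    "evolve_traits_bm",
    "evolve_traits_ou",
    "simulate_regional_pool",
]

_MAX_RESTARTS = 100_000


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TraitSet:
    """One continuous trait value per tip.

    ``alpha`` is 0 under BM semantics and strictly positive under OU.
    """

    values: dict[str, float]
    trait_model: str  # "BM" | "OU"
    sigma2: float
    alpha: float = 0.0
    root_state: float = 0.0
    theta: float | None = None

    def __post_init__(self):
        if self.trait_model not in ("BM", "OU"):
            raise ValueError(f"trait_model must be 'BM' or 'OU', got {self.trait_model!r}")
        if self.trait_model == "BM" and self.alpha != 0.0:
            raise ValueError("alpha must be 0 under BM semantics")
        for lab, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite trait value for tip {lab!r}")

    def array_for(self, labels) -> np.ndarray:
        return np.array([self.values[lab] for lab in labels], dtype=np.float64)


@dataclass
class RegionalPool:
    """Regional phylogeny + traits + the parameters that generated them."""

    phylogeny: Phylogeny
    traits: TraitSet
    params_used: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if set(self.traits.values) != set(self.phylogeny.labels):
            raise ValueError("traits must be keyed exactly by the phylogeny's tips")
        self._trait_array = self.traits.array_for(self.phylogeny.labels)

    @property
    def N(self) -> int:
        return self.phylogeny.ntips

    @property
    def trait_array(self) -> np.ndarray:
        """Trait values aligned with ``phylogeny.labels``."""
        return self._trait_array

    @property
    def phylo_distances(self) -> np.ndarray:
        return self.phylogeny.distance_matrix()

    @property
    def trait_distances(self) -> np.ndarray:
        z = self._trait_array
        return np.abs(z[:, None] - z[None, :])


def simulate_bd_tree(lam: float, mu: float, N: int, seed) -> Phylogeny:
    """Constant-rate birth-death tree conditioned on ``N`` extant tips.

    Parameters
    ----------
    lam, mu
        Speciation and extinction rates; ``mu < lam`` is required so the
        process is supercritical and the target richness is reachable.
    N
        Number of extant species to stop at (>= 2).
    seed
        Integer seed or ``numpy.random.Generator``.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if mu >= lam:
        raise ValueError(
            "mu >= lambda: subcritical/critical birth-death may never reach N extant species"
        )
    rng = _as_rng(seed)
    total = lam + mu
    p_birth = lam / total

    for _ in range(_MAX_RESTARTS):
        parent = [-1, 0, 0]
        tbirth = [0.0, 0.0, 0.0]
        tend = [0.0, np.nan, np.nan]
        active = [1, 2]
        t = 0.0
        failed = False
        while len(active) < N:
            k = len(active)
            if k == 0:
                failed = True
                break
            t += rng.exponential(1.0 / (k * total))
            j = int(rng.integers(k))
            v = active[j]
            if rng.random() < p_birth:
                tend[v] = t
                for _c in range(2):
                    parent.append(v)
                    tbirth.append(t)
                    tend.append(np.nan)
                active[j] = len(parent) - 2
                active.append(len(parent) - 1)
            else:
                tend[v] = t
                active[j] = active[-1]
                active.pop()
        if failed:
            continue
        # simple-sampling stop: extend pendant edges past the Nth birth
        t += rng.exponential(1.0 / (N * total))
        for v in active:
            tend[v] = t
        return _prune_to_extant(
            np.asarray(parent), np.asarray(tbirth), np.asarray(tend), active
        )
    raise RuntimeError("birth-death simulation failed to reach N tips")  # pragma: no cover


def _prune_to_extant(parent, tbirth, tend, extant: list[int]) -> Phylogeny:
    """Drop extinct lineages from a complete tree and relabel tips t1..tN."""
    m = parent.shape[0]
    nchild = np.bincount(parent[parent >= 0], minlength=m)
    is_tip = nchild == 0
    tip_ids = np.flatnonzero(is_tip)
    extant_set = set(extant)
    # complete tree with tips first; extant tips labeled in birth order
    order = np.concatenate([tip_ids, np.flatnonzero(~is_tip)])
    new_id = np.empty(m, dtype=np.int64)
    new_id[order] = np.arange(m)
    parent_new = np.where(parent[order] >= 0, new_id[np.clip(parent[order], 0, None)], -1)
    blen_new = tend[order] - tbirth[order]
    extant_tips_in_birth_order = [v for v in tip_ids if v in extant_set]
    lab_map = {v: f"t{i + 1}" for i, v in enumerate(extant_tips_in_birth_order)}
    labels = [lab_map.get(v, f"x{v}") for v in tip_ids]
    complete = Phylogeny(parent_new, blen_new, labels)
    keep = [lab_map[v] for v in extant_tips_in_birth_order]
    if len(keep) == complete.ntips:
        return complete
    return complete.induced(keep)


def evolve_traits_bm(tree: Phylogeny, sigma2: float, root_state: float, seed) -> TraitSet:
    """Brownian-motion trait evolution: independent Gaussian increments with
    variance ``sigma2 * branch_length`` along every branch."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = _as_rng(seed)
    s = np.sqrt(sigma2)
    z = np.zeros(tree.nnodes)
    draws = rng.standard_normal(tree.nnodes)
    order = tree.preorder()
    z[order[0]] = root_state
    for v in order:
        p = tree.parent[v]
        if p >= 0:
            z[v] = z[p] + s * np.sqrt(tree.blen[v]) * draws[v]
    values = {lab: float(z[i]) for i, lab in enumerate(tree.labels)}
    return TraitSet(values, "BM", sigma2=sigma2, alpha=0.0, root_state=root_state)


def evolve_traits_ou(
    tree: Phylogeny,
    sigma2: float,
    alpha: float,
    theta: float,
    root_state: float,
    seed,
) -> TraitSet:
    """Ornstein--Uhlenbeck trait evolution via the exact branch transition.

    Along a branch of length ``b``::

        child = theta + (parent - theta) * exp(-alpha*b)
                + N(0, sigma2/(2*alpha) * (1 - exp(-2*alpha*b)))

    For matched seeds the draws align node-for-node with
    :func:`evolve_traits_bm`, so the alpha -> 0 limit converges pathwise
    to BM.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive (use evolve_traits_bm for alpha = 0)")
    rng = _as_rng(seed)

    def step(parent_val, b, u):
        e = np.exp(-alpha * b)
        sd = np.sqrt(sigma2 / (2.0 * alpha) * (1.0 - e * e))
        return theta + (parent_val - theta) * e + sd * u

    # run with root offset folded in: start at root_state
    z = np.zeros(tree.nnodes)
    draws = rng.standard_normal(tree.nnodes)
    order = tree.preorder()
    z[order[0]] = root_state
    for v in order:
        p = tree.parent[v]
        if p >= 0:
            z[v] = step(z[p], tree.blen[v], draws[v])
    values = {lab: float(z[i]) for i, lab in enumerate(tree.labels)}
    return TraitSet(values, "OU", sigma2=sigma2, alpha=alpha, root_state=root_state, theta=theta)


def simulate_regional_pool(
    lam: float,
    mu: float,
    N: int,
    trait_model: str,
    sigma2: float,
    seed,
    alpha: float = 0.0,
    theta: float | None = None,
    root_state: float = 0.0,
    rescale_crown_age: float | None = 1.0,
) -> RegionalPool:
    """Simulate tree then traits from one seeded stream.

    By default the tree is rescaled to unit crown age before traits evolve,
    so ``sigma2`` is the expected root-to-tip trait variance and trait
    deviations are on a common scale across draws of ``lam``/``mu`` (the
    scale on which filtering/competition strengths in [1, 60] are
    meaningful).  Pass ``rescale_crown_age=None`` to keep natural time
    units.
    """
    rng = _as_rng(seed)
    tree = simulate_bd_tree(lam, mu, N, rng)
    if rescale_crown_age is not None:
        tree = tree.scaled(rescale_crown_age / tree.crown_age)
    if trait_model == "BM":
        traits = evolve_traits_bm(tree, sigma2, root_state, rng)
    elif trait_model == "OU":
        traits = evolve_traits_ou(
            tree, sigma2, alpha, root_state if theta is None else theta, root_state, rng
        )
    else:
        raise ValueError(f"unknown trait model {trait_model!r}")
    params = {
        "lambda": lam,
        "mu": mu,
        "N": N,
        "trait_model": trait_model,
        "sigma2": sigma2,
        "alpha": alpha if trait_model == "OU" else 0.0,
        "theta": (root_state if theta is None else theta) if trait_model == "OU" else None,
        "root_state": root_state,
        "rescale_crown_age": rescale_crown_age,
    }
    return RegionalPool(tree, traits, params, seed=seed if isinstance(seed, int) else None)
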