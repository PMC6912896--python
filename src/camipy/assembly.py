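"""Local community assembly from a regional pool.

Three assembly models, all driven by the same stochastic rejection
algorithm: a colonist is drawn uniformly at random from the regional
species not yet in the local community, its persistence probability is
computed, and it joins the community iff that probability exceeds a fresh
U(0,1) draw.  Rejected species stay in the regional pool and may colonize
again.  Assembly stops at local richness ``n``.

Persistence probabilities (z_i = colonist trait):

* neutral:      P = 1
* filtering:    P = exp(-(z_i - zE)^2 / tE)      (phenotypic matching to an
                environmental optimum zE; small tE = strong filter)
* competition:  P = 1 - exp(-(z_i - z_bar)^2 / tC)  (phenotypic repulsion
                from the community mean z_bar; large tC = strong
                competition).  The first colonist is accepted
                unconditionally (z_bar is undefined for an empty
                community), and z_bar is recomputed after every acceptance.

RNG contract (deterministic given seed): the neutral model draws one
uniform index among current non-members per acceptance and no U(0,1);
the non-neutral models consume (candidate, u) pairs, generated in blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regional_sim import RegionalPool, _as_rng
from .trees import Phylogeny

__all__ = [
    "AssemblyParams",
    "LocalCommunity",
    "persistence_prob_filtering",
    "persistence_prob_competition",
    "assemble_local",
    "induce_subtree",
]

MODELS = ("neutral", "filtering", "competition")


def persistence_prob_filtering(zi, zE: float, tE: float):
    """Eq.-style phenotypic matching: exp(-(zi - zE)^2 / tE), in (0, 1]."""
    if tE <= 0:
        raise ValueError("tE must be positive")
    zi = np.asarray(zi, dtype=np.float64)
    out = np.exp(-((zi - zE) ** 2) / tE)
    return float(out) if out.ndim == 0 else out


def persistence_prob_competition(zi, z_bar: float, tC: float):
    """Phenotypic repulsion: 1 - exp(-(zi - z_bar)^2 / tC), in [0, 1)."""
    if tC <= 0:
        raise ValueError("tC must be positive")
    zi = np.asarray(zi, dtype=np.float64)
    out = 1.0 - np.exp(-((zi - z_bar) ** 2) / tC)
    return float(out) if out.ndim == 0 else out


@dataclass
class AssemblyParams:
    model: str
    n: int
    tE: float | None = None
    tC: float | None = None
    zE: float | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n < 1:
            raise ValueError("local richness n must be >= 1")
        if self.model == "filtering":
            if self.tE is None or self.tE <= 0:
                raise ValueError("filtering requires tE > 0")
            if self.zE is None:
                raise ValueError("filtering requires the environmental optimum zE")
        if self.model == "competition" and (self.tC is None or self.tC <= 0):
            raise ValueError("competition requires tC > 0")


@dataclass
class LocalCommunity:
    """A subset of regional species with its induced subtree and traits."""

    members: list[str]
    member_idx: np.ndarray  # indices into the regional pool's tip order
    local_tree: Phylogeny | None
    local_traits: dict[str, float]
    z_bar_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    attempts: int = 0
    model: str = "neutral"

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def mean_trait(self) -> float:
        return float(np.mean(list(self.local_traits.values())))


def assemble_local(
    pool: RegionalPool,
    params: AssemblyParams,
    seed,
    attempt_cap: int = 1_000_000,
) -> LocalCommunity:
    """Assemble ``params.n`` species from ``pool`` under the given model.

    Raises ``RuntimeError`` with a diagnostic if the rejection algorithm
    exceeds ``attempt_cap`` colonization attempts (possible under extreme
    strength parameters).
    """
    N = pool.N
    n = params.n
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    rng = _as_rng(seed)
    z = pool.trait_array

    remaining = list(range(N))
    members: list[int] = []
    trace: list[float] = []
    attempts = 0

    if params.model == "neutral":
        for _ in range(n):
            j = int(rng.integers(len(remaining)))
            remaining[j], remaining[-1] = remaining[-1], remaining[j]
            members.append(remaining.pop())
            attempts += 1
            trace.append(float(np.mean(z[members])))
    else:
        filtering = params.model == "filtering"
        zsum = 0.0
        block = 64
        while len(members) < n:
            if attempts >= attempt_cap:
                strength = params.tE if filtering else params.tC
                raise RuntimeError(
                    f"assembly exceeded {attempt_cap} attempts "
                    f"(model={params.model}, strength={strength}, n={n}, N={N})"
                )
            if not members and not filtering:
                # first colonist under competition: unconditional
                j = int(rng.integers(len(remaining)))
                attempts += 1
            else:
                pos = rng.integers(0, len(remaining), size=block)
                u = rng.random(block)
                cand = z[[remaining[p] for p in pos]]
                if filtering:
                    P = np.exp(-((cand - params.zE) ** 2) / params.tE)
                else:
                    zbar = zsum / len(members)
                    P = 1.0 - np.exp(-((cand - zbar) ** 2) / params.tC)
                hits = np.flatnonzero(P > u)
                if hits.size == 0:
                    attempts += block
                    continue
                first = int(hits[0])
                attempts += first + 1
                j = int(pos[first])
            remaining[j], remaining[-1] = remaining[-1], remaining[j]
            idx = remaining.pop()
            members.append(idx)
            zsum += float(z[idx])
            trace.append(zsum / len(members))

    labels = [pool.phylogeny.labels[i] for i in members]
    local_tree = pool.phylogeny.induced(labels) if n >= 2 else None
    local_traits = {lab: float(z[i]) for lab, i in zip(labels, members)}
    return LocalCommunity(
        members=labels,
        member_idx=np.asarray(members, dtype=np.int64),
        local_tree=local_tree,
        local_traits=local_traits,
        z_bar_trace=np.asarray(trace),
        attempts=attempts,
        model=params.model,
    )


def induce_subtree(tree: Phylogeny, members: Sequence[str]) -> Phylogeny:
    """Subtree of ``tree`` spanning ``members`` (pairwise path lengths
    among retained tips are preserved; needs >= 2 members)."""
    return tree.induced(members)
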