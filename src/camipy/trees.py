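"""Rooted binary phylogenies on flat arrays.

The whole pipeline (birth-death simulation, trait evolution, community
assembly, dispersion nulls, summary statistics) operates on one lightweight
tree structure: a parent-pointer array with branch lengths, tips stored
first.  This keeps the per-dataset cost of patristic distances, shared-path
(MRCA-depth) matrices and induced subtrees at O(N^2) numpy work instead of
object traversals.

Conventions
-----------
* Nodes ``0 .. ntips-1`` are tips, in the order of ``labels``; internal
  nodes follow.  Exactly one node has parent ``-1`` (the root, whose branch
  length is 0).
* Branch lengths are in arbitrary time units; ultrametric trees have all
  tip depths equal to the crown age.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phylogeny",
    "gamma_statistic",
    "colless_index",
    "ltt_curve",
    "nltt_distance",
]


class Phylogeny:
    """A rooted binary tree with branch lengths and labeled tips."""

    def __init__(
        self,
        parent: np.ndarray,
        blen: np.ndarray,
        labels: Sequence[str],
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.labels = list(labels)
        self._cache: dict = {}
        if validate:
            self._validate()

    # -- basic structure ---------------------------------------------------

    @property
    def ntips(self) -> int:
        return len(self.labels)

    @property
    def nnodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        (r,) = np.flatnonzero(self.parent == -1)
        return int(r)

    def _validate(self) -> None:
        n, m = self.ntips, self.nnodes
        if n < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        if m != 2 * n - 1:
            raise ValueError(
                f"binary rooted tree with {n} tips must have {2 * n - 1} nodes, got {m}"
            )
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        if len(set(self.labels)) != n:
            raise ValueError("tip labels must be unique")
        nchild = np.bincount(self.parent[self.parent >= 0], minlength=m)
        if np.any(nchild[:n] != 0):
            raise ValueError("a tip node has children")
        internal = nchild[n:]
        if np.any(internal != 2):
            raise ValueError("tree is not binary (internal node without 2 children)")

    def children(self) -> list[list[int]]:
        if "children" not in self._cache:
            ch: list[list[int]] = [[] for _ in range(self.nnodes)]
            for v, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(v)
            self._cache["children"] = ch
        return self._cache["children"]

    def preorder(self) -> np.ndarray:
        """Node indices with every parent before its children."""
        if "preorder" not in self._cache:
            ch = self.children()
            order = np.empty(self.nnodes, dtype=np.int64)
            stack = [self.root]
            i = 0
            while stack:
                v = stack.pop()
                order[i] = v
                i += 1
                stack.extend(ch[v])
            self._cache["preorder"] = order
        return self._cache["preorder"]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        if "depths" not in self._cache:
            d = np.zeros(self.nnodes)
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.blen[v]
            self._cache["depths"] = d
        return self._cache["depths"]

    @property
    def crown_age(self) -> float:
        return float(self.depths()[: self.ntips].max())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        td = self.depths()[: self.ntips]
        return bool(td.max() - td.min() <= tol * max(1.0, td.max()))

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def tip_index(self) -> dict[str, int]:
        if "tip_index" not in self._cache:
            self._cache["tip_index"] = {lab: i for i, lab in enumerate(self.labels)}
        return self._cache["tip_index"]

    def indices_of(self, labels: Iterable[str]) -> np.ndarray:
        ti = self.tip_index()
        out = []
        for lab in labels:
            if lab not in ti:
                raise KeyError(f"unknown tip label: {lab!r}")
            out.append(ti[lab])
        return np.asarray(out, dtype=np.int64)

    # -- pairwise structure ------------------------------------------------

    def mrca_depths(self) -> np.ndarray:
        """Matrix of root-to-MRCA path lengths between tips.

        For an ultrametric tree this is, up to the local-root offset, the
        Brownian-motion covariance structure (shared path length from the
        root); the diagonal holds tip depths.
        """
        if "mrca_depths" not in self._cache:
            n = self.ntips
            depth = self.depths()
            M = np.zeros((n, n))
            tipsets: dict[int, np.ndarray] = {}
            ch = self.children()
            for v in self.preorder()[::-1]:
                if v < n:
                    tipsets[v] = np.array([v], dtype=np.int64)
                else:
                    a, b = (tipsets.pop(c) for c in ch[v])
                    M[np.ix_(a, b)] = depth[v]
                    M[np.ix_(b, a)] = depth[v]
                    tipsets[v] = np.concatenate([a, b])
            np.fill_diagonal(M, depth[:n])
            self._cache["mrca_depths"] = M
        return self._cache["mrca_depths"]

    def distance_matrix(self) -> np.ndarray:
        """Patristic (path-length) distances between tips."""
        if "distance_matrix" not in self._cache:
            d = self.depths()[: self.ntips]
            self._cache["distance_matrix"] = d[:, None] + d[None, :] - 2 * self.mrca_depths()
        return self._cache["distance_matrix"]

    # -- derived trees -----------------------------------------------------

    def scaled(self, factor: float) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.blen * factor, self.labels, validate=False)

    def induced(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree spanning ``labels`` with degree-2 nodes suppressed.

        Path lengths between retained tips are preserved; the new root is
        the MRCA of the retained tips.
        """
        members = self.indices_of(labels)
        m = members.shape[0]
        if m < 2:
            raise ValueError("an induced subtree needs at least 2 tips")
        if len(set(members.tolist())) != m:
            raise ValueError("duplicate members")

        n = self.ntips
        ch = self.children()
        depth = self.depths()
        member_mask = np.zeros(self.nnodes, dtype=bool)
        member_mask[members] = True

        count = np.zeros(self.nnodes, dtype=np.int64)
        count[members] = 1
        pre = self.preorder()
        for v in pre[::-1]:
            p = self.parent[v]
            if p >= 0:
                count[p] += count[v]

        # keep member tips and internal junctions (both children occupied)
        keep = np.zeros(self.nnodes, dtype=bool)
        keep[members] = True
        for v in range(n, self.nnodes):
            occupied = sum(1 for c in ch[v] if count[c] > 0)
            if occupied == 2:
                keep[v] = True
        # MRCA: deepest kept node ancestral to all members
        kept_all = [v for v in np.flatnonzero(keep) if count[v] == m]
        mrca = max(kept_all, key=lambda v: depth[v])
        # discard kept junctions above the MRCA (possible when the MRCA is
        # below the root and some ancestor is a junction for other tips)
        anc = np.zeros(self.nnodes, dtype=bool)
        v = mrca
        while v != -1:
            anc[v] = True
            v = self.parent[v]
        below = np.zeros(self.nnodes, dtype=bool)
        below[mrca] = True
        for v in pre:
            p = self.parent[v]
            if p >= 0 and below[p]:
                below[v] = True
        keep &= below

        kept = np.flatnonzero(keep)
        # order: member tips first (original relative order), then junctions
        kept_tips = [v for v in kept if member_mask[v]]
        kept_internal = [v for v in kept if not member_mask[v]]
        new_id = {v: i for i, v in enumerate(kept_tips + kept_internal)}

        parent_new = np.full(len(kept), -1, dtype=np.int64)
        blen_new = np.zeros(len(kept))
        # nearest kept ancestor via preorder walk from mrca
        nearest: dict[int, int] = {}
        stack = [(mrca, -1)]
        while stack:
            v, a = stack.pop()
            a_next = v if keep[v] else a
            if keep[v] and v != mrca:
                parent_new[new_id[v]] = new_id[a]
                blen_new[new_id[v]] = depth[v] - depth[a]
            for c in ch[v]:
                if count[c] > 0:
                    stack.append((c, a_next))
        labels_new = [self.labels[v] for v in kept_tips]
        return Phylogeny(parent_new, blen_new, labels_new)

    def faith_pd(self, labels: Iterable[str]) -> float:
        """Total branch length of the induced subtree spanning ``labels``."""
        return self.induced(labels).total_branch_length

    # -- serialization -----------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        """Newick string with branch lengths (iterative, recursion-safe)."""
        ch = self.children()
        fmt = f"%.{precision}g"
        out = _io.StringIO()
        # explicit stack: (node, child_cursor)
        stack = [(self.root, 0)]
        while stack:
            v, cur = stack[-1]
            kids = ch[v]
            if not kids:
                out.write(_escape_label(self.labels[v]))
                out.write(":" + fmt % self.blen[v])
                stack.pop()
                continue
            if cur == 0:
                out.write("(")
            if cur < len(kids):
                if cur > 0:
                    out.write(",")
                stack[-1] = (v, cur + 1)
                stack.append((kids[cur], 0))
            else:
                out.write(")")
                if self.parent[v] >= 0:
                    out.write(":" + fmt % self.blen[v])
                stack.pop()
        out.write(";")
        return out.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.ntips} tips, crown_age={self.crown_age:.4g}>"


def _escape_label(lab: str) -> str:
    if any(c in lab for c in "():;, '\t\n"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


# ---------------------------------------------------------------------------
# Tree-shape statistics
# ---------------------------------------------------------------------------


def _internode_intervals(tree: Phylogeny) -> tuple[np.ndarray, float]:
    """Sorted speciation depths (crown tree) and present-day depth."""
    d = tree.depths()
    bt = np.sort(d[tree.ntips :])
    present = float(d[: tree.ntips].max())
    return bt, present


def gamma_statistic(tree: Phylogeny) -> float:
    """Pybus-Harvey gamma; 0-centered for pure-birth trees.

    Requires an ultrametric tree with >= 3 tips.
    """
    n = tree.ntips
    if n < 3:
        raise ValueError("gamma requires at least 3 tips")
    bt, present = _internode_intervals(tree)
    # g[k] = interval with k+2 lineages, k = 0..n-2 (last ends at present)
    ends = np.append(bt[1:], present)
    g = ends - bt
    k = np.arange(2, n + 1)
    T = np.cumsum(k * g)  # T[j] = sum_{i=2}^{j+2} i*g_i
    Tn = T[-1]
    mean_inner = T[:-1].mean()  # (1/(n-2)) sum_{i=2}^{n-1} T_i
    return float((mean_inner - Tn / 2.0) / (Tn * np.sqrt(1.0 / (12 * (n - 2)))))


def colless_index(tree: Phylogeny, normalize: bool = True) -> float:
    """Colless imbalance: sum of |left - right| tip counts over internal nodes."""
    n = tree.ntips
    if n < 3:
        raise ValueError("Colless index requires at least 3 tips")
    ch = tree.children()
    count = np.zeros(tree.nnodes, dtype=np.int64)
    count[:n] = 1
    total = 0
    for v in tree.preorder()[::-1]:
        if v >= n:
            a, b = ch[v]
            count[v] = count[a] + count[b]
            total += abs(int(count[a]) - int(count[b]))
    if not normalize:
        return float(total)
    return float(total * 2.0 / ((n - 1) * (n - 2)))


def ltt_curve(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Lineage-through-time step function: (event times, counts after event).

    Times run from the crown (2 lineages) to the present.
    """
    bt, present = _internode_intervals(tree)
    times = np.append(bt, present)
    counts = np.append(np.arange(2, tree.ntips + 1), tree.ntips)
    return times, counts


def nltt_distance(a: Phylogeny, b: Phylogeny) -> float:
    """Normalized lineage-through-time distance.

    Both curves are rescaled to unit time (crown to present) and unit
    lineage count; the distance is the L1 norm between the two step
    functions on [0, 1].
    """
    ta, ca = ltt_curve(a)
    tb, cb = ltt_curve(b)
    ta = ta / ta[-1] if ta[-1] > 0 else ta
    tb = tb / tb[-1] if tb[-1] > 0 else tb
    fa = ca / ca[-1]
    fb = cb / cb[-1]
    grid = np.union1d(np.concatenate([ta, tb]), [0.0, 1.0])
    # step value just after each grid point
    ia = np.searchsorted(ta, grid, side="right") - 1
    ib = np.searchsorted(tb, grid, side="right") - 1
    va = np.where(ia >= 0, fa[np.clip(ia, 0, None)], 2.0 / ca[-1])
    vb = np.where(ib >= 0, fb[np.clip(ib, 0, None)], 2.0 / cb[-1])
    widths = np.diff(grid)
    dist = float(np.sum(np.abs(va[:-1] - vb[:-1]) * widths))
    return dist
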