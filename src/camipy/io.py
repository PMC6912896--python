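"""Readers, writers, fixtures and provenance records.

File formats are deliberately plain: Newick trees with branch lengths,
two-column CSV trait tables (``tip_label,trait_value``, header required),
one-label-per-line membership lists, and JSON manifests/provenance.  All
writes are atomic (temp file + rename) so interrupted runs never leave
truncated outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .assembly import AssemblyParams, assemble_local
from .regional_sim import RegionalPool, TraitSet, simulate_regional_pool
from .trees import Phylogeny

__all__ = [
    "read_newick",
    "write_newick",
    "read_traits",
    "write_traits",
    "read_membership",
    "write_membership",
    "atomic_write",
    "write_provenance",
    "make_fixture",
    "FIXTURE_KINDS",
]


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    internal = [nd for nd in nodes if not nd.is_leaf()]
    for nd in internal:
        if len(nd.child_nodes()) != 2:
            raise ValueError("tree has a non-binary node; only binary trees are supported")
    labels = []
    for nd in tips:
        if nd.taxon is None or not nd.taxon.label:
            raise ValueError("every tip must be labeled")
        labels.append(nd.taxon.label)
    index = {id(nd): i for i, nd in enumerate(tips)}
    index.update({id(nd): len(tips) + j for j, nd in enumerate(internal)})
    m = len(nodes)
    parent = np.full(m, -1, dtype=np.int64)
    blen = np.zeros(m)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                who = nd.taxon.label if nd.is_leaf() else "an internal node"
                raise ValueError(f"missing branch length on the edge above {who}")
            blen[i] = float(nd.edge.length)
    return Phylogeny(parent, blen, labels)


def read_newick(path) -> Phylogeny:
    """Parse a rooted binary Newick tree with branch lengths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              preserve_underscores=True)
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny, path) -> None:
    with atomic_write(path) as fh:
        fh.write(tree.to_newick())
        fh.write("\n")


# ---------------------------------------------------------------------------
# traits and membership
# ---------------------------------------------------------------------------


def read_traits(path, tree: Phylogeny | None = None) -> TraitSet:
    """Two-column CSV ``tip_label,trait_value`` -> TraitSet.

    If ``tree`` is given, the label sets are cross-checked and mismatches
    reported explicitly.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("trait file needs columns: tip_label, trait_value")
    labels = df.iloc[:, 0].astype(str)
    if labels.duplicated().any():
        dups = sorted(labels[labels.duplicated()].unique())
        raise ValueError(f"duplicate tip labels in trait file: {dups}")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        bad = sorted(labels[values.isna()])
        raise ValueError(f"non-numeric trait values for: {bad}")
    mapping = dict(zip(labels, values.astype(float)))
    if tree is not None:
        tips = set(tree.labels)
        extra = sorted(set(mapping) - tips)
        missing = sorted(tips - set(mapping))
        if extra or missing:
            raise ValueError(
                f"trait/tree label mismatch: not in tree {extra}; missing traits {missing}"
            )
    return TraitSet(values=mapping, trait_model="BM", sigma2=1.0)


def write_traits(traits: TraitSet, path) -> None:
    with atomic_write(path) as fh:
        fh.write("tip_label,trait_value\n")
        for lab, v in traits.values.items():
            fh.write(f"{lab},{v!r}\n")


def read_membership(path, tree: Phylogeny | None = None) -> list[str]:
    """Membership list: one tip label per line (or first CSV column)."""
    labels: list[str] = []
    with open(path) as fh:
        for line in fh:
            lab = line.strip().split(",")[0]
            if lab and lab != "tip_label":
                labels.append(lab)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in membership list")
    if tree is not None:
        unknown = sorted(set(labels) - set(tree.labels))
        if unknown:
            raise ValueError(f"members not in tree: {unknown}")
    return labels


def write_membership(members, path) -> None:
    with atomic_write(path) as fh:
        for lab in members:
            fh.write(f"{lab}\n")


def write_provenance(path, config: dict) -> None:
    """JSON record (config echo + package version) beside every output."""
    record = {"camipy_version": __version__, **config}
    with atomic_write(path) as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = (
    "tiny-deterministic",
    "neutral-N50",
    "filtering-strong",
    "competition-strong",
    "six-model-batch",
)


def _write_dataset(outdir: Path, stem: str, pool: RegionalPool, members, manifest: dict):
    write_newick(pool.phylogeny, outdir / f"{stem}.nwk")
    write_traits(pool.traits, outdir / f"{stem}_traits.csv")
    write_membership(members, outdir / f"{stem}_members.txt")
    write_provenance(outdir / f"{stem}_manifest.json", manifest)


def make_fixture(kind: str, seed: int, outdir) -> dict:
    """Write a self-contained on-disk dataset of the requested kind.

    Returns the manifest (true generating model and parameters).  Kinds:
    ``tiny-deterministic`` (a frozen 3-tip worked example),
    ``neutral-N50``, ``filtering-strong`` (tE = 1), ``competition-strong``
    (tC = 60), and ``six-model-batch`` (one dataset per assembly x trait
    combination).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")

    if kind == "tiny-deterministic":
        tree = Phylogeny(
            parent=np.array([3, 3, 4, 4, -1]),
            blen=np.array([1.0, 1.0, 2.0, 1.0, 0.0]),
            labels=["A", "B", "C"],
        )
        traits = TraitSet({"A": 0.0, "B": 0.5, "C": 3.0}, "BM", sigma2=1.0)
        pool = RegionalPool(tree, traits, {"fixture": kind})
        manifest = {"kind": kind, "model": None, "params": {"traits": traits.values}}
        _write_dataset(outdir, "tiny", pool, ["A", "B", "C"], manifest)
        return manifest

    specs = {
        "neutral-N50": [("neutral", "BM", {})],
        "filtering-strong": [("filtering", "BM", {"tE": 1.0})],
        "competition-strong": [("competition", "BM", {"tC": 60.0})],
        "six-model-batch": [
            (m, t, {"filtering": {"tE": 5.0}, "competition": {"tC": 40.0}}.get(m, {}))
            for m in ("neutral", "filtering", "competition")
            for t in ("BM", "OU")
        ],
    }[kind]
    rng = np.random.default_rng(seed)
    manifests = []
    for model, trait_model, strength in specs:
        N, n = 50, 25
        pool = simulate_regional_pool(
            lam=1.0, mu=0.0, N=N, trait_model=trait_model, sigma2=1.0,
            alpha=0.1 if trait_model == "OU" else 0.0, seed=rng,
        )
        zE = float(rng.choice(pool.trait_array)) if model == "filtering" else None
        params = AssemblyParams(
            model=model, n=n,
            tE=strength.get("tE"), tC=strength.get("tC"), zE=zE,
        )
        local = assemble_local(pool, params, rng)
        stem = f"{model}_{trait_model}" if kind == "six-model-batch" else kind.replace("-", "_")
        manifest = {
            "kind": kind, "model": model, "trait_model": trait_model,
            "params": {"lambda": 1.0, "mu": 0.0, "sigma2": 1.0, "N": N, "n": n,
                       "zE": zE, **strength},
            "seed": seed,
        }
        _write_dataset(outdir, stem, pool, local.members, manifest)
        manifests.append(manifest)
    return manifests[0] if len(manifests) == 1 else {"kind": kind, "datasets": manifests}
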