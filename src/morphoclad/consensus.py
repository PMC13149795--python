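"""Consensus trees and branch support (bootstrap, Bremer decay).

Bipartitions are represented canonically as the frozenset of taxon labels
on the side *not* containing a reference taxon (the outgroup when given,
otherwise the lexicographically smallest label), so rooted and unrooted
comparisons agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrix import CharacterMatrix
from .search import (SearchConfig, TreeSet, _bipart_key, _random_addition_adj,
                     _search_from, enumerate_trees)
from .trees import PhyloTree, tree_from_clades


def _common_taxa(trees: list[PhyloTree]) -> list[str]:
    sets = [frozenset(t.leaf_labels()) for t in trees]
    if any(s != sets[0] for s in sets):
        raise ValueError("consensus requires a common leaf set")
    return sorted(sets[0])


def _canonical(side: frozenset, taxa: frozenset, ref) -> frozenset:
    return taxa - side if ref in side else side


def strict_consensus(trees, outgroup: Optional[str] = None) -> PhyloTree:
    """Tree containing exactly the bipartitions present in every input."""
    tree_list = list(getattr(trees, "trees", trees))
    taxa = _common_taxa(tree_list)
    common = set.intersection(*(t.bipartitions() for t in tree_list)) \
        if tree_list else set()
    return _build(taxa, common, outgroup)


def majority_consensus(trees, cutoff: float = 0.5,
                       outgroup: Optional[str] = None) -> PhyloTree:
    """Tree of bipartitions occurring in strictly more than ``cutoff`` of
    the inputs (cutoff < 0.5 refused: compatibility is not guaranteed)."""
    if cutoff < 0.5:
        raise ValueError("majority cutoff below 50% is not supported")
    tree_list = list(getattr(trees, "trees", trees))
    taxa = _common_taxa(tree_list)
    counts: dict[frozenset, int] = {}
    for t in tree_list:
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    keep = {b for b, c in counts.items() if c > cutoff * len(tree_list)}
    return _build(taxa, keep, outgroup)


def _build(taxa: list[str], biparts: set, outgroup: Optional[str]) -> PhyloTree:
    """Build a rooted tree from canonical bipartitions; clades are read as
    the side away from the outgroup (or the reference taxon)."""
    full = frozenset(taxa)
    ref = outgroup if outgroup is not None else min(taxa)
    clades = {_canonical(b, full, ref) for b in biparts}
    return tree_from_clades(
        sorted(taxa, key=lambda t: (t != ref, t)), clades)


# ---------------------------------------------------------------------------
# support table
# ---------------------------------------------------------------------------

@dataclass
class SupportTable:
    """Per-bipartition support values keyed by canonical taxon-label sets."""

    taxa: list[str]
    ref: str
    rows: dict[frozenset, dict] = field(default_factory=dict)

    def set(self, bipart: frozenset, **values) -> None:
        self.rows.setdefault(bipart, {}).update(values)

    def get(self, bipart: frozenset, key: str, default=None):
        bipart = _canonical(frozenset(bipart), frozenset(self.taxa), self.ref)
        return self.rows.get(bipart, {}).get(key, default)

    def to_frame(self):
        import pandas as pd
        recs = []
        for b, vals in sorted(self.rows.items(),
                              key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            recs.append({"bipartition": ";".join(sorted(b)), **vals})
        return pd.DataFrame(recs)

    def annotate(self, tree: PhyloTree) -> PhyloTree:
        """Copy of ``tree`` with matching internal nodes annotated."""
        out = tree.copy()
        full = frozenset(out.leaf_labels())
        below = out.leafset_below()
        for node in out.postorder():
            if node.is_leaf or node.parent is None:
                continue
            side = _canonical(below[id(node)], full, self.ref)
            if side in self.rows:
                for k, v in self.rows[side].items():
                    if v is not None:
                        node.support[k] = v
        return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(matrix: CharacterMatrix,
                      n_pseudoreplicates: int = 200,
                      seed: int = 1,
                      config: Optional[SearchConfig] = None,
                      outgroup: Optional[str] = None) -> SupportTable:
    """Character bootstrap: each pseudoreplicate resamples columns with
    replacement, runs a reduced heuristic search, and records the
    bipartitions of the strict consensus of the trees it holds; support is
    the percentage of pseudoreplicates containing each bipartition.
    """
    if config is None:
        config = SearchConfig(n_replicates=3, hold_per_replicate=5)
    leafcost = matrix.leaf_costs()
    n = matrix.n_taxa
    nc = matrix.n_characters
    ref_label = outgroup if outgroup is not None else min(matrix.taxa)
    counts: dict[frozenset, int] = {}
    full_idx = frozenset(range(n))
    ref_idx = matrix.taxon_index(ref_label)
    for p in range(n_pseudoreplicates):
        rng = np.random.default_rng([seed, p])
        cols = rng.integers(0, nc, nc)
        lc = np.ascontiguousarray(leafcost[cols])
        best: Optional[int] = None
        merged: list = []
        for rep in range(config.n_replicates):
            rep_rng = np.random.default_rng([seed, p, rep])
            adj = _random_addition_adj(matrix, rep_rng, lc)
            held, b = _search_from(adj, n, lc, config.hold_per_replicate)
            if best is None or b < best:
                best, merged = b, []
            if b == best:
                merged.extend(a for a, l in held if l == best)
        biparts = [_bipart_key(a, n) for a in merged]
        common = set.intersection(*map(set, biparts))
        for side in common:
            if ref_idx in side:
                side = full_idx - side
            labels = frozenset(matrix.taxa[i] for i in side)
            counts[labels] = counts.get(labels, 0) + 1
    table = SupportTable(taxa=list(matrix.taxa), ref=ref_label)
    for b, c in counts.items():
        table.set(b, bootstrap_pct=100.0 * c / n_pseudoreplicates)
    return table


# ---------------------------------------------------------------------------
# Bremer decay
# ---------------------------------------------------------------------------

def bremer_support(matrix: CharacterMatrix, mpts: TreeSet, max_k: int = 5,
                   outgroup: Optional[str] = None,
                   method: str = "auto",
                   config: Optional[SearchConfig] = None) -> SupportTable:
    """Decay index via a single suboptimal-retention sweep.

    For k = 1..max_k the search retains every tree within k steps of the
    minimum; a bipartition's Bremer value is the smallest k at which it
    drops out of the strict consensus of the retained set (bipartitions
    still present at max_k are reported as max_k, i.e. ">= max_k").
    Exact full enumeration is used for small matrices (``method='auto'``),
    a heuristic sweep otherwise.
    """
    n = matrix.n_taxa
    ref_label = outgroup if outgroup is not None else min(matrix.taxa)
    ref_idx = matrix.taxon_index(ref_label)
    full_idx = frozenset(range(n))

    if method == "exhaustive" or (method == "auto" and n <= 9):
        kept, best = enumerate_trees(matrix, slack=max_k)
    else:
        if config is None:
            config = SearchConfig(n_replicates=10, hold_per_replicate=200)
        leafcost = matrix.leaf_costs()
        best = None
        kept = []
        for rep in range(config.n_replicates):
            rng = np.random.default_rng([config.seed, rep])
            adj = _random_addition_adj(matrix, rng, leafcost)
            held, b = _search_from(adj, n, leafcost,
                                   config.hold_per_replicate, slack=max_k)
            if best is None or b < best:
                best = b
            kept.extend(held)
        seen = set()
        uniq = []
        for a, l in kept:
            if l > best + max_k:
                continue
            key = _bipart_key(a, n)
            if key not in seen:
                seen.add(key)
                uniq.append((a, l))
        kept = uniq

    base = set.intersection(
        *(t.bipartitions(ref=ref_label) for t in mpts.trees))
    table = SupportTable(taxa=list(matrix.taxa), ref=ref_label)

    def labelled(side: frozenset) -> frozenset:
        if ref_idx in side:
            side = full_idx - side
        return frozenset(matrix.taxa[i] for i in side)

    keysets = {}
    for adj, l in kept:
        keysets.setdefault(l, []).append(
            {labelled(s) for s in _bipart_key(adj, n)})

    L = min(keysets)
    for b in base:
        value = max_k
        for k in range(1, max_k + 1):
            sets = [s for l, group in keysets.items() if l <= L + k
                    for s in group]
            if any(b not in s for s in sets):
                value = k
                break
        table.set(b, bremer=value)
    return table
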