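"""Heuristic and exhaustive maximum-parsimony tree search.

The heuristic follows the classical "traditional search" recipe: seeded
random-addition starting trees, tree-bisection–reconnection (TBR) branch
swapping accepting equal-or-better trees up to a per-replicate hold limit,
replicate results merged, filtered to the global minimum length, collapsed
(zero-length-branch rules) and deduplicated by bipartition set.

Internally search operates on unrooted binary trees stored as adjacency
maps (leaves ``0..n-1`` index matrix taxa, internal ids ``>= n``); scoring
goes through the numba Sankoff kernels.  An exhaustive enumerator over all
unrooted topologies (<= 9 taxa) serves as the exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from ._kernels import score_total
from .matrix import CharacterMatrix
from .parsimony import DownUp as _DownUp  # noqa: F401  (collapse uses it lazily)
from .trees import Node, PhyloTree

BIG = np.int64(1) << 50

Adj = dict[int, list[int]]


@dataclass
class SearchConfig:
    """Search strategy knobs.

    The published profile is 1000 replicates holding 100 trees each with
    seed 1; the default here is a scaled-down desk profile suitable for
    matrices of a few dozen taxa.
    """

    n_replicates: int = 50
    hold_per_replicate: int = 20
    seed: int = 1
    collapse_rule: str = "max_zero"  # or "min_zero"
    max_trees_total: int = 1000

    def __post_init__(self):
        if self.n_replicates < 1 or self.hold_per_replicate < 1:
            raise ValueError("replicates and hold must be >= 1")
        if self.collapse_rule not in ("max_zero", "min_zero"):
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")


@dataclass
class TreeSet:
    """Equal-length trees (the MPT collection) plus their shared length."""

    trees: list[PhyloTree]
    length: int
    provenance: Optional[SearchConfig] = None

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# adjacency-level tree operations
# ---------------------------------------------------------------------------

def _edges(adj: Adj) -> list[tuple[int, int]]:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def _copy(adj: Adj) -> Adj:
    return {u: list(vs) for u, vs in adj.items()}


def _encode_adj(adj: Adj, n_leaves: int):
    """Postorder CSR arrays rooted at the smallest present node (root
    last; partial trees during stepwise addition may lack leaf 0)."""
    start = min(adj)
    parent = {start: -1}
    pre = [start]
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                pre.append(v)
                stack.append(v)
    order = pre[::-1]  # children before parents, root (leaf 0) last
    index = {u: i for i, u in enumerate(order)}
    m = len(order)
    leaftax = np.full(m, -1, dtype=np.int64)
    kidptr = np.zeros(m + 1, dtype=np.int64)
    kids: list[int] = []
    for i, u in enumerate(order):
        if u < n_leaves:
            leaftax[i] = u
        for v in adj[u]:
            if v != parent[u]:
                kids.append(index[v])
        kidptr[i + 1] = len(kids)
    return kidptr, np.array(kids, dtype=np.int64), leaftax


def _score_adj(adj: Adj, n_leaves: int, leafcost: np.ndarray,
               bound=BIG) -> int:
    kidptr, kids, leaftax = _encode_adj(adj, n_leaves)
    return int(score_total(kidptr, kids, leaftax, leafcost, np.int64(bound)))


def _bipart_key(adj: Adj, n_leaves: int) -> frozenset[frozenset[int]]:
    """Canonical set of non-trivial splits (side not containing leaf 0)."""
    parent = {0: -1}
    pre = [0]
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                pre.append(v)
                stack.append(v)
    below: dict[int, frozenset[int]] = {}
    out = set()
    for u in pre[::-1]:
        if u < n_leaves:
            below[u] = frozenset([u])
        else:
            acc: set[int] = set()
            for v in adj[u]:
                if v != parent[u]:
                    acc |= below[v]
            below[u] = frozenset(acc)
        if parent[u] != -1 and 2 <= len(below[u]) <= n_leaves - 2:
            out.add(below[u])
    return frozenset(out)


def _insert_leaf(adj: Adj, leaf: int, u: int, v: int, new_id: int) -> None:
    """Subdivide edge (u, v) with ``new_id`` and hang ``leaf`` off it."""
    adj[u][adj[u].index(v)] = new_id
    adj[v][adj[v].index(u)] = new_id
    adj[new_id] = [u, v, leaf]
    adj[leaf] = [new_id]


def _component(adj: Adj, start: int, banned_edge: tuple[int, int]) -> set[int]:
    a, b = banned_edge
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if (u, v) in ((a, b), (b, a)) or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def _side_adj(adj: Adj, nodes: set[int], cut: int, other: int) -> Adj:
    """Adjacency of one component after cutting edge (cut, other), with the
    degree-2 cut endpoint suppressed."""
    side = {u: [v for v in adj[u] if v in nodes] for u in nodes}
    nbrs = [v for v in side[cut] if v != other]
    if len(nbrs) == 2:  # suppress internal cut point
        x, y = nbrs
        side[x][side[x].index(cut)] = y
        side[y][side[y].index(cut)] = x
        del side[cut]
    return side


def tbr_neighbors(adj: Adj, n_leaves: int) -> Iterator[Adj]:
    """All tree-bisection–reconnection neighbours of an unrooted binary
    tree (bisect every edge; reattach every rerooting of one part to every
    edge of the other)."""
    next_id = max(adj) + 1
    for (u, v) in _edges(adj):
        a_nodes = _component(adj, u, (u, v))
        b_nodes = set(adj) - a_nodes
        A = _side_adj(adj, a_nodes, u, v)
        B = _side_adj(adj, b_nodes, v, u)
        a_single = len(A) == 1
        b_single = len(B) == 1
        if a_single and b_single:
            continue
        ea_list = [None] if a_single else _edges(A)
        eb_list = [None] if b_single else _edges(B)
        for ea in ea_list:
            for eb in eb_list:
                new: Adj = {w: list(ns) for w, ns in A.items()}
                new.update({w: list(ns) for w, ns in B.items()})
                if ea is None:
                    xa = next(iter(A))
                    new.setdefault(xa, [])
                else:
                    xa = next_id
                    p, q = ea
                    new[p][new[p].index(q)] = xa
                    new[q][new[q].index(p)] = xa
                    new[xa] = [p, q]
                if eb is None:
                    xb = next(iter(B))
                    new.setdefault(xb, [])
                else:
                    xb = next_id + 1
                    p, q = eb
                    new[p][new[p].index(q)] = xb
                    new[q][new[q].index(p)] = xb
                    new[xb] = [p, q]
                new[xa].append(xb)
                new[xb].append(xa)
                yield new


# ---------------------------------------------------------------------------
# starting trees
# ---------------------------------------------------------------------------

def _random_addition_adj(matrix: CharacterMatrix, rng: np.random.Generator,
                         leafcost: Optional[np.ndarray] = None) -> Adj:
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if leafcost is None:
        leafcost = matrix.leaf_costs()
    # canonical taxon-label order, then seeded shuffle: makes tie behaviour
    # independent of matrix row order
    canonical = sorted(range(n), key=lambda i: matrix.taxa[i])
    order = [canonical[i] for i in rng.permutation(n)]
    a, b, c = order[:3]
    hub = n  # internal ids start at n_leaves
    adj: Adj = {hub: [a, b, c], a: [hub], b: [hub], c: [hub]}
    next_id = n + 1
    for leaf in order[3:]:
        best_len = None
        ties: list[Adj] = []
        for (u, v) in _edges(adj):
            cand = _copy(adj)
            _insert_leaf(cand, leaf, u, v, next_id)
            bound = BIG if best_len is None else best_len
            s = _score_adj(cand, n, leafcost, bound)
            if best_len is None or s < best_len:
                best_len, ties = s, [cand]
            elif s == best_len:
                ties.append(cand)
        adj = ties[int(rng.integers(len(ties)))]
        next_id += 1
    return adj


def random_addition_tree(matrix: CharacterMatrix, seed: int,
                         outgroup: Optional[str] = None) -> PhyloTree:
    """Stepwise-addition starting tree: taxa added in seeded-random order,
    each at the attachment point minimising total length (ties broken by
    the seeded RNG)."""
    rng = np.random.default_rng(seed)
    adj = _random_addition_adj(matrix, rng)
    return adj_to_tree(adj, matrix, outgroup)


# ---------------------------------------------------------------------------
# TBR search
# ---------------------------------------------------------------------------

def _search_from(adj: Adj, n_leaves: int, leafcost: np.ndarray,
                 hold: int, slack: int = 0):
    """Swap ``adj`` (and everything held) with TBR until no accepted move
    remains.  Returns (held list of (adj, length), best length).  With
    ``slack > 0`` trees within ``best + slack`` are retained (Bremer
    sweeps); improvement always restarts the sweep from the new best."""
    best = _score_adj(adj, n_leaves, leafcost)
    start_key = _bipart_key(adj, n_leaves)
    held: list[tuple[Adj, int, frozenset]] = [(adj, best, start_key)]
    keys = {start_key}
    swapped: set = set()
    while True:
        todo = [e for e in held if e[2] not in swapped]
        if not todo:
            return [(a, l) for a, l, _ in held], best
        cur, _, cur_key = todo[0]
        improved = False
        for nb in tbr_neighbors(cur, n_leaves):
            s = _score_adj(nb, n_leaves, leafcost, bound=best + slack)
            if s < best:
                best = s
                held = [e for e in held if e[1] <= best + slack]
                keys = {e[2] for e in held}
                k = _bipart_key(nb, n_leaves)
                if k not in keys:
                    held.append((nb, s, k))
                    keys.add(k)
                swapped = set()
                improved = True
                break
            if s <= best + slack and len(held) < hold:
                k = _bipart_key(nb, n_leaves)
                if k not in keys:
                    held.append((nb, s, k))
                    keys.add(k)
        if not improved:
            swapped.add(cur_key)


def tbr_search(start: PhyloTree, matrix: CharacterMatrix,
               config: SearchConfig,
               outgroup: Optional[str] = None) -> TreeSet:
    """TBR-swap a single starting tree, returning held minimal trees
    (collapsed per the config rule, deduplicated)."""
    adj = tree_to_adj(start, matrix)
    held, best = _search_from(adj, matrix.n_taxa, matrix.leaf_costs(),
                              config.hold_per_replicate)
    held = [(a, l) for a, l in held if l == best]
    return _finalize(held, best, matrix, config, outgroup)


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig,
                     outgroup: Optional[str] = None,
                     progress=None) -> TreeSet:
    """Replicated random-addition + TBR search ("traditional search").

    Replicate results are merged, filtered to the global minimum length,
    collapsed under the configured zero-length rule and deduplicated by
    bipartition set — in that order.
    """
    leafcost = matrix.leaf_costs()
    n = matrix.n_taxa
    best_overall: Optional[int] = None
    merged: list[tuple[Adj, int]] = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        adj = _random_addition_adj(matrix, rng, leafcost)
        held, best = _search_from(adj, n, leafcost,
                                  config.hold_per_replicate)
        if best_overall is None or best < best_overall:
            best_overall = best
            merged = []
        if best == best_overall:
            merged.extend((a, l) for a, l in held if l == best)
        if progress is not None:
            progress(rep, best, len(merged))
    return _finalize(merged, best_overall, matrix, config, outgroup)


def _finalize(held, length, matrix, config, outgroup) -> TreeSet:
    seen: set = set()
    out: list[PhyloTree] = []
    for adj, _ in held:
        tree = adj_to_tree(adj, matrix, outgroup)
        tree = collapse_branches(tree, matrix, config.collapse_rule)
        key = frozenset(tree.bipartitions())
        if key not in seen:
            seen.add(key)
            out.append(tree)
        if len(out) >= config.max_trees_total:
            break
    return TreeSet(trees=out, length=int(length), provenance=config)


# ---------------------------------------------------------------------------
# collapse rules
# ---------------------------------------------------------------------------

def collapse_branches(tree: PhyloTree, matrix: CharacterMatrix,
                      rule: str = "max_zero") -> PhyloTree:
    """Collapse zero-length internal branches.

    ``max_zero`` (default): collapse a branch only when its *maximum*
    length over all most-parsimonious reconstructions is zero (no
    character can change there under any optimal reconstruction).
    ``min_zero``: collapse when the *minimum* is zero (some optimal
    reconstruction puts no change there).
    """
    if rule not in ("max_zero", "min_zero"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    from .parsimony import DownUp
    tree = tree.copy()
    du = DownUp(tree, matrix)
    mins: dict[int, int] = {}
    values: dict[int, int] = {}
    for v in du.order:
        if v.parent is None:
            continue
        forced, possible = du.branch_change_bounds(v)
        mins[id(v)] = int(forced.sum())
        values[id(v)] = int((forced if rule == "min_zero" else possible).sum())
    root = tree.root
    # with a degree-2 root the two root edges form one unrooted edge; the
    # per-edge DP values each see the root as a real node, so evaluate the
    # merged edge directly
    merge_root = (len(root.children) == 2
                  and not any(c.is_leaf for c in root.children))
    if merge_root:
        rf, rp = du.root_edge_bounds()
        rvalue = int((rf if rule == "min_zero" else rp).sum())
        for c in root.children:
            mins[id(c)] = int(rf.sum())
    for node in list(tree.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        node.length = float(mins[id(node)])
        parent = node.parent
        if parent is root and len(root.children) == 2:
            if merge_root and rvalue == 0:
                parent.remove_child(node)
                for c in list(node.children):
                    parent.add_child(c)
            continue  # otherwise: pendant rooting edge, not internal
        if values[id(node)] == 0:
            parent.remove_child(node)
            for c in list(node.children):
                parent.add_child(c)
    return tree


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle for small instances)
# ---------------------------------------------------------------------------

def enumerate_trees(matrix: CharacterMatrix, slack: int = 0,
                    max_taxa: int = 9):
    """All unrooted topologies within ``slack`` of the global minimum.

    Branch-and-bound stepwise enumeration (adding a leaf never decreases
    length).  Returns (list of (adj, length), min_length).  Refuses more
    than ``max_taxa`` taxa (9 taxa = 135,135 topologies).
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(f"exhaustive enumeration refused for {n} taxa "
                         f"(> {max_taxa})")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    leafcost = matrix.leaf_costs()
    out: list[tuple[Adj, int]] = []
    state = {"best": None}

    base: Adj = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}

    def recurse(adj: Adj, next_leaf: int, next_id: int):
        if next_leaf == n:
            s = _score_adj(adj, n, leafcost)
            if state["best"] is None or s < state["best"]:
                state["best"] = s
            if s <= state["best"] + slack:
                out.append((_copy(adj), s))
            return
        for (u, v) in _edges(adj):
            cand = _copy(adj)
            _insert_leaf(cand, next_leaf, u, v, next_id)
            if state["best"] is not None:
                partial = _score_adj(cand, n, leafcost,
                                     bound=state["best"] + slack)
                if partial > state["best"] + slack:
                    continue
            recurse(cand, next_leaf + 1, next_id + 1)

    recurse(base, 3, n + 1)
    best = state["best"]
    kept = [(a, l) for a, l in out if l <= best + slack]
    return kept, best


def exhaustive_search(matrix: CharacterMatrix,
                      outgroup: Optional[str] = None,
                      collapse_rule: str = "max_zero",
                      max_taxa: int = 9) -> TreeSet:
    """All globally minimal trees by full enumeration (collapsed and
    deduplicated exactly like the heuristic's output)."""
    kept, best = enumerate_trees(matrix, slack=0, max_taxa=max_taxa)
    cfg = SearchConfig(collapse_rule=collapse_rule)
    return _finalize(kept, best, matrix, cfg, outgroup)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def tree_to_adj(tree: PhyloTree, matrix: CharacterMatrix) -> Adj:
    """Unrooted adjacency of a (binary) rooted tree; degree-2 root
    suppressed."""
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    n = matrix.n_taxa
    adj: Adj = {}
    counter = [n]
    node_id: dict[int, int] = {}

    for node in tree.postorder():
        if node.is_leaf:
            node_id[id(node)] = idx[node.label]
        else:
            node_id[id(node)] = counter[0]
            counter[0] += 1
        adj.setdefault(node_id[id(node)], [])
    for node in tree.postorder():
        for c in node.children:
            u, v = node_id[id(node)], node_id[id(c)]
            adj[u].append(v)
            adj[v].append(u)
    root_id = node_id[id(tree.root)]
    if len(adj[root_id]) == 2:  # suppress rooted degree-2 root
        x, y = adj[root_id]
        adj[x][adj[x].index(root_id)] = y
        adj[y][adj[y].index(root_id)] = x
        del adj[root_id]
    return adj


def adj_to_tree(adj: Adj, matrix: CharacterMatrix,
                outgroup: Optional[str] = None) -> PhyloTree:
    """Root an unrooted adjacency on the outgroup's pendant edge (default
    outgroup: first matrix taxon)."""
    og = matrix.taxon_index(outgroup) if outgroup else 0
    root = Node()
    og_node = Node(label=matrix.taxa[og])
    root.add_child(og_node)

    def build(u: int, parent_adj: int) -> Node:
        if u < matrix.n_taxa:
            return Node(label=matrix.taxa[u])
        node = Node()
        for v in adj[u]:
            if v != parent_adj:
                node.add_child(build(v, u))
        return node

    start = adj[og][0]
    root.add_child(build(start, og))
    return PhyloTree(root)
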