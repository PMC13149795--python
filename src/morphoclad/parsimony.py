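"""Parsimony scoring of trees against a character matrix.

Characters are unordered and multistate; unknown/inapplicable cells allow
every state, polymorphic cells any of their observed states.  Scoring is a
unit-cost Sankoff dynamic programme (exact for hard polytomies), which for
binary trees coincides with Fitch counting.  Besides tree lengths the
module provides the per-character quantities behind the classical fit
indices:

* ``m`` — minimum conceivable steps over all trees (smallest number of
  states that can cover every cell, minus one);
* ``s`` — observed steps on a given tree;
* ``g`` — steps on the completely unresolved star tree;
* CI = m/s, RI = (g-s)/(g-m).

Per-branch minimum/maximum change counts over all most-parsimonious
reconstructions (needed for zero-length-branch collapsing and for
character mapping) come from a down-pass/up-pass pair of cost arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from ._kernels import INF, score_per_char, score_total
from .matrix import CharacterMatrix, CellValue
from .trees import Node, PhyloTree

BIG_BOUND = np.int64(1) << 50


# ---------------------------------------------------------------------------
# tree encoding
# ---------------------------------------------------------------------------

def encode_tree(tree: PhyloTree, matrix: CharacterMatrix):
    """Flatten a tree into postorder CSR arrays for the scoring kernels."""
    order = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(order)}
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    leaftax = np.full(len(order), -1, dtype=np.int64)
    kidptr = np.zeros(len(order) + 1, dtype=np.int64)
    kids_list: list[int] = []
    for i, n in enumerate(order):
        if n.is_leaf:
            if n.label not in taxon_row:
                raise ValueError(f"leaf {n.label!r} has no matrix row")
            leaftax[i] = taxon_row[n.label]
        for c in n.children:
            kids_list.append(index[id(c)])
        kidptr[i + 1] = len(kids_list)
    return kidptr, np.array(kids_list, dtype=np.int64), leaftax, order


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def fitch_length(tree: PhyloTree, matrix: CharacterMatrix,
                 per_character: bool = False):
    """Parsimony length of ``tree``; optionally also per-character steps."""
    kidptr, kids, leaftax, _ = encode_tree(tree, matrix)
    if per_character:
        out = np.zeros(matrix.n_characters, dtype=np.int64)
        score_per_char(kidptr, kids, leaftax, matrix.leaf_costs(), out)
        return int(out.sum()), out
    total = score_total(kidptr, kids, leaftax, matrix.leaf_costs(), BIG_BOUND)
    return int(total)


def brute_force_length(tree: PhyloTree, matrix: CharacterMatrix,
                       char_index: int) -> int:
    """Independent oracle: enumerate every ancestral state assignment.

    Exponential in the number of internal nodes; intended for tiny trees in
    tests only.
    """
    k = matrix.characters[char_index].n_states
    order = list(tree.postorder())
    internal = [n for n in order if not n.is_leaf]
    leaves = [n for n in order if n.is_leaf]
    allowed = {
        id(n): sorted(matrix.cells[matrix.taxon_index(n.label)][char_index]
                      .allowed(k))
        for n in leaves
    }
    best = None
    import itertools
    leaf_choices = [allowed[id(n)] for n in leaves]
    anc_choices = [range(k)] * len(internal)
    for leaf_assign in itertools.product(*leaf_choices):
        state = {id(n): s for n, s in zip(leaves, leaf_assign)}
        for anc_assign in itertools.product(*anc_choices):
            state.update(
                {id(n): s for n, s in zip(internal, anc_assign)})
            changes = 0
            for n in order:
                if n.parent is not None and state[id(n)] != state[id(n.parent)]:
                    changes += 1
            if best is None or changes < best:
                best = changes
    return best


# ---------------------------------------------------------------------------
# per-character bounds m and g
# ---------------------------------------------------------------------------

def _allowed_sets(column: Sequence[CellValue], k: int) -> list[frozenset[int]]:
    return [c.allowed(k) for c in column]


def min_steps(column: Sequence[CellValue], k: int) -> int:
    """Minimum steps over all trees: smallest state set hitting every
    cell's allowed set, minus one (0 when all cells can share one state)."""
    sets = [s for s in _allowed_sets(column, k) if len(s) < k]
    if not sets:
        return 0
    states = sorted(set().union(*sets))
    for size in range(1, len(states) + 1):
        for combo in combinations(states, size):
            cs = set(combo)
            if all(cs & s for s in sets):
                return size - 1
    return len(states) - 1  # pragma: no cover - loop always returns


def star_steps(column: Sequence[CellValue], k: int) -> int:
    """Steps on the star tree: non-full cells minus the best central state's
    coverage of them."""
    sets = [s for s in _allowed_sets(column, k) if len(s) < k]
    if not sets:
        return 0
    best_cover = max(sum(1 for s in sets if c in s) for c in range(k))
    return len(sets) - best_cover


def is_informative(column: Sequence[CellValue], k: int) -> bool:
    """A character is parsimony-informative iff its steps can differ
    between trees (g > m)."""
    return star_steps(column, k) > min_steps(column, k)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class CharacterFit:
    id: int
    m: int
    s: int
    g: int
    informative: bool

    @property
    def ci(self) -> float:
        return 1.0 if self.s == 0 else self.m / self.s

    @property
    def ri(self) -> float:
        return 1.0 if self.g == self.m else (self.g - self.s) / (self.g - self.m)


@dataclass
class EnsembleFit:
    per_character: list[CharacterFit]
    length: int
    ci: float
    ri: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"character": f.id, "m": f.m, "s": f.s, "g": f.g,
              "ci": round(f.ci, 4), "ri": round(f.ri, 4),
              "informative": f.informative}
             for f in self.per_character]).set_index("character")


def character_fits(tree: PhyloTree, matrix: CharacterMatrix) -> list[CharacterFit]:
    _, steps = fitch_length(tree, matrix, per_character=True)
    fits = []
    for j, cdef in enumerate(matrix.characters):
        col = matrix.column(j)
        m = min_steps(col, cdef.n_states)
        g = star_steps(col, cdef.n_states)
        s = int(steps[j])
        assert m <= s <= g, f"character {cdef.id}: m <= s <= g violated"
        fits.append(CharacterFit(cdef.id, m, s, g, informative=g > m))
    return fits


def ensemble_fit(trees, matrix: CharacterMatrix,
                 include_uninformative: bool = True) -> EnsembleFit:
    """Ensemble CI and RI on one tree or a set of equal-length trees.

    CI = Σm/Σs and RI = (Σg−Σs)/(Σg−Σm) over characters; uninformative
    characters can be excluded from the sums via the flag.
    """
    tree_list = list(getattr(trees, "trees", None) or
                     ([trees] if isinstance(trees, PhyloTree) else trees))
    fits = character_fits(tree_list[0], matrix)
    for t in tree_list[1:]:
        if fitch_length(t, matrix) != sum(f.s for f in fits):
            raise ValueError("trees in an ensemble must share one length")
    used = fits if include_uninformative else [f for f in fits if f.informative]
    sm = sum(f.m for f in used)
    ss = sum(f.s for f in used)
    sg = sum(f.g for f in used)
    ci = 1.0 if ss == 0 else sm / ss
    ri = 1.0 if sg == sm else (sg - ss) / (sg - sm)
    return EnsembleFit(fits, length=sum(f.s for f in fits), ci=ci, ri=ri)


# ---------------------------------------------------------------------------
# down-pass / up-pass cost arrays and per-branch change bounds
# ---------------------------------------------------------------------------

class DownUp:
    """Down-pass (subtree) and up-pass (rest-of-tree) Sankoff cost arrays
    for every node and character, plus matching optimal-assignment counts.

    ``D[v][c, a]``: min steps inside subtree(v) given state ``a`` at v.
    ``U[v][c, a]``: min steps outside subtree(v) given state ``a`` at v's
    parent (0 at the root).  For a branch (parent u, child v) the minimum
    total length with u=a, v=b is ``U[v][c,a] + D[v][c,b] + [a != b]``.
    """

    def __init__(self, tree: PhyloTree, matrix: CharacterMatrix):
        self.tree = tree
        self.matrix = matrix
        self.order = list(tree.postorder())
        kmax = matrix.max_states
        nc = matrix.n_characters
        ks = matrix.n_states()
        self.state_mask = np.zeros((nc, kmax), dtype=bool)  # valid states
        for c in range(nc):
            self.state_mask[c, :ks[c]] = True
        leafcost = matrix.leaf_costs()
        row_of = {t: i for i, t in enumerate(matrix.taxa)}

        D: dict[int, np.ndarray] = {}
        C: dict[int, np.ndarray] = {}      # optimal-assignment counts for D
        M: dict[int, np.ndarray] = {}      # child message min(D_w, min_w + 1)
        NC: dict[int, np.ndarray] = {}     # count matching M
        invalid = ~self.state_mask
        for v in self.order:
            if v.is_leaf:
                d = leafcost[:, row_of[v.label], :].copy()
                cnt = (d == 0).astype(float)
            else:
                d = np.zeros((nc, kmax), dtype=np.int64)
                cnt = np.ones((nc, kmax))
                for w in v.children:
                    d += M[id(w)]
                    cnt *= NC[id(w)]
            d[invalid] = INF
            cnt[invalid] = 0.0
            D[id(v)] = d
            C[id(v)] = cnt
            if v.parent is not None:
                mn = d.min(axis=1, keepdims=True)
                msg = np.minimum(d, mn + 1)
                # count of optimal sub-assignments for each parent state a:
                # sum of C over states b with D[b] + [a != b] == msg[a]
                argmin_cnt = (cnt * (d == mn)).sum(axis=1, keepdims=True)
                nc_msg = np.where(
                    d == msg, cnt, 0.0)            # b == a term
                nc_msg = nc_msg + np.where(
                    mn + 1 == msg, argmin_cnt - cnt * (d == mn), 0.0)
                M[id(v)] = msg
                NC[id(v)] = nc_msg
        self.D, self.C, self.M, self.NC = D, C, M, NC

        U: dict[int, np.ndarray] = {}
        CU: dict[int, np.ndarray] = {}
        for v in reversed(self.order):  # preorder
            if v.parent is None:
                continue
            u = v.parent
            base = np.zeros((nc, kmax), dtype=np.int64)
            bcnt = np.ones((nc, kmax))
            for w in u.children:
                if w is v:
                    continue
                base += M[id(w)]
                bcnt *= NC[id(w)]
            if u.parent is not None:
                uu, cuu = U[id(u)], CU[id(u)]
                mn = uu.min(axis=1, keepdims=True)
                msg = np.minimum(uu, mn + 1)
                argmin_cnt = (cuu * (uu == mn)).sum(axis=1, keepdims=True)
                nmsg = np.where(uu == msg, cuu, 0.0) + np.where(
                    mn + 1 == msg, argmin_cnt - cuu * (uu == mn), 0.0)
                base = base + msg
                bcnt = bcnt * nmsg
            base[invalid] = INF
            bcnt[invalid] = 0.0
            U[id(v)] = base
            CU[id(v)] = bcnt
        self.U, self.CU = U, CU

        root_d = D[id(tree.root)]
        self.lengths = root_d.min(axis=1)  # per-character tree length
        rmin = self.lengths[:, None]
        self.total_count = (C[id(tree.root)] * (root_d == rmin)).sum(axis=1)

    def branch_change_bounds(self, v: Node):
        """(forced, possible) change indicators per character for the branch
        above ``v``: forced=1 when every MPR changes there, possible=1 when
        some MPR does."""
        if v.parent is None:
            raise ValueError("root has no branch")
        D, U = self.D[id(v)], self.U[id(v)]
        L = self.lengths
        same = (U + D).min(axis=1)                   # best total with a == b
        diff = U.min(axis=1) + D.min(axis=1) + 1     # best total with any a, b
        forced = (same > L).astype(np.int64)
        possible = (diff <= L).astype(np.int64)
        # a != b attaining diff == L must actually differ in argmins; when the
        # single shared argmin state gives same == diff - 1 == L - 1 that is
        # impossible, so verify properly:
        amb = (diff == L) & (forced == 0)
        if amb.any():
            for c in np.nonzero(amb)[0]:
                ok = False
                for a in np.nonzero(U[c] + 1 + D[c].min() == L[c])[0]:
                    if any(b != a and U[c, a] + D[c, b] + 1 == L[c]
                           for b in range(D.shape[1])):
                        ok = True
                        break
                possible[c] = 1 if ok else 0
        return forced, possible

    def root_edge_bounds(self):
        """(forced, possible) change indicators for the unrooted edge
        joining the two children of a degree-2 root (the root itself is a
        rooting artefact sitting on that edge)."""
        root = self.tree.root
        if len(root.children) != 2:
            raise ValueError("root edge bounds need a degree-2 root")
        c1, c2 = root.children
        D1, D2 = self.D[id(c1)], self.D[id(c2)]
        L = self.lengths
        same = (D1 + D2).min(axis=1)
        forced = (same > L).astype(np.int64)
        diff = D1.min(axis=1) + D2.min(axis=1) + 1
        possible = (diff <= L).astype(np.int64)
        amb = (diff == L) & (forced == 0)
        for c in np.nonzero(amb)[0]:
            ok = any(a != b and D1[c, a] + D2[c, b] + 1 == L[c]
                     for a in np.nonzero(D1[c] == D1[c].min())[0]
                     for b in np.nonzero(D2[c] == D2[c].min())[0])
            possible[c] = 1 if ok else 0
        return forced, possible

    def branch_expected_changes(self, v: Node) -> np.ndarray:
        """Mean change count per character on the branch above ``v`` over
        all most-parsimonious reconstructions."""
        D, U = self.D[id(v)], self.U[id(v)]
        C, CU = self.C[id(v)], self.CU[id(v)]
        L = self.lengths[:, None, None]
        tot = U[:, :, None] + D[:, None, :] + 1
        kmax = D.shape[1]
        eye = np.eye(kmax, dtype=bool)[None, :, :]
        opt_diff = (tot == L) & ~eye
        weight = (CU[:, :, None] * C[:, None, :] * opt_diff).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = weight / self.total_count
        return np.where(self.total_count > 0, out, 0.0)


def branch_lengths_minmax(tree: PhyloTree, matrix: CharacterMatrix):
    """Per-branch (min, max) total change counts over all MPRs, as dicts
    keyed by ``id(child node)`` summed across characters."""
    du = DownUp(tree, matrix)
    mins: dict[int, int] = {}
    maxs: dict[int, int] = {}
    for v in du.order:
        if v.parent is None:
            continue
        forced, possible = du.branch_change_bounds(v)
        mins[id(v)] = int(forced.sum())
        maxs[id(v)] = int(possible.sum())
    return mins, maxs
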