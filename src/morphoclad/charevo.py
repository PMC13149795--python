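"""Character optimisation on a fixed tree and grade-segment change rates.

Characters are mapped onto a (possibly polytomous) tree under one of three
resolution policies:

* ``acctran`` — changes placed as close to the root as an optimal
  reconstruction allows (reversals preferred over parallelisms);
* ``deltran`` — changes delayed toward the tips;
* ``mpr_average`` — each branch receives the mean change count over *all*
  most-parsimonious reconstructions (fractional values).

The segment-rate statistic compares evolutionary lability between taxon
groups that may be paraphyletic grades: a branch belongs to a group only
when every group-assigned leaf below it is in that group, so spine
branches spanning groups are excluded from every group and nothing is
double-counted.  The rate for character c in group g is

    r(c, g) = transitions(c, on g's branches) / n_scorable(c, g),

the number of state transitions per character per scorable taxon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import CATEGORIES, CharacterMatrix, GroupDefinition
from .parsimony import DownUp
from .trees import Node, PhyloTree

POLICIES = ("acctran", "deltran", "mpr_average")


@dataclass
class Reconstruction:
    """One character mapped on one tree under one resolution policy."""

    char_id: int
    policy: str
    tree: PhyloTree
    branch_changes: dict[int, float]      # id(child node) -> changes
    node_states: dict[int, frozenset]     # id(node) -> optimal state set
    total: float


def _policy_states(du: DownUp, j: int, policy: str) -> dict[int, int]:
    """Preorder single-state assignment for acctran/deltran."""
    D = du.D
    state: dict[int, int] = {}
    for v in reversed(du.order):  # root first
        d = D[id(v)][j]
        if v.parent is None:
            state[id(v)] = int(np.argmin(d))
            continue
        a = state[id(v.parent)]
        cost = d + (np.arange(d.shape[0]) != a)
        best = cost.min()
        options = np.nonzero(cost == best)[0]
        if policy == "deltran":
            chosen = a if a in options else int(options[0])
        else:  # acctran: prefer a change on this branch when optimal
            changing = options[options != a]
            chosen = int(changing[0]) if changing.size else int(options[0])
        state[id(v)] = chosen
    return state


def optimize_character(tree: PhyloTree, matrix: CharacterMatrix,
                       char_id: int, policy: str = "acctran",
                       du: Optional[DownUp] = None) -> Reconstruction:
    """Map one character (1-based id) on ``tree`` under ``policy``."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    j = char_id - 1
    if du is None:
        du = DownUp(tree, matrix)
    L = int(du.lengths[j])

    node_states: dict[int, frozenset] = {}
    for v in du.order:
        d, u = du.D[id(v)][j], (du.U[id(v)][j] if v.parent is not None else None)
        if u is None:
            tot = d
        else:
            umin = np.minimum(u, u.min() + 1)
            tot = d + umin
        node_states[id(v)] = frozenset(np.nonzero(tot == L)[0].tolist())

    branch: dict[int, float] = {}
    if policy == "mpr_average":
        for v in du.order:
            if v.parent is not None:
                branch[id(v)] = float(du.branch_expected_changes(v)[j])
        total = float(sum(branch.values()))
    else:
        state = _policy_states(du, j, policy)
        for v in du.order:
            if v.parent is not None:
                branch[id(v)] = float(state[id(v)] != state[id(v.parent)])
        total = float(sum(branch.values()))
        assert total == L, "policy reconstruction must attain Fitch length"
    return Reconstruction(char_id=char_id, policy=policy, tree=tree,
                          branch_changes=branch, node_states=node_states,
                          total=total)


def optimize_all(tree: PhyloTree, matrix: CharacterMatrix,
                 policy: str = "acctran"):
    """All characters on one tree: (reconstructions, per-character table)."""
    du = DownUp(tree, matrix)
    recs = [optimize_character(tree, matrix, c.id, policy, du=du)
            for c in matrix.characters]
    table = pd.DataFrame(
        [{"character": r.char_id, "transitions": r.total} for r in recs]
    ).set_index("character")
    return recs, table


# ---------------------------------------------------------------------------
# grade segments
# ---------------------------------------------------------------------------

def assign_branches(tree: PhyloTree, groups: Sequence[GroupDefinition]
                    ) -> dict[int, Optional[str]]:
    """Assign each branch (keyed by id of its child node) to a group.

    A branch belongs to group g iff at least one group-assigned leaf
    descends from it and every group-assigned descendant leaf is in g;
    spine branches spanning several groups map to ``None``.
    """
    group_of: dict[str, str] = {}
    for g in groups:
        for t in g.members:
            if t in group_of:
                raise ValueError(f"taxon {t!r} belongs to several groups")
            group_of[t] = g.name
    below = tree.leafset_below()
    out: dict[int, Optional[str]] = {}
    for v in tree.postorder():
        if v.parent is None:
            continue
        seen = {group_of[t] for t in below[id(v)] if t in group_of}
        out[id(v)] = seen.pop() if len(seen) == 1 else None
    return out


@dataclass
class RateTable:
    """Transitions per character per scorable taxon, by group and category."""

    groups: list[str]
    transitions: pd.DataFrame     # characters x groups, t(c,g)
    scorable: pd.DataFrame        # characters x groups, n(c,g)
    rates: pd.DataFrame           # characters x groups, r = t/n (NaN if n=0)
    category_of: dict[int, str]

    @property
    def category_stats(self) -> pd.DataFrame:
        recs = []
        for cat in CATEGORIES:
            chars = [c for c, k in self.category_of.items() if k == cat]
            if not chars:
                continue
            sub = self.rates.loc[chars]
            for g in self.groups:
                vals = sub[g].dropna()
                recs.append({
                    "category": cat, "group": g,
                    "n_characters": len(chars),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                })
        return pd.DataFrame(recs).set_index(["category", "group"])

    @property
    def overall_means(self) -> pd.Series:
        return self.rates.mean(axis=0, skipna=True)

    def formatted(self) -> pd.DataFrame:
        """Category x group table of "mean (SD)" strings."""
        stats = self.category_stats.reset_index()
        out = {}
        for g in self.groups:
            col = {}
            for _, row in stats[stats.group == g].iterrows():
                col[row.category] = f"{row['mean']:.3f} ({row.sd:.3f})"
            out[g] = col
        return pd.DataFrame(out)


def segment_rates(trees, matrix: CharacterMatrix,
                  groups: Sequence[GroupDefinition],
                  categories: Optional[dict[int, str]] = None,
                  policy: str = "acctran") -> RateTable:
    """Per-group, per-character state-transition rates.

    ``trees`` may be a single tree (typically the strict consensus, with
    hard polytomies) or a tree collection, in which case transition counts
    are averaged across trees.  ``categories`` maps 1-based character ids
    to the five category names (defaults to each character's own
    ``category`` field).
    """
    tree_list = list(getattr(trees, "trees", None) or
                     ([trees] if isinstance(trees, PhyloTree) else trees))
    if not groups:
        raise ValueError("at least one group is required")
    for g in groups:
        if not g.members:
            raise ValueError(f"group {g.name!r} is empty")
        unknown = g.members - set(matrix.taxa)
        if unknown:
            raise ValueError(f"group {g.name!r} lists non-matrix taxa "
                             f"{sorted(unknown)}")
    if categories is None:
        categories = {c.id: c.category for c in matrix.characters
                      if c.category is not None}

    names = [g.name for g in groups]
    char_ids = [c.id for c in matrix.characters]
    t_acc = np.zeros((len(char_ids), len(names)))

    for tree in tree_list:
        du = DownUp(tree, matrix)
        branch_group = assign_branches(tree, groups)
        for ci, cdef in enumerate(matrix.characters):
            rec = optimize_character(tree, matrix, cdef.id, policy, du=du)
            per_group = dict.fromkeys(names, 0.0)
            for node_key, changes in rec.branch_changes.items():
                g = branch_group.get(node_key)
                if g is not None:
                    per_group[g] += changes
            assert sum(per_group.values()) <= rec.total + 1e-9, \
                "grouped changes cannot exceed the character's transitions"
            for gi, g in enumerate(names):
                t_acc[ci, gi] += per_group[g]
    t_acc /= len(tree_list)

    n = np.zeros((len(char_ids), len(names)), dtype=np.int64)
    for gi, g in enumerate(groups):
        rows = [matrix.taxon_index(t) for t in g.members]
        for ci in range(len(char_ids)):
            n[ci, gi] = sum(
                1 for r in rows
                if matrix.cells[r][ci].kind in ("determinate", "polymorphic"))

    transitions = pd.DataFrame(t_acc, index=char_ids, columns=names)
    scorable = pd.DataFrame(n, index=char_ids, columns=names)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, t_acc / np.maximum(n, 1), np.nan)
    rates = pd.DataFrame(r, index=char_ids, columns=names)
    return RateTable(groups=names, transitions=transitions,
                     scorable=scorable, rates=rates,
                     category_of=dict(categories))
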