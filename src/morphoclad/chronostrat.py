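"""Stratigraphic time-scaling of trees and fossil-record gap finding.

Node ages use the "basic" a-priori rule: each internal node is as old as
the oldest first-appearance datum (FAD) among its descendants.  Internal
branches of zero duration are then stretched root-ward by a small epsilon
purely so the plot is readable.  Record gaps are the exact interval
complement of the union of taxon ranges within the study window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .matrix import StratRange
from .trees import PhyloTree

# ICS chronostratigraphic stage boundaries (Ma), Devonian through Permian.
ICS_STAGES: dict[str, tuple[float, float]] = {
    "Lochkovian": (419.2, 410.8),
    "Pragian": (410.8, 407.6),
    "Emsian": (407.6, 393.3),
    "Eifelian": (393.3, 387.7),
    "Givetian": (387.7, 382.7),
    "Frasnian": (382.7, 372.2),
    "Famennian": (372.2, 358.9),
    "Tournaisian": (358.9, 346.7),
    "Visean": (346.7, 330.9),
    "Serpukhovian": (330.9, 323.2),
    "Bashkirian": (323.2, 315.2),
    "Moscovian": (315.2, 307.0),
    "Kasimovian": (307.0, 303.7),
    "Gzhelian": (303.7, 298.9),
    "Asselian": (298.9, 293.52),
    "Sakmarian": (293.52, 290.1),
    "Artinskian": (290.1, 283.5),
    "Kungurian": (283.5, 273.01),
    "Roadian": (273.01, 266.9),
    "Wordian": (266.9, 264.28),
    "Capitanian": (264.28, 259.51),
    "Wuchiapingian": (259.51, 254.14),
    "Changhsingian": (254.14, 251.902),
}


def stage_range(first_stage: str, last_stage: Optional[str] = None
                ) -> tuple[float, float]:
    """(fad, lad) in Ma for a taxon ranging from one stage to another."""
    fad = ICS_STAGES[first_stage][0]
    lad = ICS_STAGES[last_stage or first_stage][1]
    return fad, lad


@dataclass
class TimescaledTree:
    tree: PhyloTree                    # node.age set on every node (Ma)
    ranges: dict[str, StratRange]
    epsilon_ma: float

    def root_age(self) -> float:
        return self.tree.root.age


def timescale(tree: PhyloTree, ranges: Sequence[StratRange],
              epsilon_ma: float = 0.5) -> TimescaledTree:
    """Date a tree from taxon first appearances.

    Terminal nodes sit at their taxon's FAD; every internal node at the
    oldest descendant FAD, with zero-duration internal branches stretched
    root-ward by ``epsilon_ma``.  Branch lengths are set to the resulting
    durations (>= 0).
    """
    by_taxon = {r.taxon: r for r in ranges}
    out = tree.copy()
    missing = [l.label for l in out.leaves() if l.label not in by_taxon]
    if missing:
        raise ValueError(f"no stratigraphic range for taxa: {missing}")
    for node in out.postorder():
        if node.is_leaf:
            node.age = by_taxon[node.label].fad
        else:
            node.age = max(c.age for c in node.children)
            if epsilon_ma > 0:
                stretch = max((c.age + epsilon_ma for c in node.children
                               if not c.is_leaf), default=0.0)
                node.age = max(node.age, stretch)
    for node in out.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
            assert node.length >= 0, "child older than parent"
    return TimescaledTree(tree=out, ranges=by_taxon, epsilon_ma=epsilon_ma)


def record_gaps(ranges: Sequence[StratRange],
                resolution_myr: float = 0.0,
                window: Optional[tuple[float, float]] = None
                ) -> list[tuple[float, float]]:
    """Intervals within the study window not covered by any taxon range.

    Returned oldest-first as (older bound, younger bound) in Ma; gaps
    shorter than ``resolution_myr`` are suppressed.  The window defaults
    to (oldest FAD, youngest LAD) of the supplied ranges.
    """
    if not ranges:
        raise ValueError("no stratigraphic ranges supplied")
    ivs = sorted(((r.fad, r.lad) for r in ranges), key=lambda t: -t[0])
    if window is None:
        window = (max(r.fad for r in ranges), min(r.lad for r in ranges))
    old, young = window
    gaps: list[tuple[float, float]] = []
    cursor = old  # sweep from oldest to youngest
    for fad, lad in ivs:
        if fad < cursor:
            gaps.append((cursor, fad))
            cursor = lad
        else:
            cursor = min(cursor, lad)
        if cursor <= young:
            break
    if cursor > young:
        gaps.append((cursor, young))
    return [(a, b) for a, b in gaps if (a - b) > resolution_myr and a > b]


def plot_timescaled(ts: TimescaledTree, path,
                    gaps: Optional[list[tuple[float, float]]] = None) -> None:
    """Draw the time-scaled tree with taxon range bars (requires
    matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tree = ts.tree
    ys: dict[int, float] = {}
    for i, leaf in enumerate(tree.leaves()):
        ys[id(leaf)] = float(i)
    for node in tree.postorder():
        if not node.is_leaf:
            ys[id(node)] = sum(ys[id(c)] for c in node.children) / len(node.children)
    fig, ax = plt.subplots(figsize=(8, 0.25 * tree.n_leaves + 1))
    if gaps:
        for a, b in gaps:
            ax.axvspan(a, b, color="mistyrose", zorder=0)
    for node in tree.postorder():
        if node.parent is not None:
            ax.plot([node.parent.age, node.age],
                    [ys[id(node)], ys[id(node)]], color="k", lw=1)
            ax.plot([node.parent.age] * 2,
                    [ys[id(node.parent)], ys[id(node)]], color="k", lw=1)
        if node.is_leaf:
            r = ts.ranges[node.label]
            ax.plot([r.fad, r.lad], [ys[id(node)]] * 2, lw=3, color="tab:blue")
            ax.text(r.lad, ys[id(node)], " " + node.label, va="center",
                    fontsize=6)
    ax.set_xlabel("Age (Ma)")
    ax.set_yticks([])
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
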