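"""Rooted phylogenetic trees over taxon labels.

Lightweight node/tree containers used throughout the package: leaves carry
taxon labels, internal nodes may be polytomies, branches may carry integer
step counts (parsimony) or float durations (time-scaling), and internal
nodes may carry support annotations.  Newick serialization keeps branch
lengths (``:x``) and support annotations (trailing ``[key=val,...]``
comments on internal nodes).
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Optional


class Node:
    __slots__ = ("label", "children", "parent", "length", "age", "support")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.age: Optional[float] = None
        self.support: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or 'internal'} k={len(self.children)}>"


class PhyloTree:
    """A rooted tree; polytomies are permitted, leaf labels must be unique."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.age = node.age
            new.support = dict(node.support)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return PhyloTree(_copy(self.root))

    # -- topology ----------------------------------------------------------

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.postorder()
            if not n.is_leaf and n is not self.root
        ) and len(self.root.children) in (2, 3)

    def ladderize(self, ascending: bool = True) -> None:
        """Sort children in place by subtree size (ties by smallest label)."""
        size: dict[int, tuple[int, str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                size[id(n)] = (1, n.label)
            else:
                subs = [size[id(c)] for c in n.children]
                size[id(n)] = (sum(s for s, _ in subs), min(l for _, l in subs))
                n.children.sort(key=lambda c: size[id(c)], reverse=not ascending)

    def leafset_below(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` -> frozenset of leaf labels under that node."""
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                acc: set[str] = set()
                for c in n.children:
                    acc |= below[id(c)]
                below[id(n)] = frozenset(acc)
        return below

    def bipartitions(self, ref: Optional[str] = None) -> set[frozenset[str]]:
        """Non-trivial bipartitions of the unrooted topology.

        Each split is represented canonically by the side *not* containing
        ``ref`` (default: lexicographically smallest leaf label, so that
        bipartition sets of two trees over the same taxa are comparable).
        Only informative splits (both sides of size >= 2) are returned.
        """
        labels = self.leaf_labels()
        taxa = frozenset(labels)
        if ref is None:
            ref = min(labels)
        below = self.leafset_below()
        out: set[frozenset[str]] = set()
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            side = below[id(n)]
            if ref in side:
                side = taxa - side
            if 2 <= len(side) <= len(taxa) - 2:
                out.add(side)
        return out

    def rf_distance(self, other: "PhyloTree") -> int:
        """Robinson–Foulds distance (symmetric difference of bipartitions)."""
        if frozenset(self.leaf_labels()) != frozenset(other.leaf_labels()):
            raise ValueError("trees must share an identical leaf set")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths: bool = False, supports: bool = False,
                  length_fmt: str = "%g") -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _escape_label(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support:
                    s += "[" + ",".join(
                        f"{k}={v}" for k, v in sorted(node.support.items())) + "]"
            if lengths and node.length is not None:
                s += ":" + (length_fmt % node.length)
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(_parse_newick(text))

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves}>"


def _escape_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse_newick(text: str) -> Node:
    """Parse a single Newick description (supports ``[k=v,...]`` comments)."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def error(msg: str):
        raise ValueError(f"newick parse error at position {pos}: {msg}")

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.add_child(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add_child(parse_node())
            if pos >= len(s) or s[pos] != ")":
                error("expected ')'")
            pos += 1
        # label
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'" and pos + 1 < len(s) and s[pos + 1] == "'":
                    out.append("'")
                    pos += 2
                elif s[pos] == "'":
                    pos += 1
                    break
                else:
                    out.append(s[pos])
                    pos += 1
            node.label = "".join(out)
        else:
            start = pos
            while pos < len(s) and s[pos] not in "(),:;[]":
                pos += 1
            if pos > start:
                node.label = s[start:pos].strip() or None
        # support comment
        if pos < len(s) and s[pos] == "[":
            end = s.index("]", pos)
            body = s[pos + 1:end]
            pos = end + 1
            for item in body.split(","):
                if "=" in item:
                    k, v = item.split("=", 1)
                    try:
                        node.support[k.strip()] = int(v)
                    except ValueError:
                        try:
                            node.support[k.strip()] = float(v)
                        except ValueError:
                            node.support[k.strip()] = v.strip()
        # branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        error("trailing characters")
    return root


def tree_from_clades(taxa: Iterable[str],
                     clades: Iterable[frozenset[str]],
                     support: Optional[Callable[[frozenset[str]], dict]] = None,
                     ) -> PhyloTree:
    """Build a rooted tree from a compatible set of clades.

    ``clades`` are leaf-label sets (singletons and the full set are implied).
    Incompatible (overlapping, non-nested) clades raise ``ValueError``.
    """
    taxa = list(taxa)
    full = frozenset(taxa)
    uniq = {frozenset(c) for c in clades if 1 < len(c) < len(taxa)}
    ordered = sorted(uniq, key=len, reverse=True)

    root = Node()
    node_of: dict[frozenset[str], Node] = {full: root}
    members: dict[int, frozenset[str]] = {id(root): full}
    # insert largest-first: the parent of each clade is the smallest
    # already-inserted clade strictly containing it
    inserted: list[frozenset[str]] = [full]
    for clade in ordered:
        parent_set = min((c for c in inserted if clade < c), key=len)
        for c in inserted:
            if not (clade <= c or c <= clade or not (clade & c)):
                raise ValueError("incompatible clade set")
        parent = node_of[parent_set]
        node = Node()
        if support is not None:
            node.support = dict(support(clade) or {})
        parent.add_child(node)
        node_of[clade] = node
        members[id(node)] = clade
        inserted.append(clade)
    # attach leaves under the smallest containing clade
    for t in taxa:
        parent_set = min((c for c in inserted if t in c), key=len)
        node_of[parent_set].add_child(Node(label=t))
    # children were appended clade-first; re-nest leaves that belong inside
    # a sibling clade (cannot happen with largest-first insertion, but keep
    # the invariant explicit)
    return PhyloTree(root)
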