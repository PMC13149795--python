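"""Shared test helpers: tiny matrix/tree factories and brute-force oracles."""

from __future__ import annotations

import numpy as np

from morphoclad.matrix import (CellValue, CharacterDef, CharacterMatrix,
                               parse_nexus)
from morphoclad.trees import Node, PhyloTree


def mk(rows: dict[str, str], symbols: str = "0123456789") -> CharacterMatrix:
    """Build a matrix from NEXUS-style row strings (``?``, ``-``, ``{..}``)."""
    ntax = len(rows)
    # count characters from the first row
    first = next(iter(rows.values()))
    nchar = 0
    i = 0
    while i < len(first):
        if first[i] == "{":
            i = first.index("}", i) + 1
        else:
            i += 1
        nchar += 1
    body = "\n".join(f"{t}  {seq}" for t, seq in rows.items())
    text = (f"#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX={ntax} NCHAR={nchar};\n"
            f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n'
            f"MATRIX\n{body}\n;\nEND;\n")
    return parse_nexus(text)


def column_matrix(states: list, k: int) -> CharacterMatrix:
    """Single-character matrix from a list of cell specs: int (determinate),
    '?' (unknown), '-' (inapplicable), or a set of ints (polymorphic)."""
    cells = []
    for s in states:
        if s == "?":
            cells.append([CellValue.unknown()])
        elif s == "-":
            cells.append([CellValue.inapplicable()])
        elif isinstance(s, (set, frozenset)):
            cells.append([CellValue.polymorphic(s)])
        else:
            cells.append([CellValue.determinate(s)])
    taxa = [chr(ord("A") + i) for i in range(len(states))]
    return CharacterMatrix(taxa, [CharacterDef(1, n_states=k)], cells)


def random_tree(rng: np.random.Generator, labels: list[str]) -> PhyloTree:
    """Uniform-ish random binary tree by random sequential insertion."""
    assert len(labels) >= 2
    root = Node()
    a = root.add_child(Node(labels[0]))
    b = root.add_child(Node(labels[1]))
    edges = [a, b]
    for lab in labels[2:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = mid.add_child(Node(lab))
        edges.extend([mid, leaf])
    return PhyloTree(root)


def random_matrix(rng: np.random.Generator, n_taxa: int, n_chars: int,
                  k: int = 2, p_unknown: float = 0.0,
                  p_inapplicable: float = 0.0) -> CharacterMatrix:
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    chars = [CharacterDef(j + 1, n_states=k) for j in range(n_chars)]
    cells = []
    for i in range(n_taxa):
        row = []
        for j in range(n_chars):
            u = rng.random()
            if u < p_unknown:
                row.append(CellValue.unknown())
            elif u < p_unknown + p_inapplicable:
                row.append(CellValue.inapplicable())
            else:
                row.append(CellValue.determinate(int(rng.integers(k))))
        cells.append(row)
    return CharacterMatrix(taxa, chars, cells)


def perfect_matrix(tree: PhyloTree) -> CharacterMatrix:
    """One clean binary synapomorphy per clade of ``tree`` (homoplasy-free
    by construction)."""
    taxa = tree.leaf_labels()
    below = tree.leafset_below()
    clades = [below[id(n)] for n in tree.postorder()
              if not n.is_leaf and n.parent is not None
              and 2 <= len(below[id(n)]) <= len(taxa) - 2]
    chars = [CharacterDef(j + 1, n_states=2) for j in range(len(clades))]
    cells = [[CellValue.determinate(1 if t in cl else 0) for cl in clades]
             for t in taxa]
    return CharacterMatrix(taxa, chars, cells)
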