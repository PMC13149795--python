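"""Discrete morphological character matrices and companion metadata.

The central container is :class:`CharacterMatrix`: an ordered taxa ×
characters grid of :class:`CellValue` cells.  Cells distinguish four kinds
of observation that morphological palaeontology keeps apart:

* ``determinate`` — a single observed state,
* ``polymorphic`` — two or more observed states (``{01}`` in NEXUS),
* ``unknown`` — not preserved / not observed (``?``),
* ``inapplicable`` — logically unscorable, e.g. cupule characters of an
  acupulate seed (``-``).

Unknown and inapplicable are reported separately in summaries (their sum is
the conventional "missing" percentage) even though parsimony scoring treats
both as full ambiguity.  Companion metadata — character categories, group
membership, stratigraphic ranges — travel as simple TSV sidecar files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

KINDS = ("determinate", "polymorphic", "unknown", "inapplicable")
CATEGORIES = (
    "architectural",
    "wall_structure",
    "external_topography",
    "cellular",
    "pollination",
)

NEXUS_SYMBOLS = "0123456789ABCDEFGHIJ"


@dataclass(frozen=True)
class CellValue:
    """One matrix cell: an observation kind plus its allowed state set."""

    kind: str
    states: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kind == "determinate" and len(self.states) != 1:
            raise ValueError("determinate cell must hold exactly one state")
        if self.kind == "polymorphic" and len(self.states) < 2:
            raise ValueError("polymorphic cell must hold >= 2 states")
        if self.kind in ("unknown", "inapplicable") and self.states:
            raise ValueError(f"{self.kind} cell carries no explicit states")

    @classmethod
    def determinate(cls, state: int) -> "CellValue":
        return cls("determinate", frozenset([int(state)]))

    @classmethod
    def polymorphic(cls, states: Iterable[int]) -> "CellValue":
        return cls("polymorphic", frozenset(int(s) for s in states))

    @classmethod
    def unknown(cls) -> "CellValue":
        return cls("unknown")

    @classmethod
    def inapplicable(cls) -> "CellValue":
        return cls("inapplicable")

    @property
    def is_missing(self) -> bool:
        return self.kind in ("unknown", "inapplicable")

    def allowed(self, n_states: int) -> frozenset[int]:
        """States the cell is compatible with (full set when missing)."""
        if self.is_missing:
            return frozenset(range(n_states))
        return self.states


@dataclass
class CharacterDef:
    """One character column: 1-based id, label, state count, category."""

    id: int
    label: str = ""
    n_states: int = 1
    category: Optional[str] = None
    informative: Optional[bool] = None

    def __post_init__(self):
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown character category {self.category!r}")


@dataclass
class MatrixSummary:
    n_taxa: int
    n_characters: int
    n_cells: int
    n_states_total: int
    pct_unknown: float
    pct_inapplicable: float
    pct_polymorphic: float
    per_taxon_pct_missing: dict[str, float]
    per_character_pct_missing: dict[int, float]

    @property
    def pct_missing(self) -> float:
        return self.pct_unknown + self.pct_inapplicable


@dataclass
class GroupDefinition:
    name: str
    members: frozenset[str]


@dataclass
class StratRange:
    """First/last appearance of a taxon, in Ma (older = numerically larger)."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self):
        if not (self.fad >= self.lad > 0):
            raise ValueError(
                f"range for {self.taxon}: need fad >= lad > 0, "
                f"got fad={self.fad}, lad={self.lad}")


class CharacterMatrix:
    """Taxa × characters grid of :class:`CellValue` cells.

    ``extrinsic`` holds optional per-taxon annotation columns (e.g.
    depositional environment) that never enter tree building or distance
    computation.
    """

    def __init__(self, taxa: Sequence[str], characters: Sequence[CharacterDef],
                 cells: Sequence[Sequence[CellValue]],
                 extrinsic: Optional[dict[str, dict[str, str]]] = None):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        self.extrinsic = extrinsic or {}
        if len(self.cells) != len(self.taxa):
            raise ValueError("cell grid row count != number of taxa")
        for t, row in zip(self.taxa, self.cells):
            if len(row) != len(self.characters):
                raise ValueError(f"row for taxon {t!r} has wrong length")
        for row in self.cells:
            for j, cell in enumerate(row):
                k = self.characters[j].n_states
                if cell.states and max(cell.states) >= k:
                    raise ValueError(
                        f"state index out of range for character "
                        f"{self.characters[j].id}")
        self._leaf_costs: Optional[np.ndarray] = None

    # -- basic access ------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def max_states(self) -> int:
        return max((c.n_states for c in self.characters), default=1)

    def taxon_index(self, label: str) -> int:
        return self.taxa.index(label)

    def cell(self, taxon: str, char_id: int) -> CellValue:
        return self.cells[self.taxon_index(taxon)][char_id - 1]

    def column(self, j: int) -> list[CellValue]:
        """Column by 0-based index."""
        return [row[j] for row in self.cells]

    def n_states(self) -> np.ndarray:
        return np.array([c.n_states for c in self.characters], dtype=np.int64)

    # -- numeric views -----------------------------------------------------

    def leaf_costs(self) -> np.ndarray:
        """Per-character Sankoff leaf costs, shape (chars, taxa, max_states).

        0 where the state is allowed for the cell, a large sentinel
        otherwise (missing cells allow every state of the character).
        """
        if self._leaf_costs is None:
            from ._kernels import INF
            kmax = self.max_states
            cost = np.full((self.n_characters, self.n_taxa, kmax), INF,
                           dtype=np.int64)
            for j, cdef in enumerate(self.characters):
                for i, row in enumerate(self.cells):
                    for s in row[j].allowed(cdef.n_states):
                        cost[j, i, s] = 0
            self._leaf_costs = cost
        return self._leaf_costs

    def codes(self) -> np.ndarray:
        """Determinate state codes, -1 for every non-determinate cell."""
        out = np.full((self.n_taxa, self.n_characters), -1, dtype=np.int64)
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if cell.kind == "determinate":
                    out[i, j] = next(iter(cell.states))
        return out

    # -- derived matrices --------------------------------------------------

    def recode_for_distance(self) -> "CharacterMatrix":
        """Re-score polymorphic cells as unknown (pre-distance convention)."""
        new_cells = [
            [CellValue.unknown() if c.kind == "polymorphic" else c
             for c in row]
            for row in self.cells
        ]
        return CharacterMatrix(self.taxa, self.characters, new_cells,
                               extrinsic=self.extrinsic)

    def resampled(self, column_indices: Sequence[int]) -> "CharacterMatrix":
        """Matrix with columns taken (with repetition) from this one."""
        chars = []
        for new_j, j in enumerate(column_indices, start=1):
            c = self.characters[j]
            chars.append(CharacterDef(new_j, c.label, c.n_states, c.category))
        cells = [[row[j] for j in column_indices] for row in self.cells]
        return CharacterMatrix(self.taxa, chars, cells)

    # -- summary -----------------------------------------------------------

    def summarize(self) -> MatrixSummary:
        n_cells = self.n_taxa * self.n_characters
        kinds = np.zeros(4, dtype=np.int64)
        kind_idx = {k: i for i, k in enumerate(KINDS)}
        per_taxon = {}
        per_char = np.zeros(self.n_characters, dtype=np.int64)
        for t, row in zip(self.taxa, self.cells):
            miss = 0
            for j, cell in enumerate(row):
                kinds[kind_idx[cell.kind]] += 1
                if cell.is_missing:
                    miss += 1
                    per_char[j] += 1
            per_taxon[t] = 100.0 * miss / self.n_characters
        return MatrixSummary(
            n_taxa=self.n_taxa,
            n_characters=self.n_characters,
            n_cells=n_cells,
            n_states_total=int(sum(c.n_states for c in self.characters)),
            pct_unknown=100.0 * kinds[kind_idx["unknown"]] / n_cells,
            pct_inapplicable=100.0 * kinds[kind_idx["inapplicable"]] / n_cells,
            pct_polymorphic=100.0 * kinds[kind_idx["polymorphic"]] / n_cells,
            per_taxon_pct_missing=per_taxon,
            per_character_pct_missing={
                self.characters[j].id: 100.0 * per_char[j] / self.n_taxa
                for j in range(self.n_characters)},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and [(c.id, c.n_states) for c in self.characters]
                == [(c.id, c.n_states) for c in other.characters]
                and self.cells == other.cells)


# ---------------------------------------------------------------------------
# NEXUS I/O
# ---------------------------------------------------------------------------

def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    Conventions: ``?`` (or the declared MISSING symbol) = unknown, ``-``
    (or the declared GAP symbol) = inapplicable, ``{..}``/``(..)`` =
    polymorphic.  State symbols map positionally onto 0-based indices in
    declared SYMBOLS order.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_nexus(text)


def parse_nexus(text: str) -> CharacterMatrix:
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError("not a NEXUS file (missing #NEXUS header)")
    block = re.search(
        r"BEGIN\s+(?:DATA|CHARACTERS)\s*;(.*?)END\s*;",
        text, re.IGNORECASE | re.DOTALL)
    if not block:
        raise ValueError("no DATA/CHARACTERS block found")
    body = block.group(1)

    dim = re.search(r"DIMENSIONS\s+([^;]*);", body, re.IGNORECASE)
    if not dim:
        raise ValueError("no DIMENSIONS command")
    ntax = nchar = None
    for key, val in re.findall(r"(NTAX|NCHAR)\s*=\s*(\d+)", dim.group(1),
                               re.IGNORECASE):
        if key.upper() == "NTAX":
            ntax = int(val)
        else:
            nchar = int(val)
    if ntax is None or nchar is None:
        raise ValueError("DIMENSIONS must declare NTAX and NCHAR")

    symbols, missing_sym, gap_sym = NEXUS_SYMBOLS, "?", "-"
    fmt = re.search(r"FORMAT\s+([^;]*);", body, re.IGNORECASE)
    if fmt:
        f = fmt.group(1)
        m = re.search(r"SYMBOLS\s*=\s*\"([^\"]*)\"", f, re.IGNORECASE)
        if m:
            symbols = m.group(1).replace(" ", "")
        m = re.search(r"MISSING\s*=\s*(\S)", f, re.IGNORECASE)
        if m:
            missing_sym = m.group(1)
        m = re.search(r"GAP\s*=\s*(\S)", f, re.IGNORECASE)
        if m:
            gap_sym = m.group(1)
    state_of = {sym: i for i, sym in enumerate(symbols)}

    mat = re.search(r"MATRIX(.*?);", body, re.IGNORECASE | re.DOTALL)
    if not mat:
        raise ValueError("no MATRIX command")

    taxa: list[str] = []
    rows: list[list[CellValue]] = []
    for line in mat.group(1).splitlines():
        line = re.sub(r"\[[^\]]*\]", "", line).strip()
        if not line:
            continue
        if line.startswith("'"):
            m = re.match(r"'((?:[^']|'')*)'\s*(.*)$", line)
            if not m:
                raise ValueError(f"unterminated quoted taxon label: {line!r}")
            taxon, seq = m.group(1).replace("''", "'"), m.group(2)
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"cannot split taxon row: {line!r}")
            taxon, seq = parts
        if taxon in taxa:
            raise ValueError(f"duplicate taxon {taxon!r}")
        row = _parse_state_row(seq, state_of, missing_sym, gap_sym, taxon)
        if len(row) != nchar:
            raise ValueError(
                f"row for taxon {taxon!r} has {len(row)} characters, "
                f"NCHAR declares {nchar}")
        taxa.append(taxon)
        rows.append(row)
    if len(taxa) != ntax:
        raise ValueError(f"matrix has {len(taxa)} taxa, NTAX declares {ntax}")

    characters = []
    for j in range(nchar):
        observed = [s for row in rows for s in row[j].states]
        characters.append(CharacterDef(
            id=j + 1, label=f"C{j + 1}",
            n_states=(max(observed) + 1) if observed else 1))
    return CharacterMatrix(taxa, characters, rows)


def _parse_state_row(seq: str, state_of: dict[str, int], missing_sym: str,
                     gap_sym: str, taxon: str) -> list[CellValue]:
    row: list[CellValue] = []
    i = 0
    seq = seq.replace(" ", "").replace("\t", "")
    while i < len(seq):
        ch = seq[i]
        if ch == missing_sym:
            row.append(CellValue.unknown())
            i += 1
        elif ch == gap_sym:
            row.append(CellValue.inapplicable())
            i += 1
        elif ch in "{(":
            close = "}" if ch == "{" else ")"
            end = seq.find(close, i)
            if end < 0:
                raise ValueError(
                    f"taxon {taxon!r}: unterminated polymorphism at "
                    f"character {len(row) + 1}")
            states = set()
            for sym in seq[i + 1:end]:
                if sym not in state_of:
                    raise ValueError(
                        f"taxon {taxon!r}, character {len(row) + 1}: "
                        f"undeclared symbol {sym!r}")
                states.add(state_of[sym])
            if len(states) == 1:
                row.append(CellValue.determinate(next(iter(states))))
            else:
                row.append(CellValue.polymorphic(states))
            i = end + 1
        else:
            if ch not in state_of:
                raise ValueError(
                    f"taxon {taxon!r}, character {len(row) + 1}: "
                    f"undeclared symbol {ch!r}")
            row.append(CellValue.determinate(state_of[ch]))
            i += 1
    return row


def write_nexus(matrix: CharacterMatrix, path) -> None:
    Path(path).write_text(format_nexus(matrix), encoding="utf-8")


def format_nexus(matrix: CharacterMatrix) -> str:
    kmax = matrix.max_states
    symbols = NEXUS_SYMBOLS[:max(kmax, 2)]
    name_w = max(len(_nexus_label(t)) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        cells = []
        for cell in row:
            if cell.kind == "unknown":
                cells.append("?")
            elif cell.kind == "inapplicable":
                cells.append("-")
            elif cell.kind == "determinate":
                cells.append(symbols[next(iter(cell.states))])
            else:
                cells.append("{" + "".join(symbols[s]
                                           for s in sorted(cell.states)) + "}")
        lines.append(f"{_nexus_label(taxon):<{name_w}}" + "".join(cells))
    lines += [";", "END;", ""]
    return "\n".join(lines)


def _nexus_label(label: str) -> str:
    if re.search(r"[\s(){}\[\];=,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Sidecar TSV files and output tables
# ---------------------------------------------------------------------------

def read_categories_tsv(path) -> dict[int, str]:
    """``character_id <TAB> category`` lines -> {1-based id: category}."""
    out: dict[int, str] = {}
    for ln, line in enumerate(_data_lines(path), start=1):
        cid, cat = line.split("\t")[:2]
        cat = cat.strip()
        if cat not in CATEGORIES:
            raise ValueError(f"{path} line {ln}: unknown category {cat!r}")
        out[int(cid)] = cat
    return out


def read_groups_tsv(path) -> list[GroupDefinition]:
    """``taxon <TAB> group`` lines -> disjoint group definitions."""
    members: dict[str, set[str]] = {}
    seen: set[str] = set()
    for line in _data_lines(path):
        taxon, group = line.split("\t")[:2]
        taxon, group = taxon.strip(), group.strip()
        if taxon in seen:
            raise ValueError(f"taxon {taxon!r} assigned to multiple groups")
        seen.add(taxon)
        members.setdefault(group, set()).add(taxon)
    return [GroupDefinition(g, frozenset(m)) for g, m in members.items()]


def read_ranges_tsv(path) -> list[StratRange]:
    """``taxon <TAB> fad_ma <TAB> lad_ma`` lines."""
    out = []
    for line in _data_lines(path):
        taxon, fad, lad = line.split("\t")[:3]
        out.append(StratRange(taxon.strip(), float(fad), float(lad)))
    return out


def _data_lines(path):
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n")
        if line and not line.startswith("#"):
            yield line


def write_table_tsv(df, path) -> None:
    """Write a pandas DataFrame as TSV (UTF-8, no index surprises)."""
    df.to_csv(path, sep="\t", index=True)


def write_trees_newick(trees, path, lengths: bool = False,
                       supports: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(t.to_newick(lengths=lengths, supports=supports) + "\n")


def read_trees_newick(path) -> list:
    from .trees import PhyloTree
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            out.append(PhyloTree.from_newick(line))
    return out


def xlsx_to_nexus(xlsx_path, nexus_path, sheet: Optional[str] = None) -> None:
    """Convert a spreadsheet matrix (taxa in column A, one character per
    column, NEXUS cell syntax in cells) to NEXUS.  Thin convenience shim so
    the analytical core only ever parses NEXUS."""
    import openpyxl  # optional dependency, only needed for conversion

    wb = openpyxl.load_workbook(xlsx_path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.active
    rows = [[("" if c is None else str(c).strip()) for c in r]
            for r in ws.iter_rows(values_only=True)]
    rows = [r for r in rows if any(r)]
    header, data = rows[0], rows[1:]
    nchar = len(header) - 1
    lines = ["#NEXUS", "BEGIN DATA;",
             f"DIMENSIONS NTAX={len(data)} NCHAR={nchar};",
             'FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;',
             "MATRIX"]
    for r in data:
        taxon = _nexus_label(r[0].replace(" ", "_"))
        lines.append(taxon + "  " + "".join(r[1:nchar + 1]))
    lines += [";", "END;", ""]
    Path(nexus_path).write_text("\n".join(lines), encoding="utf-8")
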