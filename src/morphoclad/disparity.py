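"""Morphological disparity: Gower distances, PCoA, similarity heatmap.

With every character treated as unordered categorical and missing cells
deleted pairwise, the Gower distance between two taxa reduces to the
simple-matching mismatch proportion over their mutually scored
characters.  Matrices are expected to be recoded first
(:meth:`CharacterMatrix.recode_for_distance`: polymorphic -> unknown).

PCoA is classical metric scaling: double-centre -D²/2, eigendecompose,
scale eigenvectors by the square root of their (positive) eigenvalues.
Negative eigenvalues — expected, since pairwise deletion can make the
distance non-Euclidean — are reported but excluded from the variance
denominator by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .trees import PhyloTree


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray          # n x n, symmetric, zero diagonal
    shared_counts: np.ndarray   # n x n mutually scored characters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


@dataclass
class Ordination:
    taxa: list[str]
    eigenvalues: np.ndarray           # all, descending (negatives included)
    coordinates: pd.DataFrame         # taxa x positive axes
    proportion_explained: np.ndarray  # per positive axis / sum of positives
    proportion_explained_abs: np.ndarray  # per positive axis / sum of |all|


def gower_distance(matrix: CharacterMatrix) -> DistanceMatrix:
    """Pairwise mismatch proportion over mutually scored characters.

    Unknown and inapplicable cells are excluded pairwise; a pair with no
    mutually scored character is an error naming the pair.  Polymorphic
    cells should have been recoded to unknown beforehand (an error
    otherwise, to avoid silently treating them as extra states).
    """
    if any(c.kind == "polymorphic" for row in matrix.cells for c in row):
        raise ValueError(
            "matrix still contains polymorphic cells; apply "
            "recode_for_distance() first")
    codes = matrix.codes()
    valid = codes >= 0
    n = matrix.n_taxa
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    undefined = []
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        ns = both.sum(axis=1)
        mism = ((codes[i] != codes[i + 1:]) & both).sum(axis=1)
        shared[i, i + 1:] = shared[i + 1:, i] = ns
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(ns > 0, mism / np.maximum(ns, 1), np.nan)
        d[i, i + 1:] = d[i + 1:, i] = row
        for j in np.nonzero(ns == 0)[0]:
            undefined.append((matrix.taxa[i], matrix.taxa[i + 1 + j]))
    if undefined:
        raise ValueError(
            "Gower distance undefined (no mutually scored characters) for "
            f"pairs: {undefined}")
    tri = d[np.triu_indices(n, 1)]
    if tri.size:
        viol = _triangle_violations(d)
        if viol:
            warnings.warn(
                f"{viol} triangle-inequality violations in Gower matrix "
                "(expected under pairwise deletion)", stacklevel=2)
    return DistanceMatrix(list(matrix.taxa), d, shared)


def _triangle_violations(d: np.ndarray, tol: float = 1e-12) -> int:
    n = d.shape[0]
    count = 0
    for k in range(n):
        if (d > d[:, [k]] + d[[k], :] + tol).any():
            count += 1
    return count


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical metric scaling (principal coordinates analysis)."""
    d = np.asarray(dm.values, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = evals[pos].sum()
    abs_sum = np.abs(evals).sum()
    return Ordination(
        taxa=list(dm.taxa),
        eigenvalues=evals,
        coordinates=pd.DataFrame(coords, index=dm.taxa, columns=axes),
        proportion_explained=evals[pos] / pos_sum if pos_sum else evals[pos],
        proportion_explained_abs=evals[pos] / abs_sum if abs_sum else evals[pos],
    )


def similarity_heatmap_export(dm: DistanceMatrix,
                              taxon_order: Optional[Sequence[str]] = None
                              ) -> pd.DataFrame:
    """Gower similarity (1 - d) with rows/columns in the given order
    (default: matrix order; typically the consensus base-to-apex order)."""
    if taxon_order is None:
        taxon_order = dm.taxa
    if sorted(taxon_order) != sorted(dm.taxa):
        raise ValueError("taxon_order must be a permutation of the taxa")
    sim = pd.DataFrame(1.0 - dm.values, index=dm.taxa, columns=dm.taxa)
    return sim.loc[list(taxon_order), list(taxon_order)]


def base_to_apex_order(consensus: PhyloTree) -> list[str]:
    """Leaf sequence of the ladderised (outgroup-first) consensus tree."""
    t = consensus.copy()
    t.ladderize(ascending=True)
    return t.leaf_labels()
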