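"""Parsimony scoring: Fitch/Sankoff lengths, m/g bounds, fit indices."""

import subprocess

import numpy as np
import pytest

from morphoclad.matrix import CharacterDef, CharacterMatrix, CellValue, \
    format_nexus
from morphoclad.parsimony import (DownUp, brute_force_length,
                                  character_fits, ensemble_fit, fitch_length,
                                  is_informative, min_steps, star_steps)
from morphoclad.search import enumerate_trees, adj_to_tree
from morphoclad.trees import PhyloTree
from util import column_matrix, mk, perfect_matrix, random_matrix, random_tree

QUARTET = "((A,B),(C,D));"


@pytest.mark.parametrize("states, expected", [
    ([0, 0, 1, 1], 1),       # single synapomorphy
    ([0, 1, 0, 1], 2),       # full conflict with the quartet
    ([0, "?", 1, 1], 1),     # ambiguity resolved freely
    ([0, "-", 1, 1], 1),     # inapplicable scored as full ambiguity
    ([{0, 1}, 0, 0, 0], 0),  # polymorphic cell can match its neighbours
])
def test_quartet_lengths(states, expected):
    m = column_matrix(states, k=2)
    t = PhyloTree.from_newick(QUARTET)
    assert fitch_length(t, m) == expected
    assert brute_force_length(t, m, 0) == expected


def test_fitch_equals_brute_force_on_random_trees_and_characters():
    rng = np.random.default_rng(11)
    for _ in range(150):
        n = int(rng.integers(4, 7))
        labels = [chr(ord("A") + i) for i in range(n)]
        t = random_tree(rng, labels)
        k = int(rng.integers(2, 4))
        col = [int(rng.integers(k)) if rng.random() > 0.25 else "?"
               for _ in range(n)]
        m = column_matrix(col, k=k)
        assert fitch_length(t, m) == brute_force_length(t, m, 0)


def test_polytomies_scored_exactly():
    # char 0,1,2 on a 3-child star: two changes, whatever the root state
    m = column_matrix([0, 1, 2], k=3)
    star = PhyloTree.from_newick("(A,B,C);")
    assert fitch_length(star, m) == 2
    assert brute_force_length(star, m, 0) == 2
    # a polytomy is never shorter than its best resolution
    rng = np.random.default_rng(5)
    for _ in range(20):
        labels = list("ABCDEF")
        t = random_tree(rng, labels)
        m6 = random_matrix(rng, 6, 6, k=2)
        m6 = CharacterMatrix(labels, m6.characters, m6.cells)
        star6 = PhyloTree.from_newick("(A,B,C,D,E,F);")
        assert fitch_length(star6, m6) >= fitch_length(t, m6)


@pytest.mark.parametrize("states, k, expected", [
    ([0, 0, 1, 1], 2, 1),
    ([0, "?", "?", "?"], 2, 0),
    ([0, 1, {0, 1}, 2], 3, 2),          # brute-force set cover case
    (["?", "?", "-"], 2, 0),            # all missing
])
def test_min_steps_examples(states, k, expected):
    m = column_matrix(states, k=k)
    assert min_steps(m.column(0), k) == expected


def test_min_steps_equals_minimum_over_all_trees():
    rng = np.random.default_rng(23)
    for _ in range(15):
        n = int(rng.integers(4, 7))
        k = int(rng.integers(2, 4))
        col = [int(rng.integers(k)) if rng.random() > 0.2 else "?"
               for _ in range(n)]
        m = column_matrix(col, k=k)
        kept, best = enumerate_trees(m, slack=0)
        assert min_steps(m.column(0), k) == best


@pytest.mark.parametrize("states, k, expected", [
    ([0, 0, 1, 1], 2, 2),
    ([0, 0, 0, 1], 2, 1),
    ([0, "?", 1, "?"], 2, 1),
])
def test_star_steps_examples(states, k, expected):
    m = column_matrix(states, k=k)
    assert star_steps(m.column(0), k) == expected


def test_star_steps_equals_fitch_on_star_tree():
    rng = np.random.default_rng(31)
    for _ in range(25):
        n = int(rng.integers(4, 8))
        k = int(rng.integers(2, 4))
        col = [int(rng.integers(k)) if rng.random() > 0.2 else "?"
               for _ in range(n)]
        m = column_matrix(col, k=k)
        star = PhyloTree.from_newick(
            "(" + ",".join(m.taxa) + ");")
        assert star_steps(m.column(0), k) == fitch_length(star, m)


@pytest.mark.parametrize("states, k, expected", [
    ([0, 0, 0, 0], 2, False),   # constant
    ([0, 0, 0, 1], 2, False),   # autapomorphy
    ([0, 0, 1, 1], 2, True),
])
def test_is_informative(states, k, expected):
    m = column_matrix(states, k=k)
    assert is_informative(m.column(0), k) is expected


def test_ensemble_fit_closed_forms():
    # homoplasy-free: CI = RI = 1
    rng = np.random.default_rng(2)
    t = random_tree(rng, list("ABCDEF"))
    clean = perfect_matrix(t)
    fit = ensemble_fit(t, clean)
    assert fit.ci == 1.0 and fit.ri == 1.0
    # the quartet conflict character: s=2, m=1, g=2 -> ci=0.5, ri=0
    m = column_matrix([0, 1, 0, 1], k=2)
    q = PhyloTree.from_newick(QUARTET)
    f = character_fits(q, m)[0]
    assert (f.m, f.s, f.g) == (1, 2, 2)
    assert f.ci == 0.5 and f.ri == 0.0


def test_constant_character_changes_no_length_and_bounds_hold():
    rng = np.random.default_rng(17)
    m = random_matrix(rng, 7, 8, k=3)
    t = random_tree(rng, m.taxa)
    base = fitch_length(t, m)
    extra = CharacterMatrix(
        m.taxa, m.characters + [CharacterDef(9, n_states=1)],
        [row + [CellValue.determinate(0)] for row in m.cells])
    assert fitch_length(t, extra) == base
    for f in character_fits(t, m):
        assert f.m <= f.s <= f.g


def test_fit_indices_match_phangorn():
    """Independent oracle: R phangorn on the same matrix and tree."""
    rng = np.random.default_rng(101)
    m = random_matrix(rng, 7, 20, k=3, p_unknown=0.1)
    t = random_tree(rng, m.taxa)
    fit = ensemble_fit(t, m)
    script = f"""
suppressMessages(library(phangorn))
tf <- tempfile(fileext=".nex"); writeLines({format_nexus(m)!r}, tf)
d <- read.nexus.data(tf)
pd <- phyDat(d, type="USER", levels=c("0","1","2"))
tr <- read.tree(text={t.to_newick()!r})
cat(parsimony(tr, pd), CI(tr, pd), RI(tr, pd), "\\n")
"""
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=120)
    assert res.returncode == 0, res.stderr
    length, ci, ri = map(float, res.stdout.split()[-3:])
    assert fit.length == int(length)
    assert fit.ci == pytest.approx(ci, abs=1e-6)
    assert fit.ri == pytest.approx(ri, abs=1e-6)


def test_branch_bounds_sum_consistency():
    """Sum of forced changes <= tree length <= sum of possible changes."""
    rng = np.random.default_rng(41)
    for _ in range(10):
        m = random_matrix(rng, 6, 10, k=2, p_unknown=0.15)
        t = random_tree(rng, m.taxa)
        du = DownUp(t, m)
        total = du.lengths.sum()
        forced = possible = 0
        for v in du.order:
            if v.parent is None:
                continue
            f, p = du.branch_change_bounds(v)
            forced += f.sum()
            possible += p.sum()
            assert (f <= p).all()
        assert forced <= total <= possible
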