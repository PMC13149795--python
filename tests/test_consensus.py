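"""Consensus trees and branch support."""

import numpy as np
import pytest

from morphoclad.consensus import (bootstrap_support, bremer_support,
                                  majority_consensus, strict_consensus)
from morphoclad.matrix import CellValue, CharacterDef, CharacterMatrix
from morphoclad.search import SearchConfig, exhaustive_search
from morphoclad.trees import PhyloTree
from util import mk, random_matrix, random_tree


def test_strict_consensus_of_one_tree_is_that_tree():
    t = PhyloTree.from_newick("((A,B),((C,D),E));")
    assert strict_consensus([t]).bipartitions() == t.bipartitions()


def test_strict_consensus_collapses_the_disputed_clade():
    t1 = PhyloTree.from_newick("(((A,B),C),(D,E));")
    t2 = PhyloTree.from_newick("(((A,C),B),(D,E));")
    cons = strict_consensus([t1, t2])
    assert cons.bipartitions() == {frozenset({"D", "E"})}


def test_strict_consensus_is_bipartition_intersection():
    rng = np.random.default_rng(19)
    labels = [f"t{i}" for i in range(9)]
    for _ in range(40):
        t1, t2 = random_tree(rng, list(labels)), random_tree(rng, list(labels))
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == t1.bipartitions() & t2.bipartitions()


def test_strict_consensus_requires_common_leaves():
    t1 = PhyloTree.from_newick("((A,B),(C,D));")
    t2 = PhyloTree.from_newick("((A,B),(C,E));")
    with pytest.raises(ValueError):
        strict_consensus([t1, t2])


def test_majority_rules():
    t1 = PhyloTree.from_newick("(((A,B),C),(D,E));")
    t2 = PhyloTree.from_newick("(((A,B),C),(D,E));")
    t3 = PhyloTree.from_newick("(((A,C),B),(D,E));")
    maj = majority_consensus([t1, t2, t3])
    # the (A,B) clade, canonically the side away from taxon A: 2/3 > 50%
    assert frozenset({"C", "D", "E"}) in maj.bipartitions()
    # clade in exactly half of the trees is excluded (strict majority)
    t4 = PhyloTree.from_newick("(((A,C),B),(D,E));")
    maj2 = majority_consensus([t1, t2, t3, t4])
    assert frozenset({"C", "D", "E"}) not in maj2.bipartitions()  # (A,B)
    assert frozenset({"B", "D", "E"}) not in maj2.bipartitions()  # (A,C)
    assert frozenset({"D", "E"}) in maj2.bipartitions()
    # identical inputs reproduce the tree
    assert majority_consensus([t1, t2]).bipartitions() == t1.bipartitions()


def test_majority_superset_of_strict():
    rng = np.random.default_rng(29)
    labels = [f"x{i}" for i in range(8)]
    trees = [random_tree(rng, list(labels)) for _ in range(5)]
    assert majority_consensus(trees).bipartitions() >= \
        strict_consensus(trees).bipartitions()


def test_majority_cutoff_below_half_refused():
    t = PhyloTree.from_newick("((A,B),(C,D));")
    with pytest.raises(ValueError):
        majority_consensus([t], cutoff=0.3)


def _one_informative_matrix(n_taxa=8, n_chars=10):
    taxa = [f"X{i}" for i in range(n_taxa)]
    chars = [CharacterDef(j + 1, n_states=2) for j in range(n_chars)]
    cells = [[CellValue.determinate(1 if (i < 4 and j == 0) else 0)
              for j in range(n_chars)] for i in range(n_taxa)]
    return CharacterMatrix(taxa, chars, cells), frozenset(taxa[:4])


def test_bootstrap_seed_stability_within_monte_carlo_error():
    m, clade = _one_informative_matrix()
    vals = []
    for seed in (3, 4):
        bt = bootstrap_support(m, n_pseudoreplicates=200, seed=seed)
        vals.append(bt.get(clade, "bootstrap_pct", 0.0))
    # binomial SE at p~0.65, n=200 is ~3.4 points; two draws differ by
    # less than 4 combined SEs essentially always
    assert abs(vals[0] - vals[1]) < 13.5


def test_bootstrap_of_clean_clade_is_high():
    # five clean characters supporting one clade of 8 taxa, no conflict
    taxa = [f"X{i}" for i in range(8)]
    chars = [CharacterDef(j + 1, n_states=2) for j in range(6)]
    cells = [[CellValue.determinate(1 if (i < 4 and j < 5) else 0)
              for j in range(6)] for i in range(8)]
    m = CharacterMatrix(taxa, chars, cells)
    bt = bootstrap_support(m, n_pseudoreplicates=100, seed=11)
    assert bt.get(frozenset(taxa[:4]), "bootstrap_pct", 0.0) >= 95.0


def test_bremer_two_clean_characters_give_two():
    # clade {A,B} backed by two identical non-homoplastic characters
    m = mk({"A": "110", "B": "110", "C": "000", "D": "001", "E": "001",
            "F": "000"})
    mpts = exhaustive_search(m)
    table = bremer_support(m, mpts, max_k=4)
    assert table.get(frozenset({"A", "B"}), "bremer") == 2
    # a bipartition absent from the consensus has no (i.e. zero) support
    assert table.get(frozenset({"A", "C"}), "bremer", 0) == 0


def test_bremer_sweep_equals_enumeration():
    rng = np.random.default_rng(47)
    checked = 0
    for _ in range(8):
        m = random_matrix(rng, 6, 12, k=2)
        mpts = exhaustive_search(m)
        exact = bremer_support(m, mpts, max_k=3, method="exhaustive")
        sweep = bremer_support(
            m, mpts, max_k=3, method="sweep",
            config=SearchConfig(n_replicates=5, hold_per_replicate=500,
                                seed=int(rng.integers(1000))))
        for b, vals in exact.rows.items():
            assert sweep.get(b, "bremer") == vals["bremer"]
            checked += 1
    assert checked > 0


def test_bremer_values_nondecreasing_in_max_k():
    rng = np.random.default_rng(53)
    m = random_matrix(rng, 6, 10, k=2)
    mpts = exhaustive_search(m)
    t2 = bremer_support(m, mpts, max_k=2)
    t4 = bremer_support(m, mpts, max_k=4)
    for b, vals in t2.rows.items():
        assert t4.get(b, "bremer") >= vals["bremer"] or vals["bremer"] == 2
        assert vals["bremer"] >= 1  # present in the MPT strict consensus


def test_support_table_annotation():
    t = PhyloTree.from_newick("(((A,B),C),(D,E));")
    m = mk({"A": "1", "B": "1", "C": "0", "D": "0", "E": "0"})
    bt = bootstrap_support(m, n_pseudoreplicates=20, seed=2)
    annotated = bt.annotate(t)
    ab = [n for n in annotated.postorder()
          if not n.is_leaf and {l.label for l in n.children if l.is_leaf}
          == {"A", "B"}]
    assert ab and "bootstrap_pct" in ab[0].support
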