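"""Heuristic search: addition trees, TBR, collapse rules, exhaustive oracle."""

import numpy as np
import pytest

from morphoclad.matrix import CharacterMatrix
from morphoclad.parsimony import fitch_length
from morphoclad.search import (SearchConfig, collapse_branches,
                               enumerate_trees, exhaustive_search,
                               heuristic_search, random_addition_tree,
                               tbr_neighbors, tbr_search, tree_to_adj)
from morphoclad.simulate import SimulationConfig, simulate_dataset
from morphoclad.trees import PhyloTree
from util import column_matrix, mk, perfect_matrix, random_matrix, random_tree


def test_three_taxa_unique_topology_any_seed():
    m = random_matrix(np.random.default_rng(0), 3, 4, k=2)
    trees = {random_addition_tree(m, seed).bipartitions() == set()
             for seed in range(5)}
    assert trees == {True}  # no internal branches: the single topology


def test_addition_recovers_clean_hierarchy_for_every_seed():
    rng = np.random.default_rng(9)
    true = random_tree(rng, [f"s{i}" for i in range(6)])
    m = perfect_matrix(true)
    for seed in range(8):
        t = random_addition_tree(m, seed)
        assert t.bipartitions() == true.bipartitions()
        assert fitch_length(t, m) == m.n_characters  # one step per character


def test_addition_trees_never_beat_the_exhaustive_minimum():
    rng = np.random.default_rng(13)
    m = random_matrix(rng, 6, 8, k=2)
    _, best = enumerate_trees(m)
    for seed in (1, 2):
        assert fitch_length(random_addition_tree(m, seed), m) >= best


def test_tbr_neighbors_are_valid_trees_and_include_nni():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, 6, 4)
    t = random_tree(rng, m.taxa)
    adj = tree_to_adj(t, m)
    from morphoclad.search import _bipart_key
    base = _bipart_key(adj, 6)
    keys = set()
    count = 0
    for nb in tbr_neighbors(adj, 6):
        count += 1
        degrees = sorted(len(v) for v in nb.values())
        # unrooted binary: n leaves of degree 1, n-2 internals of degree 3
        assert degrees == [1] * 6 + [3] * 4
        keys.add(_bipart_key(nb, 6))
    assert count > 50                      # a rich neighbourhood...
    assert any(len(base ^ k) == 2 for k in keys)   # ...including every NNI
    assert len(keys) > 10                  # many distinct topologies


def test_tbr_from_optimal_start_keeps_exhaustive_minimum():
    rng = np.random.default_rng(21)
    for trial in range(5):
        m = random_matrix(rng, 6, 10, k=2)
        ex = exhaustive_search(m)
        ts = tbr_search(ex.trees[0], m, SearchConfig(hold_per_replicate=10))
        assert ts.length == ex.length


def test_flat_landscape_caps_held_trees():
    # one informative character: huge plateau of equally short trees
    m = mk({"A": "1", "B": "1", "C": "0", "D": "0", "E": "0", "F": "0"})
    start = random_addition_tree(m, seed=1)
    ts = tbr_search(start, m, SearchConfig(hold_per_replicate=7))
    assert len(ts) <= 7
    assert ts.length == 1


def test_heuristic_matches_exhaustive_on_random_matrices():
    rng = np.random.default_rng(37)
    cfg = SearchConfig(n_replicates=3, hold_per_replicate=5, seed=5)
    for _ in range(20):
        n = int(rng.integers(6, 8))
        m = random_matrix(rng, n, 12, k=2, p_unknown=0.1)
        _, best = enumerate_trees(m)
        ts = heuristic_search(m, cfg)
        assert ts.length == best


def test_search_is_reproducible_and_deduplicated():
    ds = simulate_dataset(SimulationConfig.strong_signal(10), seed=6)
    cfg = SearchConfig(n_replicates=3, hold_per_replicate=5, seed=9)
    a = heuristic_search(ds.masked, cfg)
    b = heuristic_search(ds.masked, cfg)
    assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]
    keys = [frozenset(t.bipartitions()) for t in a.trees]
    assert len(set(keys)) == len(keys)
    for t in a.trees:
        assert fitch_length(t, ds.masked) == a.length


def test_mpt_count_invariant_to_taxon_input_order():
    rng = np.random.default_rng(55)
    m = random_matrix(rng, 7, 10, k=2)
    perm = list(rng.permutation(7))
    m2 = CharacterMatrix([m.taxa[i] for i in perm], m.characters,
                         [m.cells[i] for i in perm])
    cfg = SearchConfig(n_replicates=5, hold_per_replicate=20, seed=3)
    a, b = heuristic_search(m, cfg), heuristic_search(m2, cfg)
    assert a.length == b.length
    assert len(a) == len(b)


def test_exhaustive_counts_and_refusal():
    m3 = random_matrix(np.random.default_rng(1), 3, 2)
    kept, _ = enumerate_trees(m3, slack=10 ** 6)
    assert len(kept) == 1
    m5 = random_matrix(np.random.default_rng(1), 5, 2)
    kept, _ = enumerate_trees(m5, slack=10 ** 6)
    assert len(kept) == 15  # (2*5-5)!! unrooted topologies
    with pytest.raises(ValueError, match="refused"):
        enumerate_trees(random_matrix(np.random.default_rng(1), 10, 2))


def test_exhaustive_finds_the_supported_quartet():
    m = column_matrix([0, 0, 1, 1], k=2)
    ts = exhaustive_search(m)
    assert len(ts) == 1
    assert ts.trees[0].bipartitions() == {frozenset({"C", "D"})}


def test_collapse_rules_distinguish_ambiguous_branches():
    """Enumerate 5-taxon binary characters to find a branch whose change
    count over optimal reconstructions is min 0 / max 1: it must collapse
    under min_zero but survive under max_zero."""
    tree = PhyloTree.from_newick("(((A,B),C),(D,E));")
    from morphoclad.parsimony import branch_lengths_minmax
    found_ambiguous = found_forced = False
    for bits in range(2 ** 5):
        states = [(bits >> i) & 1 for i in range(5)]
        m = column_matrix(states, k=2)
        mins, maxs = branch_lengths_minmax(tree, m)
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n.parent is not None
                    and n.parent.parent is not None]
        for node in internal:
            mn, mx = mins[id(node)], maxs[id(node)]
            if (mn, mx) == (0, 1):
                found_ambiguous = True
                c_min = collapse_branches(tree, m, "min_zero")
                c_max = collapse_branches(tree, m, "max_zero")
                assert len(c_min.bipartitions()) < len(c_max.bipartitions())
            if mn >= 1:
                found_forced = True
                c_both = collapse_branches(tree, m, "max_zero")
                assert len(c_both.bipartitions()) >= 1
    assert found_ambiguous and found_forced


def test_collapse_zero_change_branch_under_both_rules():
    # constant character: every internal branch collapses either way
    m = column_matrix([0, 0, 0, 0, 0], k=2)
    tree = PhyloTree.from_newick("(((A,B),C),(D,E));")
    for rule in ("min_zero", "max_zero"):
        assert collapse_branches(tree, m, rule).bipartitions() == set()
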