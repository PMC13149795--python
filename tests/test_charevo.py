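"""Character mapping policies, branch-group assignment, segment rates."""

import numpy as np
import pytest

from morphoclad.charevo import (assign_branches, optimize_all,
                                optimize_character, segment_rates)
from morphoclad.matrix import GroupDefinition
from morphoclad.parsimony import fitch_length
from morphoclad.trees import PhyloTree
from util import column_matrix, random_matrix, random_tree

QUARTET = "((A,B),(C,D));"


def test_unambiguous_synapomorphy_all_policies():
    m = column_matrix([0, 0, 1, 1], k=2)
    t = PhyloTree.from_newick(QUARTET)
    for policy in ("acctran", "deltran", "mpr_average"):
        rec = optimize_character(t, m, 1, policy)
        assert rec.total == 1
        # the single change sits on an internal branch in every policy
        leaf_changes = sum(
            rec.branch_changes[id(n)] for n in t.postorder()
            if n.is_leaf and id(n) in rec.branch_changes)
        assert leaf_changes == 0


def test_conflict_character_totals_agree_and_average_splits_ambiguity():
    m = column_matrix([0, 1, 0, 1], k=2)
    t = PhyloTree.from_newick(QUARTET)
    rec_a = optimize_character(t, m, 1, "acctran")
    rec_d = optimize_character(t, m, 1, "deltran")
    assert rec_a.total == rec_d.total == 2
    rec_m = optimize_character(t, m, 1, "mpr_average")
    assert rec_m.total == pytest.approx(2.0)
    # the two reconstructions (changes on B,D or on A,C) average to 0.5
    # on every terminal branch
    for n in t.postorder():
        if n.is_leaf:
            assert rec_m.branch_changes[id(n)] == pytest.approx(0.5)


def test_acctran_prefers_reversal_deltran_prefers_parallelism():
    """Search small binary patterns on a 5-taxon ladder for a case where
    the two policies genuinely place changes on different branches."""
    t = PhyloTree.from_newick("((((A,B),C),D),E);")
    differing = 0
    for bits in range(2 ** 5):
        states = [(bits >> i) & 1 for i in range(5)]
        m = column_matrix(states, k=2)
        rec_a = optimize_character(t, m, 1, "acctran")
        rec_d = optimize_character(t, m, 1, "deltran")
        assert rec_a.total == rec_d.total
        if rec_a.branch_changes != rec_d.branch_changes:
            differing += 1
    assert differing > 0


def test_constant_character_maps_no_changes():
    m = column_matrix([0, 0, 0, 0], k=2)
    t = PhyloTree.from_newick(QUARTET)
    rec = optimize_character(t, m, 1, "acctran")
    assert rec.total == 0
    assert all(v == 0 for v in rec.branch_changes.values())


def test_polytomy_three_states_two_changes():
    m = column_matrix([0, 1, 2], k=3)
    t = PhyloTree.from_newick("(A,B,C);")
    for policy in ("acctran", "deltran", "mpr_average"):
        assert optimize_character(t, m, 1, policy).total == pytest.approx(2)


def test_unknown_policy_rejected():
    m = column_matrix([0, 1], k=2)
    t = PhyloTree.from_newick("(A,B);")
    with pytest.raises(ValueError, match="policy"):
        optimize_character(t, m, 1, "parsimonious-ish")


def test_policy_totals_equal_fitch_steps_on_random_inputs():
    rng = np.random.default_rng(61)
    for _ in range(15):
        m = random_matrix(rng, 7, 8, k=3, p_unknown=0.15)
        t = random_tree(rng, m.taxa)
        _, per_char = fitch_length(t, m, per_character=True)
        for policy in ("acctran", "deltran", "mpr_average"):
            recs, _ = optimize_all(t, m, policy)
            for rec, steps in zip(recs, per_char):
                assert rec.total == pytest.approx(int(steps), abs=1e-9)


def test_assign_branches_terminal_internal_and_spine():
    t = PhyloTree.from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    groups = [GroupDefinition("left", frozenset("ABCD")),
              GroupDefinition("right", frozenset("EF"))]
    bg = assign_branches(t, groups)
    by_leafset = {}
    below = t.leafset_below()
    for n in t.postorder():
        if n.parent is not None:
            by_leafset[below[id(n)]] = bg[id(n)]
    assert by_leafset[frozenset("A")] == "left"          # terminal branch
    assert by_leafset[frozenset("AB")] == "left"         # internal, inside
    assert by_leafset[frozenset("ABCD")] == "left"
    assert by_leafset[frozenset("EF")] == "right"
    # G, H belong to no group: their branches and any branch spanning
    # groups are unassigned
    assert by_leafset[frozenset("G")] is None
    assert by_leafset[frozenset("GH")] is None
    assert by_leafset[frozenset("EFGH")] == "right"  # only E,F assigned below


def test_assign_branches_spanning_two_groups_is_none():
    t = PhyloTree.from_newick("(((A,B),(C,D)),E);")
    groups = [GroupDefinition("g1", frozenset("AB")),
              GroupDefinition("g2", frozenset("CD"))]
    bg = assign_branches(t, groups)
    below = t.leafset_below()
    spanning = [bg[id(n)] for n in t.postorder()
                if n.parent is not None and below[id(n)] == frozenset("ABCD")]
    assert spanning == [None]


def test_overlapping_groups_rejected():
    t = PhyloTree.from_newick("((A,B),(C,D));")
    groups = [GroupDefinition("g1", frozenset("AB")),
              GroupDefinition("g2", frozenset("BC"))]
    with pytest.raises(ValueError, match="several groups"):
        assign_branches(t, groups)


def test_segment_rates_hand_counted_case():
    # one change strictly inside group A, which has 4 scorable taxa
    t = PhyloTree.from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    m = column_matrix([0, 0, 1, 1, 0, 0, 0, 0], k=2)
    groups = [GroupDefinition("ga", frozenset("ABCD")),
              GroupDefinition("gb", frozenset("EFGH"))]
    rt = segment_rates(t, m, groups, policy="acctran")
    assert rt.transitions.loc[1, "ga"] == pytest.approx(1.0)
    assert rt.transitions.loc[1, "gb"] == pytest.approx(0.0)
    assert rt.scorable.loc[1, "ga"] == 4
    assert rt.rates.loc[1, "ga"] == pytest.approx(0.25)
    assert rt.rates.loc[1, "gb"] == pytest.approx(0.0)


def test_segment_rates_exclude_unscorable_taxa_from_denominator():
    t = PhyloTree.from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    m = column_matrix([0, "?", 1, 1, 0, "-", 0, 0], k=2)
    groups = [GroupDefinition("ga", frozenset("ABCD")),
              GroupDefinition("gb", frozenset("EFGH"))]
    rt = segment_rates(t, m, groups)
    assert rt.scorable.loc[1, "ga"] == 3   # B unknown
    assert rt.scorable.loc[1, "gb"] == 3   # F inapplicable
    # a group with no scorable taxon yields an undefined (NaN) rate
    m2 = column_matrix([0, 0, 1, 1, "?", "?", "-", "?"], k=2)
    rt2 = segment_rates(t, m2, groups)
    assert np.isnan(rt2.rates.loc[1, "gb"])


def test_rates_invariant_to_child_rotation():
    rng = np.random.default_rng(71)
    m = random_matrix(rng, 8, 12, k=2, p_unknown=0.1)
    t = random_tree(rng, m.taxa)
    groups = [GroupDefinition("g1", frozenset(m.taxa[:4])),
              GroupDefinition("g2", frozenset(m.taxa[4:]))]
    r1 = segment_rates(t, m, groups)
    t2 = t.copy()
    for n in t2.postorder():
        n.children.reverse()
    r2 = segment_rates(t2, m, groups)
    assert np.allclose(r1.rates.fillna(-1).values,
                       r2.rates.fillna(-1).values)


def test_grouped_changes_never_exceed_total_transitions():
    rng = np.random.default_rng(79)
    m = random_matrix(rng, 8, 10, k=2)
    t = random_tree(rng, m.taxa)
    groups = [GroupDefinition("g1", frozenset(m.taxa[:3])),
              GroupDefinition("g2", frozenset(m.taxa[3:6]))]
    rt = segment_rates(t, m, groups)
    recs, _ = optimize_all(t, m, "acctran")
    for rec in recs:
        grouped = rt.transitions.loc[rec.char_id].sum()
        assert grouped <= rec.total + 1e-9


def test_category_stats_shape_and_overall_means():
    from morphoclad.simulate import SimulationConfig, simulate_dataset
    ds = simulate_dataset(SimulationConfig.strong_signal(10), seed=8)
    rt = segment_rates(ds.tree, ds.masked, ds.groups)
    stats = rt.category_stats
    assert set(stats.reset_index().category) == {
        "architectural", "wall_structure", "external_topography",
        "cellular", "pollination"}
    assert len(rt.overall_means) == 3
    assert (rt.rates.fillna(0).values >= 0).all()
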