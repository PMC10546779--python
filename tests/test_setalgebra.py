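"""Direction-aware set-algebra primitives against brute-force oracles."""

import numpy as np
import pytest

from mgcascade.model import AnnotatedGeneList, GeneEntry, RegulatedGeneSet
from mgcascade.setalgebra import (
    intersect_concordant,
    intersect_discordant,
    intersect_symbols,
    overlap,
    overlap_with_list,
    union_sets,
    venn_counts,
)

from .conftest import make_set, random_geneset


def brute_concordant(a, b):
    return {
        s for s in a.members
        if s in b.members and a.members[s].direction == b.members[s].direction
    }


def brute_discordant(a, b):
    return {
        s for s in a.members
        if s in b.members
        and None not in (a.members[s].direction, b.members[s].direction)
        and a.members[s].direction != b.members[s].direction
    }


@pytest.mark.parametrize("seed", [11, 23, 57])
def test_intersections_match_nested_loop(seed):
    rng = np.random.default_rng(seed)
    a = random_geneset(rng, "A", 300, universe=500)
    b = random_geneset(rng, "B", 300, universe=500)
    assert intersect_concordant(a, b).symbols() == brute_concordant(a, b)
    assert intersect_discordant(a, b).symbols() == brute_discordant(a, b)


@pytest.mark.parametrize("seed", range(12))
def test_concordant_plus_discordant_partitions_intersection(seed):
    rng = np.random.default_rng(seed)
    a = random_geneset(rng, "A", 200, universe=350)
    b = random_geneset(rng, "B", 200, universe=350)
    res = overlap(a, b)
    conc, disc = res.concordant.symbols(), res.discordant.symbols()
    assert conc.isdisjoint(disc)
    assert conc | disc | res.undirected == a.symbols() & b.symbols()
    assert intersect_symbols(a, b).symbols() == conc | disc


def test_intersection_edge_cases():
    empty = make_set("E", "human", {})
    s = make_set("S", "human", {"A": ("up", 2.0), "B": ("down", -2.0)})
    assert len(intersect_concordant(empty, s)) == 0
    assert len(intersect_discordant(s, s)) == 0  # a set cannot oppose itself
    assert intersect_concordant(s, s).symbols() == {"A", "B"}


def test_cross_species_matching_is_symmetric():
    rng = np.random.default_rng(99)
    a = random_geneset(rng, "A", 150, universe=250, species="human")
    b = random_geneset(rng, "B", 150, universe=250, species="mouse")
    assert intersect_concordant(a, b).symbols() == intersect_concordant(b, a).symbols()
    assert intersect_discordant(a, b).symbols() == intersect_discordant(b, a).symbols()
    assert intersect_concordant(a, b).species == "cross"


def test_overlap_with_list_is_filter():
    s = make_set("S", "human", {"A": ("up", 2.0), "B": ("down", -2.0), "C": ("up", 3.0)})
    l = AnnotatedGeneList("L", frozenset({"A", "C", "Z"}))
    out = overlap_with_list(s, l)
    assert out.symbols() == {"A", "C"}
    assert out.members["A"].direction == "up"
    assert out.members["A"].avg_fc == 2.0
    assert "L" in out.members["A"].sources  # list name joins the provenance
    assert len(overlap_with_list(s, AnnotatedGeneList("E", frozenset()))) == 0


@pytest.mark.parametrize("seed", [3, 17])
def test_overlap_with_list_subset_and_monotone(seed):
    rng = np.random.default_rng(seed)
    s = random_geneset(rng, "S", 200, universe=300)
    small = frozenset(f"G{i:04d}" for i in rng.choice(300, 80, replace=False))
    big = small | frozenset(f"G{i:04d}" for i in rng.choice(300, 80, replace=False))
    out_small = overlap_with_list(s, AnnotatedGeneList("Ls", small))
    out_big = overlap_with_list(s, AnnotatedGeneList("Lb", big))
    assert out_small.symbols() <= s.symbols()
    assert out_small.symbols() <= out_big.symbols()
    assert out_small.symbols() == s.symbols() & small


def test_union_disjoint_and_conflicting():
    a = make_set("A", "human", {"X": ("up", 2.0), "Y": ("up", 2.0)})
    b = make_set("B", "mouse", {"Z": ("down", -2.0), "W": ("down", -3.0), "V": ("up", 1.5)})
    assert len(union_sets([a, b])) == 5
    c = make_set("C", "mouse", {"X": ("down", -2.0)})
    u = union_sets([a, c])
    assert u.members["X"].ambiguous
    assert u.members["X"].direction is None
    assert set(u.members["X"].source_directions) == {("A", "up"), ("C", "down")}
    assert not u.members["Y"].ambiguous


@pytest.mark.parametrize("seed", [29, 31])
def test_union_algebraic_properties(seed):
    rng = np.random.default_rng(seed)
    sets = [random_geneset(rng, n, 120, universe=200) for n in "ABC"]
    tally = set().union(*(s.symbols() for s in sets))
    u = union_sets(sets)
    assert u.symbols() == tally
    # commutative and associative on membership
    assert union_sets(sets[::-1]).symbols() == tally
    assert union_sets([union_sets(sets[:2]), sets[2]]).symbols() == tally
    # idempotent on duplicated input
    assert union_sets(sets + sets).symbols() == tally
    dup = union_sets([sets[0], sets[0]])
    assert dup.members == sets[0].members or all(
        dup.members[s].direction == sets[0].members[s].direction for s in dup.members
    )


def test_venn_two_sets_disjoint():
    a = make_set("A", "human", {"X": ("up", 2.0), "Y": ("up", 2.0)})
    b = make_set("B", "human", {"P": ("up", 2.0), "Q": ("up", 2.0), "R": ("up", 2.0)})
    assert venn_counts([a, b]) == {"A": 2, "B": 3, "A&B": 0}


@pytest.mark.parametrize("seed", [7, 41])
def test_venn_three_sets_matches_tally_and_sums_to_union(seed):
    rng = np.random.default_rng(seed)
    sets = [random_geneset(rng, n, 100, universe=160) for n in "ABC"]
    regions = venn_counts(sets)
    assert len(regions) == 7
    assert all(v >= 0 for v in regions.values())
    assert sum(regions.values()) == len(set().union(*(s.symbols() for s in sets)))
    syms = {s.name: s.symbols() for s in sets}
    only_ab = (syms["A"] & syms["B"]) - syms["C"]
    assert regions["A&B"] == len(only_ab)
    assert regions["A&B&C"] == len(syms["A"] & syms["B"] & syms["C"])


def test_venn_rejects_more_than_three_sets():
    s = [make_set(n, "human", {}) for n in "ABCD"]
    with pytest.raises(ValueError):
        venn_counts(s)
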