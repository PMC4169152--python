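"""Funnel-design combinatorics, replicated selection, substitution, RIL
allocation and pedigree structure."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magicpop import design as dz


def brute_force_two_way(n):
    return {frozenset(p) for p in itertools.combinations(range(n), 2)}


def brute_force_four_way(n):
    pairs = list(brute_force_two_way(n))
    out = set()
    for a, b in itertools.combinations(pairs, 2):
        if not a & b:
            out.add(frozenset((a, b)))
    return out


@pytest.mark.parametrize("n,expected", [(2, 1), (4, 6), (8, 28)])
def test_two_way_counts_match_brute_force(n, expected):
    crosses = dz.enumerate_two_way(n)
    assert len(crosses) == expected == len(brute_force_two_way(n))
    assert len({c.id for c in crosses}) == len(crosses)  # ids unique
    # reciprocal crosses are identified
    assert dz.TwoWayCross(("B", "A")) == dz.TwoWayCross(("A", "B"))


def test_two_way_rejects_single_founder():
    with pytest.raises(dz.DesignError):
        dz.enumerate_two_way(1)


@pytest.mark.parametrize("n,expected", [(3, 0), (4, 3), (8, 210)])
def test_four_way_counts_match_brute_force(n, expected):
    crosses = dz.enumerate_four_way(n)
    assert len(crosses) == expected == len(brute_force_four_way(n))
    assert len(crosses) == n * (n - 1) * (n - 2) * (n - 3) // 8
    for c in crosses:
        assert len(c.founder_set) == 4


def test_eight_way_pairing_structure():
    fourways = dz.enumerate_four_way(8)
    eightways = dz.enumerate_eight_way(fourways)
    assert len(eightways) == 315
    usage = Counter()
    for ew in eightways:
        assert len(ew.founder_set) == 8
        a, b = ew.fourway_pair
        assert not a.founder_set & b.founder_set
        usage[a.id] += 1
        usage[b.id] += 1
    # every four-way participates in exactly 3 eight-ways; handshake identity
    assert set(usage.values()) == {3}
    assert len(eightways) == 210 * 3 // 2
    # the four-way on {A,B,C,D} pairs with the 3 pairings of {E,F,G,H}
    abcd = [fw for fw in fourways if fw.founder_set == frozenset("ABCD")][0]
    mates = [ew for ew in eightways if abcd in ew.fourway_pair]
    assert len(mates) == 3


def test_eight_way_rejects_incomplete_fourway_list():
    fourways = dz.enumerate_four_way(8)
    with pytest.raises(dz.DesignError):
        dz.enumerate_eight_way(fourways[:-1])


@pytest.mark.parametrize("usage,expected", [(1, 105), (2, 210), (3, 315)])
def test_replicated_selection_usage(usage, expected):
    eightways = dz.enumerate_eight_way(dz.enumerate_four_way(8))
    plan = dz.select_replicated_eight_ways(eightways, per_fourway_usage=usage, seed=3)
    assert len(plan.eightways) == expected
    # independent tally oracle
    tally = Counter()
    for ew in plan.eightways:
        for fw in ew.fourway_pair:
            tally[fw.id] += 1
    assert set(tally.values()) == {usage}
    assert len(tally) == 210


def test_replicated_selection_removes_perfect_matching():
    eightways = dz.enumerate_eight_way(dz.enumerate_four_way(8))
    plan = dz.select_replicated_eight_ways(eightways, per_fourway_usage=2, seed=5)
    removed = set(e.id for e in eightways) - set(e.id for e in plan.eightways)
    assert len(removed) == 105
    seen = Counter()
    for ew in eightways:
        if ew.id in removed:
            for fw in ew.fourway_pair:
                seen[fw.id] += 1
    assert set(seen.values()) == {1} and len(seen) == 210  # a perfect matching


def test_replicated_selection_deterministic_per_seed():
    eightways = dz.enumerate_eight_way(dz.enumerate_four_way(8))
    a = dz.select_replicated_eight_ways(eightways, 2, seed=9)
    b = dz.select_replicated_eight_ways(eightways, 2, seed=9)
    assert [e.id for e in a.eightways] == [e.id for e in b.eightways]


def _toy_plan():
    fourways = dz.enumerate_four_way(8)
    eightways = dz.enumerate_eight_way(fourways)
    return dz.CrossPlan(
        founders=dz.default_founders(8),
        twoways=dz.enumerate_two_way(8),
        fourways=fourways,
        eightways=eightways,
    )


def test_substitute_prefers_shared_components():
    # restricted candidate set: ABCE-type (3 shared founders) beats ABEF (2)
    tw = {p: dz.TwoWayCross(tuple(p)) for p in ("AB", "CD", "CE", "EF")}
    restricted = dz.CrossPlan(
        founders=list("ABCDEF"),
        twoways=sorted(tw.values()),
        fourways=sorted([
            dz.FourWayCross((tw["AB"], tw["CD"])),
            dz.FourWayCross((tw["AB"], tw["CE"])),
            dz.FourWayCross((tw["AB"], tw["EF"])),
        ]),
        eightways=[],
    )
    assert dz.substitute_failed_cross(restricted, "(AxB)(CxD)") == "(AxB)(CxE)"

    plan = _toy_plan()
    # full plan: a four-way on the same founder set (overlap 4) wins outright
    failed = "(AxB)(CxD)"
    sub, _ = plan.find_cross(dz.substitute_failed_cross(plan, failed))
    failed_cross, _ = plan.find_cross(failed)
    best = max(
        len(failed_cross.founder_set & c.founder_set)
        for c in plan.fourways if c.id != failed
    )
    assert len(failed_cross.founder_set & sub.founder_set) == best
    # eight-way tier: candidate sharing a four-way beats one sharing none
    failed_ew = plan.eightways[0].id
    sub_id = dz.substitute_failed_cross(plan, failed_ew)
    failed_obj, _ = plan.find_cross(failed_ew)
    sub_obj, _ = plan.find_cross(sub_id)
    assert sub_id != failed_ew
    assert len(failed_obj.fourway_set & sub_obj.fourway_set) == 1  # max possible


def test_substitute_requires_known_cross():
    plan = _toy_plan()
    with pytest.raises(dz.DesignError):
        dz.substitute_failed_cross(plan, "(ZxQ)(RxS)")


def test_allocate_rils_known_splits():
    fams = [f"f{i:03d}" for i in range(210)]
    alloc = dz.allocate_rils(fams, 1091)
    counts = Counter(alloc.values())
    assert counts == {6: 41, 5: 169}
    assert sum(alloc.values()) == 1091
    assert dz.allocate_rils(["only"], 10) == {"only": 10}
    assert set(dz.allocate_rils(["a", "b", "c"], 3).values()) == {1}


@settings(max_examples=50, deadline=None)
@given(n_fam=st.integers(1, 40), total=st.integers(0, 500))
def test_allocate_rils_conserves_and_balances(n_fam, total):
    alloc = dz.allocate_rils([f"f{i}" for i in range(n_fam)], total)
    vals = list(alloc.values())
    assert sum(vals) == total
    assert max(vals) - min(vals) <= 1


@pytest.mark.parametrize("ssd,terminal", [(0, "F1"), (3, "F4"), (6, "F7")])
def test_pedigree_generation_labels(ssd, terminal):
    plan = _toy_plan()
    fams = [e.id for e in plan.eightways[:4]]
    ped = dz.build_pedigree(plan, dz.allocate_rils(fams, 8), ssd)
    assert ped.terminal_generation == terminal
    assert len(ped.terminal_lines) == 8
    if ssd > 0:
        # chain per RIL: F1 plant + one record per selfing generation
        line = ped.terminal_lines[0]
        assert len(ped.chain(line)) == ssd + 1


def test_pedigree_strata_shared_plants():
    plan = _toy_plan()
    fams = [e.id for e in plan.eightways[:3]]
    ped = dz.build_pedigree(plan, dz.allocate_rils(fams, 12), 2, rils_per_f1_plant=2)
    strata = ped.strata()
    assert set(strata["funnel"]) == set(fams)
    # 4 RILs per family share 2 plants pairwise
    for fam in fams:
        plants = strata.loc[strata["funnel"] == fam, "f1_plant"]
        assert sorted(Counter(plants).values()) == [2, 2]


def test_pedigree_rejects_unknown_family():
    plan = _toy_plan()
    with pytest.raises(dz.DesignError):
        dz.build_pedigree(plan, {"not-a-family": 3}, 2)
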