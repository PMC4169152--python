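"""Funnel crossing designs for multiparent (MAGIC) populations.

An eight-founder MAGIC funnel has the form {[(AxB) x (CxD)] x [(ExF) x (GxH)]}:
four two-way crosses, two four-way crosses and one eight-way cross combine all
eight founders into a single pedigree.  Reciprocal crosses are identified, so
for n = 8 founders there are 28 two-way, 210 four-way and 315 eight-way
crosses.  This module enumerates those designs, selects replicated subsets
(e.g. every four-way used exactly twice), substitutes failed crosses by
relatedness, allocates recombinant inbred lines (RILs) to families and builds
the pedigree skeleton for single seed descent (SSD).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TwoWayCross",
    "FourWayCross",
    "EightWayCross",
    "CrossPlan",
    "Pedigree",
    "DesignError",
    "enumerate_two_way",
    "enumerate_four_way",
    "enumerate_eight_way",
    "select_replicated_eight_ways",
    "substitute_failed_cross",
    "allocate_rils",
    "build_pedigree",
    "default_founders",
]


class DesignError(ValueError):
    """Invalid or infeasible crossing-design request."""


def default_founders(n: int) -> list[str]:
    """Single-letter founder labels A, B, C, ... for n founders."""
    if n > 26:
        return [f"F{i:02d}" for i in range(n)]
    return [chr(ord("A") + i) for i in range(n)]


@dataclass(frozen=True, order=True)
class TwoWayCross:
    """Unordered cross between two distinct founders (reciprocals identified)."""

    parents: tuple[str, str]

    def __post_init__(self):
        if len(self.parents) != 2 or self.parents[0] == self.parents[1]:
            raise DesignError(f"two-way cross needs two distinct parents, got {self.parents}")
        object.__setattr__(self, "parents", tuple(sorted(self.parents)))

    @property
    def founder_set(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def id(self) -> str:
        return "x".join(self.parents)

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True, order=True)
class FourWayCross:
    """Unordered pair of founder-disjoint two-way crosses (an F1 x F1 cross)."""

    f1_pair: tuple[TwoWayCross, TwoWayCross]

    def __post_init__(self):
        a, b = self.f1_pair
        if a.founder_set & b.founder_set:
            raise DesignError(f"four-way cross requires disjoint F1s: {a} / {b}")
        object.__setattr__(self, "f1_pair", tuple(sorted(self.f1_pair)))

    @property
    def founder_set(self) -> frozenset[str]:
        return self.f1_pair[0].founder_set | self.f1_pair[1].founder_set

    @property
    def twoway_set(self) -> frozenset[TwoWayCross]:
        return frozenset(self.f1_pair)

    @property
    def id(self) -> str:
        return f"({self.f1_pair[0].id})({self.f1_pair[1].id})"

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True, order=True)
class EightWayCross:
    """Unordered pair of four-way crosses with complementary founder sets."""

    fourway_pair: tuple[FourWayCross, FourWayCross]

    def __post_init__(self):
        a, b = self.fourway_pair
        if a.founder_set & b.founder_set:
            pass
        else:
            object.__setattr__(self, "fourway_pair", tuple(sorted(self.fourway_pair)))
            return
        raise DesignError(f"eight-way cross requires complementary four-ways: {a} / {b}")

    @property
    def founder_set(self) -> frozenset[str]:
        return self.fourway_pair[0].founder_set | self.fourway_pair[1].founder_set

    @property
    def fourway_set(self) -> frozenset[FourWayCross]:
        return frozenset(self.fourway_pair)

    @property
    def twoway_set(self) -> frozenset[TwoWayCross]:
        return self.fourway_pair[0].twoway_set | self.fourway_pair[1].twoway_set

    @property
    def id(self) -> str:
        return f"[{self.fourway_pair[0].id}][{self.fourway_pair[1].id}]"

    def __str__(self) -> str:
        return self.id


@dataclass
class CrossPlan:
    """A selected funnel design: founders and the crosses actually made."""

    founders: list[str]
    twoways: list[TwoWayCross]
    fourways: list[FourWayCross]
    eightways: list[EightWayCross]

    def __post_init__(self):
        known = {fw.id for fw in self.fourways}
        for ew in self.eightways:
            for fw in ew.fourway_pair:
                if fw.id not in known:
                    raise DesignError(f"eight-way {ew.id} references unknown four-way {fw.id}")

    @property
    def usage_count(self) -> Counter:
        """Number of selected eight-way crosses each four-way participates in."""
        c: Counter = Counter()
        for ew in self.eightways:
            for fw in ew.fourway_pair:
                c[fw.id] += 1
        return c

    def find_cross(self, cross_id: str):
        for tier in (self.eightways, self.fourways, self.twoways):
            for cr in tier:
                if cr.id == cross_id:
                    return cr, tier
        raise DesignError(f"cross {cross_id!r} not in plan")


PEDIGREE_COLUMNS = ["line_id", "family_id", "generation", "parent_id"]


@dataclass
class Pedigree:
    """Descent records: one row per individual, parent_id links the chain.

    F1 rows descend from an eight-way cross (parent_id = family/cross id);
    later generations descend by selfing from the previous record.  Terminal
    rows (generation F(1+ssd)) are the RILs.
    """

    records: pd.DataFrame
    ssd_generations: int

    def __post_init__(self):
        missing = set(PEDIGREE_COLUMNS) - set(self.records.columns)
        if missing:
            raise DesignError(f"pedigree missing columns {sorted(missing)}")

    @property
    def terminal_generation(self) -> str:
        return f"F{1 + self.ssd_generations}"

    @property
    def terminal_lines(self) -> list[str]:
        g = self.records
        return g.loc[g["generation"] == self.terminal_generation, "line_id"].tolist()

    def chain(self, line_id: str) -> list[str]:
        """Ancestor record ids from line back to (not including) the cross."""
        by_id = self.records.set_index("line_id")
        out = [line_id]
        fam = by_id.at[line_id, "family_id"]
        cur = by_id.at[line_id, "parent_id"]
        while cur in by_id.index:
            out.append(cur)
            if by_id.at[cur, "family_id"] != fam:
                raise DesignError(f"pedigree chain of {line_id} crosses families")
            cur = by_id.at[cur, "parent_id"]
        return out

    def strata(self) -> pd.DataFrame:
        """Per terminal line: funnel (eight-way family) and the eight-way F1
        plant it descends from (the 'outcrossed plant within funnel')."""
        parent = dict(zip(self.records["line_id"], self.records["parent_id"]))
        family = dict(zip(self.records["line_id"], self.records["family_id"]))
        rows = []
        for line in self.terminal_lines:
            cur = line
            while parent[cur] in parent:
                cur = parent[cur]
            rows.append((line, family[line], cur))
        return pd.DataFrame(rows, columns=["line_id", "funnel", "f1_plant"]).set_index("line_id")


def enumerate_two_way(n_founders: int, founders: list[str] | None = None) -> list[TwoWayCross]:
    """All unordered founder pairs; n(n-1)/2 crosses for n founders."""
    if n_founders < 2:
        raise DesignError("need at least 2 founders for a two-way cross")
    founders = founders or default_founders(n_founders)
    return [TwoWayCross(pair) for pair in itertools.combinations(sorted(founders), 2)]


def enumerate_four_way(n_founders: int, founders: list[str] | None = None) -> list[FourWayCross]:
    """All unordered pairs of founder-disjoint two-way crosses.

    Count is n(n-1)(n-2)(n-3)/8; for fewer than 4 founders no disjoint
    pair exists and the list is empty.
    """
    if n_founders < 1:
        raise DesignError("n_founders must be positive")
    twoways = enumerate_two_way(n_founders, founders) if n_founders >= 2 else []
    out = []
    for a, b in itertools.combinations(twoways, 2):
        if not (a.founder_set & b.founder_set):
            out.append(FourWayCross((a, b)))
    return sorted(out)


def enumerate_eight_way(fourways: list[FourWayCross]) -> list[EightWayCross]:
    """All unordered pairs of complementary four-way crosses.

    Requires the complete four-way list for 8 founders (210 crosses); each
    four-way then participates in exactly 3 eight-ways, giving 315 in all.
    """
    founders = sorted(set().union(*(fw.founder_set for fw in fourways))) if fourways else []
    n = len(founders)
    expected = n * (n - 1) * (n - 2) * (n - 3) // 8
    if n != 8 or len(set(fourways)) != expected:
        raise DesignError(
            f"expected the complete four-way list for 8 founders ({expected} crosses), "
            f"got {len(set(fourways))} over {n} founders"
        )
    by_set: dict[frozenset, list[FourWayCross]] = {}
    for fw in fourways:
        by_set.setdefault(fw.founder_set, []).append(fw)
    all_f = frozenset(founders)
    out = set()
    for fw in fourways:
        for mate in by_set.get(all_f - fw.founder_set, []):
            out.add(EightWayCross((fw, mate)))
    return sorted(out)


def _pairing_graph(eightways: list[EightWayCross]) -> nx.Graph:
    g = nx.Graph()
    for ew in eightways:
        a, b = ew.fourway_pair
        g.add_edge(a, b, cross=ew)
    return g


def select_replicated_eight_ways(
    all_eightways: list[EightWayCross],
    per_fourway_usage: int = 2,
    seed: int = 0,
    max_restarts: int = 20,
) -> CrossPlan:
    """Select eight-way crosses so every four-way is used exactly `usage` times.

    The pairing graph (vertices = four-ways, edges = eight-ways) is 3-regular
    for 8 founders.  usage=3 keeps all edges; usage=2 removes a perfect
    matching (105 edges) leaving 210 crosses; usage=1 keeps a perfect
    matching.  The matching is found with seeded random edge weights
    (restarting with fresh weights if a maximum-weight matching is not
    perfect), so the selection is deterministic given the seed.
    """
    if not 1 <= per_fourway_usage <= 3:
        raise DesignError("per_fourway_usage must be in 1..3 for an 8-founder design")
    graph = _pairing_graph(all_eightways)
    degrees = {d for _, d in graph.degree()}
    if degrees != {3}:
        raise DesignError(f"pairing graph is not 3-regular (degrees {sorted(degrees)}); "
                          "pass the complete eight-way list")
    fourways = sorted(graph.nodes())
    if per_fourway_usage == 3:
        selected = sorted(all_eightways)
    else:
        rng = np.random.default_rng(seed)
        matching = None
        for _ in range(max_restarts):
            for u, v in graph.edges():
                graph[u][v]["weight"] = rng.random()
            cand = nx.max_weight_matching(graph, maxcardinality=True)
            if 2 * len(cand) == graph.number_of_nodes():
                matching = cand
                break
        if matching is None:
            raise DesignError("no perfect matching found in the pairing graph")
        matched_edges = {frozenset(e) for e in matching}
        if per_fourway_usage == 1:
            selected = sorted(
                graph[u][v]["cross"] for u, v in (tuple(e) for e in matched_edges)
            )
        else:  # usage == 2: full edge set minus the matching
            selected = sorted(
                d["cross"]
                for u, v, d in graph.edges(data=True)
                if frozenset((u, v)) not in matched_edges
            )
    plan = CrossPlan(
        founders=sorted(set().union(*(fw.founder_set for fw in fourways))),
        twoways=sorted({tw for fw in fourways for tw in fw.twoway_set}),
        fourways=fourways,
        eightways=selected,
    )
    usage = plan.usage_count
    bad = {k: v for k, v in usage.items() if v != per_fourway_usage}
    if bad or len(usage) != len(fourways):
        raise DesignError(f"selection infeasible: uneven four-way usage {bad}")
    return plan


def _relatedness(a, b) -> tuple:
    """Hierarchical relatedness of two same-tier crosses: shared founders
    first, then shared four-way and two-way components as tie-breaks (all
    eight-ways share all 8 founders, so their ranking falls to components)."""
    founders = len(a.founder_set & b.founder_set)
    four = len(getattr(a, "fourway_set", frozenset()) & getattr(b, "fourway_set", frozenset()))
    two = len(getattr(a, "twoway_set", frozenset()) & getattr(b, "twoway_set", frozenset()))
    return (founders, four, two)


def substitute_failed_cross(plan: CrossPlan, failed_cross_id: str, seed: int | None = None) -> str:
    """Most closely related same-tier cross in the plan, to substitute seed
    from when a cross fails.  Relatedness = shared component crosses, then
    shared founders; ties broken lexicographically on cross id.  `seed` is
    accepted for interface symmetry but the choice is deterministic.
    """
    failed, tier = plan.find_cross(failed_cross_id)
    candidates = [c for c in tier if c.id != failed_cross_id]
    if not candidates:
        raise DesignError(f"no same-tier substitute available for {failed_cross_id!r}")
    return min(candidates, key=lambda c: (tuple(-s for s in _relatedness(failed, c)), c.id)).id


def allocate_rils(families: list[str], total_lines: int) -> dict[str, int]:
    """Split total_lines across families as equally as possible (counts differ
    by at most one); the remainder goes to lexicographically first families."""
    if not families:
        raise DesignError("need at least one family")
    if total_lines < 0:
        raise DesignError("total_lines must be non-negative")
    fams = sorted(families)
    base, rem = divmod(total_lines, len(fams))
    return {f: base + (1 if i < rem else 0) for i, f in enumerate(fams)}


def build_pedigree(
    plan: CrossPlan,
    allocation: dict[str, int],
    ssd_generations: int,
    rils_per_f1_plant: int = 1,
) -> Pedigree:
    """Pedigree skeleton: per RIL one descent chain from an eight-way F1
    through `ssd_generations` selfings (terminal generation F(1+ssd)).

    With rils_per_f1_plant > 1, consecutive RILs of a family share the same
    eight-way F1 plant, creating the 'outcrossed plants within funnels'
    stratum used by the association scan.
    """
    if ssd_generations < 0:
        raise DesignError("ssd_generations must be >= 0")
    if rils_per_f1_plant < 1:
        raise DesignError("rils_per_f1_plant must be >= 1")
    known = {ew.id for ew in plan.eightways}
    unknown = set(allocation) - known
    if unknown:
        raise DesignError(f"allocation references unknown families: {sorted(unknown)[:3]}")
    rows = []
    ril_no = 0
    terminal_gen = 1 + ssd_generations
    for fam_idx, fam in enumerate(sorted(allocation)):
        plants_made: set[str] = set()
        for j in range(allocation[fam]):
            ril_no += 1
            ril = f"MAGIC_{ril_no:05d}"
            if ssd_generations == 0:
                rows.append((ril, fam, "F1", fam))
                continue
            plant = f"FAM{fam_idx:03d}.P{j // rils_per_f1_plant:02d}"
            if plant not in plants_made:
                plants_made.add(plant)
                rows.append((plant, fam, "F1", fam))
            parent = plant
            for g in range(2, terminal_gen + 1):
                lid = ril if g == terminal_gen else f"{ril}.F{g}"
                rows.append((lid, fam, f"F{g}", parent))
                parent = lid
    df = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)
    if df["line_id"].duplicated().any():
        raise DesignError("duplicate line ids in pedigree")
    return Pedigree(records=df, ssd_generations=ssd_generations)
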