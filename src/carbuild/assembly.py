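"""Progressive CAR assembly: selection set-algebra, conflict resolution, driver.

Starting from one single-block CAR per block, the driver loops over three
kinds of productive steps until no adjacency can be added:

* **step a** — detect the conserved CAR adjacencies, split them into
  fully-conserved (FS) and partly-conserved (PS), and retain the
  structurally safe subset NC = FS_NC ∪ PS_NC² (non-conflicting
  fully-conserved adjacencies, plus non-conflicting partly-conserved ones
  compatible with every fully-conserved adjacency).  Partly-conserved
  adjacencies conflicting with FS_NC (the set PS_D) are discarded
  permanently.  The leftover conflicting set C is kept for step b.
* **step b** — runs when step a retained nothing but C is nonempty: pick
  the maximum-cardinality, minimum-total-mutation-cost non-conflicting
  subset of C; losers are discarded permanently.
* **step c** — runs when both NC and C are empty: add a maximum
  non-conflicting subset of the DCJ-reliable adjacencies; losers are
  discarded permanently.

Both optimization steps are solved exactly: a non-conflicting adjacency
set is precisely a matching of the graph whose vertices are block
extremities and whose edges are the candidate adjacencies, so maximum
cardinality / minimum cost reduces to maximum-weight matching with edge
weight K - cost (K exceeding any achievable total cost).  Ties are broken
deterministically toward the lexicographically smallest canonical
adjacency list by forcing edges one at a time and re-solving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .model import (
    Adjacency,
    CARSet,
    Genome,
    InvalidInputError,
    concatenate,
    conflicts,
)
from .detection import (
    ConservedAdjacencyRecord,
    classify_conserved,
    detect_dcj_reliable,
)
from .phylogeny import SpeciesPartition, SpeciesTree, mutation_cost, partition_of


@dataclass(frozen=True)
class SelectionPartition:
    """The step-a set algebra over the conserved adjacencies S."""

    s: frozenset[Adjacency]
    fs: frozenset[Adjacency]
    ps: frozenset[Adjacency]
    fs_nc: frozenset[Adjacency]
    fs_c: frozenset[Adjacency]
    ps_d: frozenset[Adjacency]
    ps_r: frozenset[Adjacency]
    ps_nc: frozenset[Adjacency]
    ps_nc2: frozenset[Adjacency]
    nc: frozenset[Adjacency]
    c: frozenset[Adjacency]


def select_step_a(records: Iterable[ConservedAdjacencyRecord]) -> SelectionPartition:
    """Split conserved adjacencies into retained (NC) and conflicting (C) sets.

    Fully-conserved adjacencies take priority: FS_NC (those compatible with
    all of FS) is retained outright, anything conflicting with FS_NC is
    discarded permanently (PS_D), and of the remaining partly-conserved
    adjacencies only those internally non-conflicting and compatible with
    the whole of FS (PS_NC²) join the retained set.
    """
    fs = frozenset(r.adjacency for r in records if r.conservation == "fully")
    ps = frozenset(r.adjacency for r in records if r.conservation == "partly")
    s = fs | ps

    fs_nc = frozenset(a for a in fs if not any(conflicts(a, b) for b in fs))
    fs_c = fs - fs_nc
    ps_d = frozenset(p for p in ps if any(conflicts(p, a) for a in fs_nc))
    ps_r = ps - ps_d
    ps_nc = frozenset(p for p in ps_r if not any(conflicts(p, q) for q in ps_r))
    ps_nc2 = frozenset(p for p in ps_nc if not any(conflicts(p, a) for a in fs))
    nc = fs_nc | ps_nc2
    c = s - ps_d - nc
    return SelectionPartition(s, fs, ps, fs_nc, fs_c, ps_d, ps_r, ps_nc, ps_nc2, nc, c)


def _matching_value(
    adjs: Sequence[Adjacency], cost: Mapping[Adjacency, int], k: int
) -> tuple[int, int]:
    """(max size, min cost at that size) over non-conflicting subsets."""
    graph = nx.Graph()
    for a in adjs:
        e1, e2 = sorted(a.extremities())
        graph.add_edge(e1, e2, weight=k - cost[a], adj=a)
    matching = nx.max_weight_matching(graph, maxcardinality=False)
    size = len(matching)
    total = sum(cost[graph.edges[u, v]["adj"]] for u, v in matching)
    return size, total


def max_compatible_subset(
    candidates: Iterable[Adjacency],
    cost: Mapping[Adjacency, int] | None = None,
) -> tuple[list[Adjacency], list[Adjacency]]:
    """Exactly optimal non-conflicting subset: max size, then min cost.

    Returns (chosen, discarded), both sorted.  Among all optima the
    lexicographically smallest canonical adjacency list is returned, by
    greedily forcing each adjacency in canonical order and checking that
    the forced set still extends to an optimum (one matching call each).
    """
    cands = sorted(set(candidates))
    if cost is None:
        cost = {a: 0 for a in cands}
    for a in cands:
        if cost[a] < 0:
            raise InvalidInputError("adjacency costs must be non-negative")
    k = 1 + sum(cost[a] for a in cands)

    def best_with(forced: list[Adjacency]) -> tuple[int, int]:
        rest = [
            a
            for a in cands
            if a not in forced and not any(conflicts(a, f) for f in forced)
        ]
        size, total = _matching_value(rest, cost, k)
        return size + len(forced), total + sum(cost[f] for f in forced)

    target = best_with([])
    chosen: list[Adjacency] = []
    for a in cands:
        if any(conflicts(a, f) for f in chosen):
            continue
        if best_with(chosen + [a]) == target:
            chosen.append(a)
    assert (len(chosen), sum(cost[a] for a in chosen)) == target
    discarded = [a for a in cands if a not in chosen]
    return chosen, discarded


def resolve_step_b(
    c: Iterable[Adjacency], cost: Mapping[Adjacency, int]
) -> tuple[list[Adjacency], list[Adjacency]]:
    """Maximum-size, minimum-mutation-cost non-conflicting subset of C."""
    return max_compatible_subset(c, cost)


def select_step_c(
    candidates: Iterable[Adjacency],
) -> tuple[list[Adjacency], list[Adjacency]]:
    """Maximum-size non-conflicting subset of the DCJ-reliable adjacencies."""
    return max_compatible_subset(candidates, None)


@dataclass(frozen=True)
class StepReport:
    """Per-step log entry mirroring a reconstruction trajectory table."""

    step_index: int
    step_kind: str  # 'a', 'b' or 'c'
    n_cars_after: int
    car_size_range: tuple[int, int]
    n_added: int
    added: tuple[Adjacency, ...]
    discarded: tuple[Adjacency, ...]


@dataclass(frozen=True)
class DiscardEntry:
    adjacency: Adjacency
    step_index: int
    reason: str  # 'ps_d' | 'step_b_loser' | 'step_c_loser' | 'cycle_deferred'


class DiscardSet:
    """Permanently discarded adjacencies, with provenance.

    Monotone non-decreasing over a run; an adjacency recorded here is never
    re-detected or re-added.
    """

    def __init__(self) -> None:
        self._entries: dict[Adjacency, DiscardEntry] = {}

    def add(self, adjs: Iterable[Adjacency], step_index: int, reason: str) -> None:
        for a in adjs:
            self._entries.setdefault(a, DiscardEntry(a, step_index, reason))

    def __contains__(self, adj: Adjacency) -> bool:
        return adj in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def adjacencies(self) -> frozenset[Adjacency]:
        return frozenset(self._entries)

    def entries(self) -> list[DiscardEntry]:
        return sorted(self._entries.values(), key=lambda e: e.adjacency.sort_key())


@dataclass
class IterationTrace:
    """Snapshot of one detection round, for invariant auditing."""

    conserved: frozenset[Adjacency]
    internal_before: frozenset[Adjacency]
    selection: SelectionPartition
    # free extremity at each CAR end -> CAR id, before this round's additions
    car_ends_before: tuple = ()


@dataclass
class ReconstructionResult:
    car_set: CARSet
    reports: list[StepReport]
    discards: DiscardSet
    trace: list[IterationTrace] = field(default_factory=list)

    @property
    def n_adjacencies(self) -> int:
        return len(self.car_set.internal_adjacencies())


def _validate_inputs(genomes: Sequence[Genome], tree: SpeciesTree) -> None:
    if not genomes:
        raise InvalidInputError("no genomes given")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate genome names")
    if set(names) != set(tree.leaf_names):
        raise InvalidInputError(
            f"genome names {sorted(names)} do not match tree leaves "
            f"{sorted(tree.leaf_names)}"
        )
    universe = genomes[0].block_universe
    for g in genomes[1:]:
        if g.block_universe != universe:
            raise InvalidInputError(
                f"genome {g.name!r} does not share the block universe of "
                f"{genomes[0].name!r}"
            )


def reconstruct(
    genomes: Iterable[Genome],
    tree: SpeciesTree,
    max_iterations: int | None = None,
) -> ReconstructionResult:
    """Run the full progressive reconstruction at the tagged ancestor.

    Returns the final CAR set, the numbered reports of productive steps
    (steps that added at least one adjacency), the permanent discard set,
    and a per-detection-round trace for invariant checking.
    """
    genomes = sorted(genomes, key=lambda g: g.name)
    _validate_inputs(genomes, tree)
    part: SpeciesPartition = partition_of(tree)
    cs = CARSet.singletons(genomes[0].block_universe)
    discards = DiscardSet()
    reports: list[StepReport] = []
    trace: list[IterationTrace] = []
    step_no = 0
    # every iteration either merges CARs or permanently discards at least
    # one adjacency, so this guard is never reached on valid inputs
    limit = max_iterations or (len(cs) ** 2 + 4 * len(cs) + 16)

    def occupancy_of(record_map, adj):
        return record_map[adj].occupancy_map()

    for _ in range(limit):
        internal_before = cs.internal_adjacencies()
        records = classify_conserved(cs, genomes, part, discards.adjacencies())
        record_map = {r.adjacency: r for r in records}
        sel = select_step_a(records)
        trace.append(
            IterationTrace(
                sel.s,
                internal_before,
                sel,
                tuple(sorted(cs.end_extremities().items())),
            )
        )
        discards.add(sorted(sel.ps_d), step_no + 1, "ps_d")

        if sel.nc:
            res = concatenate(cs, sel.nc)
            discards.add(res.cycle_skipped, step_no + 1, "cycle_deferred")
            cs = res.car_set
            if res.added:
                step_no += 1
                reports.append(
                    StepReport(
                        step_no,
                        "a",
                        len(cs),
                        cs.sizes(),
                        len(res.added),
                        tuple(res.added),
                        tuple(sorted(sel.ps_d)),
                    )
                )
            continue

        if sel.c:
            costs = {
                a: mutation_cost(occupancy_of(record_map, a), tree) for a in sel.c
            }
            won, lost = resolve_step_b(sel.c, costs)
            discards.add(lost, step_no + 1, "step_b_loser")
            res = concatenate(cs, won)
            discards.add(res.cycle_skipped, step_no + 1, "cycle_deferred")
            cs = res.car_set
            if res.added:
                step_no += 1
                reports.append(
                    StepReport(
                        step_no,
                        "b",
                        len(cs),
                        cs.sizes(),
                        len(res.added),
                        tuple(res.added),
                        tuple(sorted(set(lost) | set(res.cycle_skipped))),
                    )
                )
            continue

        candidates = detect_dcj_reliable(cs, genomes, part, discards.adjacencies())
        if candidates:
            won, lost = select_step_c(candidates)
            discards.add(lost, step_no + 1, "step_c_loser")
            res = concatenate(cs, won)
            discards.add(res.cycle_skipped, step_no + 1, "cycle_deferred")
            cs = res.car_set
            if res.added:
                step_no += 1
                reports.append(
                    StepReport(
                        step_no,
                        "c",
                        len(cs),
                        cs.sizes(),
                        len(res.added),
                        tuple(res.added),
                        tuple(sorted(set(lost) | set(res.cycle_skipped))),
                    )
                )
            continue

        break
    else:
        raise RuntimeError("reconstruction did not converge within iteration limit")

    assert not (discards.adjacencies() & cs.internal_adjacencies())
    return ReconstructionResult(cs, reports, discards, trace)
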