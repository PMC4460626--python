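"""Detection of CAR adjacencies, conserved adjacencies and DCJ-reliable ones.

A *CAR adjacency* ``(car_a car_b)`` is a relaxed contiguity relation between
two of the current CARs, witnessed in an extant genome by a pair of
consecutive segments ``S_a`` (blocks of car_a only) and ``S_b`` (blocks of
car_b only).  The relation tolerates micro-rearrangements near the CAR
ends: with car_a read in some orientation as ``a_1 ... a_n`` the segment
``S_a`` must either

* (i)   be exactly the one-block segment ``{a_n}`` (signed match), or
* (ii)  have length > 1 and end with the unsigned block ``|a_n|``, or
* (iii) have length > 1 and be syntenic (same unsigned block set) to a
        contiguous segment of car_a containing ``|a_n|``;

symmetrically ``S_b`` must anchor the start ``b_1`` of car_b.  Tier (i) is
sign-sensitive, (ii) and (iii) are not.  The *block adjacency* carried by
the CAR adjacency is ``(a_n b_1)``.

Conserved CAR adjacencies (shared by genomes spanning two of the sets I1,
I2, O) feed step a) of the assembly; DCJ-reliable adjacencies — candidates
explained by a single Double-Cut-and-Join event against an extant genome —
feed step c).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Sequence

from .model import Adjacency, CARSet, Genome, InvalidInputError
from .phylogeny import (
    FULLY,
    PARTLY,
    SpeciesPartition,
    conservation_class,
    homoplasy_cost,
)

_ORIENT_KEY = {1: 0, -1: 1}


@dataclass(frozen=True)
class CARAdjacency:
    """An oriented CAR pair witnessed in one extant genome.

    Stored canonically under the identity
    ``(car_a car_b) = (-car_b -car_a)``.  ``a_end`` / ``b_start`` are the
    signed end blocks of the oriented CARs, so the induced block adjacency
    is ``(a_end b_start)``.  Witness metadata (genome, constraint tiers) is
    excluded from equality.
    """

    left_car: int
    left_orient: int
    right_car: int
    right_orient: int
    a_end: int
    b_start: int
    genome: str = field(compare=False, default="")
    left_tier: str = field(compare=False, default="")
    right_tier: str = field(compare=False, default="")

    def car_pair(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.left_car, self.left_orient), (self.right_car, self.right_orient))

    def block_adjacency(self) -> Adjacency:
        return Adjacency(self.a_end, self.b_start)


def make_car_adjacency(
    left_car: int,
    left_orient: int,
    right_car: int,
    right_orient: int,
    a_end: int,
    b_start: int,
    genome: str = "",
    left_tier: str = "",
    right_tier: str = "",
) -> CARAdjacency:
    """Build a :class:`CARAdjacency` in canonical orientation."""
    lhs = (left_car, _ORIENT_KEY[left_orient])
    rhs = (right_car, _ORIENT_KEY[-right_orient])
    if rhs < lhs:
        left_car, right_car = right_car, left_car
        left_orient, right_orient = -right_orient, -left_orient
        a_end, b_start = -b_start, -a_end
        left_tier, right_tier = right_tier, left_tier
    return CARAdjacency(
        left_car,
        left_orient,
        right_car,
        right_orient,
        a_end,
        b_start,
        genome,
        left_tier,
        right_tier,
    )


def block_adjacency_of(ca: CARAdjacency) -> Adjacency:
    """The block adjacency ``(a_n b_1)`` carried by a CAR adjacency."""
    return ca.block_adjacency()


def _left_tier(oriented_car: Sequence[int], run: Sequence[int]) -> str | None:
    """Which constraint tier some suffix of ``run`` satisfies for car end."""
    a_n = oriented_car[-1]
    if run[-1] == a_n:
        return "i"
    if len(run) > 1 and abs(run[-1]) == abs(a_n):
        return "ii"
    # tier iii: a suffix of the run syntenic to a segment of the car
    # containing |a_n|; such car segments are exactly the car's suffixes.
    for k in range(2, min(len(run), len(oriented_car)) + 1):
        if {abs(b) for b in run[-k:]} == {abs(b) for b in oriented_car[-k:]}:
            return "iii"
    return None


def _right_tier(oriented_car: Sequence[int], run: Sequence[int]) -> str | None:
    b_1 = oriented_car[0]
    if run[0] == b_1:
        return "i"
    if len(run) > 1 and abs(run[0]) == abs(b_1):
        return "ii"
    for k in range(2, min(len(run), len(oriented_car)) + 1):
        if {abs(b) for b in run[:k]} == {abs(b) for b in oriented_car[:k]}:
            return "iii"
    return None


def _runs(
    blocks: Sequence[int], circular: bool, car_of: dict[int, int]
) -> tuple[list[tuple[int, list[int]]], bool]:
    """Maximal runs of same-CAR blocks; second value: wrap boundary exists."""
    blocks = list(blocks)
    wrap = False
    if circular and len(blocks) > 1:
        cars = [car_of[abs(b)] for b in blocks]
        if len(set(cars)) == 1:
            return [(cars[0], blocks)], False
        # rotate so position 0 starts a new run
        i = next(i for i in range(len(blocks)) if cars[i] != cars[i - 1])
        blocks = blocks[i:] + blocks[:i]
        wrap = True
    runs: list[tuple[int, list[int]]] = []
    for b in blocks:
        cid = car_of[abs(b)]
        if runs and runs[-1][0] == cid:
            runs[-1][1].append(b)
        else:
            runs.append((cid, [b]))
    return runs, wrap


def detect_car_adjacencies(g: Genome, cs: CARSet) -> set[CARAdjacency]:
    """All CAR adjacencies of genome ``g`` given the current CAR set.

    Every boundary between a maximal run of one CAR's blocks and a maximal
    run of another's is tested under the four orientation combinations of
    the two CARs; each satisfied combination yields one CAR adjacency.
    Duplicate witnesses within the genome collapse to one record.
    """
    car_of = cs.car_of()
    missing = g.block_universe - cs.block_universe
    if missing:
        raise InvalidInputError(
            f"genome {g.name!r} has blocks outside the CAR universe: {sorted(missing)}"
        )
    found: dict[CARAdjacency, CARAdjacency] = {}
    for chrom in g.chromosomes:
        runs, wrap = _runs(chrom.blocks, chrom.circular, car_of)
        boundaries = list(zip(runs, runs[1:]))
        if wrap:
            boundaries.append((runs[-1], runs[0]))
        for (cid_l, run_l), (cid_r, run_r) in boundaries:
            if cid_l == cid_r:
                continue
            for orient_l in (1, -1):
                seq_l = cs[cid_l].oriented(orient_l)
                tier_l = _left_tier(seq_l, run_l)
                if tier_l is None:
                    continue
                for orient_r in (1, -1):
                    seq_r = cs[cid_r].oriented(orient_r)
                    tier_r = _right_tier(seq_r, run_r)
                    if tier_r is None:
                        continue
                    ca = make_car_adjacency(
                        cid_l,
                        orient_l,
                        cid_r,
                        orient_r,
                        seq_l[-1],
                        seq_r[0],
                        genome=g.name,
                        left_tier=tier_l,
                        right_tier=tier_r,
                    )
                    found.setdefault(ca, ca)
    return set(found.values())


@dataclass(frozen=True)
class ConservedAdjacencyRecord:
    """A conserved CAR adjacency, grouped by its block adjacency."""

    adjacency: Adjacency
    occupancy: tuple[tuple[str, bool], ...]  # sorted (genome, present) pairs
    conservation: str  # FULLY or PARTLY
    homoplasy: int

    def occupancy_map(self) -> dict[str, bool]:
        return dict(self.occupancy)

    @property
    def supporting_genomes(self) -> frozenset[str]:
        return frozenset(g for g, present in self.occupancy if present)


def _pooled_occupancies(
    cs: CARSet, genomes: Iterable[Genome]
) -> dict[Adjacency, set[str]]:
    pooled: dict[Adjacency, set[str]] = {}
    for g in sorted(genomes, key=lambda g: g.name):
        for ca in detect_car_adjacencies(g, cs):
            pooled.setdefault(ca.block_adjacency(), set()).add(g.name)
    return pooled


def classify_conserved(
    cs: CARSet,
    genomes: Iterable[Genome],
    part: SpeciesPartition,
    blacklist: Collection[Adjacency] = (),
) -> list[ConservedAdjacencyRecord]:
    """Conserved CAR adjacencies at the ancestor, as block adjacencies.

    Pools :func:`detect_car_adjacencies` over all genomes, groups by the
    canonical block adjacency (occupancy is boolean per genome), and keeps
    the adjacencies whose supporting genomes span at least two of I1, I2,
    O.  Permanently discarded adjacencies and adjacencies already realized
    inside a CAR are dropped.  Output is sorted canonically.
    """
    genomes = list(genomes)
    internal = cs.internal_adjacencies()
    names = sorted(g.name for g in genomes)
    pooled = _pooled_occupancies(cs, genomes)
    records: list[ConservedAdjacencyRecord] = []
    for adj in sorted(pooled):
        supporters = pooled[adj]
        if adj in blacklist or adj in internal:
            continue
        occ = {n: n in supporters for n in names}
        cls = conservation_class(occ, part)
        if cls not in (FULLY, PARTLY):
            continue
        records.append(
            ConservedAdjacencyRecord(
                adjacency=adj,
                occupancy=tuple(sorted(occ.items())),
                conservation=cls,
                homoplasy=homoplasy_cost(occ, part),
            )
        )
    return records


def detect_dcj_reliable(
    cs: CARSet,
    genomes: Iterable[Genome],
    part: SpeciesPartition,
    blacklist: Collection[Adjacency] = (),
) -> list[Adjacency]:
    """Candidate ancestral adjacencies supported by a single DCJ event.

    ``(a_n b_1)`` — joining the oriented ends of two current CARs — is
    *DCJ-reliable* if some adjacency ``(x y)`` inside the current CARs
    exists such that one extant genome G1 contains both ``(x b_1)`` and
    ``(a_n y)`` (the outcome of a DCJ cutting ``(a_n b_1)`` and ``(x y)``
    in the ancestor), while another genome G2, in a different partition
    set, witnesses the CAR adjacency ``(car_a car_b)``.  Candidates that
    are conserved (CAR-adjacency support spanning two sets) belong to step
    a) and are excluded here; consequently every returned adjacency has
    homoplasy cost exactly 2, which is asserted.
    """
    genomes = sorted(genomes, key=lambda g: g.name)
    internal = cs.internal_adjacencies()
    adj_sets = {g.name: g.adjacencies() for g in genomes}

    # genome -> canonical CAR-pair set; CAR pair -> supporting genomes
    pair_support: dict[tuple, set[str]] = {}
    for g in genomes:
        for ca in detect_car_adjacencies(g, cs):
            pair_support.setdefault(ca.car_pair(), set()).add(g.name)

    orderings: list[tuple[int, int]] = []
    for adj in sorted(internal):
        orderings.append((adj.left, adj.right))
        orderings.append((-adj.right, -adj.left))

    # (car id, orientation, signed last block a_n, signed first block b_1)
    ends: list[tuple[int, int, int, int]] = []
    for car in sorted(cs, key=lambda c: c.identifier):
        for orient in (1, -1):
            seq = car.oriented(orient)
            ends.append((car.identifier, orient, seq[-1], seq[0]))

    out: list[Adjacency] = []
    seen: set[Adjacency] = set()
    for cid_a, or_a, a_n, _ in ends:
        for cid_b, or_b, _, b_1 in ends:
            if cid_a == cid_b:
                continue
            cand = Adjacency(a_n, b_1)
            if cand in seen or cand in blacklist or cand in internal:
                continue
            pair = make_car_adjacency(cid_a, or_a, cid_b, or_b, a_n, b_1).car_pair()
            g2s = pair_support.get(pair, set())
            if not g2s:
                continue
            g2_sets = {part.set_of(g) for g in g2s}
            # conserved candidates are step-a material, not DCJ-reliable
            if len(g2_sets) >= 2:
                continue
            supported = False
            for x, y in orderings:
                if abs(x) == abs(b_1) or abs(a_n) == abs(y):
                    continue
                w1 = Adjacency(x, b_1)
                w2 = Adjacency(a_n, y)
                for g in genomes:
                    if w1 in adj_sets[g.name] and w2 in adj_sets[g.name]:
                        if part.set_of(g.name) not in g2_sets:
                            supported = True
                            break
                if supported:
                    break
            if supported:
                occ = {g.name: g.name in g2s for g in genomes}
                assert homoplasy_cost(occ, part) == 2
                seen.add(cand)
                out.append(cand)
    return sorted(out)
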