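"""Core algebra of signed synteny blocks, adjacencies, chromosomes and CARs.

Genomes are modeled as sets of chromosomes, each an ordered sequence of
*signed blocks*.  A signed block is a nonzero integer: ``+5`` and ``-5``
denote the two orientations of block 5.  All genomes in an analysis share
one universe of non-duplicated block identifiers.

Each block has two *extremities*, a tail and a head.  Reading a block in
forward orientation goes tail -> head, so the right extremity of ``+a`` is
its head and the right extremity of ``-a`` is its tail.  An *adjacency*
``(x y)`` records that signed block ``x`` is immediately followed by ``y``;
because a chromosome can always be flipped, ``(x y)`` and ``(-y -x)``
denote the same adjacency and are stored in one canonical form.

A *CAR* (Contiguous Ancestral Region) is a candidate ancestral chromosome:
an ordered sequence of signed blocks, identical to its flipped form.  A
:class:`CARSet` is the evolving ancestral state; its CARs always partition
the block universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

TAIL = "t"
HEAD = "h"

#: An extremity is a (block_id, side) pair with side in {TAIL, HEAD}.
Extremity = tuple[int, str]


class InvalidInputError(ValueError):
    """Raised when an input structure violates a model invariant."""


def check_signed_block(x: int) -> int:
    if not isinstance(x, int) or x == 0:
        raise InvalidInputError(f"signed block must be a nonzero integer, got {x!r}")
    return x


def right_extremity(x: int) -> Extremity:
    """Extremity exposed on the right of signed block ``x`` in a sequence."""
    check_signed_block(x)
    return (abs(x), HEAD if x > 0 else TAIL)


def left_extremity(x: int) -> Extremity:
    """Extremity exposed on the left of signed block ``x`` in a sequence."""
    check_signed_block(x)
    return (abs(x), TAIL if x > 0 else HEAD)


def _block_key(x: int) -> tuple[int, int]:
    # sort unsigned id first, '+' before '-'
    return (abs(x), 0 if x > 0 else 1)


@dataclass(frozen=True, order=False)
class Adjacency:
    """An unordered pair of consecutive signed blocks, stored canonically.

    ``Adjacency(x, y)`` and ``Adjacency(-y, -x)`` compare and hash equal.
    The canonical representative is the writing whose first signed block is
    smaller under (unsigned id, then ``+`` before ``-``).
    """

    left: int
    right: int

    def __init__(self, left: int, right: int):
        check_signed_block(left)
        check_signed_block(right)
        if abs(left) == abs(right):
            raise InvalidInputError(
                f"self-adjacency on block {abs(left)} is not allowed"
            )
        if _block_key(left) > _block_key(-right):
            left, right = -right, -left
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    def extremities(self) -> frozenset[Extremity]:
        """The two block extremities glued by this adjacency."""
        return frozenset((right_extremity(self.left), left_extremity(self.right)))

    def sort_key(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (_block_key(self.left), _block_key(self.right))

    def __lt__(self, other: "Adjacency") -> bool:
        return self.sort_key() < other.sort_key()

    def __repr__(self) -> str:  # (3 -5) style, readable in logs
        return f"({self.left} {self.right})"


def canonical(adj: Adjacency) -> Adjacency:
    """Identity on :class:`Adjacency` (construction already canonicalizes)."""
    return adj


def conflicts(a1: Adjacency, a2: Adjacency) -> bool:
    """True iff two distinct adjacencies involve a same block extremity."""
    if a1 == a2:
        return False
    return bool(a1.extremities() & a2.extremities())


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed blocks, linear or circular."""

    blocks: tuple[int, ...]
    circular: bool = False

    def __init__(self, blocks: Iterable[int], circular: bool = False):
        blocks = tuple(blocks)
        if not blocks:
            raise InvalidInputError("chromosome must be nonempty")
        seen = set()
        for b in blocks:
            check_signed_block(b)
            if abs(b) in seen:
                raise InvalidInputError(f"block {abs(b)} occurs twice in chromosome")
            seen.add(abs(b))
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "circular", circular)

    def flipped(self) -> "Chromosome":
        return Chromosome(tuple(-b for b in reversed(self.blocks)), self.circular)

    def adjacencies(self) -> frozenset[Adjacency]:
        out = [
            Adjacency(x, y) for x, y in zip(self.blocks, self.blocks[1:])
        ]
        if self.circular and len(self.blocks) > 1:
            out.append(Adjacency(self.blocks[-1], self.blocks[0]))
        return frozenset(out)


@dataclass(frozen=True)
class Genome:
    """A named extant genome: a set of chromosomes over the block universe."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __init__(self, name: str, chromosomes: Iterable[Chromosome]):
        chromosomes = tuple(chromosomes)
        seen: set[int] = set()
        for c in chromosomes:
            for b in c.blocks:
                if abs(b) in seen:
                    raise InvalidInputError(
                        f"block {abs(b)} occurs twice in genome {name!r}"
                    )
                seen.add(abs(b))
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "chromosomes", chromosomes)

    @property
    def block_universe(self) -> frozenset[int]:
        return frozenset(abs(b) for c in self.chromosomes for b in c.blocks)

    def adjacencies(self) -> frozenset[Adjacency]:
        out: set[Adjacency] = set()
        for c in self.chromosomes:
            out |= c.adjacencies()
        return frozenset(out)


def adjacencies_of(g: Genome) -> frozenset[Adjacency]:
    """All adjacencies of a genome (circular chromosomes wrap around)."""
    return g.adjacencies()


def syntenic(s1: Sequence[int], s2: Sequence[int]) -> bool:
    """True iff two segments contain the same unsigned block set."""
    return {abs(b) for b in s1} == {abs(b) for b in s2}


def neighbor_map(
    chromosome_blocks: Iterable[Sequence[int]],
    circular_flags: Iterable[bool] | None = None,
) -> dict[Extremity, Extremity | None]:
    """Map every block extremity to its glued neighbor (None at telomeres)."""
    seqs = [tuple(s) for s in chromosome_blocks]
    flags = list(circular_flags) if circular_flags is not None else [False] * len(seqs)
    out: dict[Extremity, Extremity | None] = {}
    for seq, circ in zip(seqs, flags):
        for x, y in zip(seq, seq[1:]):
            out[right_extremity(x)] = left_extremity(y)
            out[left_extremity(y)] = right_extremity(x)
        if circ and len(seq) > 1:
            out[right_extremity(seq[-1])] = left_extremity(seq[0])
            out[left_extremity(seq[0])] = right_extremity(seq[-1])
        else:
            out.setdefault(left_extremity(seq[0]), None)
            out.setdefault(right_extremity(seq[-1]), None)
    return out


def apply_dcj(
    g: Genome, adj1: Adjacency, adj2: Adjacency, rewiring: int = 0
) -> Genome:
    """Apply one Double-Cut-and-Join event to a genome.

    The two adjacencies are cut and the four exposed extremities are glued
    differently.  With the canonical writings ``adj1 = (p1 q1)`` and
    ``adj2 = (p2 q2)``, ``rewiring=0`` glues the right extremity of ``p1``
    with the right extremity of ``p2`` (and the left extremities of
    ``q1``/``q2`` together); ``rewiring=1`` glues right-of-``p1`` with
    left-of-``q2`` and left-of-``q1`` with right-of-``p2``.
    """
    adjs = adjacencies_of(g)
    for a in (adj1, adj2):
        if a not in adjs:
            raise InvalidInputError(f"adjacency {a} is not present in genome {g.name!r}")
    if adj1 == adj2:
        raise InvalidInputError("the two cut adjacencies must be distinct")
    if adj1.extremities() & adj2.extremities():
        raise InvalidInputError("cut adjacencies share a block extremity")
    if rewiring not in (0, 1):
        raise InvalidInputError("rewiring must be 0 or 1")

    nm = neighbor_map(
        [c.blocks for c in g.chromosomes], [c.circular for c in g.chromosomes]
    )
    p1, q1 = right_extremity(adj1.left), left_extremity(adj1.right)
    p2, q2 = right_extremity(adj2.left), left_extremity(adj2.right)
    if rewiring == 0:
        joins = [(p1, p2), (q1, q2)]
    else:
        joins = [(p1, q2), (q1, p2)]
    for e1, e2 in joins:
        nm[e1] = e2
        nm[e2] = e1
    return Genome(g.name, _chromosomes_from_neighbor_map(nm))


def _other_extremity(e: Extremity) -> Extremity:
    return (e[0], HEAD if e[1] == TAIL else TAIL)


def _chromosomes_from_neighbor_map(
    nm: Mapping[Extremity, Extremity | None]
) -> list[Chromosome]:
    """Rebuild chromosomes by walking the extremity graph (deterministic)."""
    visited: set[Extremity] = set()
    chromosomes: list[Chromosome] = []

    def walk(start: Extremity, circular: bool) -> tuple[int, ...]:
        blocks: list[int] = []
        e = start
        while True:
            visited.add(e)
            blocks.append(e[0] if e[1] == TAIL else -e[0])
            other = _other_extremity(e)
            visited.add(other)
            nxt = nm.get(other)
            if nxt is None or nxt in visited:
                break
            e = nxt
        return tuple(blocks)

    telomeres = sorted(e for e, n in nm.items() if n is None)
    for e in telomeres:
        if e not in visited:
            chromosomes.append(Chromosome(walk(e, False), circular=False))
    for e in sorted(nm):
        if e not in visited:
            chromosomes.append(Chromosome(walk(e, True), circular=True))
    return chromosomes


@dataclass(frozen=True)
class CAR:
    """A Contiguous Ancestral Region: an ordered run of signed blocks.

    A CAR and its flipped form denote the same ancestral chromosome.
    """

    blocks: tuple[int, ...]
    identifier: int

    def __init__(self, blocks: Iterable[int], identifier: int):
        blocks = tuple(blocks)
        if not blocks:
            raise InvalidInputError("CAR must be nonempty")
        if len({abs(b) for b in blocks}) != len(blocks):
            raise InvalidInputError("duplicate block in CAR")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "identifier", identifier)

    def flipped(self) -> "CAR":
        return CAR(tuple(-b for b in reversed(self.blocks)), self.identifier)

    def oriented(self, orient: int) -> tuple[int, ...]:
        """Block sequence read forward (+1) or flipped (-1)."""
        if orient == 1:
            return self.blocks
        if orient == -1:
            return tuple(-b for b in reversed(self.blocks))
        raise InvalidInputError("orientation must be +1 or -1")

    def __len__(self) -> int:
        return len(self.blocks)


class CARSet:
    """The current set of CARs; always a partition of the block universe."""

    def __init__(self, cars: Iterable[CAR]):
        self._cars: dict[int, CAR] = {}
        seen: set[int] = set()
        for car in cars:
            if car.identifier in self._cars:
                raise InvalidInputError(f"duplicate CAR identifier {car.identifier}")
            for b in car.blocks:
                if abs(b) in seen:
                    raise InvalidInputError(f"block {abs(b)} occurs in two CARs")
                seen.add(abs(b))
            self._cars[car.identifier] = car

    @classmethod
    def singletons(cls, universe: Iterable[int]) -> "CARSet":
        """One single-block CAR per block, identified by the block id."""
        return cls(CAR((b,), b) for b in sorted(universe))

    def __iter__(self) -> Iterator[CAR]:
        return iter(self._cars.values())

    def __len__(self) -> int:
        return len(self._cars)

    def __getitem__(self, identifier: int) -> CAR:
        return self._cars[identifier]

    @property
    def block_universe(self) -> frozenset[int]:
        return frozenset(abs(b) for car in self for b in car.blocks)

    def car_of(self) -> dict[int, int]:
        """Unsigned block id -> identifier of the CAR containing it."""
        return {abs(b): car.identifier for car in self for b in car.blocks}

    def internal_adjacencies(self) -> frozenset[Adjacency]:
        """All adjacencies already realized inside the CARs."""
        out: set[Adjacency] = set()
        for car in self:
            out.update(
                Adjacency(x, y) for x, y in zip(car.blocks, car.blocks[1:])
            )
        return frozenset(out)

    def end_extremities(self) -> dict[Extremity, int]:
        """Free extremity at each CAR end -> identifier of that CAR."""
        out: dict[Extremity, int] = {}
        for car in self:
            out[left_extremity(car.blocks[0])] = car.identifier
            out[right_extremity(car.blocks[-1])] = car.identifier
        return out

    def sizes(self) -> tuple[int, int]:
        ns = [len(c) for c in self]
        return (min(ns), max(ns))


@dataclass
class ConcatenationResult:
    car_set: CARSet
    added: list[Adjacency] = field(default_factory=list)
    cycle_skipped: list[Adjacency] = field(default_factory=list)


def concatenate(cs: CARSet, adjs: Iterable[Adjacency]) -> ConcatenationResult:
    """Merge CARs along a non-conflicting set of end-to-end adjacencies.

    Adjacencies are processed in canonical sort order.  An adjacency whose
    two extremities lie on the same CAR would close a circular chromosome;
    it is skipped and reported in ``cycle_skipped`` (the caller treats it
    as permanently discarded).  An adjacency whose extremities are not free
    CAR ends is an error; detection never produces one.
    """
    seqs: dict[int, list[int]] = {car.identifier: list(car.blocks) for car in cs}
    ends: dict[Extremity, tuple[int, str]] = {}
    for cid, blocks in seqs.items():
        ends[left_extremity(blocks[0])] = (cid, "L")
        ends[right_extremity(blocks[-1])] = (cid, "R")

    result = ConcatenationResult(cs)
    added: list[Adjacency] = []
    skipped: list[Adjacency] = []
    for adj in sorted(set(adjs)):
        e1 = right_extremity(adj.left)
        e2 = left_extremity(adj.right)
        if e1 not in ends or e2 not in ends:
            raise InvalidInputError(
                f"adjacency {adj} does not join two free CAR ends"
            )
        cid1, side1 = ends[e1]
        cid2, side2 = ends[e2]
        if cid1 == cid2:
            skipped.append(adj)
            continue
        left_seq = seqs[cid1]
        right_seq = seqs[cid2]
        if side1 == "L":  # flip so e1 becomes the right end
            left_seq = [-b for b in reversed(left_seq)]
        if side2 == "R":  # flip so e2 becomes the left end
            right_seq = [-b for b in reversed(right_seq)]
        keep, drop = (cid1, cid2) if cid1 < cid2 else (cid2, cid1)
        merged = left_seq + right_seq
        for e in (
            left_extremity(seqs[cid1][0]),
            right_extremity(seqs[cid1][-1]),
            left_extremity(seqs[cid2][0]),
            right_extremity(seqs[cid2][-1]),
        ):
            ends.pop(e, None)
        del seqs[cid1], seqs[cid2]
        seqs[keep] = merged
        ends[left_extremity(merged[0])] = (keep, "L")
        ends[right_extremity(merged[-1])] = (keep, "R")
        added.append(adj)

    result.car_set = CARSet(
        CAR(tuple(blocks), cid) for cid, blocks in sorted(seqs.items())
    )
    result.added = added
    result.cycle_skipped = skipped
    return result
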