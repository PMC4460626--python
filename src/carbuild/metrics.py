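"""Evaluation metrics: breakpoint distance, shared adjacencies, accuracy.

The breakpoint distance between two gene orders over the same block
universe counts the block extremities whose neighborhood (adjacent block
extremity, or a telomere) differs between the two structures, divided by
two — so a single differing adjacency against a telomere contributes 0.5.
"""

from __future__ import annotations

from typing import Sequence, Union

from .model import Adjacency, CARSet, Genome, InvalidInputError, neighbor_map

Structure = Union[Genome, CARSet]


def _as_sequences(x: Structure) -> tuple[list[Sequence[int]], list[bool]]:
    if isinstance(x, Genome):
        return [c.blocks for c in x.chromosomes], [c.circular for c in x.chromosomes]
    return [car.blocks for car in x], [False for _ in x]


def _universe(x: Structure) -> frozenset[int]:
    return x.block_universe


def adjacency_set(x: Structure) -> frozenset[Adjacency]:
    """The adjacency set of a genome or of a CAR set (CARs are linear)."""
    if isinstance(x, Genome):
        return x.adjacencies()
    return x.internal_adjacencies()


def breakpoint_distance(g1: Structure, g2: Structure) -> float:
    """Halved count of block extremities with differing neighborhoods."""
    if _universe(g1) != _universe(g2):
        raise InvalidInputError("breakpoint distance requires a shared universe")
    nm1 = neighbor_map(*_as_sequences(g1))
    nm2 = neighbor_map(*_as_sequences(g2))
    diff = sum(1 for e in nm1 if nm1[e] != nm2.get(e))
    return diff / 2


def shared_adjacencies(
    sets: Sequence[Structure],
) -> dict[frozenset[int], frozenset[Adjacency]]:
    """Partition the union of adjacencies by the subset of inputs sharing them.

    Keys are frozensets of input indices; each adjacency appears in exactly
    one cell, so cell sizes sum to the union size.
    """
    adj_sets = [adjacency_set(s) for s in sets]
    union: set[Adjacency] = set().union(*adj_sets) if adj_sets else set()
    cells: dict[frozenset[int], set[Adjacency]] = {}
    for adj in union:
        support = frozenset(i for i, s in enumerate(adj_sets) if adj in s)
        cells.setdefault(support, set()).add(adj)
    return {k: frozenset(v) for k, v in cells.items()}


def precision_recall(
    reconstructed: Structure, truth: Structure
) -> tuple[float, float]:
    """Adjacency-level precision and recall of a reconstruction vs truth.

    Empty sides yield 1.0 by convention (nothing asserted, nothing wrong).
    """
    rec = adjacency_set(reconstructed)
    tru = adjacency_set(truth)
    hit = len(rec & tru)
    precision = hit / len(rec) if rec else 1.0
    recall = hit / len(tru) if tru else 1.0
    return precision, recall
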