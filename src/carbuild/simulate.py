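"""Synthetic instance generation by simulated rearrangement along a tree.

The simulator draws a root genome (blocks ``1..n``, all forward, split
evenly into linear chromosomes) and applies a fixed number of random
rearrangement events on every branch of a species tree.  Each event is a
Double-Cut-and-Join realized as one of four classic operations, picked by
configurable weights with uniform breakpoint placement:

* **inversion** — reverse and flip a contiguous segment of one chromosome;
* **translocation** — exchange the suffixes of two chromosomes;
* **fusion** — concatenate two chromosomes (random relative orientation);
* **fission** — split one chromosome at an internal breakpoint.

The true genome at every internal node is retained, so reconstructions can
be scored against the simulated ancestor.  Runs are reproducible: the same
configuration and seed always yield the same instance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import Chromosome, Genome, InvalidInputError
from .phylogeny import SpeciesTree, TreeNode


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated evolution.

    ``events_per_branch`` applies to every branch; ``weights`` orders the
    event types (inversion, translocation, fusion, fission).  Inversions
    dominate by default, reflecting their prevalence among observed
    rearrangements.
    """

    n_blocks: int
    n_chromosomes: int = 2
    events_per_branch: int = 1
    weights: tuple[float, float, float, float] = (0.7, 0.15, 0.075, 0.075)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise InvalidInputError("simulation needs at least one block")
        if not 1 <= self.n_chromosomes <= self.n_blocks:
            raise InvalidInputError("invalid chromosome count")
        if self.events_per_branch < 0:
            raise InvalidInputError("events_per_branch must be >= 0")
        if min(self.weights) < 0 or sum(self.weights) <= 0:
            raise InvalidInputError("event weights must be non-negative, not all 0")


def root_genome(cfg: SimulationConfig, name: str = "root") -> Genome:
    """Identity root: blocks 1..n forward, split evenly into chromosomes."""
    blocks = list(range(1, cfg.n_blocks + 1))
    size, extra = divmod(cfg.n_blocks, cfg.n_chromosomes)
    chromosomes = []
    start = 0
    for i in range(cfg.n_chromosomes):
        stop = start + size + (1 if i < extra else 0)
        if stop > start:
            chromosomes.append(Chromosome(blocks[start:stop]))
        start = stop
    return Genome(name, chromosomes)


def _inversion(chroms: list[list[int]], rng: random.Random) -> None:
    ci = rng.randrange(len(chroms))
    c = chroms[ci]
    i = rng.randrange(len(c))
    j = rng.randrange(i, len(c))
    c[i : j + 1] = [-b for b in reversed(c[i : j + 1])]


def _translocation(chroms: list[list[int]], rng: random.Random) -> bool:
    if len(chroms) < 2:
        return False
    i, j = rng.sample(range(len(chroms)), 2)
    a, b = chroms[i], chroms[j]
    # cut positions keeping all four parts possibly empty, but results nonempty
    for _ in range(20):
        pa = rng.randrange(0, len(a) + 1)
        pb = rng.randrange(0, len(b) + 1)
        na, nb = a[:pa] + b[pb:], b[:pb] + a[pa:]
        if na and nb:
            chroms[i], chroms[j] = na, nb
            return True
    return False


def _fusion(chroms: list[list[int]], rng: random.Random) -> bool:
    if len(chroms) < 2:
        return False
    i, j = rng.sample(range(len(chroms)), 2)
    b = chroms[j]
    if rng.random() < 0.5:
        b = [-x for x in reversed(b)]
    chroms[i] = chroms[i] + b
    del chroms[j]
    return True


def _fission(chroms: list[list[int]], rng: random.Random) -> bool:
    splittable = [k for k, c in enumerate(chroms) if len(c) >= 2]
    if not splittable:
        return False
    k = rng.choice(splittable)
    c = chroms[k]
    p = rng.randrange(1, len(c))
    chroms[k] = c[:p]
    chroms.append(c[p:])
    return True


_EVENTS = (_inversion, _translocation, _fusion, _fission)


def apply_random_events(
    g: Genome, n_events: int, weights, rng: random.Random, name: str
) -> Genome:
    """Apply ``n_events`` weighted random rearrangements to a genome copy."""
    chroms = [list(c.blocks) for c in g.chromosomes]
    for _ in range(n_events):
        for _ in range(50):  # redraw if the drawn type is infeasible
            (op,) = rng.choices(_EVENTS, weights=weights)
            if op is _inversion:
                _inversion(chroms, rng)
                break
            if op(chroms, rng):
                break
    return Genome(name, [Chromosome(c) for c in chroms])


def simulate(
    tree: SpeciesTree, cfg: SimulationConfig
) -> tuple[list[Genome], dict[str, Genome]]:
    """Evolve a root genome down the tree.

    Returns the leaf genomes (named after the leaves) and the map of every
    node label — internal nodes included — to its true genome.
    """
    rng = random.Random(cfg.seed)
    truth: dict[str, Genome] = {}
    leaves: list[Genome] = []

    def descend(node: TreeNode, genome: Genome) -> None:
        truth[node.label] = Genome(node.label, genome.chromosomes)
        if node.is_leaf:
            leaves.append(truth[node.label])
        for child in node.children:
            evolved = apply_random_events(
                genome, cfg.events_per_branch, cfg.weights, rng, child.label
            )
            descend(child, evolved)

    descend(tree.root, root_genome(cfg, name=tree.root.label))
    return leaves, truth
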