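"""Independent brute-force oracles used to validate the optimized paths.

Everything here is deliberately naive: exhaustive enumeration over
labelings, subsets, or segment pairs, written directly from the
definitions and kept independent of the package's algorithmic code paths.
"""

from __future__ import annotations

import itertools
import random

from carbuild.model import Adjacency, CAR, CARSet, Chromosome, Genome, conflicts
from carbuild.detection import make_car_adjacency
from carbuild.phylogeny import SpeciesPartition, SpeciesTree, TreeNode


# ---------------------------------------------------------------- parsimony


def brute_mutation_cost(occ: dict[str, bool], tree: SpeciesTree) -> int:
    """Minimum over all {0,1} labelings of internal nodes (ancestor fixed 1)."""
    internals = [n for n in tree.nodes() if not n.is_leaf]
    best = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        label = {id(n): s for n, s in zip(internals, states)}
        if label[id(tree.ancestor)] != 1:
            continue
        for n in tree.nodes():
            if n.is_leaf:
                label[id(n)] = 1 if occ[n.label] else 0
        cost = 0
        for n in tree.nodes():
            for c in n.children:
                cost += label[id(n)] != label[id(c)]
        best = cost if best is None else min(best, cost)
    assert best is not None
    return best


# ---------------------------------------------------------------- detection


def _tier_left_literal(segment, car_seq) -> bool:
    a_n = car_seq[-1]
    if list(segment) == [a_n]:
        return True
    if len(segment) > 1 and abs(segment[-1]) == abs(a_n):
        return True
    if len(segment) > 1:
        seg_set = {abs(b) for b in segment}
        for i in range(len(car_seq)):
            for j in range(i + 1, len(car_seq) + 1):
                sub = car_seq[i:j]
                if abs(a_n) in {abs(b) for b in sub} and seg_set == {
                    abs(b) for b in sub
                }:
                    return True
    return False


def _tier_right_literal(segment, car_seq) -> bool:
    flipped_seg = [-b for b in reversed(segment)]
    flipped_car = tuple(-b for b in reversed(car_seq))
    return _tier_left_literal(flipped_seg, flipped_car)


def brute_car_adjacency_pairs(genome: Genome, cs: CARSet) -> set[tuple]:
    """All canonical CAR-adjacency pairs by literal segment-pair enumeration."""
    car_of = cs.car_of()
    found: set[tuple] = set()
    for chrom in genome.chromosomes:
        n = len(chrom.blocks)
        rotations = (
            [list(chrom.blocks)]
            if not chrom.circular
            else [list(chrom.blocks[r:]) + list(chrom.blocks[:r]) for r in range(n)]
        )
        for blocks in rotations:
            for i in range(n):
                for j in range(i + 1, n):
                    for k in range(j + 1, n + 1):
                        s_a, s_b = blocks[i:j], blocks[j:k]
                        cars_a = {car_of[abs(b)] for b in s_a}
                        cars_b = {car_of[abs(b)] for b in s_b}
                        if len(cars_a) != 1 or len(cars_b) != 1 or cars_a == cars_b:
                            continue
                        (cid_a,) = cars_a
                        (cid_b,) = cars_b
                        for or_a in (1, -1):
                            seq_a = cs[cid_a].oriented(or_a)
                            if not _tier_left_literal(s_a, seq_a):
                                continue
                            for or_b in (1, -1):
                                seq_b = cs[cid_b].oriented(or_b)
                                if not _tier_right_literal(s_b, seq_b):
                                    continue
                                found.add(
                                    make_car_adjacency(
                                        cid_a, or_a, cid_b, or_b,
                                        seq_a[-1], seq_b[0],
                                    ).car_pair()
                                )
    return found


def brute_dcj_reliable(
    cs: CARSet, genomes, part: SpeciesPartition, blacklist=()
) -> set[Adjacency]:
    """Literal triple enumeration of the DCJ-reliable definition."""
    genomes = list(genomes)
    internal = cs.internal_adjacencies()
    adjs = {g.name: g.adjacencies() for g in genomes}
    car_pairs = {g.name: brute_car_adjacency_pairs(g, cs) for g in genomes}

    out: set[Adjacency] = set()
    cars = list(cs)
    for car_a in cars:
        for or_a in (1, -1):
            a_n = car_a.oriented(or_a)[-1]
            for car_b in cars:
                if car_b.identifier == car_a.identifier:
                    continue
                for or_b in (1, -1):
                    b_1 = car_b.oriented(or_b)[0]
                    cand = Adjacency(a_n, b_1)
                    if cand in blacklist or cand in internal:
                        continue
                    pair = make_car_adjacency(
                        car_a.identifier, or_a, car_b.identifier, or_b, a_n, b_1
                    ).car_pair()
                    g2s = [g for g in genomes if pair in car_pairs[g.name]]
                    sets2 = {part.set_of(g.name) for g in g2s}
                    if not g2s or len(sets2) >= 2:
                        continue
                    for adj in internal:
                        for x, y in ((adj.left, adj.right), (-adj.right, -adj.left)):
                            if abs(x) == abs(b_1) or abs(y) == abs(a_n):
                                continue
                            w1, w2 = Adjacency(x, b_1), Adjacency(a_n, y)
                            for g1 in genomes:
                                if part.set_of(g1.name) in sets2:
                                    continue
                                if w1 in adjs[g1.name] and w2 in adjs[g1.name]:
                                    out.add(cand)
    return out


# ---------------------------------------------------------------- selection


def brute_max_subset(candidates, cost=None):
    """Best non-conflicting subset: max size, min cost, lexicographic."""
    cands = sorted(set(candidates))
    if cost is None:
        cost = {a: 0 for a in cands}
    best = None
    for r in range(len(cands), -1, -1):
        for combo in itertools.combinations(cands, r):
            if any(
                conflicts(a, b) for a, b in itertools.combinations(combo, 2)
            ):
                continue
            key = (-len(combo), sum(cost[a] for a in combo), list(combo))
            if best is None or key < best:
                best = key
        if best is not None and -best[0] == r:
            break
    return list(best[2]) if best else []


def brute_select_step_a(fs: set, ps: set):
    """Literal set comprehensions of the step-a selection algebra."""
    s = fs | ps
    fs_nc = {a for a in fs if all(not conflicts(a, b) for b in fs)}
    ps_d = {p for p in ps if any(conflicts(p, a) for a in fs_nc)}
    ps_r = ps - ps_d
    ps_nc = {p for p in ps_r if all(not conflicts(p, q) for q in ps_r)}
    ps_nc2 = {p for p in ps_nc if all(not conflicts(p, a) for a in fs)}
    nc = fs_nc | ps_nc2
    c = s - ps_d - nc
    return {
        "s": s, "fs": fs, "ps": ps, "fs_nc": fs_nc, "fs_c": fs - fs_nc,
        "ps_d": ps_d, "ps_r": ps_r, "ps_nc": ps_nc, "ps_nc2": ps_nc2,
        "nc": nc, "c": c,
    }


# ---------------------------------------------------------------- generators


def random_genome(rng: random.Random, n_blocks: int, name="G", circular_prob=0.0):
    blocks = [b if rng.random() < 0.5 else -b for b in range(1, n_blocks + 1)]
    rng.shuffle(blocks)
    n_chrom = rng.randint(1, min(3, n_blocks))
    cuts = sorted(rng.sample(range(1, n_blocks), n_chrom - 1)) if n_chrom > 1 else []
    bounds = [0] + cuts + [n_blocks]
    chroms = [
        Chromosome(
            blocks[i:j], circular=(rng.random() < circular_prob and j - i > 1)
        )
        for i, j in zip(bounds, bounds[1:])
    ]
    return Genome(name, chroms)


def random_carset(rng: random.Random, n_blocks: int) -> CARSet:
    blocks = [b if rng.random() < 0.5 else -b for b in range(1, n_blocks + 1)]
    rng.shuffle(blocks)
    n_cars = rng.randint(1, n_blocks)
    cuts = sorted(rng.sample(range(1, n_blocks), n_cars - 1)) if n_cars > 1 else []
    bounds = [0] + cuts + [n_blocks]
    return CARSet(
        CAR(blocks[i:j], idx + 1)
        for idx, (i, j) in enumerate(zip(bounds, bounds[1:]))
    )


def random_adjacencies(rng: random.Random, n_blocks: int, n_adj: int):
    out = set()
    for _ in range(n_adj * 4):
        if len(out) >= n_adj:
            break
        x = rng.choice([1, -1]) * rng.randint(1, n_blocks)
        y = rng.choice([1, -1]) * rng.randint(1, n_blocks)
        if abs(x) != abs(y):
            out.add(Adjacency(x, y))
    return sorted(out)


def random_species_tree(rng: random.Random, n_leaves: int) -> SpeciesTree:
    """Random rooted binary tree; a random valid internal node is tagged."""
    nodes = [TreeNode(f"L{i}", []) for i in range(1, n_leaves + 1)]
    counter = 0
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        counter += 1
        nodes.append(TreeNode(f"N{counter}", [a, b]))
    root = nodes[0]

    def internals(n):
        if n.is_leaf:
            return []
        out = [] if n is root else [n]
        for c in n.children:
            out.extend(internals(c))
        return out

    candidates = internals(root)
    if not candidates:  # 2-leaf tree: no valid ancestor; caller avoids this
        raise ValueError("tree too small")
    anc = rng.choice(sorted(candidates, key=lambda n: n.label))
    return SpeciesTree(root, anc)
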