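"""Unit tests for the signed-block / adjacency / CAR algebra."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbuild.model import (
    Adjacency,
    CAR,
    CARSet,
    Chromosome,
    Genome,
    InvalidInputError,
    adjacencies_of,
    apply_dcj,
    canonical,
    concatenate,
    conflicts,
    syntenic,
)

signed_blocks = st.integers(min_value=1, max_value=30).flatmap(
    lambda b: st.sampled_from([b, -b])
)


class TestAdjacency:
    def test_flip_identity(self):
        # (g -h) and (h -g) are the same adjacency, as are (a b) and (-b -a)
        assert Adjacency(7, -8) == Adjacency(8, -7)
        assert Adjacency(1, 2) == Adjacency(-2, -1)
        assert hash(Adjacency(7, -8)) == hash(Adjacency(8, -7))

    @given(x=signed_blocks, y=signed_blocks)
    @settings(max_examples=100, derandomize=True)
    def test_both_writings_agree(self, x, y):
        if abs(x) == abs(y):
            return
        assert Adjacency(x, y) == Adjacency(-y, -x)
        assert canonical(Adjacency(x, y)) == Adjacency(x, y)

    def test_self_adjacency_rejected(self):
        with pytest.raises(InvalidInputError):
            Adjacency(3, -3)

    def test_extremities_identify_adjacency(self):
        # conflicting adjacencies share exactly one extremity
        assert conflicts(Adjacency(7, 8), Adjacency(7, -8))
        assert not conflicts(Adjacency(1, 2), Adjacency(3, 4))
        a = Adjacency(1, 2)
        assert not conflicts(a, a)


class TestChromosomeGenome:
    def test_linear_adjacencies(self):
        c = Chromosome([1, 2, 3, 4])
        assert c.adjacencies() == {Adjacency(1, 2), Adjacency(2, 3), Adjacency(3, 4)}

    def test_single_block_has_none(self):
        assert Chromosome([5]).adjacencies() == frozenset()

    def test_circular_wraps(self):
        c = Chromosome([1, 2, 3], circular=True)
        assert Adjacency(3, 1) in c.adjacencies()
        assert len(c.adjacencies()) == 3

    @given(
        blocks=st.permutations(list(range(1, 8))).map(tuple),
        signs=st.lists(st.sampled_from([1, -1]), min_size=7, max_size=7),
    )
    @settings(max_examples=50, derandomize=True)
    def test_flip_invariance(self, blocks, signs):
        c = Chromosome([s * b for s, b in zip(signs, blocks)])
        assert c.adjacencies() == c.flipped().adjacencies()

    def test_duplicate_block_rejected(self):
        with pytest.raises(InvalidInputError):
            Chromosome([1, 2, -1])
        with pytest.raises(InvalidInputError):
            Genome("x", [Chromosome([1, 2]), Chromosome([2, 3])])


def test_syntenic_ignores_order_and_sign():
    # {h -g -f d} and {-d f g h} are syntenic
    assert syntenic([8, -7, -6, 4], [-4, 6, 7, 8])
    assert syntenic([1, 2], [1, 2])
    assert not syntenic([1, 2], [1, 3])


class TestApplyDCJ:
    def test_worked_inversion(self):
        # cutting (a b) and (c d) in (. a b c d .) yields (. a -c -b d .)
        g = Genome("A", [Chromosome([1, 2, 3, 4])])
        out = apply_dcj(g, Adjacency(1, 2), Adjacency(3, 4), rewiring=0)
        assert [c.blocks for c in out.chromosomes] == [(1, -3, -2, 4)]

    def test_involution(self):
        g = Genome("A", [Chromosome([1, 2, 3, 4])])
        out = apply_dcj(g, Adjacency(1, 2), Adjacency(3, 4), rewiring=0)
        back = apply_dcj(out, Adjacency(1, -3), Adjacency(-2, 4), rewiring=0)
        assert adjacencies_of(back) == adjacencies_of(g)

    def test_adjacency_accounting(self):
        from carbuild.model import left_extremity, right_extremity

        rng = random.Random(11)
        for _ in range(30):
            blocks = [rng.choice([1, -1]) * b for b in range(1, 9)]
            rng.shuffle(blocks)
            g = Genome("G", [Chromosome(blocks)])
            adjs = sorted(adjacencies_of(g))
            a1, a2 = rng.sample(adjs, 2)
            rewiring = rng.choice([0, 1])
            p1, q1 = right_extremity(a1.left), left_extremity(a1.right)
            p2, q2 = right_extremity(a2.left), left_extremity(a2.right)
            joins = [(p1, p2), (q1, q2)] if rewiring == 0 else [(p1, q2), (q1, p2)]
            if any(e1[0] == e2[0] for e1, e2 in joins):
                continue  # would excise a single-block circle: -2/+1 case
            out = apply_dcj(g, a1, a2, rewiring=rewiring)
            before, after = adjacencies_of(g), adjacencies_of(out)
            assert len(before - after) == 2 and len(after - before) == 2
            assert {abs(b) for c in out.chromosomes for b in c.blocks} == set(
                range(1, 9)
            )

    def test_errors(self):
        g = Genome("A", [Chromosome([1, 2, 3, 4])])
        with pytest.raises(InvalidInputError):
            apply_dcj(g, Adjacency(1, 3), Adjacency(2, 4))  # absent
        with pytest.raises(InvalidInputError):
            apply_dcj(g, Adjacency(1, 2), Adjacency(1, 2))  # same cut twice
        with pytest.raises(InvalidInputError):
            apply_dcj(g, Adjacency(1, 2), Adjacency(3, 4), rewiring=7)


class TestConcatenate:
    def test_merge_two_singletons(self):
        cs = CARSet.singletons([1, 2])
        res = concatenate(cs, [Adjacency(1, 2)])
        assert [c.blocks for c in res.car_set] == [(1, 2)]
        assert res.added == [Adjacency(1, 2)]

    def test_merge_with_flip(self):
        # cars {a b}, {c d} joined by (b -d) -> {a b -d -c}
        cs = CARSet([CAR([1, 2], 1), CAR([3, 4], 2)])
        res = concatenate(cs, [Adjacency(2, -4)])
        (car,) = list(res.car_set)
        assert car.blocks in ((1, 2, -4, -3), (3, 4, -2, -1))

    def test_identity_on_empty(self):
        cs = CARSet([CAR([1, 2], 1), CAR([3], 2)])
        res = concatenate(cs, [])
        assert {c.blocks for c in res.car_set} == {(1, 2), (3,)}

    def test_cycle_is_skipped(self):
        cs = CARSet([CAR([1, 2], 1)])
        res = concatenate(cs, [Adjacency(2, 1)])
        assert res.cycle_skipped == [Adjacency(2, 1)]
        assert res.added == []
        assert [c.blocks for c in res.car_set] == [(1, 2)]

    def test_non_end_adjacency_rejected(self):
        cs = CARSet([CAR([1, 2, 3], 1), CAR([4], 2)])
        with pytest.raises(InvalidInputError):
            concatenate(cs, [Adjacency(2, 4)])  # 2's head is internal

    def test_block_conservation_under_random_merges(self):
        rng = random.Random(5)
        for _ in range(20):
            n = rng.randint(4, 10)
            cs = CARSet.singletons(range(1, n + 1))
            # random chain of compatible end-joins
            order = [rng.choice([1, -1]) * b for b in range(1, n + 1)]
            rng.shuffle(order)
            adjs = [Adjacency(x, y) for x, y in zip(order, order[1:])]
            picked = rng.sample(adjs, rng.randint(0, len(adjs)))
            res = concatenate(cs, picked)
            assert res.car_set.block_universe == frozenset(range(1, n + 1))
            assert len(res.car_set) == n - len(res.added)
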