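"""CAR-adjacency detection, conserved classification, DCJ-reliable detection."""

import random


from oracles import brute_car_adjacency_pairs, brute_dcj_reliable, random_carset, random_genome

from carbuild.model import Adjacency, CAR, CARSet, Chromosome, Genome, adjacencies_of
from carbuild.detection import (
    block_adjacency_of,
    classify_conserved,
    detect_car_adjacencies,
    detect_dcj_reliable,
    make_car_adjacency,
)
from carbuild.phylogeny import SpeciesTree, partition_of


class TestWorkedExample:
    """car_1 = abc, car_2 = defg, car_3 = hij; G = (b c -d f)(e -g i j a -h)."""

    def test_exactly_three_car_adjacencies(self, worked_example):
        genome, cars = worked_example
        found = detect_car_adjacencies(genome, cars)
        expected = {
            make_car_adjacency(1, 1, 2, 1, 3, 4).car_pair(),  # (car1 car2)
            make_car_adjacency(2, 1, 3, -1, 7, -10).car_pair(),  # (car2 -car3)
            make_car_adjacency(3, 1, 1, 1, 10, 1).car_pair(),  # (car3 car1)
        }
        assert {ca.car_pair() for ca in found} == expected

    def test_block_adjacencies_and_tiers(self, worked_example):
        genome, cars = worked_example
        found = {ca.car_pair(): ca for ca in detect_car_adjacencies(genome, cars)}
        ca12 = found[make_car_adjacency(1, 1, 2, 1, 3, 4).car_pair()]
        assert block_adjacency_of(ca12) == Adjacency(3, 4)  # (c d)
        assert (ca12.left_tier, ca12.right_tier) == ("i", "ii")
        ca23 = found[make_car_adjacency(2, 1, 3, -1, 7, -10).car_pair()]
        assert block_adjacency_of(ca23) == Adjacency(7, -10)  # (g -j)
        assert (ca23.left_tier, ca23.right_tier) == ("ii", "iii")
        ca31 = found[make_car_adjacency(3, 1, 1, 1, 10, 1).car_pair()]
        assert block_adjacency_of(ca31) == Adjacency(10, 1)  # (j a)
        assert (ca31.left_tier, ca31.right_tier) == ("i", "i")

    def test_car_pair_flip_symmetry(self):
        a = make_car_adjacency(1, 1, 2, -1, 3, -7)
        b = make_car_adjacency(2, 1, 1, -1, 7, -3)
        assert a == b
        assert block_adjacency_of(a) == block_adjacency_of(b)


class TestSingletonCARs:
    def test_singletons_recover_block_adjacencies(self):
        rng = random.Random(9)
        for _ in range(25):
            g = random_genome(rng, rng.randint(2, 12), circular_prob=0.3)
            cs = CARSet.singletons(g.block_universe)
            found = {
                block_adjacency_of(ca) for ca in detect_car_adjacencies(g, cs)
            }
            assert found == set(adjacencies_of(g))


class TestAgainstBruteForce:
    def test_detection_matches_literal_enumeration(self):
        rng = random.Random(17)
        for _ in range(40):
            n = rng.randint(3, 12)
            g = random_genome(rng, n, circular_prob=0.25)
            cs = random_carset(rng, n)
            impl = {ca.car_pair() for ca in detect_car_adjacencies(g, cs)}
            assert impl == brute_car_adjacency_pairs(g, cs)

    def test_proposition_one_bound(self):
        # at most two CAR adjacencies of the form (car_a car_x) per signed
        # CAR end per genome
        rng = random.Random(23)
        for _ in range(40):
            n = rng.randint(4, 14)
            g = random_genome(rng, n)
            cs = random_carset(rng, n)
            counts: dict[tuple[int, int], int] = {}
            for ca in detect_car_adjacencies(g, cs):
                (l, lo), (r, ro) = ca.car_pair()
                counts[(l, lo)] = counts.get((l, lo), 0) + 1
                counts[(r, -ro)] = counts.get((r, -ro), 0) + 1
            assert all(v <= 2 for v in counts.values())


class TestClassifyConserved:
    def test_five_genome_instance(self, five_genomes):
        genomes, _, part = five_genomes
        cs = CARSet.singletons(genomes[0].block_universe)
        records = {r.adjacency: r for r in classify_conserved(cs, genomes, part)}
        assert records[Adjacency(6, 7)].conservation == "fully"  # (f g)
        for adj in [Adjacency(1, 2), Adjacency(3, -5), Adjacency(7, 8), Adjacency(7, -8)]:
            assert adj in records
            assert records[adj].homoplasy <= 1
        # (a -b) is present in genome B only: not conserved
        assert Adjacency(1, -2) not in records

    def test_same_set_support_excluded(self):
        # adjacency shared by two outgroup genomes only is not conserved
        tree = SpeciesTree.from_newick("((I1,I2)ANC,(O1,O2));", ancestor_label="ANC")
        part = partition_of(tree)
        genomes = [
            Genome("O1", [Chromosome([1, 2, 3])]),
            Genome("O2", [Chromosome([1, 2]), Chromosome([3])]),
            Genome("I1", [Chromosome([2, 1]), Chromosome([3])]),
            Genome("I2", [Chromosome([1, 3]), Chromosome([2])]),
        ]
        cs = CARSet.singletons({1, 2, 3})
        records = {r.adjacency for r in classify_conserved(cs, genomes, part)}
        assert Adjacency(1, 2) not in records  # only O1, O2
        assert Adjacency(2, 3) not in records  # only O1

    def test_blacklist_and_internal_excluded(self, five_genomes):
        genomes, _, part = five_genomes
        cs = CARSet.singletons(genomes[0].block_universe)
        records = {
            r.adjacency
            for r in classify_conserved(
                cs, genomes, part, blacklist={Adjacency(6, 7)}
            )
        }
        assert Adjacency(6, 7) not in records


class TestDCJReliable:
    def _instance(self):
        # CARs [p a], [b q], [x y]; G1 (ingroup) holds (a y) and (x b);
        # G2 (outgroup) witnesses the CAR adjacency ([p a] [b q])
        cs = CARSet([CAR([1, 2], 1), CAR([3, 4], 2), CAR([5, 6], 3)])
        tree = SpeciesTree.from_newick("((G3,G1)ANC,G2);", ancestor_label="ANC")
        genomes = [
            Genome("G1", [Chromosome([1, 2, 6]), Chromosome([5, 3, 4])]),
            Genome("G2", [Chromosome([1, 2, 3, 4]), Chromosome([5, 6])]),
            Genome("G3", [Chromosome([1, 2]), Chromosome([3, 4]), Chromosome([5, 6])]),
        ]
        return cs, genomes, partition_of(tree)

    def test_constructed_example(self):
        cs, genomes, part = self._instance()
        assert detect_dcj_reliable(cs, genomes, part) == [Adjacency(2, 3)]

    def test_no_witness_genome_means_empty(self):
        cs, genomes, part = self._instance()
        # remove the witness adjacencies from G1
        genomes[0] = Genome(
            "G1", [Chromosome([1, 2]), Chromosome([3, 4]), Chromosome([5, 6])]
        )
        assert detect_dcj_reliable(cs, genomes, part) == []

    def test_homoplasy_cost_is_two(self):
        cs, genomes, part = self._instance()
        from carbuild.phylogeny import homoplasy_cost
        from carbuild.detection import detect_car_adjacencies as det

        for cand in detect_dcj_reliable(cs, genomes, part):
            support = {
                g.name: any(
                    block_adjacency_of(ca) == cand for ca in det(g, cs)
                )
                for g in genomes
            }
            assert homoplasy_cost(support, part) == 2

    def test_matches_brute_force(self):
        rng = random.Random(31)
        tree = SpeciesTree.from_newick("((L1,L2)ANC,(L3,L4));", ancestor_label="ANC")
        part = partition_of(tree)
        for _ in range(30):
            n = rng.randint(4, 10)
            genomes = [random_genome(rng, n, name=f"L{i}") for i in range(1, 5)]
            cs = random_carset(rng, n)
            impl = set(detect_dcj_reliable(cs, genomes, part))
            assert impl == brute_dcj_reliable(cs, genomes, part)
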