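"""A small synthetic five-genome instance used in docs and acceptance checks.

This instance is constructed (synthetic, not measured data) so that the
classic textbook situations all occur at the tagged ancestor — the parent
of genomes D and E, inducing the partition I1={D}, I2={E}, O={A,B,C}:

* ``(f g)`` is fully conserved (homoplasy cost 0): present in A, B (both
  outgroup), D and E;
* ``(a b)`` is partly conserved (cost 1): present in A, C and E only;
* ``(a -b)`` occurs in a single set (cost 2): genome B only;
* ``(a c)`` occurs nowhere (cost 3);
* ``(g h)`` and ``(g -h)`` are two conflicting conserved adjacencies,
  with minimum mutation costs 3 and 2 respectively under the tree below;
* D and E contain the syntenic segments ``{h -g -f d}`` and ``{-d f g h}``.

Blocks a..h are encoded as 1..8.
"""

from __future__ import annotations

from .model import Chromosome, Genome
from .phylogeny import SpeciesTree

#: Letter names for the eight blocks, for readable tests and docs.
BLOCKS = {letter: i for i, letter in enumerate("abcdefgh", start=1)}

NEWICK = "((D,E)ANC,(C,(A,B)));"


def sb(token: str) -> int:
    """Parse a signed letter block, e.g. ``'-g'`` -> -7."""
    if token.startswith("-"):
        return -BLOCKS[token[1:]]
    return BLOCKS[token]


def seq(spec: str) -> list[int]:
    """Parse a whitespace-separated signed letter sequence."""
    return [sb(tok) for tok in spec.split()]


def five_genome_example() -> tuple[list[Genome], SpeciesTree]:
    """The five genomes A..E and their species tree, ancestor tagged ANC."""
    genomes = [
        Genome("A", [Chromosome(seq("a b c d e f g h"))]),
        Genome("B", [Chromosome(seq("a -b c d e f g -h"))]),
        Genome("C", [Chromosome(seq("a b c d")), Chromosome(seq("e f g -h"))]),
        Genome("D", [Chromosome(seq("h -g -f d")), Chromosome(seq("b c -e a"))]),
        Genome("E", [Chromosome(seq("a b c -e")), Chromosome(seq("-d f g h"))]),
    ]
    tree = SpeciesTree.from_newick(NEWICK, ancestor_label="ANC")
    return genomes, tree


def worked_example_cars():
    """The three-CAR detection example: car_1=abc, car_2=defg, car_3=hij.

    Returns (genome, car_set) over blocks 1..10 (a..j); the genome exhibits
    exactly the CAR adjacencies (car_1 car_2), (car_2 -car_3), (car_3 car_1).
    """
    from .model import CAR, CARSet

    letters = {letter: i for i, letter in enumerate("abcdefghij", start=1)}

    def lseq(spec: str) -> list[int]:
        out = []
        for tok in spec.split():
            out.append(-letters[tok[1:]] if tok.startswith("-") else letters[tok])
        return out

    cars = CARSet(
        [
            CAR(lseq("a b c"), 1),
            CAR(lseq("d e f g"), 2),
            CAR(lseq("h i j"), 3),
        ]
    )
    genome = Genome(
        "G", [Chromosome(lseq("b c -d f")), Chromosome(lseq("e -g i j a -h"))]
    )
    return genome, cars
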