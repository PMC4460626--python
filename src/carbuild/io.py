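"""Readers and writers for the block-order dialect and reconstruction output.

Block-order files follow the de facto convention of gene-order tools: a
``>`` header names a genome, and each following non-empty line is one
chromosome — whitespace-separated signed integers terminated by ``$``
(linear) or ``@`` (circular)::

    >human
    1 2 3 4 $
    -5 6 @

All genomes must share one universe of positive block identifiers, each
occurring exactly once per genome.  Parsers reject malformed input with
errors naming the genome and line; they never silently repair.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TextIO

from .assembly import StepReport
from .model import CARSet, Chromosome, Genome, InvalidInputError
from .phylogeny import SpeciesTree


class BlockOrderError(InvalidInputError):
    """Malformed block-order document."""


def read_block_orders(text: str) -> list[Genome]:
    """Parse a block-order document into genomes, validating the universe."""
    genomes: list[Genome] = []
    name: str | None = None
    chromosomes: list[Chromosome] = []

    def flush(line_no: int) -> None:
        nonlocal name, chromosomes
        if name is None:
            return
        if not chromosomes:
            raise BlockOrderError(
                f"genome {name!r} has no chromosomes (line {line_no})"
            )
        try:
            genomes.append(Genome(name, chromosomes))
        except InvalidInputError as exc:
            raise BlockOrderError(f"{exc} (line {line_no})") from exc
        name, chromosomes = None, []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(line_no)
            name = line[1:].strip()
            if not name:
                raise BlockOrderError(f"empty genome name (line {line_no})")
            continue
        if name is None:
            raise BlockOrderError(
                f"chromosome data before any '>' header (line {line_no})"
            )
        tokens = line.split()
        terminator = tokens[-1]
        if terminator not in ("$", "@"):
            raise BlockOrderError(
                f"chromosome of genome {name!r} must end with '$' or '@' "
                f"(line {line_no})"
            )
        body = tokens[:-1]
        if not body:
            raise BlockOrderError(
                f"empty chromosome in genome {name!r} (line {line_no})"
            )
        blocks: list[int] = []
        for tok in body:
            try:
                b = int(tok)
            except ValueError:
                raise BlockOrderError(
                    f"invalid block token {tok!r} in genome {name!r} "
                    f"(line {line_no})"
                ) from None
            if b == 0:
                raise BlockOrderError(
                    f"block id 0 is not allowed in genome {name!r} (line {line_no})"
                )
            blocks.append(b)
        try:
            chromosomes.append(Chromosome(blocks, circular=(terminator == "@")))
        except InvalidInputError as exc:
            raise BlockOrderError(
                f"{exc} in genome {name!r} (line {line_no})"
            ) from exc
    flush(line_no=len(text.splitlines()) + 1)

    if not genomes:
        raise BlockOrderError("document contains no genomes")
    universe = genomes[0].block_universe
    for g in genomes[1:]:
        if g.block_universe != universe:
            extra = sorted(g.block_universe - universe)
            miss = sorted(universe - g.block_universe)
            raise BlockOrderError(
                f"genome {g.name!r} does not match the block universe of "
                f"{genomes[0].name!r}: extra {extra}, missing {miss}"
            )
    return genomes


def read_tree(
    text: str,
    ancestor_label: str | None = None,
    ancestor_leaf_pair: tuple[str, str] | None = None,
) -> SpeciesTree:
    """Parse a Newick species tree and tag the ancestral node.

    Branch lengths, if present, are parsed and discarded (the method is
    topology-only).  The ancestor is named by an internal node label or by
    a pair of leaf names (their most recent common ancestor); the label
    wins when both are given.
    """
    return SpeciesTree.from_newick(text, ancestor_label, ancestor_leaf_pair)


def write_block_orders(genomes: Iterable[Genome]) -> str:
    """Serialize genomes back to the block-order dialect."""
    lines: list[str] = []
    for g in genomes:
        lines.append(f">{g.name}")
        for c in g.chromosomes:
            term = "@" if c.circular else "$"
            lines.append(" ".join(str(b) for b in c.blocks) + f" {term}")
    return "\n".join(lines) + "\n"


def _normalized_car_blocks(blocks: Sequence[int]) -> tuple[int, ...]:
    forward = tuple(blocks)
    flipped = tuple(-b for b in reversed(forward))
    # prefer a positive leading block; deterministic fallback on the tuple
    key = lambda bs: (0 if bs[0] > 0 else 1, bs)
    return min(forward, flipped, key=key)


def write_cars(cs: CARSet) -> str:
    """Write a CAR set in the block-order dialect under genome ``ANCESTOR``.

    CARs are sorted by decreasing block count, then smallest unsigned block
    id; each CAR's orientation is normalized so its first block is positive.
    """
    cars = sorted(
        (car for car in cs),
        key=lambda car: (-len(car.blocks), min(abs(b) for b in car.blocks)),
    )
    lines = [">ANCESTOR"]
    for car in cars:
        blocks = _normalized_car_blocks(car.blocks)
        lines.append(" ".join(str(b) for b in blocks) + " $")
    return "\n".join(lines) + "\n"


def write_step_log(reports: Iterable[StepReport], stream: TextIO) -> None:
    """Emit the per-step trajectory as TSV (step, kind, #CARs, sizes, added)."""
    stream.write("step\tkind\tn_cars\tsize_min\tsize_max\tn_added\tadded\n")
    for r in reports:
        added = ",".join(f"{a.left}|{a.right}" for a in r.added)
        stream.write(
            f"{r.step_index}\t{r.step_kind}\t{r.n_cars_after}\t"
            f"{r.car_size_range[0]}\t{r.car_size_range[1]}\t{r.n_added}\t{added}\n"
        )
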