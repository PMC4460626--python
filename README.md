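# carbuild

Progressive reconstruction of ancestral gene orders from signed synteny
blocks.

Given the block orders of a set of extant genomes — every genome carrying
the same set of non-duplicated synteny blocks, each block a signed unit on
a linear or circular chromosome — and a rooted species tree with a tagged
internal node `A` having two children, `carbuild` infers the **Contiguous
Ancestral Regions (CARs)** of the genome at `A`: ordered sequences of
oriented blocks that were plausibly contiguous in that ancestor.  It is a
homology-based method for the small phylogeny problem: instead of
minimizing a rearrangement distance, it detects ancestral *adjacencies*
supported by conservation across the tree and assembles them greedily but
conservatively, preferring to discard conflicting evidence over forcing
joins.  The method is parameter-free and ignores branch lengths.

## Model

The tagged node partitions the leaves into two ingroups I₁, I₂ (its child
clades) and an outgroup O.  An adjacency `(x y)` — block `x` immediately
followed by block `y`, with `(x y) = (−y −x)` — is *conserved* at `A` when
genomes from at least two of the three sets contain it, *fully conserved*
when all three do.  Its **homoplasy cost** ∈ {0,1,2,3} counts the branches
around `A` on which it must have been independently gained or lost
(0 fully conserved, 1 partly, 2 one set only, 3 absent).

Starting from one single-block CAR per block, the assembly iterates:

* **step a** — detect *CAR adjacencies*: relaxed contiguities between the
  ends of two current CARs, witnessed by consecutive segments in an extant
  genome and tolerant of micro-rearrangements near CAR ends.  Add all
  non-conflicting fully-conserved adjacencies, then the non-conflicting
  partly-conserved ones compatible with every fully-conserved adjacency.
* **step b** — when step a retains nothing but conflicts remain: score each
  conflicting adjacency by its **mutation cost** (minimum number of
  presence/absence changes on tree edges, leaves fixed by observation and
  the ancestor fixed to "present" — two-state small parsimony with
  clamping) and add an exact maximum-size, minimum-cost non-conflicting
  subset (solved as maximum-weight matching on block extremities).
* **step c** — when no conserved candidate remains: add *DCJ-reliable*
  adjacencies, non-conserved candidates that, together with an adjacency
  already inside the CARs, explain two adjacencies of an extant genome by a
  single Double-Cut-and-Join event on a path through the ancestor.

Adjacencies losing a conflict are discarded permanently; every productive
step merges CARs end-to-end until no signal remains.

## File formats

Block-order files: `>` + genome name, then one chromosome per line as
whitespace-separated signed integers terminated by `$` (linear) or `@`
(circular).  Trees are standard Newick; the ancestor is tagged by an
internal node label or by a pair of leaf names (their most recent common
ancestor).

## Worked example

The bundled synthetic five-genome instance (`carbuild.examples`, blocks
a..h = 1..8, ancestor = parent of D and E):

```
$ carbuild run --genomes genomes.txt --tree tree.nwk --ancestor ANC \
      --out cars.txt --log steps.tsv --verbose
INFO step 1 (a): 3 CARs, sizes 1-4, 5 adjacencies added
INFO step 2 (b): 2 CARs, sizes 4-4, 1 adjacencies added
2 CARs, 6 adjacencies, 2 productive steps

$ cat cars.txt
>ANCESTOR
1 2 3 -5 $
8 -7 -6 4 $
```

Step 1 adds the five non-conflicting conserved adjacencies, e.g. the fully
conserved `(6 7)` = (f g).  Step 2 resolves the conflict between `(7 8)` =
(g h) and `(7 -8)` = (g −h): their mutation costs are 3 and 2, so the
cheaper `(g −h)` is kept and `(g h)` is permanently discarded.  The two
reconstructed CARs are `a b c −e` and `h −g −f d` (a CAR equals its
flipped form, so the second is also `−d f g h`).

The same pipeline is available in the library:

```python
from carbuild import reconstruct
from carbuild.examples import five_genome_example

genomes, tree = five_genome_example()
result = reconstruct(genomes, tree)
print([car.blocks for car in result.car_set])
# [(1, 2, 3, -5), (-4, 6, 7, -8)]
```

`carbuild simulate` evolves a root genome down a tree by random DCJ events
(inversions, translocations, fusions, fissions) and writes the leaf
genomes plus the true internal genomes; `carbuild compare` reports
pairwise breakpoint distances and shared-adjacency counts between
reconstructions.

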