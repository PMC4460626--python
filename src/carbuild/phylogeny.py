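"""Species-tree handling, ancestral partition, and adjacency cost functions.

The reconstruction targets one *tagged ancestral node* of a rooted species
tree: an internal node with exactly two children.  That node induces a
partition of the extant genomes into two ingroup sets I1 and I2 (the leaf
sets of its two child subtrees) and an outgroup set O (all other leaves).

Two scores are computed on the tree for a candidate ancestral adjacency,
both from its per-genome presence/absence (its *occupancy*):

* the **homoplasy cost** in {0,1,2,3} counts, around the ancestor, the
  branches on which the adjacency must have been independently gained or
  lost: 0 if present in all three of I1, I2, O ("fully conserved"), 1 if
  conserved but not fully (present in >=2 of the sets), 2 if present in
  only one set, 3 if present nowhere;
* the **mutation cost** is the minimum number of presence/absence state
  changes over the tree edges, with leaves clamped to the occupancy and
  the ancestral node clamped to "present" — a two-state small-parsimony
  problem solved by dynamic programming (Fitch/Sankoff style) with node
  clamping.

Branch lengths carry no weight in either score; Newick branch lengths are
parsed and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

from .model import InvalidInputError

FULLY = "fully"
PARTLY = "partly"
ONE_SET_ONLY = "one_set_only"
ABSENT = "absent"

_HOMOPLASY = {FULLY: 0, PARTLY: 1, ONE_SET_ONLY: 2, ABSENT: 3}
_INF = 10**9


class TreeError(InvalidInputError):
    """Raised for malformed trees or unresolvable ancestor specifications."""


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class SpeciesPartition:
    """The three genome sets induced by the tagged ancestral node."""

    i1: frozenset[str]
    i2: frozenset[str]
    o: frozenset[str]

    def set_of(self, genome: str) -> str:
        if genome in self.i1:
            return "I1"
        if genome in self.i2:
            return "I2"
        if genome in self.o:
            return "O"
        raise KeyError(genome)

    @property
    def all_genomes(self) -> frozenset[str]:
        return self.i1 | self.i2 | self.o


class SpeciesTree:
    """A rooted species tree with one tagged binary ancestral node.

    The tree may be non-binary anywhere else (taxonomy-derived trees often
    contain polytomies).  Unlabeled internal nodes receive stable automatic
    labels ``node_1, node_2, ...`` in preorder.
    """

    def __init__(self, root: TreeNode, ancestor: TreeNode):
        self.root = root
        self.ancestor = ancestor
        labels = [lf.label for lf in root.leaves()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf names in species tree")
        self._validate_ancestor()

    def _validate_ancestor(self) -> None:
        anc = self.ancestor
        if anc.is_leaf:
            raise TreeError("ancestral node must be internal")
        if len(anc.children) != 2:
            raise TreeError(
                f"ancestral node {anc.label!r} must have exactly two children, "
                f"found {len(anc.children)}"
            )

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.label for lf in self.root.leaves())

    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(n: TreeNode) -> None:
            out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    @classmethod
    def from_newick(
        cls,
        text: str,
        ancestor_label: str | None = None,
        ancestor_leaf_pair: tuple[str, str] | None = None,
    ) -> "SpeciesTree":
        """Parse a Newick tree and tag the ancestral node.

        The ancestor is designated by an internal-node label, or by a pair
        of leaf names whose most recent common ancestor is taken; the label
        wins when both are given.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"cannot parse Newick tree: {exc}") from exc

        counter = [0]

        def convert(dnode: dendropy.Node) -> TreeNode:
            if dnode.is_leaf():
                if dnode.taxon is None or not dnode.taxon.label:
                    raise TreeError("unlabeled leaf in species tree")
                return TreeNode(dnode.taxon.label, [])
            label = dnode.label
            if not label:
                counter[0] += 1
                label = f"node_{counter[0]}"
            return TreeNode(label, [convert(c) for c in dnode.child_nodes()])

        root = convert(dtree.seed_node)
        tree_nodes: list[TreeNode] = []

        def collect(n: TreeNode) -> None:
            tree_nodes.append(n)
            for c in n.children:
                collect(c)

        collect(root)

        anc: TreeNode | None = None
        if ancestor_label is not None:
            matches = [n for n in tree_nodes if n.label == ancestor_label]
            if not matches:
                raise TreeError(f"no node labeled {ancestor_label!r} in tree")
            anc = matches[0]
        elif ancestor_leaf_pair is not None:
            anc = _mrca(root, ancestor_leaf_pair)
        else:
            raise TreeError("an ancestor label or leaf pair is required")
        return cls(root, anc)


def _mrca(root: TreeNode, leaf_pair: tuple[str, str]) -> TreeNode:
    a, b = leaf_pair

    def rec(n: TreeNode) -> tuple[TreeNode | None, frozenset[str]]:
        if n.is_leaf:
            return None, frozenset([n.label])
        found = None
        names: set[str] = set()
        for c in n.children:
            f, s = rec(c)
            if f is not None:
                found = f
            names |= s
        if found is None and a in names and b in names:
            found = n
        return found, frozenset(names)

    found, names = rec(root)
    for leaf in leaf_pair:
        if leaf not in names:
            raise TreeError(f"leaf {leaf!r} not found in tree")
    if found is None:
        raise TreeError(f"no common ancestor for {leaf_pair}")
    return found


def partition_of(tree: SpeciesTree) -> SpeciesPartition:
    """The (I1, I2, O) partition induced by the tagged ancestral node."""
    anc = tree.ancestor
    i1 = frozenset(lf.label for lf in anc.children[0].leaves())
    i2 = frozenset(lf.label for lf in anc.children[1].leaves())
    o = tree.leaf_names - i1 - i2
    if not o:
        raise TreeError(
            "outgroup is empty: the ancestral node must not cover all leaves"
        )
    return SpeciesPartition(i1, i2, o)


def conservation_class(
    occ: Mapping[str, bool], part: SpeciesPartition
) -> str:
    """Classify an adjacency occupancy relative to the species partition.

    Returns one of ``fully`` (present in >=1 genome of each of I1, I2, O),
    ``partly`` (present in exactly two of the sets), ``one_set_only``, or
    ``absent``.  ``fully`` and ``partly`` together are the *conserved*
    adjacencies: those shared by two genomes whose path crosses the
    ancestor.
    """
    missing = part.all_genomes - set(occ)
    if missing:
        raise InvalidInputError(f"occupancy missing genomes: {sorted(missing)}")
    n_sets = sum(
        any(occ[g] for g in s) for s in (part.i1, part.i2, part.o)
    )
    if n_sets == 3:
        return FULLY
    if n_sets == 2:
        return PARTLY
    if n_sets == 1:
        return ONE_SET_ONLY
    return ABSENT


def homoplasy_cost(occ: Mapping[str, bool], part: SpeciesPartition) -> int:
    """Homoplasy cost in {0,1,2,3} of an adjacency at the ancestral node."""
    return _HOMOPLASY[conservation_class(occ, part)]


def mutation_cost(occ: Mapping[str, bool], tree: SpeciesTree) -> int:
    """Minimum number of state changes explaining an adjacency's history.

    Leaves are clamped to the occupancy, the tagged ancestral node is
    clamped to state 1 (present), and every other internal node ranges
    freely over {0, 1}; the cost of a labeling is the number of tree edges
    whose endpoints differ.  Computed by postorder dynamic programming;
    handles arbitrary out-degrees.
    """
    missing = tree.leaf_names - set(occ)
    if missing:
        raise InvalidInputError(f"occupancy missing genomes: {sorted(missing)}")

    def dp(node: TreeNode) -> tuple[int, int]:
        if node.is_leaf:
            state = 1 if occ[node.label] else 0
            return (0, _INF) if state == 0 else (_INF, 0)
        c0 = c1 = 0
        for child in node.children:
            s0, s1 = dp(child)
            c0 += min(s0, s1 + 1)
            c1 += min(s1, s0 + 1)
        if node is tree.ancestor:
            c0 = _INF
        return (min(c0, _INF), min(c1, _INF))

    return min(dp(tree.root))
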