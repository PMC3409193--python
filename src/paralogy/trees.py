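"""Tree handling and Fitch small parsimony.

Trees are dendropy :class:`~dendropy.Tree` objects throughout; newick leaf
labels are taken verbatim (underscores preserved, no quoting games).  The
Fitch routine here is shared by the site-classification and micro-indel
modules: it computes the minimum number of state changes for one character
on one topology, treating missing observations as unconstrained.  Fitch
counts are invariant to root placement, so unrooted topologies may be
passed rooted arbitrarily.
"""

from __future__ import annotations

import itertools
from typing import Hashable, Mapping

import dendropy

__all__ = [
    "parse_tree",
    "tree_from_newick",
    "leaf_labels",
    "same_unrooted_topology",
    "fitch_count",
    "brute_force_count",
]


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string into a dendropy Tree, preserving underscores."""
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def parse_tree(path) -> dendropy.Tree:
    """Read a newick tree from a file path."""
    with open(path) as fh:
        return tree_from_newick(fh.read())


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def same_unrooted_topology(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> bool:
    """True iff the two trees induce the same unrooted topology on shared leaves."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=to_newick(tree_a), schema="newick",
        preserve_underscores=True, taxon_namespace=tns,
    )
    b = dendropy.Tree.get(
        data=to_newick(tree_b), schema="newick",
        preserve_underscores=True, taxon_namespace=tns,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return (
        dendropy.calculate.treecompare.symmetric_difference(a, b) == 0
    )


def fitch_count(
    tree: dendropy.Tree, states: Mapping[str, Hashable | None]
) -> int:
    """Fitch parsimony count of one character on ``tree``.

    ``states`` maps leaf label -> state; a value of ``None`` (or an absent
    label) marks missing data and places no constraint on the tree.
    """
    steps = 0

    def visit(node) -> frozenset | None:
        nonlocal steps
        if node.is_leaf():
            s = states.get(node.taxon.label)
            return None if s is None else frozenset([s])
        child_sets = [visit(c) for c in node.child_nodes()]
        child_sets = [s for s in child_sets if s is not None]
        if not child_sets:
            return None
        acc = child_sets[0]
        for s in child_sets[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                steps += 1
        return acc

    visit(tree.seed_node)
    return steps


def brute_force_count(
    tree: dendropy.Tree, states: Mapping[str, Hashable | None]
) -> int:
    """Exhaustive minimum-change count for one character (oracle, small trees).

    Enumerates every assignment of observed states to internal nodes (and to
    missing-data leaves) and counts edges whose endpoints differ.  Exponential;
    intended for trees of <= ~8 leaves.
    """
    observed = sorted(
        {s for s in states.values() if s is not None}, key=repr
    )
    if len(observed) <= 1:
        return 0
    nodes = list(tree.preorder_node_iter())
    free = [
        n for n in nodes
        if not n.is_leaf() or states.get(n.taxon.label) is None
    ]
    fixed = {
        id(n): states[n.taxon.label]
        for n in nodes
        if n.is_leaf() and states.get(n.taxon.label) is not None
    }
    best = None
    for combo in itertools.product(observed, repeat=len(free)):
        assign = dict(fixed)
        for n, s in zip(free, combo):
            assign[id(n)] = s
        changes = sum(
            1
            for n in nodes
            if n.parent_node is not None and assign[id(n)] != assign[id(n.parent_node)]
        )
        if best is None or changes < best:
            best = changes
    return best
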