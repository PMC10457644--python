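"""Reconstruct CRISPR array evolution on a fixed tree topology.

Given a Newick topology whose leaves map to input arrays, ancestral arrays
are inferred post-order with the same pairwise engine as the tree builder,
events are annotated on every branch, and spacers that must have been
acquired independently on two or more branches are flagged — the signature
of horizontal transfer (or convergent acquisition) when the forced
topology splits arrays that share recently acquired spacers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy

from .arrays import CostScheme, CRISPRArray
from .pairwise import (
    ACQUISITION,
    INDEPENDENT_ACQ,
    INSERTION,
    AlignScores,
    Event,
    PairwiseCache,
)
from .tree import ArrayTree, TreeNode, _anc_names

__all__ = ["constrain", "flag_independent_acquisitions", "FlaggedRun"]


@dataclass(frozen=True)
class FlaggedRun:
    """A contiguous run of independently acquired spacers on one branch."""

    node_name: str
    spacers: tuple[str, ...]
    position: int


def _resolve_polytomy_arrays(
    child_arrays: list[tuple[str, ...]], cache: PairwiseCache
) -> tuple[str, ...]:
    """Ancestor of 3+ children: greedily pair the two highest-scoring
    arrays, replace them by their ancestor, repeat."""
    pool = list(child_arrays)
    while len(pool) > 1:
        best = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                s = cache.score(pool[i], pool[j])
                if best is None or s > best[0]:
                    best = (s, i, j)
        _, i, j = best
        anc = cache.ancestor(pool[i], pool[j])
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [anc]
    return pool[0]


def constrain(
    topology: str | dendropy.Tree,
    leaf_to_array: Mapping[str, CRISPRArray],
    costs: CostScheme = CostScheme(),
    scores: AlignScores = AlignScores(),
) -> ArrayTree:
    """Populate a fixed topology with ancestral arrays and branch events.

    ``topology`` is Newick text (or a dendropy Tree); every leaf label must
    appear in ``leaf_to_array``. Unrooted input is rooted at the first
    bipartition with a warning. Internal nodes are filled post-order using
    the pairwise ancestor inference; polytomies are resolved by iteratively
    pairing the most similar children.
    """
    if isinstance(topology, dendropy.Tree):
        dtree = topology
    else:
        dtree = dendropy.Tree.get(data=topology, schema="newick")
    if dtree.is_rooted is False:  # explicit [&U]; plain newick reads as rooted
        warnings.warn("input tree is explicitly unrooted; rooting at the "
                      "first bipartition", stacklevel=2)
    dtree.is_rooted = True
    dtree.suppress_unifurcations()

    cache = PairwiseCache(costs, scores)
    names = _anc_names()

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = (dnode.taxon.label if dnode.taxon is not None
                     else dnode.label)
            if label not in leaf_to_array:
                raise ValueError(f"leaf {label!r} has no mapped array")
            return TreeNode(label, leaf_to_array[label].spacers)
        children = [convert(c) for c in dnode.child_nodes()]
        if len(children) == 1:
            return children[0]
        if len(children) == 2:
            arr = cache.ancestor(children[0].array, children[1].array)
        else:
            arr = _resolve_polytomy_arrays([c.array for c in children], cache)
        node = TreeNode(next(names), arr, children=children)
        for c in children:
            c.parent = node
        return node

    root = convert(dtree.seed_node)
    tree = ArrayTree(root)
    for node in tree.nodes():
        if node.parent is not None:
            node.branch_cost = cache.branch_cost(node.array, node.parent.array)
            node.events = cache.events(node.array, node.parent.array)
    return tree


def flag_independent_acquisitions(
    tree: ArrayTree,
    costs: CostScheme = CostScheme(),
    recost: bool = False,
) -> list[FlaggedRun]:
    """Flag spacers gained on two or more branches of a populated tree.

    Every spacer appearing in acquisition or insertion events on at least
    two distinct branches is flagged on each such branch; contiguous
    flagged spacers within one branch's events form a single run. With
    ``recost=True`` each flagged run is re-costed at the
    independent-acquisition cost (replacing the original acquisition /
    insertion cost of the spacers involved) and branch events updated.
    """
    gained_on: dict[str, set[str]] = {}
    for node in tree.nodes():
        if not node.events:
            continue
        for ev in node.events:
            if ev.kind in (ACQUISITION, INSERTION):
                for s in ev.spacers:
                    gained_on.setdefault(s, set()).add(node.name)
    repeated = {s for s, nodes in gained_on.items() if len(nodes) >= 2}

    runs: list[FlaggedRun] = []
    for node in tree.nodes():
        if not node.events:
            continue
        # flagged gain events on this branch, in leader-to-trailer order
        flagged = [ev for ev in sorted(node.events, key=lambda e: e.position)
                   if ev.kind in (ACQUISITION, INSERTION)
                   and any(s in repeated for s in ev.spacers)]
        if not flagged:
            continue
        # merge contiguous flagged spacers into runs
        current: list[Event] = []
        groups: list[list[Event]] = []
        for ev in flagged:
            if current and ev.position <= current[-1].position + len(
                    current[-1].spacers):
                current.append(ev)
            else:
                if current:
                    groups.append(current)
                current = [ev]
        if current:
            groups.append(current)
        for grp in groups:
            spacers = tuple(s for ev in grp for s in ev.spacers)
            runs.append(FlaggedRun(node.name, spacers, grp[0].position))
        if recost:
            keep = [ev for ev in node.events
                    if ev not in flagged]
            for grp in groups:
                spacers = tuple(s for ev in grp for s in ev.spacers)
                keep.append(Event(INDEPENDENT_ACQ, spacers, grp[0].position,
                                  costs.independent_acquisition))
            node.events.events = sorted(keep, key=lambda e: e.position)
            node.branch_cost = node.events.total_cost
    return runs
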