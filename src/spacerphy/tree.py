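"""Maximum-parsimony tree inference over CRISPR arrays.

Trees are built by sequential addition: starting from two arrays and their
inferred ancestor, each remaining array is attached as the sibling of its
closest match (by spacer-alignment score) among all arrays already in the
tree, leaf or ancestral; ancestors along the root path are then
regenerated. Repeating this over many addition orders yields candidate
trees scored by total parsimony cost (the sum of branch costs); the
cheapest tree(s) win. Internal nodes with zero-cost branches are collapsed
into polytomies. Node support is the fraction of all constructed trees
that contain the same descendant set, via a binary encoding of each
internal node.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np

from .arrays import CostScheme, CRISPRArray
from .pairwise import AlignScores, EventSet, PairwiseCache

__all__ = [
    "TreeNode",
    "ArrayTree",
    "TreeSearchResult",
    "build_tree",
    "encode_tree",
    "node_support",
    "to_newick",
    "plot_tree",
    "exhaustive_best_cost",
]


def _anc_names():
    """Anc_a, Anc_b, ..., Anc_z, Anc_aa, ... in discovery order."""
    letters = string.ascii_lowercase
    k = 1
    while True:
        if k == 1:
            for c in letters:
                yield f"Anc_{c}"
        else:
            from itertools import product
            for combo in product(letters, repeat=k):
                yield "Anc_" + "".join(combo)
        k += 1


@dataclass
class TreeNode:
    """A node of an array tree.

    Leaves carry input arrays (name = array id); internal nodes carry
    hypothetical ancestral arrays (name = "Anc_*"). ``branch_cost`` is the
    summed event cost on the branch to the parent (None at the root).
    """

    name: str
    array: tuple[str, ...]
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    branch_cost: Optional[float] = None
    events: Optional[EventSet] = None
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    def traverse_preorder(self) -> Iterable["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.traverse_preorder() if n.is_leaf}


@dataclass
class ArrayTree:
    """A rooted tree over input arrays with ancestral states and costs."""

    root: TreeNode

    def nodes(self) -> list[TreeNode]:
        return list(self.root.traverse_preorder())

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if not n.is_leaf]

    @property
    def total_cost(self) -> float:
        return sum(n.branch_cost or 0.0 for n in self.nodes()
                   if n.parent is not None)


@dataclass
class TreeSearchResult:
    """Outcome of a tree search: best tree(s) plus everything examined."""

    best_trees: list[ArrayTree]
    n_trees_examined: int
    examined_code_sets: list[frozenset[str]]
    array_order: list[str]

    @property
    def best_tree(self) -> ArrayTree:
        return self.best_trees[0]

    @property
    def total_cost(self) -> float:
        return self.best_trees[0].total_cost


# ---------------------------------------------------------------------------
# Construction for one addition order
# ---------------------------------------------------------------------------

def _recompute_costs(tree: ArrayTree, cache: PairwiseCache) -> None:
    for node in tree.nodes():
        if node.parent is not None:
            node.branch_cost = cache.branch_cost(node.array, node.parent.array)


def _annotate_all_events(tree: ArrayTree, cache: PairwiseCache) -> None:
    for node in tree.nodes():
        if node.parent is not None:
            node.events = cache.events(node.array, node.parent.array)


def _collapse_zero_cost(tree: ArrayTree) -> ArrayTree:
    """Merge zero-cost internal nodes into their parents (polytomies)."""
    changed = True
    while changed:
        changed = False
        for node in tree.nodes():
            if (node.parent is not None and not node.is_leaf
                    and node.branch_cost == 0):
                parent = node.parent
                idx = parent.children.index(node)
                for child in node.children:
                    child.parent = parent
                parent.children[idx:idx + 1] = node.children
                changed = True
                break
    return tree


def _build_one_order(
    order: Sequence[CRISPRArray], cache: PairwiseCache
) -> ArrayTree:
    names = _anc_names()
    leaves = [TreeNode(a.array_id, a.spacers) for a in order]
    root = TreeNode(next(names), cache.ancestor(leaves[0].array,
                                                leaves[1].array),
                    children=[leaves[0], leaves[1]])
    leaves[0].parent = leaves[1].parent = root
    tree = ArrayTree(root)
    for leaf in leaves[2:]:
        # closest match among all nodes already in the tree
        best = None
        best_key = None
        for node in tree.nodes():
            key = (-cache.score(leaf.array, node.array), node.depth(),
                   node.name)
            if best is None or key < best_key:
                best, best_key = node, key
        # attach as sibling of the best match
        new = TreeNode(next(names), ())
        parent = best.parent
        if parent is None:
            tree.root = new
        else:
            parent.children[parent.children.index(best)] = new
            new.parent = parent
        new.children = [best, leaf]
        best.parent = leaf.parent = new
        # regenerate ancestors from the new node up the root path
        node = new
        while node is not None:
            arr = cache.ancestor(node.children[0].array,
                                 node.children[1].array)
            if arr == node.array and node is not new:
                break  # inputs above are unchanged
            node.array = arr
            node = node.parent
    _recompute_costs(tree, cache)
    return _collapse_zero_cost(tree)


# ---------------------------------------------------------------------------
# Search over addition orders
# ---------------------------------------------------------------------------

def build_tree(
    arrays: Sequence[CRISPRArray],
    costs: CostScheme = CostScheme(),
    scores: AlignScores = AlignScores(),
    max_orders: int = 100,
    permutation_limit: int = 6,
    seed: int = 0,
) -> TreeSearchResult:
    """Search addition orders for the most parsimonious tree.

    All ``n!`` orders are tried for up to ``permutation_limit`` arrays;
    otherwise ``max_orders`` seeded random orders. Equally cheap best
    trees are deduplicated by their node encodings. Every constructed tree
    contributes to node support.
    """
    if len(arrays) < 2:
        raise ValueError("tree inference needs at least two arrays")
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array ids")
    universe: dict[str, set[str]] = {a.array_id: set(a.spacers) for a in arrays}
    for a in arrays:
        others = set().union(*(universe[i] for i in ids if i != a.array_id)) \
            if len(arrays) > 1 else set()
        if not (universe[a.array_id] & others):
            warnings.warn(
                f"array {a.array_id!r} shares no spacers with any other "
                "array; its placement is arbitrary", stacklevel=2)
    cache = PairwiseCache(costs, scores)
    array_order = list(ids)

    if len(arrays) <= permutation_limit:
        orders = list(permutations(arrays))
    else:
        rng = np.random.default_rng(seed)
        arrays = list(arrays)
        orders = []
        for _ in range(max_orders):
            idx = rng.permutation(len(arrays))
            orders.append([arrays[i] for i in idx])

    best_cost = np.inf
    best: list[tuple[frozenset[str], ArrayTree]] = []
    examined: list[frozenset[str]] = []
    for order in orders:
        tree = _build_one_order(order, cache)
        codes = frozenset(encode_tree(tree, array_order))
        examined.append(codes)
        cost = tree.total_cost
        if cost < best_cost - 1e-9:
            best_cost = cost
            best = [(codes, tree)]
        elif abs(cost - best_cost) <= 1e-9:
            if all(codes != c for c, _ in best):
                best.append((codes, tree))
    best_trees = [t for _, t in best]
    for t in best_trees:
        _annotate_all_events(t, cache)
    result = TreeSearchResult(best_trees, len(examined), examined, array_order)
    node_support(best_trees, examined, array_order)
    return result


# ---------------------------------------------------------------------------
# Encoding and node support
# ---------------------------------------------------------------------------

def encode_tree(tree: ArrayTree, array_order: Sequence[str]) -> list[str]:
    """Binary descendant-set codes of the internal nodes.

    Each input array owns one fixed position; an internal node's code has
    a 1 at every position whose array is a descendant of the node.
    """
    pos = {name: i for i, name in enumerate(array_order)}
    codes = []
    for node in tree.internal_nodes():
        bits = ["0"] * len(array_order)
        for leaf in node.leaf_names():
            bits[pos[leaf]] = "1"
        codes.append("".join(bits))
    return codes


def node_support(
    best_trees: Sequence[ArrayTree],
    examined_code_sets: Sequence[frozenset[str]],
    array_order: Sequence[str],
) -> None:
    """Set each internal node's support: the proportion of all constructed
    trees containing the node's descendant set."""
    total = len(examined_code_sets)
    if total == 0:
        raise ValueError("no trees were constructed")
    for tree in best_trees:
        pos = {name: i for i, name in enumerate(array_order)}
        for node in tree.internal_nodes():
            bits = ["0"] * len(array_order)
            for leaf in node.leaf_names():
                bits[pos[leaf]] = "1"
            code = "".join(bits)
            node.support = sum(code in cs for cs in examined_code_sets) / total


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _newick_label(name: str) -> str:
    if any(c in name for c in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: ArrayTree, include_support: bool = False) -> str:
    """Newick text with branch lengths = branch costs; internal labels are
    the ancestor names, optionally suffixed with ``/support``."""

    def fmt(node: TreeNode) -> str:
        label = node.name
        if include_support and not node.is_leaf and node.support is not None:
            label = f"{label}/{node.support:.2f}"
        label = _newick_label(label)
        if node.is_leaf:
            body = label
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
        if node.parent is not None:
            body += f":{node.branch_cost:g}"
        return body

    return fmt(tree.root) + ";"


def plot_tree(
    tree: ArrayTree,
    out_path,
    colors=None,
    width: float = 10.0,
    height: Optional[float] = None,
) -> None:
    """Draw the tree with each node's array as a spacer cartoon.

    Ancestors are semi-transparent; event glyphs mark acquisitions (+),
    trailer losses (t), deletions (x), insertions (i), duplications (d)
    and independently acquired runs (red box); colored circles show node
    support where computed.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    from .diff import assign_colors

    if colors is None:
        leaf_arrays = [CRISPRArray(n.name, n.array) for n in tree.nodes()
                       if n.array]
        colors = assign_colors(leaf_arrays)

    # simple rectangular cladogram layout
    leaves = tree.leaves()
    y_of: dict[int, float] = {}
    for i, leaf in enumerate(leaves):
        y_of[id(leaf)] = float(len(leaves) - 1 - i)

    def set_y(node: TreeNode) -> float:
        if id(node) in y_of:
            return y_of[id(node)]
        ys = [set_y(c) for c in node.children]
        y_of[id(node)] = sum(ys) / len(ys)
        return y_of[id(node)]

    set_y(tree.root)
    x_of = {id(n): float(n.depth()) for n in tree.nodes()}
    max_x = max(x_of.values()) or 1.0

    if height is None:
        height = 0.7 * len(leaves) + 1.5
    fig, ax = plt.subplots(figsize=(width, height))
    box = 0.28
    glyph = {"acquisition": "+", "trailer_loss": "t", "deletion": "x",
             "insertion": "i", "duplication": "d",
             "independent_acquisition": "!"}
    for node in tree.nodes():
        x, y = x_of[id(node)], y_of[id(node)]
        if node.parent is not None:
            px = x_of[id(node.parent)]
            py = y_of[id(node.parent)]
            ax.plot([px, px, x], [py, y, y], color="0.3", linewidth=1.0)
            ax.text((px + x) / 2, y + 0.08, f"{node.branch_cost:g}",
                    fontsize=6, color="0.4", ha="center")
        alpha = 0.45 if not node.is_leaf else 1.0
        label = node.name
        if node.support is not None:
            ax.plot([x], [y], marker="o", markersize=7,
                    color=plt.get_cmap("RdYlGn")(node.support), zorder=3)
        ax.text(x + 0.05, y + 0.18, label, fontsize=8, alpha=alpha)
        # spacer cartoon
        x0 = x + 0.05
        for k, s in enumerate(node.array):
            fill, outline = colors.style(s)
            r = Rectangle((x0 + k * 0.12, y - 0.3), 0.1, box,
                          facecolor=fill, edgecolor=outline,
                          linewidth=0.8, alpha=alpha)
            ax.add_patch(r)
        if node.events:
            kinds = "".join(sorted({glyph.get(e.kind, "?")
                                    for e in node.events}))
            ax.text(x0, y - 0.5, kinds, fontsize=7, color="crimson")
    ax.set_xlim(-0.3, max_x + 3.0)
    ax.set_ylim(-1.2, len(leaves))
    ax.axis("off")
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Exhaustive search over rooted topologies (small instances)
# ---------------------------------------------------------------------------

def _rooted_topologies(n: int):
    """All rooted binary leaf-labelled topologies on leaves 0..n-1, as
    nested pairs; (2n-3)!! of them."""
    if n == 1:
        yield 0
        return

    def attach(t, leaf):
        # replace every subtree s by (s, leaf)
        yield (t, leaf)
        if isinstance(t, tuple):
            for sub in attach(t[0], leaf):
                yield (sub, t[1])
            for sub in attach(t[1], leaf):
                yield (t[0], sub)

    def gen(k):
        if k == 2:
            yield (0, 1)
            return
        for t in gen(k - 1):
            yield from attach(t, k - 1)

    yield from gen(n)


def exhaustive_best_cost(
    arrays: Sequence[CRISPRArray],
    costs: CostScheme = CostScheme(),
    scores: AlignScores = AlignScores(),
) -> float:
    """Minimum total parsimony cost over every rooted binary topology,
    filling ancestors post-order. Tractable for a handful of arrays only."""
    cache = PairwiseCache(costs, scores)
    leaf_arrays = [a.spacers for a in arrays]

    def fill(t) -> tuple[tuple[str, ...], float]:
        if isinstance(t, int):
            return leaf_arrays[t], 0.0
        (la, ca), (ra, cb) = fill(t[0]), fill(t[1])
        anc = cache.ancestor(la, ra)
        return anc, (ca + cb + cache.branch_cost(la, anc)
                     + cache.branch_cost(ra, anc))

    best = np.inf
    for topo in _rooted_topologies(len(arrays)):
        _, cost = fill(topo)
        if cost < best:
            best = cost
    return float(best)
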