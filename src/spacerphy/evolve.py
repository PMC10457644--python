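"""In-silico evolution of CRISPR arrays with a recorded true tree, plus
Robinson-Foulds tree comparison and the tree-recovery benchmark grid.

The simulator starts from a single founder array of novel spacers. At each
step one extant lineage is chosen uniformly and spawns a child lineage: a
copy of the parent to which one sampled event is applied — acquisition of
a globally new spacer at the leader, deletion of a contiguous internal run
(uniform start, geometric length with mean 2), loss of the trailer-most
spacer, or in-place duplication of one spacer. With a configurable
probability the parent lineage is then marked lost (removed from the
output but retained as internal history). Every spawn is recorded in the
true tree, whose leaves are exactly the extant arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .arrays import CostScheme, CRISPRArray
from .tree import build_tree

__all__ = [
    "SimParams",
    "SimResult",
    "evolve",
    "rf_distance",
    "recovery_grid",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    Event-type probabilities must sum to at most 1; the remainder is the
    duplication probability. ``array_loss_rate`` is the per-event
    probability that the spawning parent lineage is lost.
    """

    n_events: int = 20
    p_acquisition: float = 1.0
    p_deletion: float = 0.0
    p_trailer_loss: float = 0.0
    array_loss_rate: float = 0.0
    initial_length: int = 5
    deletion_mean_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        probs = (self.p_acquisition, self.p_deletion, self.p_trailer_loss,
                 self.array_loss_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.p_acquisition + self.p_deletion + self.p_trailer_loss > 1 + 1e-9:
            raise ValueError("event probabilities sum to more than 1")
        if self.initial_length < 1:
            raise ValueError("initial_length must be >= 1")

    @property
    def p_duplication(self) -> float:
        return max(0.0, 1.0 - self.p_acquisition - self.p_deletion
                   - self.p_trailer_loss)


@dataclass
class _Lineage:
    name: str
    array: tuple[str, ...]
    parent: Optional[str]
    alive: bool = True
    children: list[str] = field(default_factory=list)


@dataclass
class SimResult:
    """Extant arrays, the true tree over them (Newick), and the event log."""

    arrays: list[CRISPRArray]
    true_tree: str
    events: list[dict]
    lineages: dict[str, "_Lineage"] = field(repr=False, default_factory=dict)


def _true_tree_newick(lineages: dict[str, _Lineage]) -> str:
    """Assemble the recorded history into a leaf-labelled Newick tree.

    Each lineage node's children are its spawned lineages, plus a leaf for
    the lineage's own extant array when it survived. Lost childless
    lineages vanish; single-child nodes are suppressed.
    """
    tree = dendropy.Tree()
    tree.is_rooted = True
    taxa = tree.taxon_namespace

    def build(name: str) -> Optional[dendropy.Node]:
        lin = lineages[name]
        kids = [build(c) for c in lin.children]
        kids = [k for k in kids if k is not None]
        if lin.alive:
            leaf = dendropy.Node()
            leaf.taxon = taxa.new_taxon(name)
            kids.append(leaf)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = dendropy.Node()
        for k in kids:
            node.add_child(k)
        return node

    root_name = next(n for n, l in lineages.items() if l.parent is None)
    root = build(root_name)
    if root is None:
        raise RuntimeError("no extant lineages")
    tree.seed_node = root
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def evolve(params: SimParams) -> SimResult:
    """Run one seeded simulation (identical seeds give identical results)."""
    rng = np.random.default_rng(params.seed)
    spacer_counter = 0

    def new_spacers(k: int) -> list[str]:
        nonlocal spacer_counter
        out = [f"sp{spacer_counter + i}" for i in range(k)]
        spacer_counter += k
        return out

    founder = _Lineage("A0", tuple(new_spacers(params.initial_length)), None)
    lineages: dict[str, _Lineage] = {founder.name: founder}
    log: list[dict] = []
    menu = ("acquisition", "deletion", "trailer_loss", "duplication")
    probs = np.array([params.p_acquisition, params.p_deletion,
                      params.p_trailer_loss, params.p_duplication])
    probs = probs / probs.sum()

    for step in range(params.n_events):
        alive = [l for l in lineages.values() if l.alive]
        if not alive:
            warnings.warn(
                f"all lineages lost after {step} events; returning the "
                "partial simulation", stacklevel=2)
            break
        parent = alive[rng.integers(len(alive))]
        kind = menu[rng.choice(4, p=probs)]
        arr = list(parent.array)
        if kind in ("deletion", "trailer_loss") and len(arr) == 1:
            kind = "acquisition"  # a 1-spacer array cannot shrink further
        if kind == "acquisition":
            gained = new_spacers(1)
            arr = gained + arr
            detail = {"spacers": gained}
        elif kind == "deletion":
            length = min(int(rng.geometric(1.0 / params.deletion_mean_length)),
                         len(arr) - 1)
            start = int(rng.integers(0, len(arr) - length + 1))
            detail = {"spacers": arr[start:start + length], "start": start}
            del arr[start:start + length]
        elif kind == "trailer_loss":
            detail = {"spacers": [arr[-1]]}
            arr = arr[:-1]
        else:  # duplication
            i = int(rng.integers(len(arr)))
            detail = {"spacers": [arr[i]], "start": i}
            arr.insert(i, arr[i])
        child = _Lineage(f"A{step + 1}", tuple(arr), parent.name)
        lineages[child.name] = child
        parent.children.append(child.name)
        lost = bool(rng.random() < params.array_loss_rate)
        if lost:
            parent.alive = False
        log.append({"step": step, "parent": parent.name, "child": child.name,
                    "event": kind, "parent_lost": lost, **detail})

    extant = [CRISPRArray(l.name, l.array) for l in lineages.values()
              if l.alive]
    return SimResult(extant, _true_tree_newick(lineages), log, lineages)


# ---------------------------------------------------------------------------
# Robinson-Foulds comparison
# ---------------------------------------------------------------------------

def _nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Unrooted non-trivial bipartitions, each as the frozenset of leaf
    labels on the smaller side (ties: lexicographic)."""
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    n = len(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > n - 2:
            continue
        other = frozenset(labels - side)
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def rf_distance(t1: str, t2: str) -> tuple[int, int, float]:
    """Robinson-Foulds distance between two Newick trees on the same leaf
    set (unrooted comparison).

    Returns ``(rf, max_rf, normalized)`` where rf is the symmetric
    difference of non-trivial bipartitions, max_rf the total number of
    non-trivial bipartitions across both trees, and normalized = rf/max_rf
    (0.0 when both trees are stars).
    """
    taxa = dendropy.TaxonNamespace()
    tr1 = dendropy.Tree.get(data=t1, schema="newick", taxon_namespace=taxa)
    tr2 = dendropy.Tree.get(data=t2, schema="newick", taxon_namespace=taxa)
    l1 = {l.taxon.label for l in tr1.leaf_node_iter()}
    l2 = {l.taxon.label for l in tr2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(
            "leaf sets differ: only in first tree "
            f"{sorted(l1 - l2)}, only in second {sorted(l2 - l1)}")
    s1 = _nontrivial_bipartitions(tr1)
    s2 = _nontrivial_bipartitions(tr2)
    rf = len(s1 ^ s2)
    max_rf = len(s1) + len(s2)
    return rf, max_rf, (rf / max_rf if max_rf else 0.0)


# ---------------------------------------------------------------------------
# Recovery benchmark
# ---------------------------------------------------------------------------

def recovery_grid(
    deletion_shares: Sequence[float],
    event_counts: Sequence[int],
    replicates: int = 50,
    seed: int = 0,
    array_loss_rate: float = 0.0,
    initial_length: int = 5,
    costs: CostScheme = CostScheme(),
    max_orders: int = 100,
) -> pd.DataFrame:
    """Tree-recovery benchmark over a (deletion share, event count) grid.

    Each cell runs ``replicates`` seeded simulations, infers a tree from
    the extant arrays and compares it with the true tree. Reported per
    cell: the proportion of replicates recovering the true topology
    exactly (normalized RF = 0) and the median normalized RF distance.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for p_del in deletion_shares:
        for n_ev in event_counts:
            nrfs = []
            for _ in range(replicates):
                rep_seed = int(rng.integers(2**31 - 1))
                sim = evolve(SimParams(
                    n_events=n_ev,
                    p_acquisition=1.0 - p_del,
                    p_deletion=p_del,
                    array_loss_rate=array_loss_rate,
                    initial_length=initial_length,
                    seed=rep_seed,
                ))
                if len(sim.arrays) < 3:
                    continue
                result = build_tree(sim.arrays, costs=costs,
                                    max_orders=max_orders, seed=rep_seed)
                nwk = _result_newick(result)
                _, _, nrf = rf_distance(nwk, sim.true_tree)
                nrfs.append(nrf)
            rows.append({
                "p_deletion": p_del,
                "n_events": n_ev,
                "replicates": len(nrfs),
                "prop_identical": float(np.mean([x == 0.0 for x in nrfs]))
                if nrfs else float("nan"),
                "median_norm_rf": float(np.median(nrfs)) if nrfs
                else float("nan"),
            })
    return pd.DataFrame(rows)


def _result_newick(result) -> str:
    from .tree import to_newick
    return to_newick(result.best_tree)


def plot_recovery_heatmap(table: pd.DataFrame, out_path,
                          stat: str = "prop_identical") -> None:
    """Heatmap of a recovery statistic over the parameter grid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="p_deletion", columns="n_events", values=stat)
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2,
                                    0.8 * len(pivot.index) + 2))
    im = ax.imshow(pivot.values, cmap="viridis", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), [str(c) for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{i:g}" for i in pivot.index])
    ax.set_xlabel("number of events")
    ax.set_ylabel("deletion share")
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = pivot.values[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label=stat)
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
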