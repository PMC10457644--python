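"""Independent oracles and generators shared across the test suite.

Everything here is deliberately naive — recursive enumeration, brute-force
scans, hand-rolled graph walks — so it exercises none of the code paths it
is used to check.
"""

from functools import lru_cache
from itertools import product

import numpy as np

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# alignment oracle
# ---------------------------------------------------------------------------

def nw_oracle_score(a, b, match=100, mismatch=-1, gap=-2):
    """Optimal global alignment score by plain recursion over all moves."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = NEG_INF
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, f(i + 1, j + 1) + s)
        if i < len(a):
            best = max(best, f(i + 1, j) + gap)
        if j < len(b):
            best = max(best, f(i, j + 1) + gap)
        return best

    return f(0, 0)


# ---------------------------------------------------------------------------
# graph oracle
# ---------------------------------------------------------------------------

def bfs_components(nodes, edges):
    """Connected components by breadth-first search over an adjacency map."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in nodes:
        if n in seen:
            continue
        queue, comp = [n], set()
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# tree bipartition oracle
# ---------------------------------------------------------------------------

def newick_bipartitions(newick):
    """Non-trivial unrooted bipartitions via a tiny hand-written parser,
    each canonicalized to its smaller side."""
    pos = 0

    def parse():
        nonlocal pos
        if newick[pos] == "(":
            pos += 1
            children = [parse()]
            while newick[pos] == ",":
                pos += 1
                children.append(parse())
            assert newick[pos] == ")"
            pos += 1
            # skip label / branch length
            while pos < len(newick) and newick[pos] not in ",();":
                pos += 1
            return children
        start = pos
        while newick[pos] not in ",();:":
            pos += 1
        label = newick[start:pos]
        while pos < len(newick) and newick[pos] not in ",();":
            pos += 1
        return label

    tree = parse()
    leaves = set()
    clades = []

    def walk(node):
        if isinstance(node, str):
            leaves.add(node)
            return frozenset([node])
        here = frozenset().union(*(walk(c) for c in node))
        clades.append(here)
        return here

    walk(tree)
    out = set()
    n = len(leaves)
    for clade in clades:
        if 2 <= len(clade) <= n - 2:
            other = frozenset(leaves - clade)
            out.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
    return out


def random_binary_newick(rng, labels):
    """Random rooted binary tree over labels by uniform joins."""
    nodes = [str(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# protospacer scan oracle
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s):
    return s.translate(_COMP)[::-1]


def naive_protospacer_scan(subject, spacer_id, spacer, max_mm,
                           mask_intervals=()):
    """Every-offset, both-strand scan; off-contig positions are mismatches."""
    L = len(spacer)
    found = []
    for strand, q in (("+", spacer), ("-", revcomp(spacer))):
        for start in range(-(L - 1), len(subject)):
            mm = 0
            for k in range(L):
                p = start + k
                if p < 0 or p >= len(subject) or subject[p] != q[k]:
                    mm += 1
            if mm > max_mm:
                continue
            end = start + L
            lo, hi = max(start, 0), min(end, len(subject))
            if any(lo < e and s < hi for s, e in mask_intervals):
                continue
            found.append((spacer_id, start, end, strand, mm))
    return found


# ---------------------------------------------------------------------------
# instance generators
# ---------------------------------------------------------------------------

def random_spacer_pair(rng, alphabet_size=10, max_len=7):
    alpha = [f"s{i}" for i in range(alphabet_size)]
    na = int(rng.integers(1, max_len + 1))
    nb = int(rng.integers(1, max_len + 1))
    a = tuple(alpha[i] for i in rng.integers(0, alphabet_size, na))
    b = tuple(alpha[i] for i in rng.integers(0, alphabet_size, nb))
    return a, b


def order_consistent(a, b):
    """True when the pair could have arisen without rearrangement: no
    within-array repeats, and shared spacers in the same relative order."""
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        return False
    common = set(a) & set(b)
    return [s for s in a if s in common] == [s for s in b if s in common]


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
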