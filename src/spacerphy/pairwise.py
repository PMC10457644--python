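"""Spacer-level alignment, module classification, ancestral-array inference
and event costing — the shared engine of the tree builder and Constrain.

Each spacer is an atomic character. Two arrays are globally aligned with
Needleman-Wunsch under scores chosen so that shared spacers always align
(match 100, mismatch -1, gap -2). The alignment is split into *modules* —
maximal runs of columns with one relationship between the arrays — and a
hypothetical ancestor is assembled module by module under an evolutionary
model with leader-end acquisition, one-at-a-time trailer loss, and
insertion/deletion of contiguous spacer runs anywhere. Events separating a
descendant from its ancestor are costed with the CostScheme, and the summed
cost becomes the branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .arrays import CostScheme, CRISPRArray

__all__ = [
    "GAP",
    "AlignScores",
    "SpacerAlignment",
    "ArrayModule",
    "Event",
    "EventSet",
    "align_arrays",
    "alignment_score",
    "classify_modules",
    "infer_ancestor",
    "annotate_events",
    "PairwiseCache",
]

#: Sentinel used for gap positions in spacer alignments.
GAP = "-"

# module / event kind labels
SHARED = "shared"
LEADER_ACQ = "leader_acquisition"
INTERNAL_INDEL = "internal_indel"
TRAILER_INDEL = "trailer_indel"
MISMATCH = "mismatch"
DUPLICATION = "duplication"

ACQUISITION = "acquisition"
INSERTION = "insertion"
DELETION = "deletion"
TRAILER_LOSS = "trailer_loss"
INDEPENDENT_ACQ = "independent_acquisition"


@dataclass(frozen=True)
class AlignScores:
    """Needleman-Wunsch scores for spacer characters.

    The large match score guarantees that any spacer present in both arrays
    occupies a match column in the optimal alignment.
    """

    match: float = 100.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass(frozen=True)
class SpacerAlignment:
    """Two gapped, equal-length spacer sequences plus the optimal score.

    Index 0 is the leader end. No column is gap/gap; removing gaps recovers
    the input arrays.
    """

    seq_a: tuple[str, ...]
    seq_b: tuple[str, ...]
    score: float

    def __len__(self) -> int:
        return len(self.seq_a)


@dataclass(frozen=True)
class ArrayModule:
    """A maximal run of alignment columns with one relationship type."""

    kind: str
    start: int  # half-open column span, 0-based
    end: int
    spacers_a: tuple[str, ...]
    spacers_b: tuple[str, ...]


@dataclass(frozen=True)
class Event:
    """One evolutionary event on a branch."""

    kind: str
    spacers: tuple[str, ...]
    position: int  # leader-side alignment column where the event starts
    cost: float


@dataclass
class EventSet:
    """Typed events separating a descendant from its ancestor."""

    events: list[Event] = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return sum(e.cost for e in self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _encode(a: Sequence[str], b: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    symbols = {s: i for i, s in enumerate(dict.fromkeys(list(a) + list(b)))}
    ea = np.fromiter((symbols[s] for s in a), dtype=np.int64, count=len(a))
    eb = np.fromiter((symbols[s] for s in b), dtype=np.int64, count=len(b))
    return ea, eb


def alignment_score(
    a: Sequence[str], b: Sequence[str], scores: AlignScores = AlignScores()
) -> float:
    """Optimal global alignment score only (no traceback); row-vectorized."""
    ea, eb = _encode(a, b)
    n, m = len(ea), len(eb)
    g = scores.gap
    idx = np.arange(m + 1, dtype=np.float64)
    prev = g * idx  # row 0
    for i in range(1, n + 1):
        sub = np.where(eb == ea[i - 1], scores.match, scores.mismatch)
        t = np.empty(m + 1, dtype=np.float64)
        t[0] = g * i
        np.maximum(prev[:-1] + sub, prev[1:] + g, out=t[1:])
        # horizontal (gap-in-b) moves resolved with a prefix max-scan
        u = np.maximum.accumulate(t - g * idx)
        prev = np.maximum(t, u + g * idx)
        prev[0] = g * i
    return float(prev[m])


def align_arrays(
    a: CRISPRArray | Sequence[str],
    b: CRISPRArray | Sequence[str],
    scores: AlignScores = AlignScores(),
) -> SpacerAlignment:
    """Global Needleman-Wunsch alignment of two spacer sequences.

    Traceback ties are broken deterministically: diagonal first, then
    gap-in-b (consume from ``a``), then gap-in-a.
    """
    sa = tuple(a.spacers if isinstance(a, CRISPRArray) else a)
    sb = tuple(b.spacers if isinstance(b, CRISPRArray) else b)
    if not sa or not sb:
        raise ValueError("both arrays must be non-empty")
    n, m = len(sa), len(sb)
    g = scores.gap
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = g * np.arange(m + 1)
    H[:, 0] = g * np.arange(n + 1)
    for i in range(1, n + 1):
        ai = sa[i - 1]
        row = H[i]
        above = H[i - 1]
        for j in range(1, m + 1):
            s = scores.match if ai == sb[j - 1] else scores.mismatch
            row[j] = max(above[j - 1] + s, above[j] + g, row[j - 1] + g)
    # traceback: diagonal, then up (gap in b), then left (gap in a)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = scores.match if sa[i - 1] == sb[j - 1] else scores.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + g:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(sb[j - 1])
        j -= 1
    return SpacerAlignment(tuple(reversed(out_a)), tuple(reversed(out_b)),
                           float(H[n, m]))


# ---------------------------------------------------------------------------
# Module classification
# ---------------------------------------------------------------------------

def _column_kind(x: str, y: str) -> str:
    if x != GAP and y != GAP:
        return SHARED if x == y else MISMATCH
    return "gap_a" if x == GAP else "gap_b"


def classify_modules(aln: SpacerAlignment) -> list[ArrayModule]:
    """Split an alignment into maximal single-relationship modules.

    Match columns form shared modules; mismatch columns form mismatch
    modules; gap runs are classified by position (touching the leader
    column: leader acquisition in the ungapped array; touching the trailer
    column: trailer indel; otherwise internal indel). An indel run whose
    spacers all have another copy in a shared column of the same array is a
    duplication module (extra copies of existing spacers).
    """
    ncol = len(aln)
    kinds = [_column_kind(x, y) for x, y in zip(aln.seq_a, aln.seq_b)]
    # ids matched in shared columns, and total counts, per array
    shared_a = {x for x, k in zip(aln.seq_a, kinds) if k == SHARED}
    shared_b = {y for y, k in zip(aln.seq_b, kinds) if k == SHARED}
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for x in aln.seq_a:
        if x != GAP:
            count_a[x] = count_a.get(x, 0) + 1
    for y in aln.seq_b:
        if y != GAP:
            count_b[y] = count_b.get(y, 0) + 1

    modules: list[ArrayModule] = []
    start = 0
    while start < ncol:
        end = start
        while end < ncol and kinds[end] == kinds[start]:
            end += 1
        kind = kinds[start]
        span_a = tuple(x for x in aln.seq_a[start:end] if x != GAP)
        span_b = tuple(y for y in aln.seq_b[start:end] if y != GAP)
        if kind in ("gap_a", "gap_b"):
            run = span_b if kind == "gap_a" else span_a
            shared_ids = shared_b if kind == "gap_a" else shared_a
            counts = count_b if kind == "gap_a" else count_a
            if run and all(s in shared_ids and counts[s] >= 2 for s in run):
                mkind = DUPLICATION
            elif start == 0:
                mkind = LEADER_ACQ
            elif end == ncol:
                mkind = TRAILER_INDEL
            else:
                mkind = INTERNAL_INDEL
        else:
            mkind = kind
        modules.append(ArrayModule(mkind, start, end, span_a, span_b))
        start = end
    return modules


# ---------------------------------------------------------------------------
# Ancestor inference
# ---------------------------------------------------------------------------

def _pair_cost(
    a: tuple[str, ...],
    b: tuple[str, ...],
    candidate: tuple[str, ...],
    costs: CostScheme,
    scores: AlignScores,
) -> float:
    """Summed event cost of both children against a candidate ancestor.

    Spacers gained (acquired or inserted) on *both* branches would be
    independent acquisitions of identical spacers — the event the model
    considers least plausible — so each such spacer is surcharged at the
    independent-acquisition cost. This keeps shared spacers in the
    ancestor whenever they carry any phylogenetic signal.
    """
    total = 0.0
    gains: list[set[str]] = []
    for child in (a, b):
        if child == candidate:
            gains.append(set())
            continue
        if not candidate:
            total += costs.acquisition * len(child)
            gains.append(set(child))
            continue
        ev = annotate_events(CRISPRArray("c", child),
                             CRISPRArray("anc", candidate), costs, scores)
        total += ev.total_cost
        gains.append({s for e in ev for s in e.spacers
                      if e.kind in (ACQUISITION, INSERTION)})
    for s in gains[0] & gains[1]:
        total += 2 * costs.independent_acquisition
    return total


def infer_ancestor(
    a: CRISPRArray,
    b: CRISPRArray,
    costs: CostScheme = CostScheme(),
    scores: AlignScores = AlignScores(),
    name: str = "Anc",
) -> CRISPRArray:
    """Infer the most parsimonious gap-free ancestor of two arrays.

    Module fates: shared spacers are ancestral; leader-acquisition modules
    are child-specific gains and excluded; internal-indel spacers are kept
    (a deletion in the other child is cheaper than an insertion in this
    one); trailer-indel spacers are kept (trailer loss is cheap);
    duplication modules reduce to the single ancestral copy. Mismatch
    modules (mutually exclusive spacers facing each other) have no locally
    forced fate: every combination of exclude / keep side a / keep side b
    across the mismatch modules — plus the empty ancestor when the arrays
    share nothing — is scored by the summed event cost of both children
    and the cheapest kept (ties prefer exclusion, then side a).

    Raises ``ValueError`` when no spacer is inherited (empty-overlap
    ancestor); callers prepared for that case catch it.
    """
    aln = align_arrays(a, b, scores)
    modules = classify_modules(aln)
    mismatch_idx = [i for i, m in enumerate(modules) if m.kind == MISMATCH]
    indel_idx = [i for i, m in enumerate(modules)
                 if m.kind in (INTERNAL_INDEL, TRAILER_INDEL)]

    def assemble(fates: dict[int, str]) -> tuple[str, ...]:
        out: list[str] = []
        for i, mod in enumerate(modules):
            if mod.kind == SHARED:
                out.extend(mod.spacers_a)
            elif mod.kind in (INTERNAL_INDEL, TRAILER_INDEL):
                if fates.get(i, "include") == "include":
                    out.extend(mod.spacers_a or mod.spacers_b)
            elif mod.kind == MISMATCH:
                fate = fates.get(i, "exclude")
                if fate == "keep_a":
                    out.extend(mod.spacers_a)
                elif fate == "keep_b":
                    out.extend(mod.spacers_b)
            # LEADER_ACQ and DUPLICATION contribute nothing
        return tuple(out)

    if not mismatch_idx:
        # default fates are already cost-minimal: indel spacers kept (one
        # deletion in the sibling beats an insertion here), leader gains
        # excluded, duplicates reduced
        best = assemble({})
    else:
        # mismatch fates have no forced choice, and excluding an indel
        # module next to an excluded mismatch can merge two events into
        # one; search the small fate space exactly
        from itertools import product as _product
        mm = mismatch_idx[:3]
        mm_opts = list(_product(("exclude", "keep_a", "keep_b"),
                                repeat=len(mm)))
        if 2 ** len(indel_idx) * len(mm_opts) <= 54:
            indel_opts = list(_product(("include", "exclude"),
                                       repeat=len(indel_idx)))
        else:
            indel_opts = [("include",) * len(indel_idx),
                          ("exclude",) * len(indel_idx)]
        candidates: list[tuple[str, ...]] = []
        for mm_combo in mm_opts:
            for ind_combo in indel_opts:
                fates = dict(zip(mm, mm_combo))
                fates.update(zip(indel_idx, ind_combo))
                candidates.append(assemble(fates))
        candidates.append(())
        seen: set[tuple[str, ...]] = set()
        best, best_cost = None, np.inf
        for cand in candidates:
            if cand in seen:
                continue
            seen.add(cand)
            cost = _pair_cost(a.spacers, b.spacers, cand, costs, scores)
            if cost < best_cost - 1e-9:
                best, best_cost = cand, cost
    if not best:
        raise ValueError(
            f"arrays {a.array_id!r} and {b.array_id!r} share no ancestral "
            "spacers under the model"
        )
    return CRISPRArray(name, best)


# ---------------------------------------------------------------------------
# Event annotation
# ---------------------------------------------------------------------------

def annotate_events(
    descendant: CRISPRArray,
    ancestor: CRISPRArray,
    costs: CostScheme = CostScheme(),
    scores: AlignScores = AlignScores(),
) -> EventSet:
    """Identify and cost the events separating a descendant from its
    (gap-free) ancestor.

    Spacers present only in the descendant are leader-end acquisitions
    (one cost per spacer) when they touch the leader, otherwise one
    insertion per contiguous run — except extra copies of spacers the
    ancestor already carries, which are duplications (one cost per copy).
    Ancestral spacers missing from the descendant are trailer losses (one
    per spacer) when the run touches the trailer, otherwise one deletion
    per contiguous run. A mismatch run is a replacement: at the leader,
    acquisitions plus one deletion; internally, a single insertion event.
    """
    if descendant.spacers == ancestor.spacers:
        return EventSet()
    aln = align_arrays(descendant, ancestor, scores)
    modules = classify_modules(aln)
    events: list[Event] = []
    for mod in modules:
        if mod.kind == SHARED:
            continue
        desc_run = mod.spacers_a  # descendant aligned as seq_a
        anc_run = mod.spacers_b
        if mod.kind == DUPLICATION:
            if desc_run:
                for s in desc_run:
                    events.append(Event(DUPLICATION, (s,), mod.start,
                                        costs.duplication))
            else:
                # descendant lost a duplicate copy: an ordinary loss
                if mod.end == len(aln):
                    for s in anc_run:
                        events.append(Event(TRAILER_LOSS, (s,), mod.start,
                                            costs.trailer_loss))
                else:
                    events.append(Event(DELETION, anc_run, mod.start,
                                        costs.deletion))
        elif mod.kind == LEADER_ACQ:
            if desc_run:
                for s in desc_run:
                    events.append(Event(ACQUISITION, (s,), mod.start,
                                        costs.acquisition))
            else:
                # descendant lacks the ancestor's leader-most spacers
                events.append(Event(DELETION, anc_run, mod.start,
                                    costs.deletion))
        elif mod.kind == TRAILER_INDEL:
            if anc_run:
                for s in anc_run:
                    events.append(Event(TRAILER_LOSS, (s,), mod.start,
                                        costs.trailer_loss))
            else:
                events.append(Event(INSERTION, desc_run, mod.start,
                                    costs.insertion))
        elif mod.kind == INTERNAL_INDEL:
            if anc_run:
                events.append(Event(DELETION, anc_run, mod.start,
                                    costs.deletion))
            else:
                events.append(Event(INSERTION, desc_run, mod.start,
                                    costs.insertion))
        elif mod.kind == MISMATCH:
            if mod.start == 0:
                for s in desc_run:
                    events.append(Event(ACQUISITION, (s,), mod.start,
                                        costs.acquisition))
                events.append(Event(DELETION, anc_run, mod.start,
                                    costs.deletion))
            else:
                events.append(Event(INSERTION, desc_run, mod.start,
                                    costs.insertion))
    return EventSet(events)


# ---------------------------------------------------------------------------
# Memoization used by the tree builder (arrays recur across addition orders)
# ---------------------------------------------------------------------------

class PairwiseCache:
    """Memoizes alignment scores, ancestors and branch costs per run."""

    def __init__(self, costs: CostScheme = CostScheme(),
                 scores: AlignScores = AlignScores()):
        self.costs = costs
        self.scores = scores
        self._score: dict[tuple, float] = {}
        self._anc: dict[tuple, Optional[tuple[str, ...]]] = {}
        self._cost: dict[tuple, float] = {}

    def score(self, a: tuple[str, ...], b: tuple[str, ...]) -> float:
        key = (a, b) if a <= b else (b, a)
        out = self._score.get(key)
        if out is None:
            out = alignment_score(key[0], key[1], self.scores)
            self._score[key] = out
        return out

    def ancestor(self, a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
        """Ancestral spacer tuple; empty when nothing is inherited."""
        key = (a, b)
        if key not in self._anc:
            if not a or not b:
                # one lineage is already empty-handed: the cheaper of
                # "other child gained everything" vs "it lost everything"
                other = a or b
                gain = self.costs.acquisition * len(other)
                loss = min(self.costs.deletion,
                           self.costs.trailer_loss * len(other))
                self._anc[key] = () if gain <= loss else other
            else:
                try:
                    anc = infer_ancestor(CRISPRArray("a", a),
                                         CRISPRArray("b", b),
                                         self.costs, self.scores)
                    self._anc[key] = anc.spacers
                except ValueError:
                    self._anc[key] = ()
        return self._anc[key]

    def branch_cost(self, descendant: tuple[str, ...],
                    ancestor: tuple[str, ...]) -> float:
        key = (descendant, ancestor)
        out = self._cost.get(key)
        if out is None:
            if descendant == ancestor:
                out = 0.0
            elif not ancestor:
                out = self.costs.acquisition * len(descendant)
            elif not descendant:
                out = min(self.costs.deletion,
                          self.costs.trailer_loss * len(ancestor))
            else:
                out = annotate_events(CRISPRArray("d", descendant),
                                      CRISPRArray("a", ancestor),
                                      self.costs, self.scores).total_cost
            self._cost[key] = out
        return out

    def events(self, descendant: tuple[str, ...],
               ancestor: tuple[str, ...]) -> EventSet:
        """Full event annotation (uncached; used on final trees only)."""
        if descendant == ancestor:
            return EventSet()
        if not ancestor:
            return EventSet([
                Event(ACQUISITION, (s,), i, self.costs.acquisition)
                for i, s in enumerate(descendant)
            ])
        if not descendant:
            loss = self.costs.trailer_loss * len(ancestor)
            if loss <= self.costs.deletion:
                return EventSet([
                    Event(TRAILER_LOSS, (s,), i, self.costs.trailer_loss)
                    for i, s in enumerate(ancestor)
                ])
            return EventSet([Event(DELETION, tuple(ancestor), 0,
                                   self.costs.deletion)])
        return annotate_events(CRISPRArray("d", descendant),
                               CRISPRArray("a", ancestor),
                               self.costs, self.scores)
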