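"""Core domain types and file formats for CRISPR array comparison.

A CRISPR array is stored as an ordered sequence of spacer identifiers,
*leader-first*: index 0 is the leader end (where new spacers are acquired)
and the last index is the trailer end (the evolutionarily older end). Every
downstream operation in this package assumes that convention.

The on-disk array format is a plain TSV, one array per line::

    array_id<TAB>spacer1 spacer2 spacer3 ...

Spacer and repeat nucleotide sequences travel as FASTA (record id = spacer
id), read with Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO

__all__ = [
    "CRISPRArray",
    "SpacerCatalog",
    "CostScheme",
    "read_array_file",
    "write_array_file",
    "read_fasta",
    "reverse_complement",
    "sequence_distance",
    "collapse_spacers",
    "orient_array",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CRISPRArray:
    """An identified CRISPR array: a label plus ordered spacer identifiers.

    ``spacers[0]`` is the leader-end spacer, ``spacers[-1]`` the trailer-end
    spacer. Arrays must contain at least one spacer.
    """

    array_id: str
    spacers: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacers", tuple(self.spacers))
        if not self.spacers:
            raise ValueError(f"array {self.array_id!r} has no spacers")

    def __len__(self) -> int:
        return len(self.spacers)

    @property
    def unique_spacers(self) -> frozenset[str]:
        return frozenset(self.spacers)


@dataclass
class SpacerCatalog:
    """Mapping from spacer identifier to its DNA sequence."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.entries.items():
            if not seq:
                raise ValueError(f"spacer {sid!r} has an empty sequence")
            self.entries[sid] = seq.upper()

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, sid: str) -> str:
        return self.entries[sid]

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class CostScheme:
    """Parsimony costs of the array-change events.

    Defaults: acquisition 1, duplication 1, insertion 30, deletion 10,
    trailer loss 1, independent acquisition 50. Acquisition and trailer loss
    are charged once per spacer (spacers are gained at the leader, and lost
    from the trailer, one at a time); insertion and deletion are charged
    once per contiguous event regardless of how many spacers it spans.
    """

    acquisition: float = 1.0
    duplication: float = 1.0
    insertion: float = 30.0
    deletion: float = 10.0
    trailer_loss: float = 1.0
    independent_acquisition: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "acquisition",
            "duplication",
            "insertion",
            "deletion",
            "trailer_loss",
            "independent_acquisition",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name!r} must be non-negative")


# ---------------------------------------------------------------------------
# Array file IO
# ---------------------------------------------------------------------------

def read_array_file(path) -> list[CRISPRArray]:
    """Read arrays from the TSV array file, preserving file order.

    Raises ``ValueError`` naming the offending line for malformed lines,
    empty spacer lists, or duplicate array identifiers.
    """
    arrays: list[CRISPRArray] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected 'array_id<TAB>spacer ids', got {line!r}"
                )
            array_id, _, rest = line.partition("\t")
            array_id = array_id.strip()
            if not array_id:
                raise ValueError(f"{path}:{lineno}: empty array id")
            spacers = tuple(rest.split())
            if not spacers:
                raise ValueError(f"{path}:{lineno}: array {array_id!r} has no spacers")
            if array_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate array id {array_id!r}")
            seen.add(array_id)
            arrays.append(CRISPRArray(array_id, spacers))
    return arrays


def write_array_file(arrays: Iterable[CRISPRArray], path) -> None:
    """Write arrays in the TSV array format (round-trips with the reader)."""
    with open(path, "w") as fh:
        for arr in arrays:
            fh.write(f"{arr.array_id}\t{' '.join(arr.spacers)}\n")


def read_fasta(path) -> SpacerCatalog:
    """Read a FASTA file of spacer (or repeat) sequences into a catalog."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        entries[rec.id] = str(rec.seq).upper()
    return SpacerCatalog(entries)


# ---------------------------------------------------------------------------
# Spacer collapsing
# ---------------------------------------------------------------------------

def sequence_distance(a: str, b: str) -> int:
    """Base differences between two sequences.

    Equal lengths: Hamming distance. Unequal lengths: unit-cost edit
    distance (via edlib).
    """
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    return edlib.align(a, b)["editDistance"]


def collapse_spacers(catalog: SpacerCatalog, threshold: int) -> dict[str, str]:
    """Group near-identical spacers and map each id to a representative.

    Spacers whose sequences differ by at most ``threshold`` bases are placed
    in the same group by single linkage (connected components of the
    <=threshold graph). Threshold 0 merges only identical sequences. The
    representative of a group is the identifier of the group's most frequent
    sequence; ties are broken lexicographically.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ids = sorted(catalog.entries)
    n = len(ids)
    # union-find over the <=threshold graph
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_distance(catalog[ids[i]], catalog[ids[j]]) <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[str]] = {}
    for i, sid in enumerate(ids):
        groups.setdefault(find(i), []).append(sid)

    mapping: dict[str, str] = {}
    for members in groups.values():
        seq_count: dict[str, int] = {}
        for sid in members:
            seq_count[catalog[sid]] = seq_count.get(catalog[sid], 0) + 1
        best_seq = min(seq_count, key=lambda s: (-seq_count[s], s))
        rep = min(sid for sid in members if catalog[sid] == best_seq)
        for sid in members:
            mapping[sid] = rep
    return mapping


# ---------------------------------------------------------------------------
# Repeat-based orientation
# ---------------------------------------------------------------------------

def orient_array(
    spacer_seqs: Sequence[str],
    repeat_seqs: Sequence[str],
    reference_repeat: str,
) -> tuple[list[str], str]:
    """Orient an array using its repeats against a reference repeat.

    Compares the summed distance of the array's repeats to the reference
    repeat against the summed distance to its reverse complement. If the
    reverse orientation fits better, the spacer order is reversed and each
    spacer reverse-complemented; the returned flag is ``"reversed"``,
    otherwise ``"forward"``. An exact tie keeps the input orientation and
    emits a warning.
    """
    if not reference_repeat:
        raise ValueError("reference repeat must be non-empty")
    if not repeat_seqs:
        raise ValueError("at least one repeat sequence is required")
    fwd = sum(sequence_distance(r.upper(), reference_repeat.upper()) for r in repeat_seqs)
    rev = sum(sequence_distance(reverse_complement(r.upper()), reference_repeat.upper())
              for r in repeat_seqs)
    if rev < fwd:
        oriented = [reverse_complement(s) for s in reversed(spacer_seqs)]
        return oriented, "reversed"
    if rev == fwd:
        warnings.warn(
            "repeat orientation is ambiguous (equal mismatches forward and "
            "reverse); keeping input orientation",
            stacklevel=2,
        )
    return list(spacer_seqs), "forward"
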