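"""Protospacer prediction: spacer matches in subject sequences with
identity thresholds, PAM detection on the protospacer strand, and region
masking.

The search is an internal seed-and-extend scan: exact k-mer seeds (length
8, shortened when the allowed mismatch count demands it) are located in
the subject, candidate placements extended to the full spacer length, and
mismatches counted over the full length — positions running off a contig
end count as mismatches. Both strands are searched. The PAM is read from
the flank immediately adjacent to the protospacer on the protospacer's own
strand (default: "CC" on the 5' side, the type I-F motif) and matched as
an IUPAC pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .arrays import CRISPRArray, SpacerCatalog, reverse_complement

__all__ = [
    "ProtospacerHit",
    "find_protospacers",
    "summarize_targets",
    "read_bed_mask",
    "write_hits_tsv",
    "write_target_colors",
]

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SEED_LEN = 8


@dataclass(frozen=True)
class ProtospacerHit:
    """One predicted protospacer.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the subject (``end - start`` equals the spacer length, so a
    window may extend past a contig end when mismatches allow).
    ``pam_observed`` is read on the protospacer strand; ``pam_pass`` is
    None when the flank is unreachable.
    """

    spacer_id: str
    subject_id: str
    start: int
    end: int
    strand: str
    percent_identity: float
    mismatches: int
    pam_observed: str
    pam_pass: Optional[bool]


def _check_iupac(pattern: str) -> None:
    bad = [c for c in pattern.upper() if c not in _IUPAC]
    if bad:
        raise ValueError(f"unknown IUPAC symbol(s) {bad!r} in PAM pattern")


def _pam_matches(observed: str, pattern: str) -> Optional[bool]:
    if len(observed) < len(pattern):
        return None
    return all(base in _IUPAC[sym] for base, sym in
               zip(observed.upper(), pattern.upper()))


def read_bed_mask(path) -> dict[str, list[tuple[int, int]]]:
    """Read masked regions from a BED file (0-based half-open)."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed interval") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: malformed interval "
                                 f"[{start}, {end})")
            mask.setdefault(parts[0], []).append((start, end))
    return mask


def _count_mismatches(subject: str, query: str, start: int) -> int:
    """Mismatches of query placed at subject[start:start+len(query)];
    off-contig positions count as mismatches."""
    mm = 0
    slen = len(subject)
    for k, q in enumerate(query):
        p = start + k
        if p < 0 or p >= slen or subject[p] != q:
            mm += 1
    return mm


def _seed_candidates(subject: str, query: str, max_mm: int) -> set[int]:
    """Candidate start offsets via pigeonhole seeding: with max_mm
    mismatches allowed, at least one of max_mm+1 disjoint seeds is exact."""
    L = len(query)
    k = max(1, min(_SEED_LEN, L // (max_mm + 1)))
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        index.setdefault(subject[i:i + k], []).append(i)
    candidates: set[int] = set()
    offsets = [i * k for i in range(max_mm + 1)]
    if offsets[-1] + k > L:  # degenerate short spacer: fall back to one seed
        offsets = [0]
    for off in offsets:
        seed = query[off:off + k]
        for pos in index.get(seed, ()):
            candidates.add(pos - off)
    return candidates


def _overlaps_mask(start: int, end: int,
                   intervals: Sequence[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def find_protospacers(
    spacers: SpacerCatalog,
    subjects: Mapping[str, str],
    min_identity: float = 100.0,
    pam: str = "CC",
    pam_side: int = 5,
    mask: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> list[ProtospacerHit]:
    """Locate protospacers for every spacer in every subject sequence.

    Hits below ``min_identity`` (percent over the full spacer length) are
    dropped, as are hits overlapping a masked interval by at least one
    base. The PAM pattern is matched on the ``pam_side`` flank (5 or 3)
    relative to the protospacer strand.
    """
    if not 0.0 < min_identity <= 100.0:
        raise ValueError("min_identity must be in (0, 100]")
    if pam_side not in (5, 3):
        raise ValueError("pam_side must be 5 or 3")
    _check_iupac(pam)
    mask = mask or {}
    for sid, intervals in mask.items():
        for s, e in intervals:
            if s < 0 or e < s:
                raise ValueError(f"malformed mask interval [{s}, {e}) "
                                 f"on {sid!r}")
    hits: list[ProtospacerHit] = []
    for subject_id, subject in subjects.items():
        subject = subject.upper()
        intervals = mask.get(subject_id, ())
        for spacer_id, seq in spacers.items():
            L = len(seq)
            max_mm = int(L * (100.0 - min_identity) / 100.0)
            for strand, query in (("+", seq), ("-", reverse_complement(seq))):
                for start in sorted(_seed_candidates(subject, query, max_mm)):
                    end = start + L
                    mm = _count_mismatches(subject, query, start)
                    if mm > max_mm:
                        continue
                    if _overlaps_mask(max(start, 0), min(end, len(subject)),
                                      intervals):
                        continue
                    pam_obs, pam_ok = _read_pam(subject, start, end, strand,
                                                pam, pam_side)
                    hits.append(ProtospacerHit(
                        spacer_id, subject_id, start, end, strand,
                        round(100.0 * (L - mm) / L, 4), mm, pam_obs, pam_ok))
    hits.sort(key=lambda h: (h.subject_id, h.start, h.spacer_id, h.strand))
    return hits


def _read_pam(subject: str, start: int, end: int, strand: str,
              pattern: str, pam_side: int) -> tuple[str, Optional[bool]]:
    """Extract the flank adjacent to the protospacer on the requested side
    of the protospacer strand, and match it to the IUPAC pattern."""
    n = len(pattern)
    # which forward-strand window holds the flank
    upstream = (strand == "+") == (pam_side == 5)
    if upstream:
        lo, hi = start - n, start
    else:
        lo, hi = end, end + n
    chunk = subject[max(lo, 0):max(hi, 0)]
    complete = lo >= 0 and hi <= len(subject)
    if strand == "-":
        chunk = reverse_complement(chunk)
    if not complete:
        return chunk, None
    return chunk, _pam_matches(chunk, pattern)


def summarize_targets(
    hits: Iterable[ProtospacerHit],
    arrays: Optional[Sequence[CRISPRArray]] = None,
    pam_only: bool = False,
) -> dict[str, int]:
    """Count distinct subjects (isolates) with hits per spacer.

    When ``arrays`` is given, spacers of those arrays without any hit are
    included with count 0. ``pam_only`` restricts to PAM-passing hits.
    """
    subjects: dict[str, set[str]] = {}
    for h in hits:
        if pam_only and not h.pam_pass:
            continue
        subjects.setdefault(h.spacer_id, set()).add(h.subject_id)
    counts = {s: len(v) for s, v in subjects.items()}
    if arrays is not None:
        for arr in arrays:
            for s in arr.spacers:
                counts.setdefault(s, 0)
    return counts


def write_hits_tsv(hits: Iterable[ProtospacerHit], path) -> None:
    cols = ("spacer_id", "subject_id", "start", "end", "strand",
            "percent_identity", "mismatches", "pam_observed", "pam_pass")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            pam_pass = "NA" if h.pam_pass is None else str(h.pam_pass)
            fh.write(f"{h.spacer_id}\t{h.subject_id}\t{h.start}\t{h.end}\t"
                     f"{h.strand}\t{h.percent_identity:g}\t{h.mismatches}\t"
                     f"{h.pam_observed}\t{pam_pass}\n")


def write_target_colors(counts: Mapping[str, int], path,
                        palette: Optional[Sequence[str]] = None) -> None:
    """Emit a diff/constrain color-scheme TSV keyed by target count.

    Spacers are binned by their count onto a sequential ramp so heavily
    targeted spacers stand out in array plots.
    """
    if palette is None:
        palette = ("#DDDDDD", "#FEE391", "#FEC44F", "#FE9929",
                   "#EC7014", "#CC4C02", "#8C2D04")
    maxc = max(counts.values(), default=0)
    with open(path, "w") as fh:
        for spacer, c in sorted(counts.items()):
            idx = 0 if maxc == 0 else min(len(palette) - 1,
                                          int(c / max(maxc, 1)
                                              * (len(palette) - 1)))
            color = palette[idx]
            fh.write(f"{spacer}\t{color}\t{color}\n")
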