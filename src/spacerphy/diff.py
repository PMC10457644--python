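"""Comparison plots of CRISPR arrays (array ordering, colors, rendering).

Arrays are drawn one per row, leader end on the left. Spacers present in
two or more plotted arrays get a unique (fill, outline) color combination;
spacers found in only one array are drawn as thin black rectangles.
Identical spacers in adjacently plotted rows are joined by lines, so the
row order is chosen to maximize the number of spacers shared between
adjacent arrays — exhaustively for small numbers of arrays, by a seeded
stochastic search (random restarts plus pairwise swaps) for larger sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations, product
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .arrays import CRISPRArray

__all__ = [
    "DEFAULT_PALETTE",
    "UNIQUE_STYLE",
    "ColorAssignment",
    "order_arrays",
    "adjacency_score",
    "assign_colors",
    "read_color_file",
    "render_diff",
]

#: Colorblind-safe default palette (Wong's eight-color scheme).
DEFAULT_PALETTE: tuple[str, ...] = (
    "#000000", "#E69F00", "#56B4E9", "#009E73",
    "#F0E442", "#0072B2", "#D55E00", "#CC79A7",
)

#: Sentinel style for spacers present in exactly one plotted array.
UNIQUE_STYLE: tuple[str, str] = ("#000000", "#000000")


@dataclass
class ColorAssignment:
    """(fill, outline) pairs for shared spacers; unique spacers use the
    thin-black sentinel style."""

    shared: dict[str, tuple[str, str]] = field(default_factory=dict)
    unique: set[str] = field(default_factory=set)

    def style(self, spacer: str) -> tuple[str, str]:
        return self.shared.get(spacer, UNIQUE_STYLE)

    def is_unique(self, spacer: str) -> bool:
        return spacer not in self.shared


def adjacency_score(arrays: Sequence[CRISPRArray],
                    order: Sequence[str]) -> int:
    """Sum over adjacent pairs of the number of unique spacers shared."""
    by_id = {a.array_id: a.unique_spacers for a in arrays}
    return sum(
        len(by_id[order[i]] & by_id[order[i + 1]])
        for i in range(len(order) - 1)
    )


def order_arrays(
    arrays: Sequence[CRISPRArray],
    exhaustive_limit: int = 9,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[list[str], int]:
    """Order arrays to maximize sharing between adjacent rows.

    For up to ``exhaustive_limit`` arrays every order is scored and a
    maximum returned (ties: lexicographically smallest order). For larger
    sets a seeded stochastic search (restarts + pairwise-swap hill
    climbing) returns the best order found.
    """
    ids = [a.array_id for a in arrays]
    n = len(ids)
    if n <= 1:
        return list(ids), 0
    sets = {a.array_id: a.unique_spacers for a in arrays}
    shared = {
        (x, y): len(sets[x] & sets[y]) for x in ids for y in ids if x != y
    }

    def score(order: Sequence[str]) -> int:
        return sum(shared[order[i], order[i + 1]] for i in range(n - 1))

    if n <= exhaustive_limit:
        best_order, best_score = None, -1
        for perm in permutations(ids):
            if perm[0] > perm[-1]:  # each order ties with its reverse
                continue
            s = score(perm)
            if s > best_score or (s == best_score and list(perm) < best_order):
                best_order, best_score = list(perm), s
        return best_order, best_score

    rng = np.random.default_rng(seed)
    best_order, best_score = list(ids), score(ids)
    for _ in range(restarts):
        order = list(ids)
        rng.shuffle(order)
        s = score(order)
        improved = True
        while improved:
            improved = False
            for i in range(n - 1):
                for j in range(i + 1, n):
                    order[i], order[j] = order[j], order[i]
                    s2 = score(order)
                    if s2 > s:
                        s = s2
                        improved = True
                    else:
                        order[i], order[j] = order[j], order[i]
        if s > best_score:
            best_order, best_score = order, s
    return best_order, best_score


def assign_colors(
    arrays: Sequence[CRISPRArray],
    palette: Sequence[str] = DEFAULT_PALETTE,
    overrides: Optional[Mapping[str, tuple[str, str]]] = None,
) -> ColorAssignment:
    """Deterministically assign (fill, outline) combinations to spacers
    present in two or more arrays.

    Combinations are drawn fill-major from palette x palette in order of
    each spacer's first appearance (scanning arrays in the given order,
    leader to trailer). When the k^2 combination space is exhausted the
    cycle restarts with a warning. ``overrides`` pins specific spacers to
    user-chosen colors; overrides naming unknown spacers are ignored with
    a warning.
    """
    if len(palette) < 2:
        raise ValueError("palette needs at least two colors")
    counts: dict[str, int] = {}
    first_seen: list[str] = []
    for arr in arrays:
        for s in dict.fromkeys(arr.spacers):
            if s not in counts:
                first_seen.append(s)
            counts[s] = counts.get(s, 0) + 1
    known = set(counts)
    overrides = dict(overrides or {})
    for s in list(overrides):
        if s not in known:
            warnings.warn(f"color override for unknown spacer {s!r} ignored",
                          stacklevel=2)
            del overrides[s]

    combos = list(product(palette, repeat=2))
    assignment = ColorAssignment()
    i = 0
    warned = False
    for s in first_seen:
        if counts[s] < 2:
            assignment.unique.add(s)
            continue
        if s in overrides:
            assignment.shared[s] = tuple(overrides[s])
            continue
        if i >= len(combos) and not warned:
            warnings.warn(
                f"more than {len(combos)} shared spacers: color combinations "
                "are being reused", stacklevel=2)
            warned = True
        assignment.shared[s] = combos[i % len(combos)]
        i += 1
    return assignment


def read_color_file(path) -> dict[str, tuple[str, str]]:
    """Read a per-spacer color TSV: spacer_id<TAB>fill<TAB>outline."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'spacer<TAB>fill<TAB>outline'")
            out[parts[0]] = (parts[1], parts[2])
    return out


_SUPPORTED_FORMATS = ("svg", "png", "pdf", "jpg", "jpeg", "tif", "tiff")


def render_diff(
    arrays: Sequence[CRISPRArray],
    order: Sequence[str],
    colors: ColorAssignment,
    out_path,
    width: float = 10.0,
    height: Optional[float] = None,
) -> None:
    """Draw the array comparison plot, one row per array, leader left.

    Each spacer occurrence is a rectangle (thin black when unique);
    identical spacers in adjacent rows are joined by lines. Output format
    follows the file extension (SVG, PNG, PDF, ...).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    ext = Path(out_path).suffix.lstrip(".").lower()
    if ext not in _SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported plot format {ext!r}; supported: "
            + ", ".join(_SUPPORTED_FORMATS))
    by_id = {a.array_id: a for a in arrays}
    missing = [i for i in order if i not in by_id]
    if missing:
        raise ValueError(f"order references unknown arrays: {missing}")

    nrows = len(order)
    if height is None:
        height = 0.6 * nrows + 1.0
    fig, ax = plt.subplots(figsize=(width, height))
    box_h = 0.55
    for row, array_id in enumerate(order):
        arr = by_id[array_id]
        y = nrows - 1 - row
        for col, s in enumerate(arr.spacers):
            fill, outline = colors.style(s)
            w = 0.25 if colors.is_unique(s) else 0.85
            rect = Rectangle((col + (0.85 - w) / 2, y - box_h / 2), w, box_h,
                             facecolor=fill, edgecolor=outline, linewidth=1.8)
            rect.set_gid(f"spacer.{array_id}.{col}")
            ax.add_patch(rect)
        ax.text(-0.4, y, array_id, ha="right", va="center", fontsize=9)
    # connecting lines between identical spacers in adjacent rows
    for row in range(nrows - 1):
        top = by_id[order[row]]
        bot = by_id[order[row + 1]]
        y_top = nrows - 1 - row - box_h / 2
        y_bot = nrows - 2 - row + box_h / 2
        for ci, s in enumerate(top.spacers):
            if colors.is_unique(s):
                continue
            for cj, t in enumerate(bot.spacers):
                if s == t:
                    ax.plot([ci + 0.425, cj + 0.425], [y_top, y_bot],
                            color="0.55", linewidth=0.8, zorder=0)
    max_len = max(len(by_id[i]) for i in order)
    ax.set_xlim(-0.5 - 0.1 * max_len, max_len + 0.5)
    ax.set_ylim(-0.7, nrows - 0.3)
    ax.axis("off")
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
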