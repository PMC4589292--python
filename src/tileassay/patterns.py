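"""Labeled 2D lattice patterns and the congruence similarity metric.

A :class:`Pattern` is a finite, nonempty set of integer lattice cells, each
carrying a single-character label from a finite alphabet.  Patterns are the
common currency of this package: tile assemblies, cellular-automaton
space-times and target sets are all compared as patterns.

Two patterns that differ only by a rigid translation are considered equal in
*canonical form*, where the support snugly fits the coordinate axes (minimum
row = 0 and minimum column = 0, first quadrant).  Rotations and reflections
are never quotiented out.

The similarity metric is *congruence modulo p*: two patterns of identical
size n are congruent mod p if they can be overlapped (by translation) so
that a common subpattern of at least ``p * n`` cells matches label-for-label.
``congruence`` computes the tightest such p by exhaustive shift search.

Coordinate convention used throughout the package: ``(row, col)`` integers,
row 0 at the seed/bottom, rows increase upward.  The text-grid format prints
the top row first so that row 0 is the bottom line of the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

Coord = Tuple[int, int]

#: Valid size notions.
SIZE_NOTIONS = ("area", "manhattan_radius", "height", "width")

EMPTY_CHAR = "."
_ALPHABET_HEADER = "#alphabet:"


class PatternError(ValueError):
    """Degenerate pattern input (empty support, size mismatch, ...)."""


class Pattern:
    """A finite labeled region of the 2D integer lattice.

    Parameters
    ----------
    cells
        Mapping from ``(row, col)`` coordinates to single-character labels.
        Must be nonempty.
    origin
        Designated origin for Manhattan-radius measurements.  Defaults to
        ``(0, 0)``.  The origin is *not* translated by :meth:`canonical`;
        radius is always measured in the pattern's own frame.
    """

    __slots__ = ("_cells", "origin", "_hash")

    def __init__(self, cells: Mapping[Coord, str], origin: Coord = (0, 0)):
        if not cells:
            raise PatternError("pattern support must be nonempty")
        frozen: Dict[Coord, str] = {}
        for (r, c), label in cells.items():
            label = str(label)
            if len(label) != 1:
                raise PatternError(
                    f"labels must be single characters, got {label!r}"
                )
            if label == EMPTY_CHAR:
                raise PatternError(f"label {EMPTY_CHAR!r} is reserved for empty cells")
            frozen[(int(r), int(c))] = label
        self._cells = frozen
        self.origin = (int(origin[0]), int(origin[1]))
        self._hash = None

    # -- basic container protocol -------------------------------------------------

    @property
    def cells(self) -> Dict[Coord, str]:
        return dict(self._cells)

    def items(self):
        return self._cells.items()

    @property
    def support(self) -> frozenset:
        return frozenset(self._cells)

    def __len__(self) -> int:
        return len(self._cells)

    def __contains__(self, coord: Coord) -> bool:
        return coord in self._cells

    def __getitem__(self, coord: Coord) -> str:
        return self._cells[coord]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pattern):
            return NotImplemented
        return self.canonical()._cells == other.canonical()._cells

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(frozenset(self.canonical()._cells.items()))
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Pattern({len(self)} cells, bbox={self.bounding_box()})"

    # -- geometry -----------------------------------------------------------------

    def bounding_box(self) -> Tuple[int, int, int, int]:
        """``(min_row, min_col, max_row, max_col)`` of the support."""
        rows = [r for r, _ in self._cells]
        cols = [c for _, c in self._cells]
        return min(rows), min(cols), max(rows), max(cols)

    def translate(self, drow: int, dcol: int) -> "Pattern":
        return Pattern(
            {(r + drow, c + dcol): v for (r, c), v in self._cells.items()},
            origin=(self.origin[0] + drow, self.origin[1] + dcol),
        )

    def canonical(self) -> "Pattern":
        """Translate so the support snugly fits both axes (min row/col = 0)."""
        min_r, min_c, _, _ = self.bounding_box()
        if min_r == 0 and min_c == 0:
            return self
        return self.translate(-min_r, -min_c)

    # -- size ---------------------------------------------------------------------

    def size(self, notion: str = "area") -> int:
        """Pattern size under the chosen notion.

        ``area``: number of occupied cells.  ``manhattan_radius``: maximum
        over occupied cells of ``|row - origin_row| + |col - origin_col|``.
        ``height``/``width``: number of distinct rows/columns.
        """
        if notion == "area":
            return len(self._cells)
        if notion == "manhattan_radius":
            orow, ocol = self.origin
            return max(abs(r - orow) + abs(c - ocol) for r, c in self._cells)
        if notion == "height":
            return len({r for r, _ in self._cells})
        if notion == "width":
            return len({c for _, c in self._cells})
        raise ValueError(f"unknown size notion {notion!r}; expected one of {SIZE_NOTIONS}")


def pattern_size(x: Pattern, notion: str = "area") -> int:
    """Functional alias for :meth:`Pattern.size`."""
    return x.size(notion)


# -- subpattern containment and congruence -----------------------------------------


def _shift_overlap(z: Mapping[Coord, str], x: Mapping[Coord, str], dr: int, dc: int) -> int:
    """Number of cells of ``z`` that land on identically labeled cells of ``x``."""
    n = 0
    for (r, c), v in z.items():
        if x.get((r + dr, c + dc)) == v:
            n += 1
    return n


def _candidate_shifts(z: Pattern, x: Pattern) -> Iterable[Coord]:
    """All translations of ``z`` for which its support meets the support of ``x``.

    Exhaustive but finite: each shift is the difference of one ``x`` cell and
    one ``z`` cell, so every overlap of at least one cell is covered.
    """
    return sorted(
        {
            (xr - zr, xc - zc)
            for (zr, zc) in z.support
            for (xr, xc) in x.support
        }
    )


def is_subpattern(z: Pattern, x: Pattern) -> bool:
    """True iff some translation places every cell of ``z`` onto an
    identically labeled cell of ``x``."""
    if len(z) > len(x):
        return False
    nz = len(z)
    for dr, dc in _candidate_shifts(z, x):
        if _shift_overlap(z._cells, x._cells, dr, dc) == nz:
            return True
    return False


@dataclass(frozen=True)
class CongruenceResult:
    """Outcome of a maximum-overlap congruence computation.

    ``fraction = matched_cells / size_used`` (0 when ``size_used`` is 0);
    ``best_shift`` is the lexicographically smallest ``(drow, dcol)``
    achieving the maximum, applied to the second pattern.
    """

    fraction: float
    best_shift: Coord
    matched_cells: int
    size_used: int


def congruence(
    x: Pattern,
    y: Pattern,
    notion: str = "area",
    relax: bool = False,
) -> CongruenceResult:
    """Tightest p such that ``x`` and ``y`` are congruent modulo p.

    The two patterns must have identical size under ``notion`` unless
    ``relax`` is set, in which case the larger of the two cell counts is
    used as the normalizer.  The fraction is the maximum, over all relative
    translations, of the number of coordinates where both patterns are
    occupied with equal labels, divided by the size.  The matching cell-set
    is the common subpattern witness (no connectivity requirement; see
    :func:`congruence_connected` for the 4-connected variant).
    """
    nx, ny = x.size(notion), y.size(notion)
    if nx != ny and not relax:
        raise PatternError(
            f"patterns have different sizes under {notion!r} ({nx} != {ny}); "
            "pass relax=True to compare anyway"
        )
    if notion == "area" or relax:
        size_used = max(len(x), len(y)) if relax else nx
    else:
        size_used = nx
    best = (0, (0, 0))
    xc = x.canonical()
    yc = y.canonical()
    for dr, dc in _candidate_shifts(yc, xc):
        m = _shift_overlap(yc._cells, xc._cells, dr, dc)
        if m > best[0]:
            best = (m, (dr, dc))
    matched, shift = best
    frac = matched / size_used if size_used > 0 else 0.0
    return CongruenceResult(
        fraction=frac, best_shift=shift, matched_cells=matched, size_used=size_used
    )


def _connected_components(cells: Iterable[Coord]):
    cells = set(cells)
    while cells:
        comp = set()
        stack = [next(iter(cells))]
        cells.discard(stack[0])
        while stack:
            r, c = stack.pop()
            comp.add((r, c))
            for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                if nb in cells:
                    cells.discard(nb)
                    stack.append(nb)
        yield comp


def congruence_connected(
    x: Pattern,
    y: Pattern,
    notion: str = "area",
    relax: bool = False,
) -> CongruenceResult:
    """Variant of :func:`congruence` requiring the common subpattern witness
    to be 4-connected: scores each shift by its largest connected matching
    component rather than the full matching set."""
    nx, ny = x.size(notion), y.size(notion)
    if nx != ny and not relax:
        raise PatternError(
            f"patterns have different sizes under {notion!r} ({nx} != {ny})"
        )
    size_used = max(len(x), len(y)) if (relax or notion != "area") else nx
    if notion == "area" and not relax:
        size_used = nx
    best = (0, (0, 0))
    xc, yc = x.canonical(), y.canonical()
    for dr, dc in _candidate_shifts(yc, xc):
        matching = [
            (r, c)
            for (r, c), v in yc._cells.items()
            if xc._cells.get((r + dr, c + dc)) == v
        ]
        if not matching:
            continue
        m = max(len(comp) for comp in _connected_components(matching))
        if m > best[0]:
            best = (m, (dr, dc))
    matched, shift = best
    frac = matched / size_used if size_used > 0 else 0.0
    return CongruenceResult(
        fraction=frac, best_shift=shift, matched_cells=matched, size_used=size_used
    )


# -- text-grid I/O ------------------------------------------------------------------


def to_text(x: Pattern, alphabet_header: bool = False) -> str:
    """Render a pattern as a text grid.

    One line per row, one character per cell, ``.`` for empty cells.  The
    top row is printed first so that row 0 ends up as the bottom line.
    """
    xc = x.canonical()
    _, _, max_r, max_c = xc.bounding_box()
    lines = []
    if alphabet_header:
        alphabet = "".join(sorted(set(xc._cells.values())))
        lines.append(_ALPHABET_HEADER + alphabet)
    for r in range(max_r, -1, -1):
        lines.append(
            "".join(xc._cells.get((r, c), EMPTY_CHAR) for c in range(max_c + 1))
        )
    return "\n".join(lines) + "\n"


def from_text(text: str) -> Pattern:
    """Parse the text-grid format produced by :func:`to_text`.

    Round-trips bit-exactly: ``from_text(to_text(x)) == x`` and rendering
    again reproduces the same grid.
    """
    rows = [
        line
        for line in text.splitlines()
        if line and not line.startswith(_ALPHABET_HEADER)
    ]
    if not rows:
        raise PatternError("empty text grid")
    cells: Dict[Coord, str] = {}
    nrows = len(rows)
    for i, line in enumerate(rows):
        r = nrows - 1 - i  # top line is the highest row
        for c, ch in enumerate(line):
            if ch != EMPTY_CHAR:
                cells[(r, c)] = ch
    return Pattern(cells)
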