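"""Example tile systems, each paired with its target-set oracle.

Four constructors:

``binary_counter``
    The canonical cooperative (tau=2) binary counter: starting from an
    n-bit zero seed row, each new row increments the previous one.  The
    target set is every correct partial counting space-time, compared by
    Manhattan radius from the seed's lower-left corner.  The same tile set
    run at tau=1 is the error-prone noncooperative variant.

``rgb_system``
    An AND-gate gadget inside an L x L seed frame: a red signal grows from
    input site r (west edge) and a green signal from g (south edge) toward
    the designated cooperation point C at (L/2, L/2).  Terminator tiles
    (D on red, E on green) attach nondeterministically at any extension
    site; only when both signals terminate exactly adjacent to C can the
    cooperation tile O bind (cooperatively at tau=2, via two strength-1
    glues), after which a hard-coded blue signal grows to the output B on
    the east edge.  Targets are the successful AND assembly and all partial
    assemblies on its pathway.

``eca_tileset``
    Compiles an elementary cellular automaton (rule 0-255) into a directed
    tau=2 tile system whose unique tiling reproduces the rule's space-time
    row for row.  Rows are assembled in zig-zag order (odd rows left to
    right, even rows right to left) so that each tile's two input edges
    carry enough neighborhood information to determine the next state; two
    wall columns supply the fixed inactive boundary.

``dkca_tileset``
    Compiles a Domany-Kinzel probabilistic CA (activation probability p1
    with one active parent, p2 with two, 0 with none) into a tau=2 tile
    system with concentration-programmed nondeterminism.  The space-time is
    laid out in light-cone (45-degree rotated) geometry, where each site's
    two parents are its lattice S and W neighbors; tile concentrations make
    the class-conditional attachment probabilities equal (p1, p2, 0).
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .atam import (
    Assembly,
    GlueFunction,
    TileSystem,
    TileType,
    enumerate_assemblies,
)
from .patterns import Coord, Pattern

LabelMap = FrozenSet[Tuple[Coord, str]]


def _label_map(cells: Dict[Coord, str]) -> LabelMap:
    return frozenset(cells.items())


def assembly_label_map(asm: Assembly, system: TileSystem) -> LabelMap:
    """Absolute-frame label map of an assembly (seed excluded when the
    system measures only grown cells)."""
    if system.measure_seed:
        return frozenset((c, t.label) for c, t in asm.placements.items())
    return frozenset(
        (c, t.label) for c, t in asm.placements.items() if c not in system.seed
    )


def map_to_pattern(m: LabelMap, origin: Coord = (0, 0)) -> Optional[Pattern]:
    if not m:
        return None
    return Pattern(dict(m), origin=origin)


class TargetSet:
    """A target set of patterns, layered by a size notion.

    Exposes three views used by the metrics:

    * ``label_maps(n)`` — the targets of size ``n`` as absolute-frame
      label maps (the seed fixes the coordinate frame, so set operations
      against assembled patterns are exact);
    * ``enumerate(n)`` — the same targets as canonical :class:`Pattern`
      objects, for congruence scoring;
    * ``promising(m)`` — whether an assembled label map can still become a
      target by further monotone growth (labels are immutable, so this is
      decidable from the map alone for every shipped system).
    """

    def __init__(
        self,
        notion: str,
        description: str,
        label_maps_fn: Callable[[int], Set[LabelMap]],
        promising_fn: Callable[[LabelMap], bool],
        membership_fn: Optional[Callable[[LabelMap], bool]] = None,
        size_origin: Coord = (0, 0),
        max_size: Optional[int] = None,
    ):
        self.notion = notion
        self.description = description
        self._label_maps_fn = label_maps_fn
        self._promising_fn = promising_fn
        self._membership_fn = membership_fn
        self.size_origin = size_origin
        self.max_size = max_size
        self._cache: Dict[int, Set[LabelMap]] = {}

    def label_maps(self, n: int) -> Set[LabelMap]:
        if n not in self._cache:
            self._cache[n] = set(self._label_maps_fn(n))
        return self._cache[n]

    def enumerate(self, n: int) -> List[Pattern]:
        pats = []
        for m in sorted(self.label_maps(n), key=sorted):
            p = map_to_pattern(m, origin=self.size_origin)
            if p is not None:
                pats.append(p)
        return pats

    def membership(self, m: LabelMap, n: Optional[int] = None) -> bool:
        if self._membership_fn is not None:
            ok = self._membership_fn(m)
            if not ok or n is None:
                return ok
            return m in self.label_maps(n)
        if n is not None:
            return m in self.label_maps(n)
        raise ValueError("size n required when no analytic membership is available")

    def promising(self, m: LabelMap) -> bool:
        return self._promising_fn(m)


# ===================================================================================
# Binary counter
# ===================================================================================


def _counter_bit(row: int, col: int, n_bits: int) -> int:
    """Bit displayed at (row, col) of the correct counting space-time:
    row r spells r in binary, most significant bit in column 0."""
    return (row >> (n_bits - 1 - col)) & 1


def _counter_tiles(n_bits: int) -> Tuple[Dict[str, TileType], GlueFunction]:
    tiles: Dict[str, TileType] = {}

    def add(t: TileType):
        tiles[t.name] = t

    strengths: Dict[str, int] = {}
    if n_bits == 1:
        # single-column counter: one increment step, then overflow halts it
        strengths.update({"s0": 2, "s1": 2})
        add(TileType("O0", S="s0", N="s1", label="1"))
        seeds = {"seed0": TileType("seed0", N="s0", label="0")}
        tiles.update(seeds)
        return tiles, GlueFunction(strengths)
    # rightmost (least significant) column: strength-2 bottom glues indexed
    # by row, so each row's increment starts unconditionally and the column
    # halts at the all-ones row (no successor tile at the overflow)
    for g in ("b0", "b1", "c0", "c1", "l0", "l1"):
        strengths[g] = 1
    for k in range(2**n_bits - 1):
        strengths[f"r{k}"] = 2
        strengths[f"r{k+1}"] = 2
        lsb = k & 1
        add(
            TileType(
                f"R{k}",
                S=f"r{k}",
                N=f"r{k+1}",
                W=f"c{lsb}",
                label=str(1 - lsb),
            )
        )
    # interior columns: bit from below, carry from the right
    for x, y in itertools.product((0, 1), repeat=2):
        v, carry = x ^ y, x & y
        add(
            TileType(
                f"I{x}{y}",
                S=f"b{x}",
                E=f"c{y}",
                N=f"b{v}",
                W=f"c{carry}",
                label=str(v),
            )
        )
    # leftmost column: same increment but the overflow tile does not exist,
    # halting the counter at the all-ones row
    for x, y in ((0, 0), (0, 1), (1, 0)):
        v = x ^ y
        add(TileType(f"L{x}{y}", S=f"l{x}", E=f"c{y}", N=f"l{v}", label=str(v)))
    # seed row tiles
    add(TileType("seedL", N="l0", label="0"))
    add(TileType("seedI", N="b0", label="0"))
    add(TileType("seedR", N="r0", label="0"))
    return tiles, GlueFunction(strengths)


def _counter_staircases(n_bits: int, radius: int) -> Set[LabelMap]:
    """All correct partial counting patterns of exactly the given Manhattan
    radius, generated arithmetically (no tile dynamics involved).

    A correct partial pattern is the full zero seed row plus, for rows
    r = 1, 2, ..., a suffix of columns [j_r, n_bits) with j_r nondecreasing
    in r (each cell needs its south neighbor, and interior cells their east
    neighbor), every cell labeled with the bit of r it should carry.
    """
    out: Set[LabelMap] = set()
    max_row = 2**n_bits - 1

    def radius_of(cells) -> int:
        return max(r + c for r, c in cells)

    seed_cells = {(0, c): str(_counter_bit(0, c, n_bits)) for c in range(n_bits)}

    def rec(cells: Dict[Coord, str], row: int, j_prev: int):
        rad = radius_of(cells)
        if rad == radius:
            out.add(_label_map(cells))
        if rad >= radius or row > max_row:
            return
        # add row `row` as a suffix starting at j >= j_prev
        for j in range(j_prev, n_bits):
            new = dict(cells)
            for c in range(j, n_bits):
                new[(row, c)] = str(_counter_bit(row, c, n_bits))
            if radius_of(new) <= radius:
                rec(new, row + 1, j)

    rec(seed_cells, 1, 0)
    return out


def _counter_promising(m: LabelMap, n_bits: int) -> bool:
    """Promising iff every placed cell agrees with the correct counting
    space-time (any such placement can be completed to a staircase)."""
    for (r, c), label in m:
        if not (0 <= c < n_bits) or not (0 <= r <= 2**n_bits - 1):
            return False
        if label != str(_counter_bit(r, c, n_bits)):
            return False
    return True


def _counter_is_target(m: LabelMap, n_bits: int) -> bool:
    if not _counter_promising(m, n_bits):
        return False
    cells = dict(m)
    # full seed row
    if any((0, c) not in cells for c in range(n_bits)):
        return False
    rows = sorted({r for r, _ in cells})
    if rows != list(range(len(rows))):
        return False
    j_prev = 0
    for r in rows[1:]:
        cols = sorted(c for rr, c in cells if rr == r)
        if cols != list(range(cols[0], n_bits)):  # must be a suffix
            return False
        if cols[0] < j_prev:
            return False
        j_prev = cols[0]
    return True


def binary_counter(n_bits: int, tau: int = 2) -> Tuple[TileSystem, TargetSet]:
    """The n-bit binary counter and its target set of correct partial
    counting patterns (size notion: Manhattan radius from the seed's
    lower-left corner)."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    if tau not in (1, 2):
        raise ValueError("tau must be 1 or 2")
    tiles, glue = _counter_tiles(n_bits)
    seed: Dict[Coord, TileType] = {}
    if n_bits == 1:
        seed[(0, 0)] = tiles["seed0"]
    else:
        seed[(0, 0)] = tiles["seedL"]
        for c in range(1, n_bits - 1):
            seed[(0, c)] = tiles["seedI"]
        seed[(0, n_bits - 1)] = tiles["seedR"]
    system = TileSystem(
        tiles={k: v for k, v in tiles.items()},
        seed=seed,
        temperature=tau,
        glue_function=glue,
        measure_seed=True,
        size_origin=(0, 0),
        name=f"binary counter ({n_bits}-bit, tau={tau})",
    )
    targets = TargetSet(
        notion="manhattan_radius",
        description=f"correct partial counting patterns of a {n_bits}-bit counter",
        label_maps_fn=functools.partial(_counter_staircases, n_bits),
        promising_fn=functools.partial(_counter_promising, n_bits=n_bits),
        membership_fn=functools.partial(_counter_is_target, n_bits=n_bits),
        max_size=(2**n_bits - 1) + (n_bits - 1),
    )
    return system, targets


# ===================================================================================
# RGB AND-gate gadget
# ===================================================================================


@dataclass
class RGBGeometry:
    """Site layout of the RGB gadget for frame size L (even, >= 6)."""

    L: int

    @property
    def C(self) -> Coord:
        return (self.L // 2, self.L // 2)

    @property
    def r_site(self) -> Coord:
        return (self.L // 2, 0)

    @property
    def g_site(self) -> Coord:
        return (0, self.L // 2)

    @property
    def b_site(self) -> Coord:
        return (self.L // 2, self.L - 1)

    def red_site(self, i: int) -> Coord:
        return (self.L // 2, i)

    def green_site(self, j: int) -> Coord:
        return (j, self.L // 2)

    def blue_site(self, k: int) -> Coord:
        return (self.L // 2, self.L // 2 + k)

    @property
    def n_signal(self) -> int:
        """Number of signal sites per color (1 .. L/2 - 1)."""
        return self.L // 2 - 1

    @property
    def n_blue(self) -> int:
        return self.L // 2 - 2


def rgb_system(L: int, tau: int = 2) -> Tuple[TileSystem, TargetSet]:
    """The RGB AND-gate assembler inside an L x L seed frame.

    Red tiles occupy (L/2, 1..L/2-1) growing east from input r, green tiles
    (1..L/2-1, L/2) growing north from input g; positions are hard-coded in
    the glues.  At every extension site past the first, the plain signal
    tile and the terminator (D/E) are both eligible — the nondeterminism of
    the model.  Only a terminator adjacent to C presents the strength-1
    input glue that the cooperation tile O needs; at tau=2, O requires both.
    """
    if L < 6 or L % 2:
        raise ValueError("L must be an even integer >= 6")
    if tau not in (1, 2):
        raise ValueError("tau must be 1 or 2")
    geo = RGBGeometry(L)
    tiles: Dict[str, TileType] = {}
    strengths: Dict[str, int] = {"dred": 1, "egreen": 1}

    def add(t: TileType):
        tiles[t.name] = t

    # frame tiles (seed)
    add(TileType("F", label="F"))
    add(TileType("Fr", E="rin", label="F"))
    add(TileType("Fg", N="gin", label="F"))
    add(TileType("Fb", label="F"))
    strengths["rin"] = 2
    strengths["gin"] = 2
    ns = geo.n_signal
    # red chain
    add(TileType("R1", W="rin", E="red1", label="R"))
    strengths["red1"] = 2
    for i in range(2, ns + 1):
        strengths[f"red{i}"] = 2
        add(TileType(f"R{i}", W=f"red{i-1}", E=f"red{i}", label="R"))
        add(TileType(f"D{i}", W=f"red{i-1}", E="dred", label="D"))
    # green chain
    add(TileType("G1", S="gin", N="green1", label="G"))
    strengths["green1"] = 2
    for j in range(2, ns + 1):
        strengths[f"green{j}"] = 2
        add(TileType(f"G{j}", S=f"green{j-1}", N=f"green{j}", label="G"))
        add(TileType(f"E{j}", S=f"green{j-1}", N="egreen", label="E"))
    # cooperation tile and hard-coded blue path
    add(TileType("O", W="dred", S="egreen", E="u1", label="O"))
    for k in range(1, geo.n_blue + 1):
        strengths[f"u{k}"] = 2
        strengths[f"u{k+1}"] = strengths.get(f"u{k+1}", 2)
        add(TileType(f"B{k}", W=f"u{k}", E=f"u{k+1}", label="B"))
    seed: Dict[Coord, TileType] = {}
    for r in range(L):
        for c in range(L):
            if r in (0, L - 1) or c in (0, L - 1):
                seed[(r, c)] = tiles["F"]
    seed[geo.r_site] = tiles["Fr"]
    seed[geo.g_site] = tiles["Fg"]
    seed[geo.b_site] = tiles["Fb"]
    system = TileSystem(
        tiles=tiles,
        seed=seed,
        temperature=tau,
        glue_function=GlueFunction(strengths),
        measure_seed=False,
        size_origin=(0, 0),
        name=f"RGB gadget (L={L}, tau={tau})",
    )
    targets = _rgb_targets(geo)
    return system, targets


def _rgb_pathway_maps(geo: RGBGeometry) -> List[Dict[Coord, str]]:
    """All assemblies on the successful AND pathway, as label maps.

    Red states: growing prefixes R_1..R_m (m = 0..ns-1 of plain tiles, the
    last site left open), or the completed signal R..R D (D adjacent to C).
    A plain R at the last site is *not* on the pathway: it can never present
    the cooperation glue.  Green symmetric; O and the blue prefix only once
    both signals have terminated at C.
    """
    ns = geo.n_signal
    red_states: List[Dict[Coord, str]] = []
    for m in range(0, ns):  # growing, last site still open
        red_states.append({geo.red_site(i): "R" for i in range(1, m + 1)})
    done_red = {geo.red_site(i): "R" for i in range(1, ns)}
    done_red[geo.red_site(ns)] = "D"
    green_states: List[Dict[Coord, str]] = []
    for m in range(0, ns):
        green_states.append({geo.green_site(j): "G" for j in range(1, m + 1)})
    done_green = {geo.green_site(j): "G" for j in range(1, ns)}
    done_green[geo.green_site(ns)] = "E"
    out: List[Dict[Coord, str]] = []
    for red in red_states + [done_red]:
        for green in green_states + [done_green]:
            base = {**red, **green}
            out.append(base)
            if len(red) == ns and len(green) == ns and "D" in red.values():
                with_o = {**base, geo.C: "O"}
                out.append(with_o)
                blue = dict(with_o)
                for k in range(1, geo.n_blue + 1):
                    blue = {**blue, geo.blue_site(k): "B"}
                    out.append(dict(blue))
    return out


def _rgb_targets(geo: RGBGeometry) -> TargetSet:
    maps = _rgb_pathway_maps(geo)
    by_size: Dict[int, Set[LabelMap]] = {}
    all_maps: Set[LabelMap] = set()
    for cells in maps:
        m = _label_map(cells)
        all_maps.add(m)
        if cells:
            n = max(r + c for r, c in cells)
        else:
            n = 0
        by_size.setdefault(n, set()).add(m)

    def promising(m: LabelMap) -> bool:
        cells = set(m)
        return any(cells <= t for t in all_maps)

    return TargetSet(
        notion="manhattan_radius",
        description=f"AND-gate pathway assemblies in an L={geo.L} frame",
        label_maps_fn=lambda n: by_size.get(n, set()),
        promising_fn=promising,
        membership_fn=lambda m: m in all_maps,
        max_size=max(by_size) if by_size else 0,
    )


def rgb_pre_cooperation_size(L: int) -> int:
    """The pattern size (Manhattan radius) at which one signal has just
    reached the cooperation point: the stage the per-size error counts are
    read at when checking their linear growth in L."""
    return L - 1


# ===================================================================================
# Elementary cellular automata -> tile systems (zig-zag compiler)
# ===================================================================================


def eca_rule_table(rule: int) -> Dict[Tuple[int, int, int], int]:
    if not 0 <= rule <= 255:
        raise ValueError("ECA rule must be in 0..255")
    table = {}
    for k in range(8):
        a, b, c = (k >> 2) & 1, (k >> 1) & 1, k & 1
        table[(a, b, c)] = (rule >> k) & 1
    return table


WALL_LABEL = "#"


def eca_tileset(rule: int, seed_row: Sequence[int]) -> Tuple[TileSystem, TargetSet]:
    """Compile an ECA rule plus a concrete seed row into a directed tau=2
    tile system whose unique tiling is the rule's bounded space-time.

    Layout: CA column i sits at grid column i+1; grid row t is CA time t.
    Wall columns at grid columns 0 and w+1 grow with strength-2 vertical
    glues and present the constant inactive boundary to row starts.  Odd
    rows assemble left to right (inputs S and W), even rows right to left
    (inputs S and E); glue payloads carry the 2-cell windows needed to make
    every attachment locally deterministic.
    """
    seed_row = [int(b) for b in seed_row]
    w = len(seed_row)
    if w < 3:
        raise ValueError("seed row must have width >= 3")
    if any(b not in (0, 1) for b in seed_row):
        raise ValueError("seed row must be binary")
    delta = eca_rule_table(rule)
    tiles: Dict[str, TileType] = {}
    strengths: Dict[str, int] = {"WLv": 2, "WRv": 2, "WL": 1, "WR": 1}

    def glue(fam: str, *bits: int) -> str:
        g = fam + "".join(str(b) for b in bits)
        strengths.setdefault(g, 1)
        return g

    def add(t: TileType):
        tiles[t.name] = t

    # walls
    add(TileType("wallL", S="WLv", N="WLv", E="WL", label=WALL_LABEL))
    add(TileType("wallR", S="WRv", N="WRv", W="WR", label=WALL_LABEL))
    # odd rows, left to right: type (a,b,c,d) with window a,b,c = row below
    # at i-1..i+1 and d = own-row value at i-1; value v = delta(a,b,c)
    for a, b, c, d in itertools.product((0, 1), repeat=4):
        v = delta[(a, b, c)]
        add(
            TileType(
                f"L{a}{b}{c}{d}",
                S=glue("eN", b, c),
                W=glue("oE", a, d),
                N=glue("oN", d, v),
                E=glue("oE", b, v),
                label=str(v),
            )
        )
        if a == 0 and d == 0:  # start variant binds to the left wall
            add(
                TileType(
                    f"Ls{b}{c}",
                    S=glue("eN", b, c),
                    W="WL",
                    N=glue("oN", 0, v),
                    E=glue("oE", b, v),
                    label=str(v),
                )
            )
    # even rows, right to left: type (a,b,c,e) with e = own-row value at i+1
    for a, b, c, e in itertools.product((0, 1), repeat=4):
        v = delta[(a, b, c)]
        add(
            TileType(
                f"R{a}{b}{c}{e}",
                S=glue("oN", a, b),
                E=glue("eW", c, e),
                N=glue("eN", v, e),
                W=glue("eW", b, v),
                label=str(v),
            )
        )
        if c == 0 and e == 0:  # start variant binds to the right wall
            add(
                TileType(
                    f"Rs{a}{b}",
                    S=glue("oN", a, b),
                    E="WR",
                    N=glue("eN", v, 0),
                    W=glue("eW", b, v),
                    label=str(v),
                )
            )
    # bespoke seed tiles: N payload carries (x0_i, x0_{i+1})
    seed: Dict[Coord, TileType] = {}
    padded = seed_row + [0]
    for i, bit in enumerate(seed_row):
        name = f"seed{i}"
        add(TileType(name, N=glue("eN", bit, padded[i + 1]), label=str(bit)))
        seed[(0, i + 1)] = tiles[name]
    add(TileType("seedWL", N="WLv", label=WALL_LABEL))
    add(TileType("seedWR", N="WRv", label=WALL_LABEL))
    seed[(0, 0)] = tiles["seedWL"]
    seed[(0, w + 1)] = tiles["seedWR"]
    system = TileSystem(
        tiles=tiles,
        seed=seed,
        temperature=2,
        glue_function=GlueFunction(strengths),
        measure_seed=True,
        size_origin=(0, 0),
        name=f"ECA rule {rule} tiling (width {w})",
    )
    targets = _eca_targets(rule, seed_row, system)
    return system, targets


def _eca_spacetime_labels(rule: int, seed_row: Sequence[int], steps: int) -> Dict[Coord, str]:
    """Label map of the full bounded tiling (CA cells plus walls) for the
    given number of steps — the analytic reference the tiling must match."""
    from .ca import eca_run  # local import to avoid a cycle at module load

    st = eca_run(rule, seed_row, steps)
    w = len(seed_row)
    cells: Dict[Coord, str] = {}
    for t in range(steps + 1):
        cells[(t, 0)] = WALL_LABEL
        cells[(t, w + 1)] = WALL_LABEL
        for i in range(w):
            cells[(t, i + 1)] = str(int(st.grid[t, i]))
    return cells


def _eca_targets(rule: int, seed_row: Sequence[int], system: TileSystem) -> TargetSet:
    w = len(seed_row)

    @functools.lru_cache(maxsize=None)
    def reference(steps: int) -> Dict[Coord, str]:
        return _eca_spacetime_labels(rule, seed_row, steps)

    def promising(m: LabelMap) -> bool:
        if not m:
            return True
        max_t = max(r for (r, _), _ in m)
        ref = reference(max_t)
        return all(ref.get(coord) == label for coord, label in m)

    @functools.lru_cache(maxsize=None)
    def maps_of_size(n: int) -> FrozenSet[LabelMap]:
        # the target patterns are exactly the reachable tilings (the
        # deterministic space-time and its partial assemblies); enumerate
        # them through the ideal system itself
        enum = enumerate_assemblies(system, notion="height", n_max=n)
        return frozenset(
            assembly_label_map(a, system) for a in enum.by_size.get(n, [])
        )

    return TargetSet(
        notion="height",
        description=f"space-time tilings of ECA rule {rule}, width {w}",
        label_maps_fn=lambda n: set(maps_of_size(n)),
        promising_fn=promising,
        membership_fn=promising,  # every consistent reachable map is a target
    )


def run_bounded(system: TileSystem, max_row: int) -> Assembly:
    """Attach greedily (first eligible event in deterministic order) while
    ignoring sites above ``max_row``, until nothing below the bound is
    eligible.  For a locally deterministic system this yields its unique
    bounded tiling."""
    from .atam import attach, eligible_attachments

    asm = system.initial_assembly()
    while True:
        events = [
            e for e in eligible_attachments(asm, system) if e[0][0] <= max_row
        ]
        if not events:
            return asm
        site, tile, _ = events[0]
        asm = attach(asm, site, tile, system)


def tiling_to_spacetime(asm: Assembly, system: TileSystem, width: int) -> np.ndarray:
    """Extract the CA space-time array from a (complete-rows) ECA tiling."""
    rows = sorted({r for (r, c) in asm.placements if 1 <= c <= width})
    full = [
        r
        for r in rows
        if all((r, c) in asm.placements for c in range(1, width + 1))
    ]
    grid = np.zeros((len(full), width), dtype=np.int8)
    for t in full:
        for i in range(width):
            grid[t, i] = int(asm.placements[(t, i + 1)].label)
    return grid


# ===================================================================================
# Domany-Kinzel CA -> tile systems (light-cone geometry)
# ===================================================================================


def lightcone_sites(width: int, max_depth: Optional[int] = None) -> List[Tuple[int, int]]:
    """Sites (t, j) of the light cone of a width-w seed row: row t has
    width - t sites, j = 0 .. width-1-t; site (t+1, j) has parents (t, j)
    and (t, j+1)."""
    depth = width - 1 if max_depth is None else min(max_depth, width - 1)
    return [(t, j) for t in range(depth + 1) for j in range(width - t)]


def lightcone_to_grid(t: int, j: int, width: int) -> Coord:
    """Rotate light-cone site (t, j) onto the tile grid: parents land at
    the lattice S and W neighbors."""
    return (t + j, width - 1 - j)


def dkca_tileset(
    p1: float,
    p2: float,
    seed_row: Sequence[int],
    max_depth: Optional[int] = None,
) -> Tuple[TileSystem, TargetSet]:
    """Compile DKCA(p1, p2) into a tau=2 tile system in light-cone geometry.

    One tile per (parent context, output) combination; the N and W input
    edges carry strength-1 glues marked with the parent values, so a tile
    needs both parents (cooperative binding).  Concentrations are chosen so
    the class-conditional attachment probabilities equal p1 (one active
    parent), p2 (two active parents) and 0 (no active parent — the
    corresponding activating tile simply does not exist, and likewise for
    p = 0 or 1 exactly).

    ``max_depth`` bounds the compiled depth by indexing the glues with the
    time step; None compiles generic (depth-free) tiles, in which case the
    system halts naturally at the apex of the light cone.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("p1 and p2 must be probabilities")
    seed_row = [int(b) for b in seed_row]
    w = len(seed_row)
    if w < 2:
        raise ValueError("seed row must have width >= 2")
    tiles: Dict[str, TileType] = {}
    strengths: Dict[str, int] = {}

    def glue(fam: str, t: Optional[int], bit: int) -> str:
        g = f"{fam}{t}:{bit}" if t is not None else f"{fam}{bit}"
        strengths.setdefault(g, 1)
        return g

    def add(t: TileType):
        tiles[t.name] = t

    depths = range(1, (max_depth or (w - 1)) + 1) if max_depth is not None else [None]
    for depth in depths:
        for s, wv in itertools.product((0, 1), repeat=2):
            n_active = s + wv
            prob1 = (0.0, p1, p2)[n_active]
            for out, conc in ((1, prob1), (0, 1.0 - prob1)):
                if conc <= 0:
                    continue
                tag = "" if depth is None else f"@{depth}"
                d_in = None if depth is None else depth - 1
                add(
                    TileType(
                        f"T{s}{wv}>{out}{tag}",
                        S=glue("v", d_in, s),
                        W=glue("h", d_in, wv),
                        N=glue("v", depth, out),
                        E=glue("h", depth, out),
                        label=str(out),
                        conc=conc,
                    )
                )
    seed: Dict[Coord, TileType] = {}
    for j, bit in enumerate(seed_row):
        name = f"seed{j}"
        d0 = None if max_depth is None else 0
        add(TileType(name, N=glue("v", d0, bit), E=glue("h", d0, bit), label=str(bit)))
        seed[lightcone_to_grid(0, j, w)] = tiles[name]
    system = TileSystem(
        tiles=tiles,
        seed=seed,
        temperature=2,
        glue_function=GlueFunction(strengths),
        measure_seed=True,
        size_origin=(0, 0),
        name=f"DKCA({p1}, {p2}) tiling (width {w})",
    )
    targets = dkca_lightcone_targets(p1, p2, seed_row, max_depth)
    return system, targets


def dkca_reachable_lightcone(
    p1: float, p2: float, seed_row: Sequence[int], max_depth: Optional[int] = None
) -> Set[Tuple[Tuple[int, ...], ...]]:
    """Exhaustive set of DKCA space-times reachable with positive
    probability in light-cone geometry, as tuples of rows (row t has
    width - t entries).  Independent of the tile machinery: a direct
    combinatorial closure of the transition rules."""
    seed = tuple(int(b) for b in seed_row)
    w = len(seed)
    depth = w - 1 if max_depth is None else min(max_depth, w - 1)

    def choices(s: int, wv: int) -> Tuple[int, ...]:
        prob1 = (0.0, p1, p2)[s + wv]
        opts = []
        if prob1 < 1:
            opts.append(0)
        if prob1 > 0:
            opts.append(1)
        return tuple(opts)

    frontier: Set[Tuple[Tuple[int, ...], ...]] = {(seed,)}
    for t in range(1, depth + 1):
        nxt = set()
        for st in frontier:
            prev = st[-1]
            options = [choices(prev[j], prev[j + 1]) for j in range(w - t)]
            for combo in itertools.product(*options):
                nxt.add(st + (tuple(combo),))
        frontier = nxt
    return frontier


def dkca_lightcone_targets(
    p1: float, p2: float, seed_row: Sequence[int], max_depth: Optional[int] = None
) -> TargetSet:
    """Target set for the DKCA tiling: every partial tiling whose labels
    are consistent with some positively-probable DKCA space-time.  Built by
    combinatorial closure (down-sets of the light-cone dependency order
    with rule-consistent labels), not by running the tile system."""
    seed = tuple(int(b) for b in seed_row)
    w = len(seed)
    depth = w - 1 if max_depth is None else min(max_depth, w - 1)

    def choices(s: int, wv: int) -> Tuple[int, ...]:
        prob1 = (0.0, p1, p2)[s + wv]
        opts = []
        if prob1 < 1:
            opts.append(0)
        if prob1 > 0:
            opts.append(1)
        return tuple(opts)

    @functools.lru_cache(maxsize=None)
    def all_partial_maps() -> FrozenSet[LabelMap]:
        seed_cells = {
            lightcone_to_grid(0, j, w): str(b) for j, b in enumerate(seed)
        }
        sites = [(t, j) for t in range(1, depth + 1) for j in range(w - t)]
        seen: Set[LabelMap] = set()
        stack = [dict(seed_cells)]
        # values indexed by light-cone site for parent lookup
        def value_at(cells, t, j):
            return int(cells[lightcone_to_grid(t, j, w)])

        seen.add(_label_map(seed_cells))
        while stack:
            cells = stack.pop()
            for (t, j) in sites:
                g = lightcone_to_grid(t, j, w)
                if g in cells:
                    continue
                pa = lightcone_to_grid(t - 1, j, w)
                pb = lightcone_to_grid(t - 1, j + 1, w)
                if pa not in cells or pb not in cells:
                    continue
                for out in choices(value_at(cells, t - 1, j), value_at(cells, t - 1, j + 1)):
                    new = dict(cells)
                    new[g] = str(out)
                    m = _label_map(new)
                    if m not in seen:
                        seen.add(m)
                        stack.append(new)
        return frozenset(seen)

    def by_size(n: int) -> Set[LabelMap]:
        out = set()
        for m in all_partial_maps():
            pat = map_to_pattern(m)
            if pat is not None and pat.size("height") == n:
                out.add(m)
        return out

    def promising(m: LabelMap) -> bool:
        return any(set(m) <= set(t) for t in all_partial_maps())

    return TargetSet(
        notion="height",
        description=f"DKCA({p1}, {p2}) light-cone tilings, width {w}",
        label_maps_fn=by_size,
        promising_fn=promising,
        membership_fn=lambda m: m in all_partial_maps(),
    )


ZOO: Dict[str, Callable] = {
    "counter": binary_counter,
    "rgb": rgb_system,
    "eca": eca_tileset,
    "dkca": dkca_tileset,
}
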