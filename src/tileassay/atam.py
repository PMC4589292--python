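"""Seeded monotonic tile assembly at temperature tau.

The model: square tiles on the 2D integer lattice, each tile type carrying
four glue labels (N, E, S, W).  A symmetric glue function assigns a
nonnegative integer strength to pairs of glue labels (by default diagonal:
a glue binds only its own label, with its declared strength).  Growth starts
from a fixed seed assembly; a tile may attach at an empty site iff the sum
of glue strengths against its already-placed neighbors is at least the
temperature tau.  Attached tiles never detach (monotonic accretion), so
assemblies only grow along any assembly sequence.

Beyond single attachments this module provides exhaustive breadth-first
enumeration of all reachable assemblies up to a size bound (the per-size
sets A_n that the yield metrics are computed from), stochastic sampling with
concentration-weighted attachment, and the minimum single-event attachment
probability K used by the probability lower bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .patterns import Coord, Pattern

NULL_GLUE = ""

# Neighbor direction -> (offset, own edge, opposing edge).
_NEIGHBORS = (
    ((1, 0), "N", "S"),
    ((0, 1), "E", "W"),
    ((-1, 0), "S", "N"),
    ((0, -1), "W", "E"),
)


class AssemblyError(ValueError):
    """Raised for ineligible attachments or inconsistent systems."""


@dataclass(frozen=True)
class TileType:
    """A Wang tile: four glue labels and a display label.

    ``conc`` is the relative concentration (positive weight) used by the
    stochastic sampler; enumeration ignores it.
    """

    name: str
    N: str = NULL_GLUE
    E: str = NULL_GLUE
    S: str = NULL_GLUE
    W: str = NULL_GLUE
    label: str = "?"
    conc: float = 1.0

    def glue(self, edge: str) -> str:
        return getattr(self, edge)


class GlueFunction:
    """Symmetric integer-valued glue strength function.

    Default is diagonal: ``strength(g, g) = strengths[g]`` and 0 for any
    mismatched pair.  Arbitrary symmetric off-diagonal entries can be added
    through ``pairs``.  The reserved null glue has strength 0 to everything.
    """

    def __init__(
        self,
        strengths: Optional[Dict[str, int]] = None,
        pairs: Optional[Dict[FrozenSet[str], int]] = None,
    ):
        self.strengths = dict(strengths or {})
        self.pairs = {frozenset(k): int(v) for k, v in (pairs or {}).items()}
        for g, s in self.strengths.items():
            if s < 0:
                raise AssemblyError(f"glue {g!r} has negative strength {s}")

    def strength(self, g1: str, g2: str) -> int:
        if g1 == NULL_GLUE or g2 == NULL_GLUE:
            return 0
        key = frozenset((g1, g2))
        if key in self.pairs:
            return self.pairs[key]
        if g1 == g2:
            return self.strengths.get(g1, 0)
        return 0


@dataclass
class TileSystem:
    """A seeded tile assembly system ``(T, s, tau)`` plus glue function.

    ``measure_seed`` controls whether seed cells participate in pattern
    extraction and size measurement (True for free-standing constructions
    like the counter; False when the seed is a frame abstracting the
    reaction vessel, as in the RGB gadget).  ``size_origin`` is the origin
    for Manhattan-radius size measurements.
    """

    tiles: Dict[str, TileType]
    seed: Dict[Coord, TileType]
    temperature: int
    glue_function: GlueFunction
    measure_seed: bool = True
    size_origin: Coord = (0, 0)
    name: str = "tile system"

    def __post_init__(self):
        if not self.seed:
            raise AssemblyError("seed assembly must be nonempty")
        if self.temperature < 1:
            raise AssemblyError("temperature must be a positive integer")
        for t in self.tiles.values():
            if t.conc <= 0:
                raise AssemblyError(f"tile {t.name!r} has nonpositive concentration")

    def initial_assembly(self) -> "Assembly":
        return Assembly(dict(self.seed), provenance=())

    def _glue_index(self) -> Dict[Tuple[str, str], Tuple[TileType, ...]]:
        """Candidate tiles per (own edge, neighbor glue) with positive
        binding strength — prunes the tile scan in eligibility checks."""
        idx = getattr(self, "_glue_index_cache", None)
        if idx is not None:
            return idx
        labels = {
            t.glue(e) for t in self.tiles.values() for e in ("N", "E", "S", "W")
        }
        labels.discard(NULL_GLUE)
        idx = {}
        for name in sorted(self.tiles):
            t = self.tiles[name]
            for edge in ("N", "E", "S", "W"):
                g = t.glue(edge)
                for g_nb in labels:
                    if self.glue_function.strength(g, g_nb) > 0:
                        idx.setdefault((edge, g_nb), []).append(t)
        idx = {k: tuple(v) for k, v in idx.items()}
        self._glue_index_cache = idx
        return idx


class Assembly:
    """A placement of tiles grown monotonically from a seed.

    ``placements`` maps coordinates to tile types; ``provenance`` is the
    ordered tuple of ``(coord, tile_name)`` attachment events after the
    seed.  Assemblies are value objects: :func:`attach` returns a new
    assembly and never mutates its input.
    """

    __slots__ = ("placements", "provenance", "_key")

    def __init__(self, placements: Dict[Coord, TileType], provenance: Tuple = ()):
        self.placements = placements
        self.provenance = provenance
        self._key = None

    @property
    def key(self) -> FrozenSet:
        """Identity as an exact placement map (seeded growth fixes the
        coordinate frame, so no translation quotient)."""
        if self._key is None:
            self._key = frozenset(
                (coord, t.name) for coord, t in self.placements.items()
            )
        return self._key

    def __len__(self) -> int:
        return len(self.placements)

    def __eq__(self, other):
        return isinstance(other, Assembly) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def to_pattern(self, system: TileSystem) -> Optional[Pattern]:
        """Label pattern of this assembly in the system's measurement frame.

        Returns None when the system excludes seed cells and nothing has
        grown yet (empty measurable support).
        """
        if system.measure_seed:
            cells = {c: t.label for c, t in self.placements.items()}
        else:
            cells = {
                c: t.label
                for c, t in self.placements.items()
                if c not in system.seed
            }
        if not cells:
            return None
        return Pattern(cells, origin=system.size_origin)

    def size(self, system: TileSystem, notion: str) -> int:
        pat = self.to_pattern(system)
        if pat is None:
            return 0
        return pat.size(notion)


# -- attachment rules ---------------------------------------------------------------


def binding_strength(a: Assembly, site: Coord, t: TileType, sys: TileSystem) -> int:
    """Total binding strength of tile ``t`` at ``site``: the sum of glue
    strengths over occupied neighbors (the cooperative total)."""
    total = 0
    r, c = site
    for (dr, dc), own_edge, opp_edge in _NEIGHBORS:
        nb = a.placements.get((r + dr, c + dc))
        if nb is not None:
            total += sys.glue_function.strength(t.glue(own_edge), nb.glue(opp_edge))
    return total


def eligible_attachments(
    a: Assembly, sys: TileSystem
) -> List[Tuple[Coord, TileType, int]]:
    """All tau-stable attachment events on ``a``.

    Returns ``(site, tile, strength)`` for every empty site adjacent to the
    assembly where some tile's summed glue strengths meet or exceed the
    temperature.  Deterministically ordered: site row-major, then tile name.
    """
    frontier = set()
    for (r, c) in a.placements:
        for (dr, dc), _, _ in _NEIGHBORS:
            site = (r + dr, c + dc)
            if site not in a.placements:
                frontier.add(site)
    index = sys._glue_index()
    events = []
    for site in sorted(frontier):
        r, c = site
        candidates: Dict[str, TileType] = {}
        for (dr, dc), own_edge, opp_edge in _NEIGHBORS:
            nb = a.placements.get((r + dr, c + dc))
            if nb is None:
                continue
            for t in index.get((own_edge, nb.glue(opp_edge)), ()):
                candidates.setdefault(t.name, t)
        for name in sorted(candidates):
            t = candidates[name]
            s = binding_strength(a, site, t, sys)
            if s >= sys.temperature:
                events.append((site, t, s))
    return events


def attach(a: Assembly, site: Coord, t: TileType, sys: TileSystem) -> Assembly:
    """Return a new assembly with ``t`` placed at ``site``.

    The event must be tau-stable; otherwise an :class:`AssemblyError` naming
    the site, tile and computed strength is raised.
    """
    if site in a.placements:
        raise AssemblyError(f"site {site} is already occupied")
    s = binding_strength(a, site, t, sys)
    if s < sys.temperature:
        raise AssemblyError(
            f"attachment of {t.name!r} at {site} has strength {s} < "
            f"temperature {sys.temperature}"
        )
    placements = dict(a.placements)
    placements[site] = t
    return Assembly(placements, a.provenance + ((site, t.name),))


def is_terminal(a: Assembly, sys: TileSystem) -> bool:
    return not eligible_attachments(a, sys)


# -- exhaustive enumeration ---------------------------------------------------------


@dataclass
class EnumerationResult:
    """Per-size sets of distinct reachable assemblies.

    ``by_size[n]`` holds every reachable assembly of size exactly ``n``
    (deduplicated as exact placement maps); ``terminal`` flags the subset
    admitting no further attachment.  ``truncated`` is set when the
    retention cap was hit, in which case the sets are lower bounds.
    """

    by_size: Dict[int, List[Assembly]]
    terminal: Dict[int, List[Assembly]]
    truncated: bool
    notion: str
    n_max: int
    system: TileSystem = field(repr=False)

    @property
    def sizes(self) -> List[int]:
        return sorted(self.by_size)

    def all_assemblies(self) -> List[Assembly]:
        return [a for n in self.sizes for a in self.by_size[n]]


def enumerate_assemblies(
    sys: TileSystem,
    notion: str = "area",
    n_max: int = 8,
    cap: int = 200_000,
) -> EnumerationResult:
    """Breadth-first closure of :func:`attach` from the seed.

    Explores every reachable assembly whose size (under ``notion``, in the
    system's measurement frame) is at most ``n_max``, deduplicating exact
    placement maps.  All four size notions are nondecreasing under monotone
    growth, so branches exceeding ``n_max`` are pruned safely.  If more than
    ``cap`` distinct assemblies are encountered the result is truncated
    (flagged, with a warning) rather than raising.
    """
    seed_asm = sys.initial_assembly()
    seen = {seed_asm.key}
    by_size: Dict[int, Dict[FrozenSet, Assembly]] = {}
    terminal: Dict[int, Dict[FrozenSet, Assembly]] = {}
    truncated = False

    def record(asm: Assembly, n: int, term: bool):
        by_size.setdefault(n, {})[asm.key] = asm
        if term:
            terminal.setdefault(n, {})[asm.key] = asm

    queue: List[Tuple[Assembly, int]] = []
    n0 = seed_asm.size(sys, notion)
    if n0 <= n_max:
        queue.append((seed_asm, n0))
    while queue:
        asm, n_asm = queue.pop()
        events = eligible_attachments(asm, sys)
        record(asm, n_asm, not events)
        for site, tile, _ in events:
            child = attach(asm, site, tile, sys)
            if child.key in seen:
                continue
            n = child.size(sys, notion)
            if n > n_max:
                continue
            if len(seen) >= cap:
                truncated = True
                break
            seen.add(child.key)
            queue.append((child, n))
        if truncated:
            break
    if truncated:
        warnings.warn(
            f"enumeration cap {cap} hit for {sys.name!r}; per-size sets are "
            "lower bounds",
            stacklevel=2,
        )
    return EnumerationResult(
        by_size={n: list(d.values()) for n, d in sorted(by_size.items())},
        terminal={n: list(d.values()) for n, d in sorted(terminal.items())},
        truncated=truncated,
        notion=notion,
        n_max=n_max,
        system=sys,
    )


# -- stochastic sampling ------------------------------------------------------------


def _event_weights(events: Sequence[Tuple[Coord, TileType, int]]) -> np.ndarray:
    return np.array([t.conc for _, t, _ in events], dtype=float)


def sample_assembly(
    sys: TileSystem,
    rng: "int | np.random.Generator",
    max_steps: int = 10_000,
) -> Assembly:
    """Sample one assembly trajectory.

    At each step one eligible ``(site, tile)`` event is drawn with
    probability proportional to the attaching tile's concentration
    (uniform when concentrations are all equal), until the assembly is
    terminal or ``max_steps`` attachments have been made.  Reproducible
    from an integer seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    asm = sys.initial_assembly()
    for _ in range(max_steps):
        events = eligible_attachments(asm, sys)
        if not events:
            break
        w = _event_weights(events)
        idx = int(rng.choice(len(events), p=w / w.sum()))
        site, tile, _ = events[idx]
        asm = attach(asm, site, tile, sys)
    return asm


def min_attachment_probability(sys: TileSystem, enum: EnumerationResult) -> float:
    """Minimum positive probability K of any single attachment event.

    The event model matches :func:`sample_assembly`: from any reachable
    non-terminal assembly, one eligible event is drawn with probability
    proportional to its tile's concentration.  K is the smallest such event
    probability over every enumerated assembly.  Requires a complete
    (non-truncated) enumeration; a truncated one would make K unsound.
    """
    if enum.truncated:
        raise AssemblyError("K is unsound on a truncated enumeration")
    k = None
    for asm in enum.all_assemblies():
        events = eligible_attachments(asm, sys)
        if not events:
            continue
        w = _event_weights(events)
        p_min = float(w.min() / w.sum())
        k = p_min if k is None else min(k, p_min)
    if k is None:
        # no attachment is ever possible; the seed is terminal
        return 1.0
    return k


# -- JSON dialect -------------------------------------------------------------------

_TOP_KEYS = {
    "alphabet",
    "glues",
    "glue_pairs",
    "tiles",
    "seed",
    "temperature",
    "measure_seed",
    "size_origin",
    "name",
}
_TILE_KEYS = {"name", "N", "E", "S", "W", "label", "conc"}
_SEED_KEYS = {"row", "col", "tile"}


def system_to_json(sys: TileSystem) -> str:
    """Serialize a tile system to the package's JSON dialect."""
    doc = {
        "name": sys.name,
        "alphabet": sorted({t.label for t in sys.tiles.values()}),
        "glues": {g: s for g, s in sorted(sys.glue_function.strengths.items())},
        "glue_pairs": [
            [*sorted(pair), s] for pair, s in sorted(sys.glue_function.pairs.items())
        ],
        "tiles": [
            {
                "name": t.name,
                "N": t.N,
                "E": t.E,
                "S": t.S,
                "W": t.W,
                "label": t.label,
                "conc": t.conc,
            }
            for _, t in sorted(sys.tiles.items())
        ],
        "seed": [
            {"row": r, "col": c, "tile": t.name}
            for (r, c), t in sorted(sys.seed.items())
        ],
        "temperature": sys.temperature,
        "measure_seed": sys.measure_seed,
        "size_origin": list(sys.size_origin),
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def system_from_json(text: str) -> TileSystem:
    """Parse and validate the JSON dialect.  Unknown keys are rejected."""
    doc = json.loads(text)
    if not isinstance(doc, dict):
        raise AssemblyError("tile-system JSON must be an object")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise AssemblyError(f"unknown top-level keys: {sorted(unknown)}")
    for req in ("tiles", "seed", "temperature"):
        if req not in doc:
            raise AssemblyError(f"missing required key {req!r}")
    glues = doc.get("glues", {})
    if not all(isinstance(v, int) and v >= 0 for v in glues.values()):
        raise AssemblyError("glue strengths must be nonnegative integers")
    pairs = {}
    for entry in doc.get("glue_pairs", []):
        if len(entry) != 3:
            raise AssemblyError("glue_pairs entries must be [glueA, glueB, strength]")
        a, b, s = entry
        pairs[frozenset((a, b))] = int(s)
    tiles: Dict[str, TileType] = {}
    seen_names = set()
    for td in doc["tiles"]:
        unknown = set(td) - _TILE_KEYS
        if unknown:
            raise AssemblyError(f"unknown tile keys: {sorted(unknown)}")
        name = td["name"]
        if name in seen_names:
            raise AssemblyError(f"duplicate tile name {name!r}")
        seen_names.add(name)
        tiles[name] = TileType(
            name=name,
            N=td.get("N", NULL_GLUE),
            E=td.get("E", NULL_GLUE),
            S=td.get("S", NULL_GLUE),
            W=td.get("W", NULL_GLUE),
            label=td.get("label", "?"),
            conc=float(td.get("conc", 1.0)),
        )
    alphabet = doc.get("alphabet")
    if alphabet is not None:
        bad = {t.label for t in tiles.values()} - set(alphabet)
        if bad:
            raise AssemblyError(f"tile labels outside declared alphabet: {sorted(bad)}")
    seed = {}
    for sd in doc["seed"]:
        unknown = set(sd) - _SEED_KEYS
        if unknown:
            raise AssemblyError(f"unknown seed keys: {sorted(unknown)}")
        if sd["tile"] not in tiles:
            raise AssemblyError(f"seed references unknown tile {sd['tile']!r}")
        seed[(int(sd["row"]), int(sd["col"]))] = tiles[sd["tile"]]
    return TileSystem(
        tiles=tiles,
        seed=seed,
        temperature=int(doc["temperature"]),
        glue_function=GlueFunction(strengths=glues, pairs=pairs),
        measure_seed=bool(doc.get("measure_seed", True)),
        size_origin=tuple(doc.get("size_origin", (0, 0))),
        name=doc.get("name", "tile system"),
    )
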