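"""Cellular-automaton assemblers: ECA and Domany-Kinzel simulators,
directed-percolation detection, and the ECA-simulates-DKCA experiment.

An elementary cellular automaton (ECA) is a radius-1 binary rule numbered
0..255 applied synchronously; its space-time (row 0 = seed, row t = state
at time t) is a 2D pattern.  The Domany-Kinzel CA (DKCA) is its canonical
probabilistic counterpart: a site activates with probability p1 when
exactly one of its two outer parents is active, p2 when both are, and
never when neither is (no spontaneous generation) — the standard model of
directed percolation.

A space-time *percolates* when a cluster of active sites connects the seed
row to the output row.  Cluster connectivity follows the generation
dependency (each active site is linked to its active parents), the
standard directed-percolation reading; an undirected 8-neighborhood
variant is available behind a flag.

The central experiment: an ECA without spontaneous generation, run from
random Bernoulli(1/2) seed rows, behaves like *some* DKCA whose (p1, p2)
can be estimated by counting how often each parent class produces an
active child.  Running the matched DKCA and comparing the two ensembles on
the percolation property measures how strongly the deterministic ECA
assembler simulates the probabilistic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .patterns import Pattern

# -- space-times --------------------------------------------------------------------


@dataclass
class SpaceTime:
    """Binary space-time history: ``grid[t, i]`` is the state of site i at
    time t (row 0 = seed), shape ``(steps + 1, width)``."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2:
            raise ValueError("space-time grid must be 2D")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("space-time values must be binary")

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def steps(self) -> int:
        return self.grid.shape[0] - 1

    def to_pattern(self, active_only: bool = False) -> Pattern:
        cells = {}
        for t in range(self.grid.shape[0]):
            for i in range(self.width):
                v = int(self.grid[t, i])
                if v or not active_only:
                    cells[(t, i)] = str(v)
        return Pattern(cells)


# -- ECA ----------------------------------------------------------------------------


def _rule_array(rule: int) -> np.ndarray:
    if not 0 <= rule <= 255:
        raise ValueError("ECA rule must be in 0..255")
    return np.array([(rule >> k) & 1 for k in range(8)], dtype=np.int8)


def eca_run(rule: int, seed_row: Sequence[int], steps: int) -> SpaceTime:
    """Synchronous ECA evolution with fixed inactive boundaries.

    ``grid[t+1, i] = delta(grid[t, i-1], grid[t, i], grid[t, i+1])`` with
    out-of-range neighbors treated as 0.
    """
    row = np.asarray(seed_row, dtype=np.int8)
    if row.ndim != 1 or row.size < 3:
        raise ValueError("seed row must be a binary vector of width >= 3")
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    lut = _rule_array(rule)
    grid = np.zeros((steps + 1, row.size), dtype=np.int8)
    grid[0] = row
    for t in range(steps):
        padded = np.pad(grid[t], 1)
        idx = 4 * padded[:-2] + 2 * padded[1:-1] + padded[2:]
        grid[t + 1] = lut[idx]
    return SpaceTime(grid)


def has_spontaneous_generation(rule: int) -> bool:
    """True when the rule can activate a cell whose outer neighbors are
    both inactive (contexts 000 or 010)."""
    lut = _rule_array(rule)
    return bool(lut[0b000] or lut[0b010])


# -- DKCA ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DKCAParams:
    """Domany-Kinzel activation probabilities: p1 for one active outer
    parent, p2 for two; zero active parents never activate."""

    p1: float
    p2: float

    def __post_init__(self):
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ValueError("p1 and p2 must be probabilities")


def dkca_run(
    params: DKCAParams,
    seed_row: Sequence[int],
    steps: int,
    rng: "int | np.random.Generator",
    u: Optional[np.ndarray] = None,
) -> SpaceTime:
    """DKCA evolution on the square lattice: site (t+1, i) looks at parents
    (t, i-1) and (t, i+1), fixed inactive boundaries.

    ``u``, if given, is a uniform(0,1) field of shape (steps, width) used
    in place of fresh draws — the standard monotone coupling (the same
    field realizes every (p1, p2) simultaneously, and activation sets are
    nondecreasing in p1 and p2 when p1 <= p2 pointwise orderings hold).
    """
    row = np.asarray(seed_row, dtype=np.int8)
    if row.ndim != 1 or row.size < 3:
        raise ValueError("seed row must be a binary vector of width >= 3")
    if u is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        u = rng.random((steps, row.size))
    grid = np.zeros((steps + 1, row.size), dtype=np.int8)
    grid[0] = row
    probs = np.array([0.0, params.p1, params.p2])
    for t in range(steps):
        padded = np.pad(grid[t], 1)
        n_active = padded[:-2] + padded[2:]  # outer parents only
        grid[t + 1] = (u[t] < probs[n_active]).astype(np.int8)
    return SpaceTime(grid)


# -- percolation --------------------------------------------------------------------


def percolates(
    st: SpaceTime,
    neighborhood: str = "outer",
    undirected_8: bool = False,
) -> Tuple[bool, List[Tuple[int, int]]]:
    """Spanning-cluster test: does a cluster of active sites touch both the
    seed row and the output (last) row?

    ``neighborhood`` selects the generation dependency: ``outer`` links a
    site to its active parents (t, i-1) and (t, i+1) (the two DKCA
    parents); ``eca`` additionally links (t, i) (the three ECA parents).
    ``undirected_8`` ignores the dependency structure and uses plain
    undirected 8-connectivity instead.  Returns ``(flag, witness)`` where
    witness is one seed-to-output path of active sites (empty when the
    space-time does not percolate).
    """
    g = st.grid
    active = g.astype(bool)
    T = g.shape[0]
    if T < 2:
        raise ValueError("need at least one step")
    if undirected_8:
        from scipy import ndimage

        labels, _ = ndimage.label(active, structure=np.ones((3, 3), dtype=int))
        common = set(labels[0][active[0]]) & set(labels[-1][active[-1]])
        common.discard(0)
        if not common:
            return False, []
        lab = min(common)
        # witness by BFS inside the chosen component
        return True, _undirected_witness(active, labels == lab)
    use_center = neighborhood == "eca"
    reach = np.zeros_like(active)
    reach[0] = active[0]
    for t in range(1, T):
        prev = reach[t - 1]
        padded = np.pad(prev, 1)
        linked = padded[:-2] | padded[2:]
        if use_center:
            linked = linked | prev
        reach[t] = active[t] & linked
    ends = np.flatnonzero(reach[-1])
    if ends.size == 0:
        return False, []
    # backtrack one witness path
    path = [(T - 1, int(ends[0]))]
    for t in range(T - 1, 0, -1):
        _, i = path[-1]
        cands = [i - 1, i + 1] + ([i] if use_center else [])
        for j in cands:
            if 0 <= j < st.width and reach[t - 1, j]:
                path.append((t - 1, j))
                break
    path.reverse()
    return True, path


def _undirected_witness(active: np.ndarray, comp: np.ndarray) -> List[Tuple[int, int]]:
    from collections import deque

    T, W = comp.shape
    starts = [(0, int(i)) for i in np.flatnonzero(comp[0])]
    prev: Dict[Tuple[int, int], Optional[Tuple[int, int]]] = {s: None for s in starts}
    q = deque(starts)
    goal = None
    while q:
        t, i = q.popleft()
        if t == T - 1:
            goal = (t, i)
            break
        for dt in (-1, 0, 1):
            for di in (-1, 0, 1):
                nb = (t + dt, i + di)
                if (
                    (dt or di)
                    and 0 <= nb[0] < T
                    and 0 <= nb[1] < W
                    and comp[nb]
                    and nb not in prev
                ):
                    prev[nb] = (t, i)
                    q.append(nb)
    if goal is None:
        return []
    path = []
    node = goal
    while node is not None:
        path.append(node)
        node = prev[node]
    path.reverse()
    return path


# -- empirical transition-rate estimation -------------------------------------------


@dataclass
class RateEstimate:
    """Class-conditional activation frequencies observed in space-times:
    class 1 = exactly one active outer parent, class 2 = both active."""

    p1_hat: float
    p2_hat: float
    n1: int
    n2: int
    se1: float
    se2: float
    undefined: Tuple[str, ...] = ()

    @property
    def params(self) -> DKCAParams:
        if self.undefined:
            raise ValueError(f"rate classes with no observations: {self.undefined}")
        return DKCAParams(self.p1_hat, self.p2_hat)


def count_transitions(grids: Sequence[np.ndarray]) -> RateEstimate:
    """Pool parent-class/child-activity counts over space-time grids.

    Works on any binary space-time (ECA- or DKCA-generated): every site of
    every non-seed row is one rule application, classified by the activity
    of its outer parents (boundaries inactive).
    """
    n = np.zeros(3, dtype=np.int64)  # occurrences per class 0/1/2
    k = np.zeros(3, dtype=np.int64)  # active children per class
    for g in grids:
        g = np.asarray(g, dtype=np.int8)
        for t in range(g.shape[0] - 1):
            padded = np.pad(g[t], 1)
            cls = padded[:-2] + padded[2:]
            child = g[t + 1]
            for c in (0, 1, 2):
                mask = cls == c
                n[c] += int(mask.sum())
                k[c] += int(child[mask].sum())
    undefined = tuple(f"class{c}" for c in (1, 2) if n[c] == 0)

    def frac(c):
        return k[c] / n[c] if n[c] else float("nan")

    def se(c):
        if not n[c]:
            return float("nan")
        p = frac(c)
        return float(np.sqrt(p * (1 - p) / n[c]))

    return RateEstimate(
        p1_hat=float(frac(1)),
        p2_hat=float(frac(2)),
        n1=int(n[1]),
        n2=int(n[2]),
        se1=se(1),
        se2=se(2),
        undefined=undefined,
    )


def estimate_rates(
    rule: int,
    n_runs: int,
    width: int,
    steps: int,
    rng: "int | np.random.Generator",
    density: float = 0.5,
) -> RateEstimate:
    """Estimate the effective DKCA parameters of an ECA rule from runs on
    i.i.d. Bernoulli(density) random seed rows."""
    if has_spontaneous_generation(rule):
        raise ValueError(
            f"rule {rule} spontaneously activates cells with inactive outer "
            "neighbors; it has no DKCA counterpart"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    grids = []
    for _ in range(n_runs):
        seed = (rng.random(width) < density).astype(np.int8)
        grids.append(eca_run(rule, seed, steps).grid)
    return count_transitions(grids)


# -- the ECA-simulates-DKCA experiment ----------------------------------------------


@dataclass
class SimulationExperimentReport:
    rule: int
    n_runs: int
    width: int
    steps: int
    rates: RateEstimate
    agreement: float
    agreement_se: float
    eca_perc_rate: float
    dkca_perc_rate: float
    thresholds: Tuple[float, ...]
    passed: Dict[float, bool] = field(default_factory=dict)


def simulation_strength_experiment(
    rule: int,
    n_runs: int = 100,
    width: int = 300,
    rng_seed: int = 0,
    thresholds: Sequence[float] = (0.9, 0.94),
    steps: Optional[int] = None,
    density: float = 0.5,
) -> SimulationExperimentReport:
    """Measure how strongly an ECA assembler simulates its matched DKCA on
    the percolation property.

    Protocol: run ``n_runs`` ECA space-times from Bernoulli(density) seed
    rows; pool the class-conditional activation counts into (p1_hat,
    p2_hat); run one DKCA(p1_hat, p2_hat) space-time from each of the same
    seed rows; report the fraction of paired runs agreeing on whether a
    spanning cluster connects seed to output row.  Defaults are 100 runs at
    width 300 (steps = width).
    """
    if steps is None:
        steps = width
    rng = np.random.default_rng(rng_seed)
    seeds = [(rng.random(width) < density).astype(np.int8) for _ in range(n_runs)]
    eca_sts = [eca_run(rule, s, steps) for s in seeds]
    rates = count_transitions([st.grid for st in eca_sts])
    if rates.undefined:
        raise ValueError(
            f"cannot match a DKCA: no observations for {rates.undefined}"
        )
    params = rates.params
    eca_perc = np.array(
        [percolates(st, neighborhood="eca")[0] for st in eca_sts], dtype=bool
    )
    dkca_perc = np.array(
        [
            percolates(dkca_run(params, s, steps, rng), neighborhood="outer")[0]
            for s in seeds
        ],
        dtype=bool,
    )
    agree = float(np.mean(eca_perc == dkca_perc))
    se = float(np.sqrt(max(agree * (1 - agree), 1e-12) / n_runs))
    return SimulationExperimentReport(
        rule=rule,
        n_runs=n_runs,
        width=width,
        steps=steps,
        rates=rates,
        agreement=agree,
        agreement_se=se,
        eca_perc_rate=float(eca_perc.mean()),
        dkca_perc_rate=float(dkca_perc.mean()),
        thresholds=tuple(thresholds),
        passed={th: agree > th for th in thresholds},
    )


# -- phase sweep --------------------------------------------------------------------


def phase_sweep(
    p1_values: Sequence[float],
    p2_values: Sequence[float],
    width: int = 64,
    steps: int = 64,
    reps: int = 20,
    rng_seed: int = 0,
    density: float = 0.5,
    coupled: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo percolation probability over a (p1, p2) grid.

    With ``coupled`` (default), each repetition reuses one uniform random
    field and one seed row across the whole grid — the monotone coupling,
    under which the estimated percolation probability is exactly
    nondecreasing in p1 and in p2 along the grid.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    fields = []
    for _ in range(reps):
        seed = (rng.random(width) < density).astype(np.int8)
        if not seed.any():
            seed[width // 2] = 1
        u = rng.random((steps, width))
        fields.append((seed, u))
    for p1 in p1_values:
        for p2 in p2_values:
            params = DKCAParams(float(p1), float(p2))
            hits = 0
            for seed, u in fields:
                st = dkca_run(params, seed, steps, rng, u=u if coupled else None)
                if percolates(st, neighborhood="outer")[0]:
                    hits += 1
            rows.append(
                {
                    "p1": float(p1),
                    "p2": float(p2),
                    "percolation_prob": hits / reps,
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)
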