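"""Yield metrics for pattern assemblers: strength, impurity, efficiency.

Given the per-size sets ``A_n`` of patterns an assembler produces
(exhaustive enumeration) and a target set ``P`` layered by the same size
notion, every assembled pattern falls into exactly one of three classes:

* **target** — it is a target pattern of its size (``A_n ∩ P_n``);
* **promising** — not yet a target, but some further valid growth reaches
  one (``A'_n`` minus the targets);
* **erroneous** (junk) — it can never become a target (``E_n = A_n − A'_n``).

From the partition come the yield metrics:

* strength ``p`` — the largest constant such that, at every size, the
  assembler covers a fraction >= p of the targets *and* every assembled
  pattern is p-congruent (maximum cell overlap, normalized by cell count)
  to some same-size target; ``p = 1`` iff A = P on the evidence;
* impurity ``q`` — the tightest constant with ``|E_n| <= q |P_n|`` at
  every size (0 when nothing erroneous is ever produced);
* efficiency ``E = p / q`` — the composite quality measure, reported as
  infinity when q = 0 with p > 0 ("arbitrarily large efficiency");
* ``K`` — the minimum positive probability of a single attachment event,
  which turns (p, q) into probability lower bounds on producing target and
  promising patterns (target >= K·E/(1+E), promising >= E/(1+E),
  erroneous <= 1/(1+E)).

All reported values are evidence-bounded: they are exact over the
enumerated sizes (<= n_max) and say nothing about larger patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .atam import (
    Assembly,
    EnumerationResult,
    TileSystem,
    attach,
    eligible_attachments,
    min_attachment_probability,
)
from .patterns import Pattern, congruence
from .zoo import LabelMap, TargetSet, assembly_label_map, map_to_pattern

INF = math.inf


# -- partition ----------------------------------------------------------------------


@dataclass
class SizeClasses:
    targets: Set[LabelMap]
    promising_only: Set[LabelMap]
    erroneous: Set[LabelMap]
    undecided: Set[LabelMap] = field(default_factory=set)

    @property
    def assembled(self) -> Set[LabelMap]:
        return self.targets | self.promising_only | self.erroneous

    @property
    def promising(self) -> Set[LabelMap]:
        """A'_n: targets plus promising nontargets (undecided states are
        conservatively counted here)."""
        return self.targets | self.promising_only


@dataclass
class PartitionReport:
    """Per-size partition of assembled patterns into the three classes."""

    by_size: Dict[int, SizeClasses]
    horizon: Optional[int]
    truncated: bool

    @property
    def sizes(self) -> List[int]:
        return sorted(self.by_size)

    def counts(self) -> pd.DataFrame:
        rows = []
        for n in self.sizes:
            sc = self.by_size[n]
            rows.append(
                {
                    "size": n,
                    "assembled": len(sc.assembled),
                    "targets_hit": len(sc.targets),
                    "promising": len(sc.promising),
                    "erroneous": len(sc.erroneous),
                    "undecided": len(sc.undecided),
                }
            )
        return pd.DataFrame(rows)


def _forward_reaches_target(
    asm: Assembly,
    sys: TileSystem,
    targets: TargetSet,
    horizon: int,
) -> bool:
    """Bounded forward search: can the assembly become a target within
    `horizon` further attachments?  Used only when the target set has no
    analytic promising oracle."""
    seen = {asm.key}
    frontier = [asm]
    for _ in range(horizon):
        nxt = []
        for a in frontier:
            for site, tile, _ in eligible_attachments(a, sys):
                child = attach(a, site, tile, sys)
                if child.key in seen:
                    continue
                seen.add(child.key)
                m = assembly_label_map(child, sys)
                if targets.membership(m, child.size(sys, targets.notion)):
                    return True
                nxt.append(child)
        if not nxt:
            return False
        frontier = nxt
    return False


def classify(
    enum: EnumerationResult,
    targets: TargetSet,
    sys: Optional[TileSystem] = None,
    horizon: Optional[int] = None,
) -> PartitionReport:
    """Partition every enumerated pattern into target / promising /
    erroneous.

    Patterns are compared as absolute-frame label maps (the seed fixes the
    coordinate frame) and deduplicated per size.  Promisingness uses the
    target set's analytic oracle when it has one — for all shipped systems
    "can still become a target" is decidable from the map alone, because
    labels are immutable under monotone growth.  Otherwise a forward
    search bounded by ``horizon`` attachments decides; states still
    undecided at the horizon are conservatively counted as promising and
    flagged.
    """
    sys = sys or enum.system
    if horizon is None:
        horizon = 2 * enum.n_max
    by_size: Dict[int, SizeClasses] = {}
    for n in enum.sizes:
        sc = SizeClasses(set(), set(), set())
        maps: Dict[LabelMap, Assembly] = {}
        for asm in enum.by_size[n]:
            maps.setdefault(assembly_label_map(asm, sys), asm)
        target_maps = targets.label_maps(n)
        for m, asm in maps.items():
            if m in target_maps:
                sc.targets.add(m)
            elif targets.promising(m):
                sc.promising_only.add(m)
            elif targets._membership_fn is None and _forward_reaches_target(
                asm, sys, targets, horizon
            ):
                sc.promising_only.add(m)
            else:
                sc.erroneous.add(m)
        by_size[n] = sc
    return PartitionReport(by_size=by_size, horizon=horizon, truncated=enum.truncated)


# -- strength -----------------------------------------------------------------------


def best_congruence(y: Pattern, candidates: Sequence[Pattern]) -> float:
    """Max over targets x of the area-normalized overlap congruence."""
    best = 0.0
    for x in candidates:
        frac = congruence(x, y, notion="area", relax=True).fraction
        if frac > best:
            best = frac
            if best == 1.0:
                break
    return best


def strength(
    enum: EnumerationResult,
    targets: TargetSet,
    part: Optional[PartitionReport] = None,
) -> Tuple[float, pd.DataFrame]:
    """Strength p of the assembler on the enumerated evidence.

    ``p = min_n min(c_n, w_n)`` where ``c_n`` is the fraction of size-n
    targets actually assembled and ``w_n`` the worst, over assembled
    patterns of size n, best congruence to any same-size target.  Sizes
    where targets exist but nothing of that size was assembled drive
    ``c_n`` to 0; assembled sizes with no targets at all drive ``w_n`` to
    0 (flagged in the diagnostics).
    """
    if part is None:
        part = classify(enum, targets)
    rows = []
    p = 1.0
    for n in part.sizes:
        sc = part.by_size[n]
        target_maps = targets.label_maps(n)
        n_p = len(target_maps)
        if n_p == 0 and not sc.assembled:
            continue
        c_n = len(sc.targets) / n_p if n_p else 0.0
        target_pats = targets.enumerate(n)
        w_n = 1.0
        for m in sorted(sc.assembled, key=sorted):
            if m in target_maps:
                continue  # a target is 1-congruent to itself
            y = map_to_pattern(m, origin=targets.size_origin)
            if y is None:
                continue  # nothing measurable has grown yet
            if not target_pats:
                w_n = 0.0
                break
            w_n = min(w_n, best_congruence(y, target_pats))
            if w_n == 0.0:
                break
        rows.append(
            {
                "size": n,
                "coverage": c_n,
                "worst_congruence": w_n,
                "n_targets": n_p,
                "n_assembled": len(sc.assembled),
            }
        )
        p = min(p, c_n, w_n)
    return p, pd.DataFrame(rows)


# -- impurity and efficiency --------------------------------------------------------


def impurity(part: PartitionReport, targets: TargetSet) -> float:
    """Tightest q with |E_n| <= q |P_n| over the observed sizes.

    Perfect purity (no junk anywhere) is reported as q = 0 ("any q > 0
    will do"); junk at a size with no targets at all yields the infinity
    sentinel.
    """
    q = 0.0
    for n in part.sizes:
        sc = part.by_size[n]
        e_n = len(sc.erroneous)
        if e_n == 0:
            continue
        p_n = len(targets.label_maps(n))
        if p_n == 0:
            return INF
        q = max(q, e_n / p_n)
    return q


def efficiency(p: float, q: float) -> float:
    """E = p/q, with the infinity sentinel for perfect purity and 0 for a
    strengthless assembler."""
    if p <= 0:
        return 0.0
    if q == 0:
        return INF
    return p / q


@dataclass(frozen=True)
class ProbabilityBounds:
    """Probability bounds implied by (p, q, K) for a monotonic assembler:
    targets with probability >= K·E/(1+E), promising >= E/(1+E),
    nontarget <= (1+(1-K)E)/(1+E), erroneous <= 1/(1+E)."""

    target_lb: float
    promising_lb: float
    nontarget_ub: float
    erroneous_ub: float


def probability_bounds(p: float, q: float, K: float) -> ProbabilityBounds:
    if not 0 < p <= 1:
        return ProbabilityBounds(0.0, 0.0, 1.0, 1.0)
    if not 0 < K <= 1:
        raise ValueError("K must be in (0, 1]")
    s = p + q
    return ProbabilityBounds(
        target_lb=K * p / s,
        promising_lb=p / s,
        nontarget_ub=((1 - K) * p + q) / s,
        erroneous_ub=q / s,
    )


# -- rate sequences and the trichotomy ----------------------------------------------


@dataclass
class RateSequences:
    """Per-size class rates: rho_n = |A'_n|/|A_n|, nu_n = |E_n|/|A_n|,
    p_n = |A_n ∩ P_n|/|A_n|, plus the raw counts."""

    sizes: List[int]
    rho: List[float]
    nu: List[float]
    p_n: List[float]
    count_A: List[int]
    count_promising: List[int]

    @classmethod
    def from_partition(cls, part: PartitionReport) -> "RateSequences":
        sizes, rho, nu, p_n, cA, cP = [], [], [], [], [], []
        for n in part.sizes:
            sc = part.by_size[n]
            a = len(sc.assembled)
            if a == 0:
                continue
            sizes.append(n)
            rho.append(len(sc.promising) / a)
            nu.append(len(sc.erroneous) / a)
            p_n.append(len(sc.targets) / a)
            cA.append(a)
            cP.append(len(sc.promising))
        return cls(sizes, rho, nu, p_n, cA, cP)


def classify_rate_regime(
    seq: RateSequences,
    tol: float = 0.05,
    growth_rate: float = 1.1,
) -> str:
    """Heuristic trichotomy of the assembler's long-run behavior from a
    finite prefix: the junk rate stabilizes, promising and junk alternate
    in dominance, or the pattern counts grow at least exponentially.

    Diagnostic only — the underlying trichotomy concerns limits, which no
    finite prefix can certify; with fewer than 6 observed sizes the answer
    is always ``inconclusive``.
    """
    k = len(seq.sizes)
    if k < 6:
        return "inconclusive"
    tail = slice(k // 2, None)
    nu_tail = np.array(seq.nu[tail])
    if nu_tail.max() - nu_tail.min() < tol:
        return "stabilizes"
    diff = np.array(seq.rho[tail]) - np.array(seq.nu[tail])
    signs = np.sign(diff[np.abs(diff) > 1e-12])
    if signs.size >= 2 and int(np.sum(signs[1:] != signs[:-1])) >= 2:
        return "alternates"
    for counts in (seq.count_A, seq.count_promising):
        c = np.array(counts, dtype=float)
        if (c > 0).all():
            slope = np.polyfit(seq.sizes, np.log(c), 1)[0]
            r = np.corrcoef(seq.sizes, np.log(c))[0, 1] if c.std() > 0 else 0.0
            if slope >= math.log(growth_rate) and r > 0.9:
                return "exponential"
    return "inconclusive"


# -- full report --------------------------------------------------------------------


@dataclass
class MetricsReport:
    system_name: str
    notion: str
    n_max: int
    strength: float
    impurity: float
    efficiency: float
    K: Optional[float]
    bounds: Optional[ProbabilityBounds]
    classification: str
    per_size: pd.DataFrame
    partition: PartitionReport = field(repr=False)
    truncated: bool = False

    def to_dict(self) -> dict:
        def num(x):
            if x is None:
                return None
            return "inf" if x == INF else float(x)

        return {
            "system": self.system_name,
            "size_notion": self.notion,
            "n_max": self.n_max,
            "strength_p": num(self.strength),
            "impurity_q": num(self.impurity),
            "efficiency_E": num(self.efficiency),
            "min_attachment_probability_K": num(self.K),
            "probability_bounds": None
            if self.bounds is None
            else {
                "target_lb": num(self.bounds.target_lb),
                "promising_lb": num(self.bounds.promising_lb),
                "nontarget_ub": num(self.bounds.nontarget_ub),
                "erroneous_ub": num(self.bounds.erroneous_ub),
            },
            "trichotomy": self.classification,
            "truncated": self.truncated,
            "per_size": self.per_size.to_dict(orient="records"),
        }


def analyze(
    sys: TileSystem,
    targets: TargetSet,
    n_max: int,
    cap: int = 200_000,
    horizon: Optional[int] = None,
    compute_K: bool = True,
) -> MetricsReport:
    """End-to-end analysis: enumerate, partition, and compute all metrics."""
    from .atam import enumerate_assemblies

    enum = enumerate_assemblies(sys, notion=targets.notion, n_max=n_max, cap=cap)
    part = classify(enum, targets, sys, horizon=horizon)
    p, diag = strength(enum, targets, part)
    q = impurity(part, targets)
    E = efficiency(p, q)
    K = None
    bounds = None
    if compute_K and not enum.truncated:
        K = min_attachment_probability(sys, enum)
        if p > 0:
            bounds = probability_bounds(p, q, K)
    seq = RateSequences.from_partition(part)
    counts = part.counts()
    per_size = counts.merge(diag, on="size", how="outer") if len(diag) else counts
    per_size["rho"] = [
        len(part.by_size[n].promising) / max(len(part.by_size[n].assembled), 1)
        for n in part.sizes
    ]
    per_size["nu"] = [
        len(part.by_size[n].erroneous) / max(len(part.by_size[n].assembled), 1)
        for n in part.sizes
    ]
    return MetricsReport(
        system_name=sys.name,
        notion=targets.notion,
        n_max=n_max,
        strength=p,
        impurity=q,
        efficiency=E,
        K=K,
        bounds=bounds,
        classification=classify_rate_regime(seq),
        per_size=per_size,
        partition=part,
        truncated=enum.truncated,
    )


def sampled_worst_congruence(
    sys: TileSystem,
    targets: TargetSet,
    n_samples: int,
    rng_seed: int,
    n_max: int,
    max_steps: int = 200,
    greedy_refine: bool = True,
) -> Dict[int, float]:
    """Estimate the per-size worst best-congruence w_n by sampling.

    For systems whose reachable set explodes (noncooperative runaway
    growth), exhaustive minimization over A_n is infeasible; this samples
    trajectories, scores the first pattern reaching each size against all
    same-size targets, and keeps the minimum.  With ``greedy_refine``, the
    current worst assembly at each size is additionally extended by the
    single attachment minimizing congruence at the next size — a cheap
    adversarial descent that tightens the estimate (still an upper bound
    on the true w_n).
    """
    rng = np.random.default_rng(rng_seed)
    worst: Dict[int, float] = {}
    argmin: Dict[int, Assembly] = {}

    def score(asm: Assembly, n: int):
        pat = map_to_pattern(assembly_label_map(asm, sys), origin=targets.size_origin)
        if pat is None:
            return
        b = best_congruence(pat, targets.enumerate(n))
        if b < worst.get(n, 2.0):
            worst[n] = b
            argmin[n] = asm

    for _ in range(n_samples):
        asm = sys.initial_assembly()
        seen_sizes = set()
        for _ in range(max_steps):
            events = eligible_attachments(asm, sys)
            if not events:
                break
            w = np.array([t.conc for _, t, _ in events])
            idx = int(rng.choice(len(events), p=w / w.sum()))
            asm = attach(asm, events[idx][0], events[idx][1], sys)
            n = asm.size(sys, targets.notion)
            if n > n_max:
                break
            if n not in seen_sizes:
                seen_sizes.add(n)
                score(asm, n)
    if greedy_refine:
        for n in sorted(worst):
            base = argmin.get(n)
            if base is None:
                continue
            for site, tile, _ in eligible_attachments(base, sys):
                child = attach(base, site, tile, sys)
                m = child.size(sys, targets.notion)
                if n < m <= n_max:
                    score(child, m)
    return dict(sorted(worst.items()))


# -- empirical audit of the probability bounds --------------------------------------


def sample_class_frequencies(
    sys: TileSystem,
    targets: TargetSet,
    n_samples: int,
    rng_seed: int,
    n_max: int,
    max_steps: int = 10_000,
) -> pd.DataFrame:
    """Empirical per-size class frequencies from sampled trajectories.

    Each trajectory records, for every size n <= n_max it passes through,
    the first pattern reaching that size; the pattern is classified and
    the per-size frequencies of target / promising / erroneous returned.
    """
    rng = np.random.default_rng(rng_seed)
    tallies: Dict[int, Dict[str, int]] = {}
    for _ in range(n_samples):
        asm = sys.initial_assembly()
        seen_sizes = set()

        def record(a: Assembly):
            n = a.size(sys, targets.notion)
            if n in seen_sizes or n > n_max:
                return
            seen_sizes.add(n)
            m = assembly_label_map(a, sys)
            if targets.membership(m, n):
                cls = "target"
            elif targets.promising(m):
                cls = "promising"
            else:
                cls = "erroneous"
            t = tallies.setdefault(n, {"target": 0, "promising": 0, "erroneous": 0})
            t[cls] += 1

        record(asm)
        for _ in range(max_steps):
            events = eligible_attachments(asm, sys)
            if not events:
                break
            w = np.array([t.conc for _, t, _ in events])
            idx = int(rng.choice(len(events), p=w / w.sum()))
            site, tile, _ = events[idx]
            asm = attach(asm, site, tile, sys)
            if asm.size(sys, targets.notion) > n_max:
                break
            record(asm)
    rows = []
    for n in sorted(tallies):
        t = tallies[n]
        total = sum(t.values())
        rows.append(
            {
                "size": n,
                "n_obs": total,
                "freq_target": t["target"] / total,
                "freq_promising": (t["target"] + t["promising"]) / total,
                "freq_erroneous": t["erroneous"] / total,
            }
        )
    return pd.DataFrame(rows)


def check_probability_bounds(
    freqs: pd.DataFrame,
    bounds: ProbabilityBounds,
) -> pd.DataFrame:
    """Compare empirical class frequencies against the probability bounds.

    A violation beyond 3 binomial standard errors indicates an
    implementation bug (the bounds are proved for every monotonic
    assembler), so the returned frame flags any such size.
    """
    out = freqs.copy()

    def se(p_emp, n):
        return np.sqrt(np.maximum(p_emp * (1 - p_emp), 1e-12) / n)

    n = out["n_obs"]
    out["target_bound"] = bounds.target_lb
    out["promising_bound"] = bounds.promising_lb
    out["erroneous_bound"] = bounds.erroneous_ub
    out["target_ok"] = (
        out["freq_target"] + 3 * se(out["freq_target"], n) >= bounds.target_lb
    )
    out["promising_ok"] = (
        out["freq_promising"] + 3 * se(out["freq_promising"], n)
        >= bounds.promising_lb
    )
    out["erroneous_ok"] = (
        out["freq_erroneous"] - 3 * se(out["freq_erroneous"], n)
        <= bounds.erroneous_ub
    )
    out["all_ok"] = out["target_ok"] & out["promising_ok"] & out["erroneous_ok"]
    return out
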