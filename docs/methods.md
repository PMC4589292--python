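# Methods

## Assembly model

`tileassay` implements seeded, monotonic tile assembly on the square
lattice ℤ². A tile type carries four glue labels (N, E, S, W); a symmetric
glue function g assigns nonnegative integer strengths to label pairs
(diagonal by default: a glue binds only its own label; arbitrary symmetric
tables are accepted through the JSON dialect). A tile may attach at an
empty site iff the **sum** of glue strengths against its already-placed
neighbors reaches the temperature τ — the standard cooperative reading, so
at τ=2 either one strength-2 bond or two strength-1 bonds suffice. Tiles
never detach; along any assembly sequence the domain only grows, which is
the monotonicity assumption behind the probability bounds below. Negative
glues, detachment, kinetic (rate-based) models and unseeded two-handed
aggregation are out of scope.

Assemblies are identified by their exact placement maps: the seed fixes
the coordinate frame, so no translation quotient is applied during
enumeration. Translation equivalence enters only when assemblies are
converted to canonical patterns for congruence scoring. For metric
counting, assemblies that display the same labels at the same coordinates
are counted once (pattern-level counting); the per-size junk counts of the
AND-gadget, which match the analytic expectation exactly (7/13/19 junk
patterns at the pre-cooperation stage for L=6/8/10, an exactly affine
trend), confirm this convention.

## Patterns, sizes, congruence

Patterns are finite nonempty labeled cell sets, canonicalized by
translating the bounding box to the first quadrant. Four size notions are
supported: `area` (cell count), `manhattan_radius` (maximum |Δrow|+|Δcol|
from a designated origin), `height`, `width`. The counter and AND-gadget
analyses layer patterns by Manhattan radius; CA space-times by height.

Congruence-modulo-p is computed exhaustively: every translation for which
the supports overlap in at least one cell is scored by the number of
coordinates where both patterns are occupied with equal labels. The
normalizer is the cell count (for equal-size patterns under the area
notion, their common size; with `relax=True`, the larger of the two cell
counts). The common matching cell set is the subpattern witness and is
**not** required to be connected — congruence is the normalized maximum
cell overlap, which is what makes a 4-tile error assembly sharing its
first red and green tiles with a target exactly 1/2-congruent. A
4-connected variant (`congruence_connected`) is available for users who
want contiguous witnesses; it can only lower the fraction. Ties among
maximizing shifts resolve to the lexicographically smallest
(Δrow, Δcol), making all reported shifts deterministic.

## Enumeration, sampling, K

`enumerate_assemblies` is a breadth-first closure of single attachments
from the seed with exact-placement deduplication. All four size notions
are nondecreasing under monotone growth, so branches whose size exceeds
`n_max` are pruned soundly. A retention cap (default 2·10⁵ states) guards
against runaway systems; hitting it flags the result truncated (per-size
sets become lower bounds) instead of raising.

The stochastic model: from any non-terminal assembly, one eligible
(site, tile) event is drawn with probability proportional to the attaching
tile's concentration (uniform when concentrations are equal). This is the
simplest event model consistent with concentration-programmed tile
systems; the minimum attachment probability K is defined under the same
model, as the smallest single-event probability over every enumerated
reachable state, so the probability bounds and the sampler are mutually
coherent. K is refused on truncated enumerations (it would be unsound).
An alternative two-stage model (choose a site uniformly, then a tile by
concentration) would change K for systems where eligible-event counts
vary across sites; the single-draw model is used throughout.

## Target sets and the partition

A target set exposes three views: per-size target patterns as
absolute-frame label maps (for exact set operations against assemblies),
the same patterns canonicalized (for congruence), and a promising oracle.
Because labels are immutable under monotone growth, "can this assembly
still become a target" is decidable from the current label map for every
shipped system (a map that is not a sub-map of any target can never become
one); a horizon-bounded forward search (default horizon 2·n_max, with
undecided states conservatively counted as promising and flagged) is the
fallback for user-supplied target sets without an oracle.

Strength is p = minₙ min(cₙ, wₙ) with cₙ the fraction of size-n targets
assembled and wₙ the worst best-congruence of any assembled size-n
pattern; impurity is q = maxₙ |Eₙ|/|Pₙ| (0 when no junk exists — "any
q > 0 will do" — and an ∞ sentinel when junk appears at a size with no
targets); efficiency E = p/q with E = ∞ for q = 0, p > 0. All reported
values are evidence-bounded by n_max and say nothing asymptotic; growth
claims (junk linear in frame size) are checked as trends across several
frame sizes, never as single numbers.

The trichotomy classifier (junk rate stabilizes / alternates /
exponential growth) is a diagnostic heuristic on a finite prefix —
tail variation below 0.05 for "stabilizes", two or more dominance
switches for "alternates", log-count regression slope ≥ log 1.1 with
r > 0.9 for "exponential", otherwise "inconclusive" (always, below six
observed sizes). Limits cannot be certified from finite data.

## The example systems

**Binary counter.** Seed row encodes zero in n bits (most significant bit
at column 0); each row increments the previous one, carries propagating
from the least significant column. The least-significant column uses
row-indexed strength-2 glues, so each new row starts unconditionally and
the column has no successor tile at the all-ones row: the system halts
after 2ⁿ rows and is directed (unique terminal assembly). Interior and
most-significant columns use generic bit/carry glues of strength 1. The
target oracle is arithmetic, independent of the tile dynamics: correct
partial counting patterns are a full seed row plus row suffixes (each cell
needing its south and east neighbors) whose cells carry the bits of their
row index. At τ=2 the enumerated patterns coincide with this oracle
exactly (strength 1, zero junk). At τ=1 the same tiles attach off single
glue matches in any direction; the reachable set explodes combinatorially
(measured: over 7·10⁵ distinct assemblies within Manhattan radius 3), so
noncooperative degradation is assessed on sampled evidence — per-size
class frequencies from sampled trajectories, and a sampled worst
best-congruence sharpened by a one-step greedy adversarial extension of
the current worst assembly. Both are upper bounds on the true worst-case;
their monotone degradation (erroneous fraction 0 → 1, worst congruence
0.75 → 0.30 over five sizes at 400 samples) is the qualitative content of
"efficiency 0", not an exact wₙ.

**RGB AND-gadget.** An L×L seed frame (L even, ≥ 6) abstracts a finite
reaction vessel; the frame is treated as context, so pattern size and
congruence are computed over grown cells only, with radius measured from
the frame origin. A red signal grows east from the west-edge input along
the middle row, a green signal north from the south-edge input along the
middle column, toward the cooperation point C at (L/2, L/2). The first
tile of each signal is forced (the input glue is distinct from the
propagation glue); at every later site the plain signal tile and a
terminator (D/E) are both eligible — the model's nondeterminism. Only a
terminator directly adjacent to C presents the strength-1 glue the
cooperation tile O needs, and at τ=2 O requires both inputs; O then seeds
a hard-coded blue path to the east-edge output. Signal positions are
hard-coded in the glues (like the blue path), so signals cannot overrun C.
Targets are the successful AND assembly and all partial assemblies on its
pathway. Consequences, all computed, none assumed: strength exactly 1/2
(the earliest terminal error shares 2 of its 4 tiles with its best
same-size target); junk at the pre-cooperation stage exactly 3L−11;
|E|/|P| → 3. At τ=1, O misbinds next to any terminator, phantom blue
signals grow, and green backfills beneath misbound O tiles: strength drops
to 1/3 and impurity to ~140 at L=8. The τ=1 gadget remains exhaustively
enumerable because the positional glues confine all growth to the frame.

**ECA compiler.** Any elementary CA rule (0–255) plus a concrete seed row
compiles to a τ=2 system whose tiling reproduces the rule's space-time
with fixed inactive boundaries, one tile per CA cell. Rows assemble in
zig-zag order (odd rows left-to-right off S+W inputs, even rows
right-to-left off S+E), because a site's three parents cannot all be
lattice-adjacent: the glue payloads carry the two-cell windows
(neighbor values and the already-computed own-row neighbor) that make
every attachment uniquely determined. Two wall columns with strength-2
vertical glues present the constant inactive boundary to row starts; they
grow unboundedly, so "the terminal tiling" is realized as the unique
bounded tiling under a row cap. The construction is validated against the
direct simulator cell-for-cell (rules 0, 90, 122, 204; widths to 16,
8 steps) — that equivalence, not any structural resemblance, is what the
compiler is accountable to.

**DKCA compiler.** The Domany-Kinzel CA activates a site with probability
p1 when exactly one of its two outer parents is active, p2 when both are,
never when neither is. `dkca_run` simulates it on the square lattice
(parents (t, i−1), (t, i+1), fixed inactive boundaries, all sites updated
each step). The tile encoding instead uses light-cone geometry — seed row
of width w, row t has w−t sites, site (t+1, j) with parents (t, j) and
(t, j+1) — rotated 45° onto the tile grid so each site's two parents are
exactly its S and W neighbors. One tile per (parent context, output) with
strength-1 input glues (cooperative τ=2 binding enforces synchronization)
and concentrations p/(1−p) within each context class, which makes the
class-conditional attachment probabilities equal (p1, p2, 0) regardless of
how many sites are open. Tiles whose probability would be 0 (spontaneous
generation; p=0 or 1 exactly) are simply not generated. An optional depth
bound indexes glues by time step, hard-capping growth for exhaustive
study. The correspondence check enumerates both sides independently —
τ=2 tilings by the assembly engine, reachable space-times by direct
combinatorial closure of the transition rules — and finds them identical
(260 terminal tilings = 260 reachable space-times at width 5, depth 3),
with strength 1 and zero junk. In light-cone geometry every partial
tiling spans the full grid height (the seed diagonal does), so the
per-size layering is flat there; the equivalence and metrics are read at
that single size.

## Percolation and the simulation experiment

A space-time percolates when a cluster of active sites touches both the
seed row and the last row. Connectivity follows the generation dependency
(a site linked to its active parents: the two outer parents for DKCA, the
three-cell neighborhood for ECA), the standard directed-percolation
reading, computed by row-wise boolean propagation with a backtracked
witness path; an undirected 8-neighborhood variant is available behind a
flag. Boundaries are fixed inactive, not periodic (matching the bounded
tiling encodings).

The effective (p1, p2) of an ECA without spontaneous generation (contexts
000 and 010 both map to 0) is estimated by pooling, over runs from i.i.d.
Bernoulli(1/2) seed rows, the activation frequency of children in each
outer-parent class — three-parent ECA contexts are classified by their
two outer parents only, since the matched DKCA has no center dependence.
The simulation-strength experiment then runs one DKCA(p̂1, p̂2) space-time
from each ECA run's seed row and reports the fraction of pairs agreeing
on the percolation property, with a binomial standard error, against the
0.9 / 0.94 thresholds. Defaults are 100 runs at width 300 (steps = width);
the test suite uses 50 runs at width 100, a scale at which the agreement
estimate for rule 122 is already far from the thresholds. The phase sweep
estimates percolation probability over a (p1, p2) grid, by default under a
shared-uniform-field coupling that makes the estimated map exactly
monotone in both parameters and maximally comparable across grid points.

## What the examples do and do not emulate

The zoo systems are idealized: perfect glue specificity, no lattice
defects, no detachment, dimensionless integer strengths, and
nondeterminism only where the constructions put it (terminator placement,
probabilistic tile choice, random CA seeds). Passing their checks
validates the metrics and the compilers, and reproduces the qualitative
cooperative-vs-noncooperative story; it says nothing about kinetic error
rates, melting, or real DNA-tile thermodynamics, which the model does not
represent. The glue-level details of the canonical gadgets are design choices of
this package, and their constructions are accountable to their
quantitative signatures (strength 1/2, 2-of-4 congruent tiles, linear
junk growth, q → 3), which the tests compute.

## Problem sizes used by the shipped checks

Counter: 3 bits, radius ≤ 6 exhaustive (35 patterns); τ=1 evidence from
400 sampled trajectories. AND-gadget: L ∈ {6, 8, 10} exhaustive to the
full pathway radius (≤ 13). DKCA correspondence: width 5, depth 3
(1370 tilings). Percolation experiment: 100×300 in the acceptance script,
50×100 in tests. Probability-bound audit: 1000 sampled trajectories per
system. These sizes were chosen so every exhaustive claim is genuinely
exhaustive and every stochastic claim has its standard error reported.
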