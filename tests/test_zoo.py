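"""The example systems and their target-set oracles."""

import itertools

import numpy as np
import pytest

import tileassay as ta
from tileassay.atam import eligible_attachments
from tileassay.zoo import (
    RGBGeometry,
    assembly_label_map,
    lightcone_to_grid,
    run_bounded,
    tiling_to_spacetime,
)


# -- binary counter -----------------------------------------------------------------


@pytest.mark.parametrize("n_bits", [1, 2, 3])
def test_counter_rows_encode_integers(n_bits):
    """The unique terminal assembly has 2^n rows, the k-th encoding k in
    binary — checked against plain integer formatting."""
    system, _ = ta.binary_counter(n_bits, tau=2)
    asm = ta.sample_assembly(system, 0, max_steps=1000)  # directed: seed-free
    assert eligible_attachments(asm, system) == []
    rows = sorted({r for r, _ in asm.placements})
    assert rows == list(range(2**n_bits))
    for k in rows:
        word = "".join(
            asm.placements[(k, c)].label for c in range(n_bits)
        )
        assert word == format(k, f"0{n_bits}b")


def test_counter_target_oracle_agrees_with_enumeration(counter2):
    """Exhaustion cross-check: the arithmetic staircase oracle and the
    tile dynamics generate identical per-size pattern sets."""
    system, targets = counter2
    enum = ta.enumerate_assemblies(system, notion="manhattan_radius", n_max=6)
    for n in enum.sizes:
        got = {assembly_label_map(a, system) for a in enum.by_size[n]}
        assert got == targets.label_maps(n)


def test_counter_membership_consistent_with_enumerate(counter2):
    _, targets = counter2
    for n in range(2, 7):
        for m in targets.label_maps(n):
            assert targets.membership(m, n)
            assert targets.promising(m)
    wrong = frozenset({((0, 0), "1"), ((0, 1), "0"), ((0, 2), "0")})
    assert not targets.membership(wrong, 2)


def test_counter_targets_layered(counter2):
    """Every target of size n properly extends a target of size n-1 or n
    (layered partition of the pattern space)."""
    _, targets = counter2
    for n in range(3, 7):
        smaller = targets.label_maps(n - 1) | targets.label_maps(n)
        for m in targets.label_maps(n):
            cells = set(m)
            assert any(
                set(other) < cells or set(other) == cells for other in smaller
            )


def test_counter_rejects_bad_params():
    with pytest.raises(ValueError):
        ta.binary_counter(0)
    with pytest.raises(ValueError):
        ta.binary_counter(3, tau=3)


# -- RGB gadget ---------------------------------------------------------------------


def test_rgb_least_congruent_shares_two_of_four(rgb8):
    """The earliest-terminating error assembly places 4 tiles of which
    exactly 2 (the first R and the first G) match its best same-size
    target."""
    system, targets = rgb8
    geo = RGBGeometry(8)
    enum = ta.enumerate_assemblies(system, notion="manhattan_radius", n_max=7)
    # both signals terminate immediately after their forced first tile
    want = frozenset(
        {
            (geo.red_site(1), "R"),
            (geo.red_site(2), "D"),
            (geo.green_site(1), "G"),
            (geo.green_site(2), "E"),
        }
    )
    n = 6
    maps = {assembly_label_map(a, system) for a in enum.by_size[n]}
    assert want in maps
    from tileassay.metrics import best_congruence
    from tileassay.zoo import map_to_pattern

    y = map_to_pattern(want)
    scores = [
        ta.congruence(x, y, notion="area", relax=True)
        for x in targets.enumerate(n)
    ]
    best = max(scores, key=lambda r: r.fraction)
    assert best.matched_cells == 2
    assert best.size_used == 4
    assert best.fraction == 0.5


def test_rgb_error_count_linear_in_L():
    counts = {}
    for L in (6, 8, 10):
        system, targets = ta.rgb_system(L, tau=2)
        rep = ta.analyze(system, targets, n_max=targets.max_size, compute_K=False)
        n_pre = ta.rgb_pre_cooperation_size(L)
        sc = rep.partition.by_size[n_pre]
        counts[L] = len(sc.erroneous)
    xs = np.array(sorted(counts))
    ys = np.array([counts[L] for L in xs])
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1 - (resid**2).sum() / ss_tot
    assert slope > 0
    assert r2 > 0.99


def test_rgb_tau1_phantom_cooperation():
    """At tau=1 the cooperation tile misbinds off a lone terminator and
    spawns phantom blue/green signals — erroneous patterns the cooperative
    system never makes."""
    system1, targets = ta.rgb_system(8, tau=1)
    enum = ta.enumerate_assemblies(system1, notion="manhattan_radius", n_max=10)
    geo = RGBGeometry(8)
    phantom_o = [
        m
        for m in {
            assembly_label_map(a, system1)
            for v in enum.by_size.values()
            for a in v
        }
        if any(label == "O" and coord != geo.C for coord, label in m)
    ]
    assert phantom_o, "expected misbound cooperation tiles at tau=1"
    assert all(not targets.promising(m) for m in phantom_o)
    # cooperative system never produces them
    system2, _ = ta.rgb_system(8, tau=2)
    enum2 = ta.enumerate_assemblies(system2, notion="manhattan_radius", n_max=10)
    maps2 = {
        assembly_label_map(a, system2) for v in enum2.by_size.values() for a in v
    }
    assert all(m not in maps2 for m in phantom_o)


def test_rgb_rejects_bad_params():
    with pytest.raises(ValueError):
        ta.rgb_system(4)
    with pytest.raises(ValueError):
        ta.rgb_system(7)


# -- ECA tilesets -------------------------------------------------------------------


@pytest.mark.parametrize("rule", [0, 90, 122, 204])
def test_eca_tiling_reproduces_simulator(rule):
    rng = np.random.default_rng(rule + 1)
    for width, steps in ((11, 5), (16, 8)):
        seed = rng.integers(0, 2, width)
        system, _ = ta.eca_tileset(rule, seed)
        asm = run_bounded(system, steps)
        got = tiling_to_spacetime(asm, system, width)
        want = ta.eca_run(rule, seed, steps).grid
        assert got.shape == want.shape
        assert (got == want).all()


def test_eca_rule0_and_identity_tilings():
    seed = [1, 0, 1, 1, 0]
    for rule, expect_row in ((0, [0, 0, 0, 0, 0]), (204, seed)):
        system, _ = ta.eca_tileset(rule, seed)
        asm = run_bounded(system, 3)
        grid = tiling_to_spacetime(asm, system, 5)
        for t in range(1, 4):
            assert list(grid[t]) == expect_row


def test_eca_tiling_locally_deterministic():
    """At every growth step each eligible site admits exactly one tile."""
    system, _ = ta.eca_tileset(122, [1, 0, 1, 1, 0])
    asm = system.initial_assembly()
    from tileassay.atam import attach

    for _ in range(20):
        events = [e for e in eligible_attachments(asm, system) if e[0][0] <= 3]
        if not events:
            break
        sites = [s for s, _, _ in events]
        assert len(sites) == len(set(sites)), "a site admitted two tile types"
        asm = attach(asm, *events[0][:2], system)


def test_eca_targets_accept_partial_tilings():
    system, targets = ta.eca_tileset(90, [0, 1, 0])
    asm = run_bounded(system, 2)
    m = assembly_label_map(asm, system)
    assert targets.membership(m)
    bad = frozenset(set(m) ^ {((1, 2), "0"), ((1, 2), "1")})  # flip one cell
    assert not targets.membership(bad)


def test_eca_tileset_rejects_bad_input():
    with pytest.raises(ValueError):
        ta.eca_tileset(256, [1, 0, 1])
    with pytest.raises(ValueError):
        ta.eca_tileset(90, [1, 2, 0])


# -- DKCA tilesets ------------------------------------------------------------------


def test_dkca_degenerate_probabilities():
    seed = [1, 0, 1, 1]
    # p1 = p2 = 0: only the all-inactive continuation is reachable
    reach0 = ta.dkca_reachable_lightcone(0, 0, seed)
    assert len(reach0) == 1
    st = next(iter(reach0))
    assert all(all(v == 0 for v in row) for row in st[1:])
    # p1 = p2 = 1: the unique OR-rule space-time
    reach1 = ta.dkca_reachable_lightcone(1, 1, seed)
    assert len(reach1) == 1
    st = next(iter(reach1))
    for t in range(1, len(st)):
        for j, v in enumerate(st[t]):
            assert v == (st[t - 1][j] | st[t - 1][j + 1])


def test_dkca_tileset_equals_reachable_set(dkca_small):
    """Exhaustive two-sided check: terminal tilings of the compiled tile
    system coincide with the combinatorial DKCA-reachable set."""
    system, _ = dkca_small
    seed = [1, 0, 1, 1, 0]
    enum = ta.enumerate_assemblies(system, notion="height", n_max=10)
    assert not enum.truncated
    terminals = [a for v in enum.terminal.values() for a in v]

    def rows_of(asm):
        return tuple(
            tuple(
                int(asm.placements[lightcone_to_grid(t, j, 5)].label)
                for j in range(5 - t)
            )
            for t in range(4)
        )

    got = {rows_of(a) for a in terminals}
    want = ta.dkca_reachable_lightcone(0.7, 0.8, seed, max_depth=3)
    assert got == want


def test_dkca_no_spontaneous_generation_in_tilings(dkca_small):
    system, _ = dkca_small
    enum = ta.enumerate_assemblies(system, notion="height", n_max=10)
    for v in enum.by_size.values():
        for asm in v:
            for (coord, tile) in asm.placements.items():
                if tile.name.startswith("T00>"):
                    assert tile.label == "0"


def test_dkca_concentration_recovery():
    """Class-conditional attachment frequencies in sampled tilings match
    (p1, p2) within 3 standard errors."""
    p1, p2 = 0.7, 0.8
    seed = [1, 1, 0, 1, 1, 0, 1, 1]
    system, _ = ta.dkca_tileset(p1, p2, seed)
    n = np.zeros(3)
    k = np.zeros(3)
    rng = np.random.default_rng(42)
    for _ in range(400):
        asm = ta.sample_assembly(system, rng, max_steps=100)
        w = len(seed)
        for t in range(1, w):
            for j in range(w - t):
                site = lightcone_to_grid(t, j, w)
                if site not in asm.placements:
                    continue
                pa = int(asm.placements[lightcone_to_grid(t - 1, j, w)].label)
                pb = int(asm.placements[lightcone_to_grid(t - 1, j + 1, w)].label)
                c = pa + pb
                n[c] += 1
                k[c] += int(asm.placements[site].label)
    assert k[0] == 0  # no spontaneous generation ever
    for c, p in ((1, p1), (2, p2)):
        p_hat = k[c] / n[c]
        se = np.sqrt(p * (1 - p) / n[c])
        assert abs(p_hat - p) <= 3 * se


def test_dkca_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        ta.dkca_tileset(1.5, 0.5, [1, 0, 1])


def test_zoo_oracles_enumerate_membership_agree(counter2, rgb8):
    """Each oracle's enumerate/membership views agree on small sizes."""
    for _, targets in (counter2, rgb8):
        for n in range(0, 7):
            for m in targets.label_maps(n):
                assert targets.membership(m, n)
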