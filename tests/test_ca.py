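"""ECA/DKCA simulators, percolation, rate estimation, experiments."""

import numpy as np
import pytest

import tileassay as ta
from tileassay.ca import (
    DKCAParams,
    SpaceTime,
    count_transitions,
    dkca_run,
    eca_run,
    estimate_rates,
    has_spontaneous_generation,
    percolates,
    phase_sweep,
    simulation_strength_experiment,
)


# -- eca_run ------------------------------------------------------------------------


def test_eca_rule0_all_dead():
    st = eca_run(0, [1, 1, 1, 0, 1], 4)
    assert st.grid[1:].sum() == 0


def test_eca_identity_rule_repeats_seed():
    seed = [1, 0, 1, 1, 0]
    st = eca_run(204, seed, 4)
    assert (st.grid == np.array(seed)).all()


def lookup_oracle(rule, seed, steps):
    """Independent cell-by-cell table application (no vectorization)."""
    table = {
        (a, b, c): (rule >> (4 * a + 2 * b + c)) & 1
        for a in (0, 1) for b in (0, 1) for c in (0, 1)
    }
    rows = [list(seed)]
    w = len(seed)
    for _ in range(steps):
        prev = rows[-1]
        get = lambda i: prev[i] if 0 <= i < w else 0
        rows.append([table[(get(i - 1), get(i), get(i + 1))] for i in range(w)])
    return np.array(rows)


def test_eca_rule122_matches_lookup_oracle():
    seed = [0] * 5 + [1] + [0] * 5  # single centered 1, width 11
    st = eca_run(122, seed, 5)
    assert (st.grid == lookup_oracle(122, seed, 5)).all()


def test_eca_input_validation():
    with pytest.raises(ValueError):
        eca_run(300, [1, 0, 1], 2)
    with pytest.raises(ValueError):
        eca_run(90, [1], 2)


def test_spontaneous_generation_flag():
    assert not has_spontaneous_generation(122)
    assert has_spontaneous_generation(1)  # 000 -> 1


# -- dkca_run -----------------------------------------------------------------------


def test_dkca_no_spontaneous_generation():
    st = dkca_run(DKCAParams(0.9, 0.9), [0] * 8, 10, rng=1)
    assert st.grid.sum() == 0


def test_dkca_or_rule_deterministic():
    seed = [0, 1, 0, 0, 1, 0]
    grids = [
        dkca_run(DKCAParams(1, 1), seed, 5, rng=s).grid for s in (1, 2, 3)
    ]
    assert all((g == grids[0]).all() for g in grids)
    # p1=p2=1 is the outer-neighbor OR rule
    for t in range(5):
        padded = np.pad(grids[0][t], 1)
        assert (grids[0][t + 1] == (padded[:-2] | padded[2:])).all()


def test_dkca_activation_frequency_binomial():
    """One-active-parent contexts activate at p1 = 0.5 within 3 SE over
    >= 10^4 rule applications."""
    rng = np.random.default_rng(8)
    n = k = 0
    for _ in range(120):
        seed = (rng.random(60) < 0.5).astype(int)
        g = dkca_run(DKCAParams(0.5, 0.5), seed, 30, rng).grid
        for t in range(g.shape[0] - 1):
            padded = np.pad(g[t], 1)
            cls = padded[:-2] + padded[2:]
            mask = cls == 1
            n += mask.sum()
            k += g[t + 1][mask].sum()
    assert n >= 10_000
    se = np.sqrt(0.25 / n)
    assert abs(k / n - 0.5) <= 3 * se


def test_dkca_every_active_cell_has_active_parent():
    rng = np.random.default_rng(3)
    for _ in range(5):
        seed = (rng.random(40) < 0.5).astype(int)
        g = dkca_run(DKCAParams(0.8, 0.6), seed, 40, rng).grid
        for t in range(g.shape[0] - 1):
            padded = np.pad(g[t], 1)
            support = padded[:-2] | padded[2:]
            assert not (g[t + 1] & ~support).any()


# -- percolation --------------------------------------------------------------------


def test_percolates_trivial_cases():
    assert percolates(SpaceTime(np.ones((5, 5))))[0]
    dead = np.zeros((5, 5), dtype=int)
    dead[0] = 1
    assert not percolates(SpaceTime(dead))[0]


def test_percolates_zigzag_and_broken_path():
    g = np.zeros((6, 6), dtype=int)
    cols = [0, 1, 2, 3, 4, 5]  # diagonal chain: each child from parent i-1
    for t, c in enumerate(cols):
        g[t, c] = 1
    ok, path = percolates(SpaceTime(g))
    assert ok
    assert path[0][0] == 0 and path[-1][0] == 5
    assert all(g[t, c] for t, c in path)
    g[3, 3] = 0  # remove one link
    assert not percolates(SpaceTime(g))[0]


def flood_fill_oracle(grid, use_center):
    """Independent directed flood fill over generation-dependency edges."""
    T, W = grid.shape
    reach = {(0, i) for i in range(W) if grid[0, i]}
    changed = True
    while changed:
        changed = False
        for t in range(1, T):
            for i in range(W):
                if not grid[t, i] or (t, i) in reach:
                    continue
                parents = [i - 1, i + 1] + ([i] if use_center else [])
                if any(
                    0 <= j < W and (t - 1, j) in reach for j in parents
                ):
                    reach.add((t, i))
                    changed = True
    return any(t == T - 1 for t, _ in reach)


@pytest.mark.parametrize("neighborhood", ["outer", "eca"])
def test_percolates_matches_flood_fill_on_random_grids(neighborhood):
    rng = np.random.default_rng(17)
    for _ in range(50):
        g = (rng.random((8, 8)) < 0.55).astype(int)
        st = SpaceTime(g)
        got, path = percolates(st, neighborhood=neighborhood)
        want = flood_fill_oracle(g, use_center=neighborhood == "eca")
        assert got == want
        if got:
            assert all(g[t, c] for t, c in path)


def test_percolates_undirected_variant_is_weaker():
    # a vertical column: each site's outer parents are inactive, so it is
    # not directed-connected, but plain 8-connectivity spans it
    g = np.zeros((4, 5), dtype=int)
    g[:, 2] = 1
    directed, _ = percolates(SpaceTime(g))
    undirected, path = percolates(SpaceTime(g), undirected_8=True)
    assert not directed and undirected
    assert path[0][0] == 0 and path[-1][0] == 3


# -- rate estimation ----------------------------------------------------------------


def test_estimate_rates_parameter_recovery():
    """Feeding DKCA-generated space-times through the transition counter
    recovers (p1, p2) within 3 standard errors."""
    p1, p2 = 0.7, 0.8
    rng = np.random.default_rng(5)
    grids = []
    for _ in range(40):
        seed = (rng.random(80) < 0.5).astype(int)
        grids.append(dkca_run(DKCAParams(p1, p2), seed, 60, rng).grid)
    est = count_transitions(grids)
    assert not est.undefined
    assert abs(est.p1_hat - p1) <= 3 * est.se1
    assert abs(est.p2_hat - p2) <= 3 * est.se2


def test_estimate_rates_consistency_bias_shrinks():
    """Bias of the estimator shrinks as the number of runs grows."""
    p1, p2 = 0.6, 0.9

    def bias(n_runs, seed):
        rng = np.random.default_rng(seed)
        grids = [
            dkca_run(
                DKCAParams(p1, p2), (rng.random(60) < 0.5).astype(int), 40, rng
            ).grid
            for _ in range(n_runs)
        ]
        est = count_transitions(grids)
        return abs(est.p1_hat - p1) + abs(est.p2_hat - p2)

    small = np.mean([bias(2, s) for s in range(8)])
    large = np.mean([bias(40, s) for s in range(8)])
    assert large < small


def test_estimate_rates_or_like_rule_saturates():
    # rule 250: both two-active-parent contexts output 1 -> p2_hat = 1
    est = estimate_rates(250, n_runs=5, width=40, steps=20, rng=1)
    assert est.p2_hat == 1.0


def test_estimate_rates_all_zero_seed_undefined():
    est = count_transitions([np.zeros((10, 10), dtype=int)])
    assert set(est.undefined) == {"class1", "class2"}
    with pytest.raises(ValueError):
        est.params


def test_estimate_rates_rejects_spontaneous_rules():
    with pytest.raises(ValueError):
        estimate_rates(1, n_runs=2, width=20, steps=10, rng=0)


# -- experiment and sweep -----------------------------------------------------------


def test_dkca_self_agreement_with_identical_streams():
    """The matched comparison is exact when both ensembles are the same
    process driven by the same random streams."""
    rng_a = np.random.default_rng(9)
    rng_b = np.random.default_rng(9)
    seeds = [(np.random.default_rng(s).random(50) < 0.5).astype(int) for s in range(10)]
    flags_a = [
        percolates(dkca_run(DKCAParams(0.7, 0.8), s, 50, rng_a))[0] for s in seeds
    ]
    flags_b = [
        percolates(dkca_run(DKCAParams(0.7, 0.8), s, 50, rng_b))[0] for s in seeds
    ]
    assert flags_a == flags_b


def test_simulation_experiment_rule122_scaled():
    rep = simulation_strength_experiment(122, n_runs=30, width=80, rng_seed=11)
    assert rep.rates.p1_hat == 1.0  # every one-active-outer context of rule 122 fires
    assert rep.agreement > 0.9
    assert rep.passed[0.9]


def test_phase_sweep_corners_and_monotonicity():
    df = phase_sweep(
        [0.0, 0.6, 1.0], [0.0, 0.6, 1.0], width=40, steps=40, reps=15, rng_seed=4
    )
    piv = df.pivot(index="p1", columns="p2", values="percolation_prob")
    assert piv.loc[0.0, 0.0] == 0.0
    assert piv.loc[1.0, 1.0] == 1.0
    arr = piv.values
    # exact monotonicity under the shared-field coupling
    assert (np.diff(arr, axis=0) >= 0).all()
    assert (np.diff(arr, axis=1) >= 0).all()


def test_spacetime_pattern_conversion():
    st = eca_run(204, [1, 0, 1], 1)
    pat = st.to_pattern()
    assert pat.size("height") == 2
    assert pat.size("area") == 6
    active = st.to_pattern(active_only=True)
    assert active.size("area") == 4
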