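from itertools import combinations

import numpy as np
import pytest
from scipy.stats import fisher_exact

from tumoratlas.atlas import GroupedMasks
from tumoratlas.image_io import GridSpec, MapLabel
from tumoratlas.permutation import (
    ContingencyTable,
    PermutationConfig,
    build_p_lookup,
    fisher_p,
    observed_p_map,
    permutation_adjust,
    run_comparison,
    significance_mask,
    standard_comparisons,
)

from .conftest import make_mask


@pytest.mark.parametrize(
    "table,expected",
    [
        ((0, 5, 0, 5), 1.0),  # degenerate margin
        ((5, 5, 0, 5), 2 / 252),  # exhaustive enumeration over the support
        ((2, 4, 2, 4), 1.0),  # identical proportions
        ((4, 4, 0, 4), 2 / 70),
    ],
)
def test_fisher_examples(table, expected):
    assert fisher_p(ContingencyTable(*table)) == pytest.approx(expected, abs=1e-12)


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n_a, n_b = rng.integers(1, 40, size=2)
        k_a, k_b = rng.integers(0, n_a + 1), rng.integers(0, n_b + 1)
        ours = fisher_p(ContingencyTable(k_a, n_a, k_b, n_b))
        ref = fisher_exact(
            [[k_a, n_a - k_a], [k_b, n_b - k_b]], alternative="two-sided"
        ).pvalue
        assert ours == pytest.approx(ref, abs=1e-9)


def test_fisher_symmetry_under_group_and_label_swap():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n_a, n_b = rng.integers(1, 25, size=2)
        k_a, k_b = rng.integers(0, n_a + 1), rng.integers(0, n_b + 1)
        p = fisher_p(ContingencyTable(k_a, n_a, k_b, n_b))
        swap_groups = fisher_p(ContingencyTable(k_b, n_b, k_a, n_a))
        flip_labels = fisher_p(ContingencyTable(n_a - k_a, n_a, n_b - k_b, n_b))
        assert p == pytest.approx(swap_groups, abs=1e-12)
        assert p == pytest.approx(flip_labels, abs=1e-12)


def test_lookup_consistent_with_fisher_p():
    lut = build_p_lookup(5, 5)
    assert lut.shape == (6, 6)
    assert lut[5, 0] == pytest.approx(fisher_p(ContingencyTable(5, 5, 0, 5)), abs=1e-14)
    assert ((lut >= 0) & (lut <= 1)).all()


def test_lookup_shape_for_cohort_sized_groups():
    lut = build_p_lookup(52, 122)
    assert lut.shape == (53, 123)
    assert ((lut > 0) & (lut <= 1)).all()


def _two_groups(grid, patterns_a, patterns_b):
    ga = GroupedMasks("A", [make_mask(grid, v, f"A{i}") for i, v in enumerate(patterns_a)])
    gb = GroupedMasks("B", [make_mask(grid, v, f"B{i}") for i, v in enumerate(patterns_b)])
    return ga, gb


@pytest.fixture
def toy_groups():
    """8 patients, 4 informative voxels on a 4x1x1 grid."""
    grid = GridSpec(shape=(4, 1, 1), affine=np.eye(4))
    v = [(i, 0, 0) for i in range(4)]
    patterns_a = [[v[0], v[1]], [v[0], v[1]], [v[0], v[2]], [v[0], v[3]]]
    patterns_b = [[v[1]], [v[1], v[2]], [v[2], v[3]], [v[3]]]
    return _two_groups(grid, patterns_a, patterns_b)


def test_observed_p_map_values(toy_groups):
    ga, gb = toy_groups
    pmap = observed_p_map(ga, gb)
    # voxel 0: 4/4 vs 0/4 -> 2/70 by exhaustive enumeration
    assert pmap.values[0, 0, 0] == pytest.approx(2 / 70, rel=1e-6)
    # voxel 1: 2/4 vs 2/4, identical proportions
    assert pmap.values[1, 0, 0] == pytest.approx(1.0)


def test_observed_p_is_one_where_nobody_has_tumor(unit_grid):
    ga, gb = _two_groups(unit_grid, [[(0, 0, 0)]] * 3, [[(0, 0, 0)]] * 3)
    domain = np.ones(unit_grid.shape, dtype=bool)  # includes uncovered voxels
    pmap = observed_p_map(ga, gb, domain=domain)
    assert pmap.values[3, 3, 3] == pytest.approx(1.0)


def _exhaustive_adjust(ga, gb, count_ties=True):
    """Enumerate all label assignments preserving group sizes."""
    n_a, n = ga.n, ga.n + gb.n
    lut = build_p_lookup(n_a, gb.n)
    flat = [m.voxels.reshape(-1) for m in ga.masks + gb.masks]
    x = np.asarray(flat)
    k_tot = x.sum(axis=0)
    obs = lut[x[:n_a].sum(axis=0), k_tot - x[:n_a].sum(axis=0)]
    hits = np.zeros(obs.shape)
    total = 0
    for idx in combinations(range(n), n_a):
        k_a = x[list(idx)].sum(axis=0)
        null_p = lut[k_a, k_tot - k_a]
        hits += (null_p <= obs) if count_ties else (null_p < obs)
        total += 1
    return obs, hits / total


def test_monte_carlo_matches_exhaustive_enumeration(toy_groups):
    ga, gb = toy_groups
    obs_map = observed_p_map(ga, gb)
    config = PermutationConfig(n_perm=2000, seed=42)
    adj = permutation_adjust(ga, gb, obs_map, config)
    _, exact = _exhaustive_adjust(ga, gb)
    mc = np.asarray(adj.values, float).reshape(-1)
    exact = exact.reshape(-1)
    dom = np.isfinite(mc)
    se = np.sqrt(exact[dom] * (1 - exact[dom]) / config.n_perm)
    assert np.all(np.abs(mc[dom] - exact[dom]) <= 3 * se + 1e-12)


def test_permutation_reproducible_and_chunk_invariant(toy_groups):
    ga, gb = toy_groups
    obs = observed_p_map(ga, gb)
    a = permutation_adjust(ga, gb, obs, PermutationConfig(n_perm=300, seed=7))
    b = permutation_adjust(ga, gb, obs, PermutationConfig(n_perm=300, seed=7, chunk_size=11))
    c = permutation_adjust(ga, gb, obs, PermutationConfig(n_perm=300, seed=8))
    assert np.array_equal(a.values, b.values, equal_nan=True)
    assert not np.array_equal(a.values, c.values, equal_nan=True)


def test_strict_rule_gives_zero_at_minimal_p(toy_groups):
    """The literal 'strictly smaller' rule returns adjusted p = 0 wherever the
    observed p attains the minimum of the voxel's null support."""
    ga, gb = toy_groups
    obs = observed_p_map(ga, gb)
    adj = permutation_adjust(
        ga, gb, obs, PermutationConfig(n_perm=500, seed=1, count_ties=False)
    )
    assert float(adj.values[0, 0, 0]) == 0.0


def test_identical_groups_yield_no_significant_voxels(unit_grid):
    patterns = [[(0, 0, 0)], [(0, 0, 0), (1, 0, 0)], [(1, 0, 0)], [(2, 0, 0)]]
    ga, gb = _two_groups(unit_grid, patterns, patterns)
    res = run_comparison(ga, gb, config=PermutationConfig(n_perm=200, seed=0))
    assert res.significance.values.sum() == 0


def test_significance_mask_boundary(unit_grid):
    vals = np.full(unit_grid.shape, np.nan)
    vals[0, 0, 0] = 0.01
    vals[1, 0, 0] = 0.011
    vals[2, 0, 0] = 0.0
    from tumoratlas.image_io import VoxelMap

    adj = VoxelMap(MapLabel.ADJ_PVALUE, unit_grid, vals)
    sig = significance_mask(adj, alpha=0.01)
    assert sig.values[0, 0, 0] == 1  # boundary included
    assert sig.values[1, 0, 0] == 0
    assert sig.values[2, 0, 0] == 1
    assert sig.values[3, 3, 3] == 0  # NaN domain -> 0


def test_run_comparison_invariants(toy_groups):
    ga, gb = toy_groups
    res = run_comparison(ga, gb, config=PermutationConfig(n_perm=100, seed=2))
    assert res.n_included == 8
    adj = np.asarray(res.adj_p_map.values, float)
    dom = np.isfinite(adj)
    expect_sig = dom & (adj <= 0.01)
    assert np.array_equal(res.significance.values == 1, expect_sig)
    # masked log-OR finite exactly at significant voxels
    finite = np.isfinite(np.asarray(res.masked_log_or.values, float))
    assert np.array_equal(finite, expect_sig)
    assert res.metadata["n_perm"] == 100


def test_standard_comparisons_pairing_and_sizes(unit_grid):
    groups = {}
    for lab, n in (("SHORT", 3), ("MEDIUM", 4), ("LONG", 2)):
        groups[lab] = GroupedMasks(
            lab, [make_mask(unit_grid, [(i % 4, 0, 0)], f"{lab}{i}") for i in range(n)]
        )
    results = standard_comparisons(groups, config=PermutationConfig(n_perm=50, seed=0))
    pairs = [(r.group_a_label, r.group_b_label, r.n_included) for r in results]
    assert pairs == [("MEDIUM", "SHORT", 7), ("LONG", "MEDIUM", 6), ("LONG", "SHORT", 5)]


def test_global_scheme_runs_and_is_reproducible(unit_grid):
    rng = np.random.default_rng(1)
    groups = {}
    for lab, n in (("SHORT", 4), ("MEDIUM", 5), ("LONG", 3)):
        ms = []
        for i in range(n):
            vox = np.argwhere(rng.random(unit_grid.shape) < 0.3)
            ms.append(make_mask(unit_grid, vox if len(vox) else [(0, 0, 0)], f"{lab}{i}"))
        groups[lab] = GroupedMasks(lab, ms)
    cfg = PermutationConfig(n_perm=100, seed=5, scheme="global")
    r1 = standard_comparisons(groups, config=cfg)
    r2 = standard_comparisons(groups, config=cfg)
    for a, b in zip(r1, r2):
        assert a.adj_p_map.metadata["scheme"] == "global"
        assert np.array_equal(a.adj_p_map.values, b.adj_p_map.values, equal_nan=True)


def test_config_validation():
    with pytest.raises(ValueError):
        PermutationConfig(n_perm=0)
    with pytest.raises(ValueError):
        PermutationConfig(alpha=1.5)
    with pytest.raises(ValueError):
        PermutationConfig(scheme="bogus")


def test_adjust_rejects_mismatched_observed(toy_groups):
    ga, gb = toy_groups
    grid = ga.grid
    other_a, other_b = _two_groups(
        grid, [[(0, 0, 0)]] * 4, [[(1, 0, 0)], [(1, 0, 0)], [(2, 0, 0)], [(3, 0, 0)]]
    )
    obs_other = observed_p_map(other_a, other_b)
    with pytest.raises(ValueError, match="inconsistent"):
        permutation_adjust(ga, gb, obs_other, PermutationConfig(n_perm=10, seed=0))
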