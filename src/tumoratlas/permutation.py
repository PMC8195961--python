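"""Voxel-wise Fisher exact tests with permutation-adjusted p-values.

For a pairwise comparison of two survival groups, each voxel yields a 2x2
table (group membership x tumor presence) whose two-sided Fisher exact
p-value is looked up from a precomputed (nA+1) x (nB+1) table — group
sizes are fixed, so both the observed pass and every permutation reduce to
an O(voxels) lookup. The spatial dependence between voxels is handled by
permuting the group labels (preserving group sizes), recomputing the
p-value map per permutation, and reporting per voxel the proportion of
null p-values at or below the observed one. Voxels whose adjusted
p-value is at or below alpha form the significance mask.

Counting ties (null p equal to the observed p) is deliberate: the null
p-value at a voxel is a discrete statistic, and at sparsely covered
voxels its support is tiny — under a strict "proportion smaller than"
rule every voxel whose observed p attains the minimum of its own null
support gets adjusted p = 0 and is flagged, which under a label-permuted
null inflates the significant fraction far beyond alpha. The strict rule
remains available via ``PermutationConfig(count_ties=False)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.stats import hypergeom

from .atlas import EpsilonPolicy, GroupedMasks, log_odds_ratio_map, mask_log_or
from .image_io import GridMismatchError, MapLabel, VoxelMap

__all__ = [
    "ContingencyTable",
    "PermutationConfig",
    "ComparisonResult",
    "fisher_p",
    "build_p_lookup",
    "observed_p_map",
    "permutation_adjust",
    "significance_mask",
    "run_comparison",
    "standard_comparisons",
    "STANDARD_PAIRS",
]

#: relative tolerance for treating two table probabilities as tied in the
#: two-sided Fisher test (floating-point-safe "probability <= observed").
TIE_REL_TOL = 1e-7

#: the three pairwise OS-group comparisons, first-listed group on top
#: (medium vs short, long vs medium, long vs short).
STANDARD_PAIRS = (("MEDIUM", "SHORT"), ("LONG", "MEDIUM"), ("LONG", "SHORT"))


class ContingencyTable(NamedTuple):
    """Tumor-present counts and group sizes for one voxel."""

    k_a: int
    n_a: int
    k_b: int
    n_b: int


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings.

    ``count_ties`` (default) counts null p-values at or below the observed
    one; with ``count_ties=False`` only strictly smaller null p-values
    count, a rule that can return adjusted p = 0 (see module docstring).
    ``smoothed`` switches from b/n_perm to the (b+1)/(n_perm+1) estimator.
    ``scheme`` is 'pairwise' (labels reshuffled among the two compared
    groups) or 'global' (all three OS-group labels reshuffled jointly;
    only available through :func:`standard_comparisons`).
    """

    n_perm: int = 2000
    alpha: float = 0.01
    seed: int = 0
    scheme: str = "pairwise"
    count_ties: bool = True
    smoothed: bool = False
    chunk_size: int = 256

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scheme not in ("pairwise", "global"):
            raise ValueError("scheme must be 'pairwise' or 'global'")


@dataclass
class ComparisonResult:
    """All maps and metadata of one pairwise OS-group comparison."""

    group_a_label: str
    group_b_label: str
    n_included: int
    p_map: VoxelMap
    adj_p_map: VoxelMap
    significance: VoxelMap
    log_or: VoxelMap
    masked_log_or: VoxelMap
    metadata: dict = field(default_factory=dict)


def _two_sided_p(pmf: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p per support point, given the hypergeometric pmf
    over the support: sum of probabilities <= own probability (ties within
    TIE_REL_TOL)."""
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    pos = np.searchsorted(sorted_pmf, pmf * (1.0 + TIE_REL_TOL), side="right")
    return np.minimum(cum[pos - 1], 1.0)


def build_p_lookup(n_a: int, n_b: int) -> np.ndarray:
    """(n_a+1) x (n_b+1) table of two-sided Fisher exact p-values.

    Entry [kA, kB] is the p-value of the table with kA of n_a and kB of
    n_b tumor-present patients; conditioning is on the tumor-present
    margin m = kA + kB.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    n = n_a + n_b
    lut = np.empty((n_a + 1, n_b + 1), dtype=np.float64)
    for m in range(n + 1):
        lo = max(0, m - n_b)
        hi = min(n_a, m)
        xs = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(xs, n, m, n_a)
        lut[xs, m - xs] = _two_sided_p(pmf)
    return lut


def fisher_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value of one 2x2 table."""
    k_a, n_a, k_b, n_b = table
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError(f"invalid contingency table {table}")
    m = k_a + k_b
    lo = max(0, m - n_b)
    hi = min(n_a, m)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, n_a + n_b, m, n_a)
    return float(_two_sided_p(pmf)[xs.searchsorted(k_a)])


def _check_pair(group_a: GroupedMasks, group_b: GroupedMasks) -> None:
    if not group_a.grid.matches(group_b.grid):
        raise GridMismatchError("groups live on different grids")
    overlap = set(group_a.patient_ids) & set(group_b.patient_ids)
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)[:5]}")


def _default_domain(group_a: GroupedMasks, group_b: GroupedMasks) -> np.ndarray:
    """Analysis domain: voxels covered by at least one patient of the pair."""
    return (group_a.counts() + group_b.counts()) >= 1


def observed_p_map(
    group_a: GroupedMasks,
    group_b: GroupedMasks,
    domain: np.ndarray | None = None,
    lookup: np.ndarray | None = None,
) -> VoxelMap:
    """Voxel-wise two-sided Fisher p-values for one pairwise comparison.

    Outside the analysis domain the map is NaN. The default domain is the
    pair's tumor-covered voxels; pass ``domain`` to widen or narrow it.
    """
    _check_pair(group_a, group_b)
    if domain is None:
        domain = _default_domain(group_a, group_b)
    if lookup is None:
        lookup = build_p_lookup(group_a.n, group_b.n)
    k_a = group_a.counts()
    k_b = group_b.counts()
    values = np.full(group_a.grid.shape, np.nan, dtype=np.float64)
    values[domain] = lookup[k_a[domain], k_b[domain]]
    return VoxelMap(
        label=MapLabel.PVALUE,
        grid=group_a.grid,
        values=values,
        metadata={
            "group_a": group_a.group_label,
            "group_b": group_b.group_label,
            "n_a": group_a.n,
            "n_b": group_b.n,
            "domain_voxels": int(domain.sum()),
        },
    )


def _perm_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based stream for permutation ``index``: the index lives in
    the third 64-bit counter word (2^128 block spacing), so draws are
    independent of traversal order."""
    return np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, index, 0]))


def _stack_domain(masks, domain_idx) -> np.ndarray:
    flat = [m.voxels.reshape(-1)[domain_idx] for m in masks]
    return np.asarray(flat, dtype=np.float32)


def permutation_adjust(
    group_a: GroupedMasks,
    group_b: GroupedMasks,
    observed: VoxelMap,
    config: PermutationConfig,
) -> VoxelMap:
    """Permutation-adjusted p-value map.

    The nA + nB patients of the pair have their group labels randomly
    reassigned (group sizes preserved) ``n_perm`` times; per voxel, the
    adjusted p-value is the proportion of null p-values at or below
    (strictly below with ``count_ties=False``) the observed one, each
    voxel against its own null distribution. Deterministic given
    ``config.seed``. The analysis domain is read off the finite voxels
    of ``observed``.
    """
    _check_pair(group_a, group_b)
    if observed.label is not MapLabel.PVALUE:
        raise ValueError("observed must be a PVALUE map")
    n_a, n_b = group_a.n, group_b.n
    n = n_a + n_b
    domain = np.isfinite(np.asarray(observed.values, dtype=np.float64))
    domain_idx = np.flatnonzero(domain.reshape(-1))
    grid = group_a.grid

    lookup = build_p_lookup(n_a, n_b)
    x = np.concatenate(
        [_stack_domain(group_a.masks, domain_idx), _stack_domain(group_b.masks, domain_idx)]
    )  # (n, V) patient-by-voxel indicator
    k_tot = x.sum(axis=0).astype(np.int64)
    k_a_obs = x[:n_a].sum(axis=0).astype(np.int64)
    # recompute observed p in float64 from the same lookup so that ties with
    # null p-values are exact (the stored map may be float32)
    obs_p = lookup[k_a_obs, k_tot - k_a_obs]
    stored = np.asarray(observed.values, dtype=np.float64).reshape(-1)[domain_idx]
    if not np.allclose(stored, obs_p, atol=1e-6, rtol=0.0, equal_nan=True):
        raise ValueError("observed map is inconsistent with the supplied groups")

    below = np.zeros(obs_p.shape, dtype=np.int64)
    lut_flat = lookup.reshape(-1)
    for start in range(0, config.n_perm, config.chunk_size):
        stop = min(start + config.chunk_size, config.n_perm)
        p_rows = np.zeros((stop - start, n), dtype=np.float32)
        for i in range(start, stop):
            idx = _perm_rng(config.seed, i).permutation(n)[:n_a]
            p_rows[i - start, idx] = 1.0
        k_a = np.rint(p_rows @ x).astype(np.int64)  # (chunk, V)
        flat_idx = k_a * (n_b + 1) + (k_tot[None, :] - k_a)
        null_p = lut_flat[flat_idx]
        if config.count_ties:
            below += (null_p <= obs_p[None, :]).sum(axis=0)
        else:
            below += (null_p < obs_p[None, :]).sum(axis=0)

    if config.smoothed:
        adj = (below + 1) / (config.n_perm + 1)
    else:
        adj = below / config.n_perm
    values = np.full(grid.shape, np.nan, dtype=np.float64)
    values.reshape(-1)[domain_idx] = adj
    meta = dict(observed.metadata)
    meta.update(
        {
            "n_perm": config.n_perm,
            "seed": config.seed,
            "scheme": "pairwise",
            "count_ties": config.count_ties,
            "smoothed": config.smoothed,
        }
    )
    return VoxelMap(label=MapLabel.ADJ_PVALUE, grid=grid, values=values, metadata=meta)


def significance_mask(adj_p: VoxelMap, alpha: float) -> VoxelMap:
    """1 where the adjusted p-value is <= alpha, else 0 (NaN domain -> 0)."""
    if adj_p.label is not MapLabel.ADJ_PVALUE:
        raise ValueError("expected an ADJ_PVALUE map")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    values = np.asarray(adj_p.values, dtype=np.float64)
    sig = np.where(np.isfinite(values) & (values <= alpha), 1, 0)
    meta = dict(adj_p.metadata)
    meta["alpha"] = alpha
    return VoxelMap(label=MapLabel.SIGNIFICANCE, grid=adj_p.grid, values=sig, metadata=meta)


def run_comparison(
    group_a: GroupedMasks,
    group_b: GroupedMasks,
    policy: EpsilonPolicy | None = None,
    config: PermutationConfig | None = None,
    domain: np.ndarray | None = None,
) -> ComparisonResult:
    """Full pairwise comparison: p map, adjusted-p map, significance mask
    and the significance-masked log-odds-ratio map."""
    policy = policy or EpsilonPolicy()
    config = config or PermutationConfig()
    _check_pair(group_a, group_b)
    if domain is None:
        domain = _default_domain(group_a, group_b)
    observed = observed_p_map(group_a, group_b, domain=domain)
    adj = permutation_adjust(group_a, group_b, observed, config)
    sig = significance_mask(adj, config.alpha)
    log_or = log_odds_ratio_map(group_a, group_b, policy, domain=domain)
    masked = mask_log_or(log_or, sig)
    meta = {
        "group_a": group_a.group_label,
        "group_b": group_b.group_label,
        "n_a": group_a.n,
        "n_b": group_b.n,
        "n_included": group_a.n + group_b.n,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "seed": config.seed,
        "epsilon": policy.epsilon,
        "domain_voxels": int(domain.sum()),
    }
    return ComparisonResult(
        group_a_label=group_a.group_label,
        group_b_label=group_b.group_label,
        n_included=group_a.n + group_b.n,
        p_map=observed,
        adj_p_map=adj,
        significance=sig,
        log_or=log_or,
        masked_log_or=masked,
        metadata=meta,
    )


def _global_adjust(
    groups: dict[str, GroupedMasks],
    pair: tuple[str, str],
    observed: VoxelMap,
    config: PermutationConfig,
) -> VoxelMap:
    """Adjusted p-values for one pair under a joint reshuffle of all group
    labels (group sizes preserved across all groups)."""
    labels = list(groups)
    sizes = {lab: groups[lab].n for lab in labels}
    order: list[str] = []
    masks = []
    for lab in labels:
        order.extend([lab] * sizes[lab])
        masks.extend(groups[lab].masks)
    n_total = len(masks)
    a_label, b_label = pair
    n_a, n_b = sizes[a_label], sizes[b_label]

    domain = np.isfinite(np.asarray(observed.values, dtype=np.float64))
    domain_idx = np.flatnonzero(domain.reshape(-1))
    x = _stack_domain(masks, domain_idx)
    lookup = build_p_lookup(n_a, n_b)
    lut_flat = lookup.reshape(-1)

    obs_a = _stack_domain(groups[a_label].masks, domain_idx).sum(axis=0).astype(np.int64)
    obs_b = _stack_domain(groups[b_label].masks, domain_idx).sum(axis=0).astype(np.int64)
    obs_p = lookup[obs_a, obs_b]

    slot = np.asarray(order)
    a_slots = slot == a_label
    b_slots = slot == b_label
    below = np.zeros(obs_p.shape, dtype=np.int64)
    for start in range(0, config.n_perm, config.chunk_size):
        stop = min(start + config.chunk_size, config.n_perm)
        rows_a = np.zeros((stop - start, n_total), dtype=np.float32)
        rows_b = np.zeros((stop - start, n_total), dtype=np.float32)
        for i in range(start, stop):
            perm = _perm_rng(config.seed, i).permutation(n_total)
            rows_a[i - start, perm[a_slots]] = 1.0
            rows_b[i - start, perm[b_slots]] = 1.0
        k_a = np.rint(rows_a @ x).astype(np.int64)
        k_b = np.rint(rows_b @ x).astype(np.int64)
        null_p = lut_flat[k_a * (n_b + 1) + k_b]
        if config.count_ties:
            below += (null_p <= obs_p[None, :]).sum(axis=0)
        else:
            below += (null_p < obs_p[None, :]).sum(axis=0)

    adj = (below + 1) / (config.n_perm + 1) if config.smoothed else below / config.n_perm
    values = np.full(observed.grid.shape, np.nan, dtype=np.float64)
    values.reshape(-1)[domain_idx] = adj
    meta = dict(observed.metadata)
    meta.update(
        {
            "n_perm": config.n_perm,
            "seed": config.seed,
            "scheme": "global",
            "count_ties": config.count_ties,
            "smoothed": config.smoothed,
        }
    )
    return VoxelMap(label=MapLabel.ADJ_PVALUE, grid=observed.grid, values=values, metadata=meta)


def standard_comparisons(
    groups: dict[str, GroupedMasks],
    policy: EpsilonPolicy | None = None,
    config: PermutationConfig | None = None,
    pairs: tuple = STANDARD_PAIRS,
) -> list[ComparisonResult]:
    """Run the three standard pairwise OS-group comparisons.

    ``groups`` maps OS-group labels (SHORT/MEDIUM/LONG) to their masks.
    With ``config.scheme == 'global'`` the permutation null reshuffles all
    group labels jointly instead of within each pair.
    """
    policy = policy or EpsilonPolicy()
    config = config or PermutationConfig()
    results = []
    for j, (a_label, b_label) in enumerate(pairs):
        group_a, group_b = groups[a_label], groups[b_label]
        pair_config = replace(config, seed=config.seed + j)
        if config.scheme == "global":
            domain = _default_domain(group_a, group_b)
            observed = observed_p_map(group_a, group_b, domain=domain)
            adj = _global_adjust(groups, (a_label, b_label), observed, pair_config)
            sig = significance_mask(adj, config.alpha)
            log_or = log_odds_ratio_map(group_a, group_b, policy, domain=domain)
            masked = mask_log_or(log_or, sig)
            results.append(
                ComparisonResult(
                    group_a_label=a_label,
                    group_b_label=b_label,
                    n_included=group_a.n + group_b.n,
                    p_map=observed,
                    adj_p_map=adj,
                    significance=sig,
                    log_or=log_or,
                    masked_log_or=masked,
                    metadata=dict(adj.metadata),
                )
            )
        else:
            results.append(run_comparison(group_a, group_b, policy, pair_config))
    return results
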