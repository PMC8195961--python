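"""Tumor distribution, odds and log-odds-ratio maps.

Per survival group, the tumor odds at a voxel are k/(n-k): the number of
patients of the group with tumor there over the number without. Where a
group has no patients with tumor at a voxel (k = 0), the count is replaced
by a small epsilon (default 1e-6) so the odds stay positive and finite;
the mirrored substitution (n - epsilon)/epsilon is applied when every
patient has tumor there (k = n), which preserves the antisymmetry of the
log odds ratio and is logged as a warning since it only arises in small
groups. The log odds ratio of two groups is ln(odds_A / odds_B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image_io import GridMismatchError, GridSpec, MapLabel, TumorMask, VoxelMap

__all__ = [
    "EpsilonPolicy",
    "GroupedMasks",
    "distribution_map",
    "count_array",
    "odds_map",
    "log_odds_ratio_map",
    "mask_log_or",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpsilonPolicy:
    """Zero-count substitution for odds computation.

    ``epsilon`` replaces a tumor count of 0; with ``substitute_in_denominator``
    (the default) the patients-without-tumor denominator becomes n - epsilon,
    i.e. the substitution acts on the count itself.
    """

    epsilon: float = 1e-6
    substitute_in_denominator: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")


@dataclass
class GroupedMasks:
    """All tumor masks of one survival group on the shared grid."""

    group_label: str
    masks: list[TumorMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError(f"group {self.group_label!r} has no masks")
        grid = self.masks[0].grid
        for m in self.masks[1:]:
            if not m.grid.matches(grid):
                raise GridMismatchError(
                    f"group {self.group_label!r}: mask {m.patient_id!r} is on a "
                    "different grid"
                )

    @property
    def n(self) -> int:
        return len(self.masks)

    @property
    def grid(self) -> GridSpec:
        return self.masks[0].grid

    @property
    def patient_ids(self) -> list[str]:
        return [m.patient_id for m in self.masks]

    def counts(self) -> np.ndarray:
        """Per-voxel number of patients of this group with tumor (int array)."""
        out = np.zeros(self.grid.shape, dtype=np.int32)
        for m in self.masks:
            out += m.voxels
        return out


def count_array(masks) -> np.ndarray:
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    grid = masks[0].grid
    out = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        if not m.grid.matches(grid):
            raise GridMismatchError(f"mask {m.patient_id!r} is on a different grid")
        out += m.voxels
    return out


def distribution_map(masks) -> VoxelMap:
    """Number of patients with tumor in each voxel, over the whole cohort."""
    masks = list(masks)
    counts = count_array(masks)
    return VoxelMap(
        label=MapLabel.COUNT,
        grid=masks[0].grid,
        values=counts,
        metadata={"n_patients": len(masks)},
    )


def _substituted_counts(k: np.ndarray, n: int, policy: EpsilonPolicy) -> np.ndarray:
    k = k.astype(np.float64)
    n_full = int((k == n).sum())
    if n_full:
        logger.warning(
            "%d voxel(s) covered by every patient of a group of %d; applying "
            "the mirrored (n - eps)/eps substitution",
            n_full,
            n,
        )
    k = np.where(k == 0, policy.epsilon, k)
    k = np.where(k == n, n - policy.epsilon, k)
    return k


def _odds_array(k: np.ndarray, n: int, policy: EpsilonPolicy) -> np.ndarray:
    ks = _substituted_counts(k, n, policy)
    if policy.substitute_in_denominator:
        return ks / (n - ks)
    # alternative reading: denominator keeps the unsubstituted complement
    denom = np.maximum(n - k.astype(np.float64), policy.epsilon)
    return ks / denom


def odds_map(
    group: GroupedMasks,
    policy: EpsilonPolicy | None = None,
    domain: np.ndarray | None = None,
) -> VoxelMap:
    """Per-voxel tumor odds k/(n-k) of one group (epsilon-substituted).

    ``domain`` restricts the map to an analysis region; outside it the
    map is NaN.
    """
    policy = policy or EpsilonPolicy()
    odds = _odds_array(group.counts(), group.n, policy)
    if domain is not None:
        odds = np.where(domain, odds, np.nan)
    return VoxelMap(
        label=MapLabel.ODDS,
        grid=group.grid,
        values=odds,
        metadata={"group": group.group_label, "n": group.n, "epsilon": policy.epsilon},
    )


def log_odds_ratio_map(
    group_a: GroupedMasks,
    group_b: GroupedMasks,
    policy: EpsilonPolicy | None = None,
    domain: np.ndarray | None = None,
) -> VoxelMap:
    """ln(odds_A / odds_B) per voxel; positive where group A's odds exceed B's."""
    policy = policy or EpsilonPolicy()
    if not group_a.grid.matches(group_b.grid):
        raise GridMismatchError("groups live on different grids")
    overlap = set(group_a.patient_ids) & set(group_b.patient_ids)
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)[:5]}")
    odds_a = _odds_array(group_a.counts(), group_a.n, policy)
    odds_b = _odds_array(group_b.counts(), group_b.n, policy)
    log_or = np.log(odds_a) - np.log(odds_b)
    if domain is not None:
        log_or = np.where(domain, log_or, np.nan)
    return VoxelMap(
        label=MapLabel.LOG_OR,
        grid=group_a.grid,
        values=log_or,
        metadata={
            "group_a": group_a.group_label,
            "group_b": group_b.group_label,
            "n_a": group_a.n,
            "n_b": group_b.n,
            "epsilon": policy.epsilon,
        },
    )


def mask_log_or(log_or: VoxelMap, significance: VoxelMap) -> VoxelMap:
    """Keep log-OR values only at significant voxels; others become NaN."""
    if log_or.label is not MapLabel.LOG_OR:
        raise ValueError("first argument must be a LOG_OR map")
    if significance.label is not MapLabel.SIGNIFICANCE:
        raise ValueError("second argument must be a SIGNIFICANCE map")
    if not log_or.grid.matches(significance.grid):
        raise GridMismatchError("log-OR and significance maps are on different grids")
    values = np.where(significance.values == 1, log_or.values, np.nan)
    meta = dict(log_or.metadata)
    meta["masked_by"] = dict(significance.metadata)
    return VoxelMap(label=MapLabel.LOG_OR, grid=log_or.grid, values=values, metadata=meta)
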