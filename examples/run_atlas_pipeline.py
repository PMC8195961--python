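"""Build the statistical tumor atlas on a synthetic cohort.

Generates 215 patients with a planted short-survival region near the
third-ventricle reference point, then runs the three pairwise OS-group
comparisons: per-voxel Fisher exact tests, permutation-adjusted p-values
and significance-masked log-odds-ratio maps.
"""

import numpy as np

import tumoratlas as ta
from tumoratlas.atlas import GroupedMasks, distribution_map
from tumoratlas.permutation import PermutationConfig, standard_comparisons

config = ta.SimulationConfig(seed=7, tumor_radius_mm=(22.0, 32.0), effect_radius_mm=8.0)
masks, registry, truth = ta.generate_cohort(config)

dist = distribution_map(masks)
print(f"cohort: {len(masks)} patients, max tumors per voxel = {int(dist.values.max())}")

by_id = dict(zip(registry.df["patient_id"], registry.df["os_group"]))
groups = {
    lab: GroupedMasks(lab, [m for m in masks if by_id[m.patient_id] == lab])
    for lab in ("SHORT", "MEDIUM", "LONG")
}
print("group sizes:", {lab: g.n for lab, g in groups.items()})

# n_perm kept small here so the example runs in seconds
results = standard_comparisons(groups, config=PermutationConfig(n_perm=500, alpha=0.01, seed=7))
for r in results:
    sig = int(r.significance.values.sum())
    finite = np.asarray(r.masked_log_or.values, float)
    med = float(np.nanmedian(finite)) if sig else float("nan")
    print(
        f"{r.group_a_label} vs {r.group_b_label}: n = {r.n_included}, "
        f"{sig} significant voxels (adjusted p <= 0.01), median log-OR there = {med:.2f}"
    )

# a positive log-OR means higher tumor odds in the first-listed group; for
# MEDIUM vs SHORT, negative log-OR voxels mark locations where tumors go
# with short survival -- they should cluster near the planted region.
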