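# tumoratlas

Statistical tumor atlases for lesion–survival mapping. `tumoratlas` takes a
cohort of co-registered binary 3D tumor segmentations (NIfTI, one mask per
patient on a common reference grid) plus a clinical registry (CSV) and asks
*where in the brain does tumor location go with survival?* — then quantifies
the answer with a centrality metric and survival regression. It was built
around the analysis of a population-based glioblastoma cohort, but the
machinery applies to any binary-lesion cohort with a grouped outcome.

## What it computes

**Voxel-wise maps.** Patients are split by overall survival (OS) into
short (< 6 months), medium (6–24 months) and long (> 24 months) groups.
Per group, the tumor odds at voxel $v$ are

$$\mathrm{odds}_g(v) = \frac{k_g(v)}{n_g - k_g(v)},$$

with $k_g(v)$ the number of group-$g$ patients with tumor at $v$; zero
counts are replaced by $\varepsilon = 10^{-6}$ (and $n-\varepsilon$ when
every patient has tumor there) so odds stay finite. Pairs of groups are
compared by the log odds ratio $\ln(\mathrm{odds}_A/\mathrm{odds}_B)$ and,
per voxel, a two-sided Fisher exact test on the 2×2 table (group × tumor
presence). Spatial dependence is handled by permuting group labels
(2000 permutations by default): the adjusted p-value at a voxel is the
proportion of its own permutation-null p-values at or below the observed
one, and voxels with adjusted p ≤ 0.01 form the significance mask applied
to the log-OR map.

**Tumor centrality.** TVTB — the shortest Euclidean distance (cm) from a
reference point (clinically the center of the third ventricle, supplied in
world coordinates) to the tumor border, computed over border voxel centers
with full anisotropic-spacing support.

**Regression stage.** Cox proportional hazards for OS with an age × TVTB
interaction screened at p ≤ 0.01 (candidates screened univariably at
p ≤ 0.1), binomial logistic models for biopsy-only and radiochemotherapy,
and a proportional-odds model on 5-mL residual-tumor-volume bins. With an
interaction, the per-cm hazard ratio of TVTB at age $a$ is
$\mathrm{HR}_{\mathrm{TVTB}} \cdot \mathrm{HR}_{\mathrm{age\times TVTB}}^{\,a}$.

**Synthetic cohorts.** `tumoratlas.simulate` generates full cohorts —
ellipsoidal tumors in a brain ellipsoid on a small grid, a planted
short-survival region, centrality-coupled covariates, administrative
censoring — so the entire pipeline is testable without patient data.

## Worked example

`examples/run_atlas_pipeline.py` generates a 215-patient synthetic cohort
with a planted short-survival region near the reference point and runs the
three pairwise comparisons:

```
cohort: 215 patients, max tumors per voxel = 37
group sizes: {'SHORT': 61, 'MEDIUM': 124, 'LONG': 30}
MEDIUM vs SHORT: n = 185, 672 significant voxels (adjusted p <= 0.01), median log-OR there = -1.55
LONG vs MEDIUM: n = 154, 4 significant voxels (adjusted p <= 0.01), median log-OR there = 1.28
LONG vs SHORT: n = 91, 12 significant voxels (adjusted p <= 0.01), median log-OR there = -2.33
```

The MEDIUM-vs-SHORT map lights up (negative log-OR: higher tumor odds in
the short-survival group) exactly around the planted region. The companion
script `examples/tvtb_and_survival.py` fits the Cox model on a
hazard-driven cohort and prints the age-conditional TVTB hazard ratio:

```
per-cm HR of TVTB at age 60: 0.90
per-cm HR of TVTB at age 80: 0.70
```

i.e. each centimeter of distance from the third ventricle lowers the
hazard, more strongly in older patients. `examples/treatment_models.py`
runs the biopsy-only / radiochemotherapy / residual-volume models.

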