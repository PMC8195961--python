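"""Synthetic cohorts: blob tumors on a small grid plus a clinical registry.

The generator emulates the statistical structure the atlas pipeline
assumes, so every stage is testable without patient data:

* ellipsoidal tumors with uniformly drawn radii, centered uniformly inside
  a brain ellipsoid on a small common grid (default 32^3 voxels at 4 mm);
* a planted spherical effect region R near the third-ventricle reference
  point: tumors overlapping R have an elevated probability of short-OS
  group membership (the location-survival coupling the maps should find);
* covariates correlated with tumor centrality: biopsy-only more likely for
  central tumors (low TVTB), radiochemotherapy less likely, KPS declining
  with age, preoperative volume equal to tumor voxel count x voxel volume;
* survival either sampled within the assigned OS-group interval (planted-
  effect mode, the default) or from an exponential model with log-hazard
  linear in age, TVTB and age x TVTB (parameter-recovery mode), with
  administrative censoring.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import CohortRegistry
from .geometry import ReferencePoint, tvtb_cm
from .image_io import GridSpec, TumorMask

__all__ = ["SimulationConfig", "CohortSample", "generate_cohort", "generate_null_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults give a cohort of 215 patients on a 32^3 grid at 4 mm, with the
    short-OS probability raised from 0.15 to 0.6 for tumors overlapping the
    planted region (20-mm sphere at the reference point).
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_patients: int = 215

    # anatomy / tumor model
    brain_semiaxes_mm: tuple[float, float, float] = (54.0, 60.0, 54.0)
    tumor_radius_mm: tuple[float, float] = (8.0, 30.0)

    # reference point for TVTB and the planted effect region R
    ref_point_mm: tuple[float, float, float] = (0.0, -4.0, 2.0)
    ref_label: str = "center of third ventricle"
    effect_center_mm: tuple[float, float, float] | None = None  # default: ref point
    effect_radius_mm: float = 20.0

    # planted-effect group model: P(SHORT) by overlap with R, remaining
    # mass split between MEDIUM and LONG
    p_short_base: float = 0.15
    p_short_effect: float = 0.6
    medium_long_split: tuple[float, float] = (0.75, 0.25)

    # survival sampling per OS group (days) and administrative censoring
    short_days: tuple[int, int] = (8, 182)
    medium_days: tuple[int, int] = (183, 731)
    long_tail_mean_days: float = 400.0
    censor_day: int = 1400

    # parameter-recovery mode: exponential survival with log-hazard linear
    # in age, TVTB and age x TVTB (activates when not None)
    hazard_coefs: dict | None = None
    baseline_median_days: float = 374.0

    # covariate model
    age_mean: float = 65.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    male_p: float = 0.61
    kps_logit: tuple[float, float] = (1.0, -0.06)  # intercept, slope on (age - 65)
    biopsy_logit: tuple[float, float] = (-0.2, -0.5)  # intercept, slope on tvtb_cm
    radiochemo_logit: tuple[float, float, float] = (1.0, 0.3, -0.05)
    #: Beta(a, b) fraction of the preoperative volume left after resection
    residual_fraction_beta: tuple[float, float] = (0.8, 8.0)

    # fixed group sizes used by the null generator (sum must equal n_patients)
    null_group_sizes: tuple[int, int, int] = (52, 122, 41)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 < self.tumor_radius_mm[0] <= self.tumor_radius_mm[1]:
            raise ValueError("tumor radii must be positive and ordered")
        for p in (self.p_short_base, self.p_short_effect):
            if not 0 <= p <= 1:
                raise ValueError("group probabilities must lie in [0, 1]")
        half_extent = (np.asarray(self.shape) - 1) / 2 * np.asarray(self.spacing_mm)
        if np.any(np.asarray(self.brain_semiaxes_mm) > half_extent + 1e-9):
            raise ValueError(
                "brain ellipsoid (hence the tumors) cannot fit the grid: semiaxes "
                f"{self.brain_semiaxes_mm} exceed the half-extent {tuple(half_extent)}"
            )
        center = np.asarray(self.effect_center_mm or self.ref_point_mm, dtype=float)
        semi = np.asarray(self.brain_semiaxes_mm, dtype=float)
        if np.linalg.norm(center / semi) + self.effect_radius_mm / semi.min() > 1 + 1e-9:
            raise ValueError("effect region R must lie inside the brain ellipsoid")

    @property
    def grid(self) -> GridSpec:
        spacing = np.asarray(self.spacing_mm, dtype=float)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = -(np.asarray(self.shape) - 1) / 2 * spacing
        return GridSpec(shape=self.shape, affine=affine)

    @property
    def reference_point(self) -> ReferencePoint:
        return ReferencePoint(world_mm=self.ref_point_mm, label=self.ref_label)


#: "fullres" profile approximating a 2-mm MNI-like grid (not used in tests)
FULLRES = {"shape": (91, 109, 91), "spacing_mm": (2.0, 2.0, 2.0), "brain_semiaxes_mm": (72.0, 88.0, 72.0)}


class CohortSample(NamedTuple):
    masks: list[TumorMask]
    registry: CohortRegistry
    truth: dict


def _axis_coords(config: SimulationConfig):
    grid = config.grid
    return [
        grid.affine[i, i] * np.arange(config.shape[i]) + grid.affine[i, 3]
        for i in range(3)
    ]


def _sample_center(rng: np.random.Generator, semi: np.ndarray) -> np.ndarray:
    while True:
        pt = rng.uniform(-semi, semi)
        if np.sum((pt / semi) ** 2) <= 1.0:
            return pt


def _rasterize_tumor(
    center: np.ndarray,
    radii: np.ndarray,
    config: SimulationConfig,
    coords,
) -> np.ndarray:
    """Boolean full-grid mask of an ellipsoidal tumor clipped to the brain."""
    shape = config.shape
    spacing = np.asarray(config.spacing_mm)
    semi = np.asarray(config.brain_semiaxes_mm)
    lo = np.maximum(0, np.floor((center - radii - config.grid.affine[:3, 3]) / spacing)).astype(int)
    hi = np.minimum(
        np.asarray(shape) - 1,
        np.ceil((center + radii - config.grid.affine[:3, 3]) / spacing),
    ).astype(int)
    out = np.zeros(shape, dtype=bool)
    xs = coords[0][lo[0] : hi[0] + 1][:, None, None]
    ys = coords[1][lo[1] : hi[1] + 1][None, :, None]
    zs = coords[2][lo[2] : hi[2] + 1][None, None, :]
    in_tumor = (
        ((xs - center[0]) / radii[0]) ** 2
        + ((ys - center[1]) / radii[1]) ** 2
        + ((zs - center[2]) / radii[2]) ** 2
    ) <= 1.0
    in_brain = ((xs / semi[0]) ** 2 + (ys / semi[1]) ** 2 + (zs / semi[2]) ** 2) <= 1.0
    out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = in_tumor & in_brain
    return out


def _generate_masks(config: SimulationConfig, rng: np.random.Generator):
    grid = config.grid
    coords = _axis_coords(config)
    semi = np.asarray(config.brain_semiaxes_mm)
    r_lo, r_hi = config.tumor_radius_mm
    masks: list[TumorMask] = []
    overlaps = np.zeros(config.n_patients, dtype=bool)
    tvtbs = np.zeros(config.n_patients)
    center_r = np.asarray(config.effect_center_mm or config.ref_point_mm, dtype=float)
    ref = config.reference_point
    for i in range(config.n_patients):
        for _ in range(100):
            center = _sample_center(rng, semi)
            radii = rng.uniform(r_lo, r_hi, size=3)
            vox = _rasterize_tumor(center, radii, config, coords)
            if vox.any():
                break
        else:  # pragma: no cover - defensive; min radius >> spacing
            raise RuntimeError("could not place a non-empty tumor on the grid")
        mask = TumorMask(patient_id=f"P{i:04d}", grid=grid, voxels=vox)
        masks.append(mask)
        idx = np.argwhere(vox)
        centers_mm = grid.voxel_to_world(idx)
        overlaps[i] = bool(
            (np.linalg.norm(centers_mm - center_r, axis=1) <= config.effect_radius_mm).any()
        )
        tvtbs[i] = tvtb_cm(mask, ref)
    return masks, overlaps, tvtbs


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - filled, keep.size)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _sample_covariates(config: SimulationConfig, rng, masks, tvtbs):
    n = config.n_patients
    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_bounds, n)
    sex = np.where(rng.random(n) < config.male_p, "male", "female")
    kps = (
        rng.random(n)
        < _logistic(config.kps_logit[0] + config.kps_logit[1] * (age - config.age_mean))
    ).astype(int)
    biopsy = (
        rng.random(n) < _logistic(config.biopsy_logit[0] + config.biopsy_logit[1] * tvtbs)
    ).astype(int)
    rc0, rc_tvtb, rc_age = config.radiochemo_logit
    radiochemo = (
        rng.random(n) < _logistic(rc0 + rc_tvtb * tvtbs + rc_age * (age - config.age_mean))
    ).astype(int)
    preop = np.array([m.volume_ml for m in masks])
    a, b = config.residual_fraction_beta
    frac = rng.beta(a, b, size=n)
    residual = np.where(biopsy == 1, np.nan, preop * frac)
    return {
        "age_years": age,
        "sex": sex,
        "kps_at_least_70": kps,
        "biopsy_only": biopsy,
        "radiochemo": radiochemo,
        "preop_volume_ml": preop,
        "residual_ce_volume_ml": residual,
    }


def _survival_from_groups(config: SimulationConfig, rng, groups: np.ndarray):
    n = len(groups)
    days = np.zeros(n, dtype=int)
    event = np.ones(n, dtype=int)
    for i, grp in enumerate(groups):
        if grp == "SHORT":
            days[i] = rng.integers(config.short_days[0], config.short_days[1] + 1)
        elif grp == "MEDIUM":
            days[i] = rng.integers(config.medium_days[0], config.medium_days[1] + 1)
        else:
            t = config.medium_days[1] + 1 + rng.exponential(config.long_tail_mean_days)
            if t > config.censor_day:
                days[i] = config.censor_day
                event[i] = 0
            else:
                days[i] = int(math.ceil(t))
    return days, event


def _survival_from_hazard(config: SimulationConfig, rng, age, tvtbs):
    coefs = dict(config.hazard_coefs or {})
    beta_age = coefs.get("age_years", 0.0)
    beta_tvtb = coefs.get("tvtb_cm", 0.0)
    beta_int = coefs.get("age_x_tvtb", 0.0)
    lp = beta_age * age + beta_tvtb * tvtbs + beta_int * age * tvtbs
    # anchor the baseline so median survival at typical covariates matches
    lp0 = beta_age * config.age_mean + (beta_tvtb + beta_int * config.age_mean) * 2.5
    rate = math.log(2.0) / config.baseline_median_days * np.exp(lp - lp0)
    t = rng.exponential(1.0 / rate)
    days = np.maximum(1, np.ceil(t)).astype(int)
    event = (days <= config.censor_day).astype(int)
    days = np.minimum(days, config.censor_day)
    return days, event


def _assemble(config, masks, overlaps, tvtbs, covs, groups, days, event, extra_truth):
    df = pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in masks],
            "survival_days": days,
            "event": event,
            **covs,
        }
    )
    registry = CohortRegistry.from_dataframe(df)
    registry.set_tvtb({m.patient_id: t for m, t in zip(masks, tvtbs)})
    truth = {
        "seed": config.seed,
        "effect_center_mm": tuple(config.effect_center_mm or config.ref_point_mm),
        "effect_radius_mm": config.effect_radius_mm,
        "p_short_base": config.p_short_base,
        "p_short_effect": config.p_short_effect,
        "overlaps_region": overlaps.copy(),
        "tvtb_cm": tvtbs.copy(),
        "groups": None if groups is None else np.asarray(groups).copy(),
        "hazard_coefs": dict(config.hazard_coefs or {}),
    }
    truth.update(extra_truth)
    return CohortSample(masks=masks, registry=registry, truth=truth)


def generate_cohort(config: SimulationConfig | None = None) -> CohortSample:
    """Generate masks, registry and the planted-truth record.

    In the default planted-effect mode, each patient's OS group is drawn
    with P(SHORT) depending on overlap with the effect region and survival
    days are sampled within the group's interval. When ``hazard_coefs`` is
    set, survival is exponential with the given log-hazard coefficients and
    groups follow from the sampled times.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    masks, overlaps, tvtbs = _generate_masks(config, rng)
    covs = _sample_covariates(config, rng, masks, tvtbs)

    if config.hazard_coefs is not None:
        days, event = _survival_from_hazard(config, rng, covs["age_years"], tvtbs)
        groups = None
    else:
        p_short = np.where(overlaps, config.p_short_effect, config.p_short_base)
        w_m, w_l = config.medium_long_split
        w_m, w_l = w_m / (w_m + w_l), w_l / (w_m + w_l)
        u = rng.random(config.n_patients)
        groups = np.where(
            u < p_short,
            "SHORT",
            np.where(u < p_short + (1 - p_short) * w_m, "MEDIUM", "LONG"),
        )
        days, event = _survival_from_groups(config, rng, groups)

    return _assemble(
        config, masks, overlaps, tvtbs, covs, groups, days, event, {"mode": "effect" if groups is not None else "hazard"}
    )


def generate_null_cohort(config: SimulationConfig | None = None) -> CohortSample:
    """Cohort with all location-outcome couplings removed.

    Group labels are a random permutation of a fixed label vector with the
    configured group sizes (default 52/122/41), independent of the masks;
    used for type-I-error suites.
    """
    config = config or SimulationConfig()
    sizes = config.null_group_sizes
    if sum(sizes) != config.n_patients:
        raise ValueError(
            f"null_group_sizes {sizes} must sum to n_patients {config.n_patients}"
        )
    rng = np.random.default_rng(config.seed)
    masks, overlaps, tvtbs = _generate_masks(config, rng)
    covs = _sample_covariates(config, rng, masks, tvtbs)
    labels = np.repeat(["SHORT", "MEDIUM", "LONG"], sizes)
    groups = rng.permutation(labels)
    days, event = _survival_from_groups(config, rng, groups)
    return _assemble(
        config, masks, overlaps, tvtbs, covs, groups, days, event, {"mode": "null"}
    )
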