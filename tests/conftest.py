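import numpy as np
import pandas as pd
import pytest

from tumoratlas.cohort import CohortRegistry
from tumoratlas.image_io import GridSpec, TumorMask


@pytest.fixture
def unit_grid():
    """4x4x4 grid with 1 mm isotropic spacing, origin at voxel (0,0,0)."""
    return GridSpec(shape=(4, 4, 4), affine=np.eye(4))


def make_mask(grid, voxels, patient_id="P0"):
    """TumorMask with tumor at the given (i, j, k) voxel indices."""
    arr = np.zeros(grid.shape, dtype=bool)
    for ijk in voxels:
        arr[tuple(ijk)] = True
    return TumorMask(patient_id=patient_id, grid=grid, voxels=arr)


def make_registry_frame(
    n,
    rng=None,
    survival_days=None,
    event=None,
    age_years=None,
    biopsy_only=None,
    **overrides,
):
    """Minimal valid registry DataFrame with sensible filler columns."""
    rng = rng or np.random.default_rng(0)
    if survival_days is None:
        survival_days = rng.integers(8, 1500, size=n)
    if event is None:
        event = np.ones(n, dtype=int)
    if age_years is None:
        age_years = rng.normal(65, 10, size=n).clip(20, 90)
    if biopsy_only is None:
        biopsy_only = (rng.random(n) < 0.2).astype(int)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "survival_days": survival_days,
            "event": event,
            "age_years": age_years,
            "sex": np.where(rng.random(n) < 0.6, "male", "female"),
            "kps_at_least_70": (rng.random(n) < 0.7).astype(int),
            "biopsy_only": biopsy_only,
            "radiochemo": (rng.random(n) < 0.75).astype(int),
            "preop_volume_ml": rng.uniform(1, 100, size=n),
            "residual_ce_volume_ml": rng.uniform(0, 30, size=n),
        }
    )
    for col, val in overrides.items():
        df[col] = val
    # biopsy-only rows carry no post-operative volume
    df.loc[df["biopsy_only"] == 1, "residual_ce_volume_ml"] = np.nan
    return df


def make_registry(n, rng=None, **kwargs) -> CohortRegistry:
    return CohortRegistry.from_dataframe(make_registry_frame(n, rng=rng, **kwargs))
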