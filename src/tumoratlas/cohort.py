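"""Clinical registry handling: validation and derived survival variables.

Derivation rules
----------------
* Overall-survival (OS) groups: deceased patients are classed as short
  (< 6 months), medium (6-24 months) or long (> 24 months) survivors;
  censored patients can only be classed long (follow-up beyond 24 months),
  otherwise they are unassignable and excluded from the maps. Months are
  converted to days as round(365.25 * k / 12): 183 and 731 days.
* Residual tumor volume (RTV): contrast-enhancing components only in
  resected patients; equal to the preoperative volume (including the
  necrotic core) in biopsy-only patients. Resected patients without a
  post-operative volume are flagged for exclusion from RTV models.
* RTV bins: 5-mL interval groups (0-5], (5-10], (10-15], (15-20], (20, inf),
  with 0 mL in the first bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OSGroup",
    "RTVBin",
    "PatientRecord",
    "CohortRegistry",
    "RegistrySchemaError",
    "RegistryValidationError",
    "DAYS_6_MONTHS",
    "DAYS_24_MONTHS",
    "assign_os_group",
    "derive_rtv",
    "bin_rtv",
    "load_registry",
    "summarize",
]

logger = logging.getLogger(__name__)

#: month thresholds in days, round(365.25 * k / 12)
DAYS_6_MONTHS = 183
DAYS_24_MONTHS = 731


class OSGroup(str, Enum):
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"
    UNASSIGNABLE = "UNASSIGNABLE"


class RTVBin(str, Enum):
    """Ordered 5-mL residual-volume bins; enum definition order is bin order."""

    B0_5 = "0-5"
    B5_10 = "5-10"
    B10_15 = "10-15"
    B15_20 = "15-20"
    B20PLUS = ">20"

    @property
    def order(self) -> int:
        return list(RTVBin).index(self)


RTV_BIN_CATEGORIES = [b.value for b in RTVBin]

REQUIRED_COLUMNS = [
    "patient_id",
    "survival_days",
    "event",
    "age_years",
    "sex",
    "kps_at_least_70",
    "biopsy_only",
    "radiochemo",
    "preop_volume_ml",
    "residual_ce_volume_ml",
]


class RegistrySchemaError(ValueError):
    """The registry file does not expose the required columns."""


class RegistryValidationError(ValueError):
    """One or more rows violate the registry invariants."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid registry rows:\n" + "\n".join(errors))


@dataclass
class PatientRecord:
    patient_id: str
    survival_days: int
    event: int
    age_years: float
    sex: str
    kps_at_least_70: int
    biopsy_only: int
    radiochemo: int
    preop_volume_ml: float
    residual_ce_volume_ml: float | None = None


def assign_os_group(
    survival_days: int,
    event: int,
    t6_days: int = DAYS_6_MONTHS,
    t24_days: int = DAYS_24_MONTHS,
) -> OSGroup:
    """OS group of one patient.

    Deceased: short if < ``t6_days``, medium if in [t6, t24], long if
    beyond. Censored: long only when follow-up exceeds ``t24_days``; the
    6-24-month window is taken closed on both ends.
    """
    if survival_days < 0:
        raise ValueError(f"survival_days must be >= 0, got {survival_days}")
    if event:
        if survival_days < t6_days:
            return OSGroup.SHORT
        if survival_days <= t24_days:
            return OSGroup.MEDIUM
        return OSGroup.LONG
    if survival_days > t24_days:
        return OSGroup.LONG
    return OSGroup.UNASSIGNABLE


def derive_rtv(record: PatientRecord) -> float | None:
    """Residual tumor volume (mL), or None if the record must be excluded
    from RTV-using models (resected, no post-operative volume)."""
    if record.biopsy_only:
        return float(record.preop_volume_ml)
    residual = record.residual_ce_volume_ml
    if residual is None or (isinstance(residual, float) and np.isnan(residual)):
        return None
    if residual < 0:
        raise ValueError(
            f"patient {record.patient_id!r}: residual volume must be >= 0"
        )
    return float(residual)


def bin_rtv(rtv_ml: float) -> RTVBin:
    """5-mL interval group of a residual volume; bins closed on the right."""
    if rtv_ml < 0:
        raise ValueError(f"rtv_ml must be >= 0, got {rtv_ml}")
    if rtv_ml <= 5:
        return RTVBin.B0_5
    if rtv_ml <= 10:
        return RTVBin.B5_10
    if rtv_ml <= 15:
        return RTVBin.B10_15
    if rtv_ml <= 20:
        return RTVBin.B15_20
    return RTVBin.B20PLUS


@dataclass
class CohortRegistry:
    """Validated clinical registry with derived columns.

    ``df`` holds one row per patient with the canonical columns plus
    ``os_group``, ``rtv_ml``, ``rtv_bin`` and ``tvtb_cm`` (NaN until the
    geometry stage fills it). ``rtv_excluded`` lists patients without a
    usable residual volume.
    """

    df: pd.DataFrame
    rtv_excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    survival_days=int(row["survival_days"]),
                    event=int(row["event"]),
                    age_years=float(row["age_years"]),
                    sex=row["sex"],
                    kps_at_least_70=int(row["kps_at_least_70"]),
                    biopsy_only=int(row["biopsy_only"]),
                    radiochemo=int(row["radiochemo"]),
                    preop_volume_ml=float(row["preop_volume_ml"]),
                    residual_ce_volume_ml=(
                        None
                        if pd.isna(row["residual_ce_volume_ml"])
                        else float(row["residual_ce_volume_ml"])
                    ),
                )
            )
        return out

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        t6_days: int = DAYS_6_MONTHS,
        t24_days: int = DAYS_24_MONTHS,
    ) -> "CohortRegistry":
        df = df.copy().reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise RegistrySchemaError(f"missing required columns: {missing}")

        errors: list[str] = []
        numeric = [
            "survival_days",
            "event",
            "age_years",
            "kps_at_least_70",
            "biopsy_only",
            "radiochemo",
            "preop_volume_ml",
            "residual_ce_volume_ml",
        ]
        for col in numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            for i in bad:
                errors.append(f"row {i + 1}: non-numeric {col} ({df.at[i, col]!r})")
            df[col] = coerced

        dup = df["patient_id"].astype(str)
        dupes = dup[dup.duplicated()].unique()
        if len(dupes):
            errors.append(f"duplicate patient_id values: {sorted(dupes)}")
        df["patient_id"] = dup

        for i, row in df.iterrows():
            if pd.isna(row["survival_days"]) or row["survival_days"] < 0:
                errors.append(f"row {i + 1}: survival_days must be >= 0")
            if not pd.isna(row["event"]) and row["event"] not in (0, 1):
                errors.append(f"row {i + 1}: event must be 0 or 1")
            if pd.isna(row["preop_volume_ml"]) or row["preop_volume_ml"] <= 0:
                errors.append(f"row {i + 1}: preop_volume_ml must be > 0")
            sex = str(row["sex"]).strip().lower()
            if sex not in ("female", "male"):
                errors.append(f"row {i + 1}: sex must be female/male, got {row['sex']!r}")
            else:
                df.at[i, "sex"] = sex
            for col in ("kps_at_least_70", "biopsy_only", "radiochemo"):
                if not pd.isna(row[col]) and row[col] not in (0, 1):
                    errors.append(f"row {i + 1}: {col} must be 0 or 1")
        if errors:
            raise RegistryValidationError(errors)

        df["survival_days"] = df["survival_days"].astype(int)
        for col in ("event", "kps_at_least_70", "biopsy_only", "radiochemo"):
            df[col] = df[col].astype(int)

        registry = cls(df=df)
        registry._derive(t6_days=t6_days, t24_days=t24_days)
        return registry

    def _derive(self, t6_days: int, t24_days: int) -> None:
        df = self.df
        groups, rtvs, bins = [], [], []
        excluded: list[str] = []
        for rec in self.records:
            grp = assign_os_group(rec.survival_days, rec.event, t6_days, t24_days)
            if grp is OSGroup.UNASSIGNABLE:
                logger.warning(
                    "patient %s censored at %d days (<= %d): OS group unassignable, "
                    "excluded from maps",
                    rec.patient_id,
                    rec.survival_days,
                    t24_days,
                )
            groups.append(grp.value)
            rtv = derive_rtv(rec)
            if rtv is None:
                excluded.append(rec.patient_id)
                rtvs.append(np.nan)
                bins.append(None)
            else:
                rtvs.append(rtv)
                bins.append(bin_rtv(rtv).value)
        df["os_group"] = groups
        df["rtv_ml"] = rtvs
        df["rtv_bin"] = pd.Categorical(bins, categories=RTV_BIN_CATEGORIES, ordered=True)
        if "tvtb_cm" not in df.columns:
            df["tvtb_cm"] = np.nan
        self.rtv_excluded = excluded

    def os_group_ids(self, group: OSGroup | str) -> list[str]:
        value = OSGroup(group).value
        return list(self.df.loc[self.df["os_group"] == value, "patient_id"])

    def set_tvtb(self, tvtb_by_patient: dict[str, float]) -> None:
        self.df["tvtb_cm"] = self.df["patient_id"].map(tvtb_by_patient)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _load_schema_config(schema_config) -> dict:
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        payload = yaml.safe_load(Path(schema_config).read_text())
        return payload.get("columns", payload) or {}
    return dict(schema_config)


def load_registry(path, schema_config=None) -> CohortRegistry:
    """Load and validate a clinical registry CSV.

    ``schema_config`` maps canonical column names to the file's column
    names (dict, or path to a YAML file with a ``columns:`` mapping).
    Missing values are empty cells; rows violating invariants raise
    :class:`RegistryValidationError` naming the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = _load_schema_config(schema_config)
    df = pd.read_csv(path)
    rename = {src: canon for canon, src in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)
    return CohortRegistry.from_dataframe(df)


def summarize(registry: CohortRegistry) -> dict:
    """Cohort descriptives: group sizes and key percentages."""
    df = registry.df
    n = len(df)
    out: dict = {"n": n}
    counts = df["os_group"].value_counts()
    for grp in OSGroup:
        k = int(counts.get(grp.value, 0))
        out[f"n_{grp.value.lower()}"] = k
        out[f"pct_{grp.value.lower()}"] = 100.0 * k / n if n else np.nan
    n_resected = int((df["biopsy_only"] == 0).sum())
    out["n_resected"] = n_resected
    out["pct_resected"] = 100.0 * n_resected / n if n else np.nan
    out["median_survival_days"] = float(df["survival_days"].median())
    out["median_preop_volume_ml"] = float(df["preop_volume_ml"].median())
    return out
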