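"""Survival and treatment regressions on the derived registry.

Models mirror the clinical analysis stage: a Cox proportional-hazards
model for overall survival (with an age x TVTB interaction screened at
p <= 0.01), binomial logistic models for biopsy-only and adjuvant
radiochemotherapy, and a proportional-odds (ordered logistic) model on
5-mL residual-volume bins in resected patients. Candidate covariates are
screened univariably at p <= 0.1 before entering the multivariable model.
All confidence intervals are Wald intervals on the log scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.miscmodels.ordinal_model import OrderedModel
import statsmodels.api as sm

from .cohort import CohortRegistry, RTV_BIN_CATEGORIES

__all__ = [
    "ModelSpec",
    "HazardModelResult",
    "OddsRatioResult",
    "ScreeningResult",
    "ModelFitError",
    "univariable_screen",
    "fit_cox_os",
    "fit_binomial",
    "fit_ordered",
    "combined_hr_tvtb",
    "DEFAULT_CANDIDATES",
]

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = {
    "os": [
        "age_years",
        "sex",
        "kps_at_least_70",
        "preop_volume_ml",
        "tvtb_cm",
        "biopsy_only",
        "rtv_ml",
        "radiochemo",
    ],
    "biopsy_only": ["age_years", "sex", "kps_at_least_70", "preop_volume_ml", "tvtb_cm"],
    "radiochemo": [
        "age_years",
        "sex",
        "kps_at_least_70",
        "preop_volume_ml",
        "tvtb_cm",
        "biopsy_only",
        "rtv_ml",
    ],
    "rtv_bin": ["age_years", "sex", "kps_at_least_70", "preop_volume_ml", "tvtb_cm"],
}


class ModelFitError(RuntimeError):
    """A model failed to converge (e.g. separation); carries diagnostics."""


@dataclass
class ModelSpec:
    """What to fit: outcome, candidate covariates and screening thresholds."""

    outcome: str = "os"
    candidate_covariates: list[str] = field(default_factory=list)
    interaction_terms: list[tuple[str, str]] = field(default_factory=list)
    screening_alpha: float = 0.1
    interaction_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.outcome not in ("os", "biopsy_only", "radiochemo", "rtv_bin"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.candidate_covariates:
            self.candidate_covariates = list(DEFAULT_CANDIDATES[self.outcome])
        if self.outcome == "os" and not self.interaction_terms:
            self.interaction_terms = [("age_years", "tvtb_cm")]
        if self.outcome in self.candidate_covariates:
            raise ValueError("outcome cannot also be a covariate")


@dataclass
class ScreeningResult:
    """Univariable screening outcome: retained covariates and the p table."""

    retained: list[str]
    table: pd.DataFrame

    def __iter__(self):
        return iter(self.retained)


@dataclass
class HazardModelResult:
    """Fitted hazard model: per-term coefficients, HRs and Wald CIs.

    ``summary`` is indexed by term with columns coef, hr, ci_low, ci_high, p.
    """

    summary: pd.DataFrame
    n_used: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)
    screening: pd.DataFrame | None = None

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    @property
    def terms(self) -> list[str]:
        return list(self.summary.index)

    @classmethod
    def from_hazard_ratios(cls, hazard_ratios: dict[str, float]) -> "HazardModelResult":
        """Build a result from published hazard ratios (for desk use, e.g.
        evaluating age-conditional combined HRs from a reported table)."""
        rows = {
            term: {
                "coef": float(np.log(hr)),
                "hr": float(hr),
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
            }
            for term, hr in hazard_ratios.items()
        }
        return cls(summary=pd.DataFrame.from_dict(rows, orient="index"))

    def to_csv(self, path) -> None:
        self.summary.rename_axis("term").to_csv(path)


@dataclass
class OddsRatioResult:
    """Fitted logistic/ordered-logistic model: per-term ORs and Wald CIs."""

    summary: pd.DataFrame
    n_used: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)
    screening: pd.DataFrame | None = None

    def odds_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "or"])

    def to_csv(self, path) -> None:
        self.summary.rename_axis("term").to_csv(path)


def _interaction_name(a: str, b: str) -> str:
    return f"{a}_x_{b}"


def _numeric_frame(registry: CohortRegistry, columns: list[str]) -> pd.DataFrame:
    df = registry.df.copy()
    if "sex" in columns:
        df["sex"] = (df["sex"] == "male").astype(int)
    return df[columns]


def _check_not_constant(df: pd.DataFrame, covariates: list[str]) -> None:
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant in the analysis sample")


def _cox_fit(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="survival_days", event_col="event")
    except ConvergenceError as err:
        design = df.drop(columns=["survival_days", "event"]).to_numpy(dtype=float)
        cond = float(np.linalg.cond(design))
        raise ModelFitError(
            f"Cox model failed to converge (design condition number {cond:.3g}): {err}"
        ) from err
    return cph


def _logit_fit(endog, exog):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(endog, exog).fit(disp=0, maxiter=200)
    except Exception as err:  # statsmodels raises several separation flavors
        raise ModelFitError(f"logistic model failed to converge: {err}") from err
    if not res.mle_retvals.get("converged", True):
        raise ModelFitError("logistic model failed to converge")
    if np.any(~np.isfinite(res.bse)) or np.any(res.bse > 1e3):
        raise ModelFitError(
            "logistic model shows (quasi-)separation: unbounded standard errors"
        )
    return res


def _ordered_fit(endog, exog):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(endog, exog, distr="logit")
            res = model.fit(method="bfgs", disp=0, maxiter=500)
    except Exception as err:
        raise ModelFitError(f"ordered logistic model failed to converge: {err}") from err
    return res


def _prepare(registry: CohortRegistry, spec: ModelSpec, covariates: list[str]):
    """Analysis frame (outcome columns + covariates), complete cases only."""
    if spec.outcome == "os":
        base_cols = ["survival_days", "event"]
    elif spec.outcome == "rtv_bin":
        base_cols = ["rtv_bin"]
    else:
        base_cols = [spec.outcome]
    df = _numeric_frame(registry, base_cols + covariates)
    excluded: list[tuple[str, str]] = []
    if spec.outcome == "os":
        nonpos = df["survival_days"] <= 0
        excluded += [
            (pid, "non-positive survival time")
            for pid in registry.df.loc[nonpos.to_numpy(), "patient_id"]
        ]
        df = df.loc[~nonpos]
    if spec.outcome == "rtv_bin":
        biopsy = registry.df["biopsy_only"] == 1
        excluded += [
            (pid, "biopsy only") for pid in registry.df.loc[biopsy, "patient_id"]
        ]
        df = df.loc[~biopsy.to_numpy()[df.index]]
    kept_ids = registry.df.loc[df.index, "patient_id"]
    keep = df.notna().all(axis=1)
    excluded += [(pid, "missing data") for pid in kept_ids[~keep]]
    if "rtv_ml" in covariates:
        # mirrors exclusion of patients without post-operative imaging
        excluded = [
            (pid, "missing residual tumor volume" if pid in registry.rtv_excluded else why)
            for pid, why in excluded
        ]
    return df.loc[keep].reset_index(drop=True), excluded


def _fit_single(spec: ModelSpec, df: pd.DataFrame, cov: str) -> float:
    """p-value of one covariate in a single-covariate model of the outcome."""
    if spec.outcome == "os":
        cph = _cox_fit(df[["survival_days", "event", cov]])
        return float(cph.summary.loc[cov, "p"])
    if spec.outcome == "rtv_bin":
        endog = pd.Series(
            pd.Categorical(df["rtv_bin"], categories=RTV_BIN_CATEGORIES, ordered=True)
        ).cat.remove_unused_categories()
        res = _ordered_fit(endog, df[[cov]].reset_index(drop=True))
        return float(res.pvalues[cov])
    res = _logit_fit(df[spec.outcome], sm.add_constant(df[[cov]]))
    return float(res.pvalues[cov])


def univariable_screen(registry: CohortRegistry, spec: ModelSpec) -> ScreeningResult:
    """Fit one single-covariate model per candidate; retain p <= screening_alpha.

    Candidates whose model fails to converge are flagged in the table
    (status 'failed') rather than silently dropped.
    """
    rows = []
    for cov in spec.candidate_covariates:
        df, _ = _prepare(registry, spec, [cov])
        try:
            _check_not_constant(df, [cov])
            p = _fit_single(spec, df, cov)
            status = "ok"
        except (ModelFitError, ValueError) as err:
            logger.warning("univariable screen: %s failed (%s)", cov, err)
            p, status = np.nan, "failed"
        rows.append(
            {
                "candidate": cov,
                "p": p,
                "retained": bool(p <= spec.screening_alpha) if np.isfinite(p) else False,
                "status": status,
                "n_used": len(df),
            }
        )
    if not rows:
        table = pd.DataFrame(
            columns=["p", "retained", "status", "n_used"],
            index=pd.Index([], name="candidate"),
        )
        return ScreeningResult(retained=[], table=table)
    table = pd.DataFrame(rows).set_index("candidate")
    return ScreeningResult(retained=list(table.index[table["retained"]]), table=table)


def _wald_summary_from_cox(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
            "p": s["p"],
        }
    )
    out.index.name = "term"
    return out


def fit_cox_os(
    registry: CohortRegistry,
    spec: ModelSpec | None = None,
    screen: bool = True,
) -> HazardModelResult:
    """Multivariable Cox PH fit for overall survival.

    Candidates are first screened univariably (p <= 0.1); the age x TVTB
    interaction (and any other configured interaction) is tested in the
    multivariable model and kept only at p <= interaction_alpha. Ties are
    handled with the Efron approximation.
    """
    spec = spec or ModelSpec(outcome="os")
    if screen:
        screening = univariable_screen(registry, spec)
        covariates = screening.retained
        screening_table = screening.table
    else:
        covariates = list(spec.candidate_covariates)
        screening_table = None
    if not covariates:
        raise ValueError("no covariates retained for the multivariable model")
    df, excluded = _prepare(registry, spec, covariates)
    _check_not_constant(df, covariates)

    kept_interactions = []
    for a, b in spec.interaction_terms:
        if a not in covariates or b not in covariates:
            continue
        name = _interaction_name(a, b)
        trial = df.copy()
        trial[name] = trial[a] * trial[b]
        cph = _cox_fit(trial)
        p_int = float(cph.summary.loc[name, "p"])
        if p_int <= spec.interaction_alpha:
            df[name] = df[a] * df[b]
            kept_interactions.append(name)
        else:
            logger.info("interaction %s not retained (p = %.3f)", name, p_int)

    cph = _cox_fit(df)
    return HazardModelResult(
        summary=_wald_summary_from_cox(cph),
        n_used=len(df),
        excluded=excluded,
        screening=screening_table,
    )


def combined_hr_tvtb(result: HazardModelResult, age_years: float) -> float:
    """Per-cm hazard ratio of TVTB at a given age.

    With an age x TVTB interaction, the hazard ratio for a 1-cm increase of
    TVTB at age a is HR_tvtb * HR_interaction ** a.
    """
    terms = result.terms
    if "tvtb_cm" not in terms:
        raise ValueError("model has no TVTB main effect")
    inter = [t for t in terms if "tvtb" in t and "age" in t and t != "tvtb_cm"]
    if not inter:
        raise ValueError("model has no age x TVTB interaction term")
    return result.hr("tvtb_cm") * result.hr(inter[0]) ** age_years


def _or_summary(params, bse, pvalues, terms) -> pd.DataFrame:
    z = 1.959963984540054
    rows = {}
    for t in terms:
        rows[t] = {
            "coef": float(params[t]),
            "or": float(np.exp(params[t])),
            "ci_low": float(np.exp(params[t] - z * bse[t])),
            "ci_high": float(np.exp(params[t] + z * bse[t])),
            "p": float(pvalues[t]),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "term"
    return out


def fit_binomial(
    registry: CohortRegistry,
    spec: ModelSpec,
    screen: bool = True,
) -> OddsRatioResult:
    """Multivariable binomial logistic fit (biopsy-only or radiochemotherapy)."""
    if spec.outcome not in ("biopsy_only", "radiochemo"):
        raise ValueError("fit_binomial expects a binary treatment outcome")
    if screen:
        screening = univariable_screen(registry, spec)
        covariates = screening.retained
        screening_table = screening.table
    else:
        covariates = list(spec.candidate_covariates)
        screening_table = None
    if not covariates:
        raise ValueError("no covariates retained for the multivariable model")
    df, excluded = _prepare(registry, spec, covariates)
    outcome = df[spec.outcome]
    if outcome.nunique() <= 1:
        raise ModelFitError(
            f"outcome {spec.outcome!r} is constant: complete separation"
        )
    _check_not_constant(df, covariates)
    res = _logit_fit(outcome, sm.add_constant(df[covariates]))
    return OddsRatioResult(
        summary=_or_summary(res.params, res.bse, res.pvalues, covariates),
        n_used=len(df),
        excluded=excluded,
        screening=screening_table,
    )


def fit_ordered(
    registry: CohortRegistry,
    spec: ModelSpec | None = None,
    screen: bool = True,
) -> OddsRatioResult:
    """Proportional-odds model on the 5-mL RTV bins, resected patients only."""
    spec = spec or ModelSpec(outcome="rtv_bin")
    if spec.outcome != "rtv_bin":
        raise ValueError("fit_ordered expects the rtv_bin outcome")
    if screen:
        screening = univariable_screen(registry, spec)
        covariates = screening.retained
        screening_table = screening.table
    else:
        covariates = list(spec.candidate_covariates)
        screening_table = None
    if not covariates:
        raise ValueError("no covariates retained for the multivariable model")
    df, excluded = _prepare(registry, spec, covariates)
    endog = pd.Series(
        pd.Categorical(df["rtv_bin"], categories=RTV_BIN_CATEGORIES, ordered=True)
    )
    occupied = endog.value_counts()
    empty = [c for c in RTV_BIN_CATEGORIES if occupied.get(c, 0) == 0]
    if empty:
        logger.warning("RTV bins with zero members: %s", empty)
    if (occupied > 0).sum() < 2:
        raise ValueError("fewer than 2 occupied RTV bins; ordered model is degenerate")
    endog = endog.cat.remove_unused_categories()
    _check_not_constant(df, covariates)
    res = _ordered_fit(endog, df[covariates].reset_index(drop=True))
    return OddsRatioResult(
        summary=_or_summary(res.params, res.bse, res.pvalues, covariates),
        n_used=len(df),
        excluded=excluded,
        screening=screening_table,
    )
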