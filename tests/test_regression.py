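import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from tumoratlas.regression import (
    HazardModelResult,
    ModelFitError,
    ModelSpec,
    combined_hr_tvtb,
    fit_binomial,
    fit_cox_os,
    fit_ordered,
    univariable_screen,
)

from .conftest import make_registry, make_registry_frame


# --- combined age-conditional hazard ratio ---------------------------------

PUBLISHED = {"tvtb_cm": 2.406, "age_x_tvtb": 0.983}


def test_combined_hr_at_reported_ages():
    result = HazardModelResult.from_hazard_ratios(PUBLISHED)
    assert round(combined_hr_tvtb(result, 60), 2) == 0.86
    assert round(combined_hr_tvtb(result, 80), 2) == 0.61


def test_combined_hr_at_age_zero_is_main_effect():
    result = HazardModelResult.from_hazard_ratios(PUBLISHED)
    assert combined_hr_tvtb(result, 0) == 2.406


def test_combined_hr_monotone_decreasing_when_interaction_below_one():
    result = HazardModelResult.from_hazard_ratios(PUBLISHED)
    ages = np.linspace(20, 90, 15)
    hrs = [combined_hr_tvtb(result, a) for a in ages]
    assert all(a > b for a, b in zip(hrs, hrs[1:]))


def test_combined_hr_requires_interaction():
    result = HazardModelResult.from_hazard_ratios({"tvtb_cm": 2.0})
    with pytest.raises(ValueError, match="interaction"):
        combined_hr_tvtb(result, 60)


def test_hr_equals_exp_coef():
    result = HazardModelResult.from_hazard_ratios(PUBLISHED)
    s = result.summary
    assert np.allclose(s["hr"], np.exp(s["coef"]), rtol=1e-10)


# --- Cox model --------------------------------------------------------------


def _cox_oracle_beta(times, events, x):
    """Maximize the partial likelihood by enumerating risk sets (no ties)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]

    def neg_log_pl(beta):
        ll = 0.0
        for i in range(len(times)):
            if events[i]:
                risk = np.arange(len(times)) >= i
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded")
    return float(res.x)


def test_cox_matches_partial_likelihood_oracle_on_tiny_instance():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.ones(6, dtype=int)
    x = np.array([1, 0, 1, 0, 0, 1])
    reg = make_registry(
        6,
        survival_days=times.astype(int),
        event=events,
        biopsy_only=x,
    )
    spec = ModelSpec(outcome="os", candidate_covariates=["biopsy_only"], interaction_terms=[])
    result = fit_cox_os(reg, spec, screen=False)
    beta_oracle = _cox_oracle_beta(times, events, x.astype(float))
    assert result.summary.loc["biopsy_only", "coef"] == pytest.approx(beta_oracle, abs=1e-4)


def test_cox_constant_covariate_raises():
    reg = make_registry(30, kps_at_least_70=np.ones(30, dtype=int))
    spec = ModelSpec(outcome="os", candidate_covariates=["kps_at_least_70"], interaction_terms=[])
    with pytest.raises(ValueError, match="kps_at_least_70"):
        fit_cox_os(reg, spec, screen=False)


def test_cox_null_data_gives_unit_hazard_ratios():
    rng = np.random.default_rng(8)
    n = 600
    reg = make_registry(
        n,
        rng=rng,
        survival_days=np.maximum(1, rng.exponential(400, size=n).astype(int)),
        event=np.ones(n, dtype=int),
    )
    spec = ModelSpec(
        outcome="os", candidate_covariates=["age_years", "preop_volume_ml"], interaction_terms=[]
    )
    result = fit_cox_os(reg, spec, screen=False)
    for term in ("age_years", "preop_volume_ml"):
        lo, hi = result.summary.loc[term, ["ci_low", "ci_high"]]
        assert lo <= 1.0 <= hi


def test_cox_single_replicate_parameter_recovery():
    import tumoratlas as ta

    coefs = {"age_years": 0.079, "tvtb_cm": 0.6, "age_x_tvtb": -0.012}
    cfg = ta.SimulationConfig(seed=500, n_patients=2000, hazard_coefs=coefs)
    _, reg, _ = ta.generate_cohort(cfg)
    spec = ModelSpec(
        outcome="os",
        candidate_covariates=["age_years", "tvtb_cm"],
        interaction_terms=[("age_years", "tvtb_cm")],
    )
    result = fit_cox_os(reg, spec, screen=False)
    s = result.summary
    assert np.log(s.loc["age_years", "ci_low"]) <= coefs["age_years"] <= np.log(
        s.loc["age_years", "ci_high"]
    )
    assert "age_years_x_tvtb_cm" in result.terms


# --- univariable screening ---------------------------------------------------


def test_screen_retains_strong_and_reports_table():
    rng = np.random.default_rng(12)
    n = 400
    age = rng.normal(65, 10, size=n)
    days = np.maximum(1, rng.exponential(400 * np.exp(-0.06 * (age - 65)), size=n)).astype(int)
    reg = make_registry(n, rng=rng, survival_days=days, event=np.ones(n, dtype=int), age_years=age)
    spec = ModelSpec(outcome="os", candidate_covariates=["age_years", "sex"], interaction_terms=[])
    screening = univariable_screen(reg, spec)
    assert "age_years" in screening.retained
    assert set(screening.table.index) == {"age_years", "sex"}


def test_screen_null_covariate_retained_near_alpha_rate():
    """A covariate independent of the outcome is retained at roughly the
    screening level (p <= 0.1 -> ~10% of replicates)."""
    rng = np.random.default_rng(99)
    n, reps, hits = 400, 100, 0
    spec = ModelSpec(outcome="os", candidate_covariates=["age_years"], interaction_terms=[])
    for _ in range(reps):
        reg = make_registry(
            n,
            rng=rng,
            survival_days=np.maximum(1, rng.exponential(400, size=n).astype(int)),
            event=np.ones(n, dtype=int),
            age_years=rng.normal(65, 10, size=n),
        )
        hits += "age_years" in univariable_screen(reg, spec).retained
    # binomial 99.9% band around 0.1 at 100 replicates
    assert 1 <= hits <= 21


def test_screen_empty_candidates():
    reg = make_registry(20)
    spec = ModelSpec(outcome="os", candidate_covariates=["age_years"], interaction_terms=[])
    spec.candidate_covariates = []
    assert univariable_screen(reg, spec).retained == []


# --- binomial logistic -------------------------------------------------------


def test_binomial_recovers_planted_odds_ratio():
    rng = np.random.default_rng(31)
    n = 1500
    age = rng.normal(65, 10, size=n)
    beta = 0.07  # OR per year ~ 1.073
    p = 1 / (1 + np.exp(-(-0.5 + beta * (age - 65))))
    outcome = (rng.random(n) < p).astype(int)
    reg = make_registry(n, rng=rng, age_years=age, biopsy_only=outcome)
    spec = ModelSpec(outcome="biopsy_only", candidate_covariates=["age_years"])
    result = fit_binomial(reg, spec, screen=False)
    lo, hi = result.summary.loc["age_years", ["ci_low", "ci_high"]]
    assert lo <= np.exp(beta) <= hi


def test_binomial_constant_outcome_is_separation_error():
    reg = make_registry(40, biopsy_only=np.ones(40, dtype=int))
    spec = ModelSpec(outcome="biopsy_only", candidate_covariates=["age_years"])
    with pytest.raises(ModelFitError):
        fit_binomial(reg, spec, screen=False)


def test_binomial_perfectly_separating_covariate_raises():
    rng = np.random.default_rng(2)
    n = 60
    age = np.r_[rng.uniform(30, 50, n // 2), rng.uniform(70, 90, n // 2)]
    outcome = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
    reg = make_registry(n, rng=rng, age_years=age, biopsy_only=outcome)
    spec = ModelSpec(outcome="biopsy_only", candidate_covariates=["age_years"])
    with pytest.raises(ModelFitError):
        fit_binomial(reg, spec, screen=False)


# --- ordered logistic --------------------------------------------------------


def _rtv_registry(n, rng):
    preop = rng.uniform(2, 120, size=n)
    frac = rng.beta(1.2, 6, size=n)
    df = make_registry_frame(
        n,
        rng=rng,
        biopsy_only=(rng.random(n) < 0.15).astype(int),
        preop_volume_ml=preop,
    )
    df["residual_ce_volume_ml"] = preop * frac
    df.loc[df["biopsy_only"] == 1, "residual_ce_volume_ml"] = np.nan
    from tumoratlas.cohort import CohortRegistry

    return CohortRegistry.from_dataframe(df)


def test_ordered_excludes_biopsy_only_and_recovers_direction():
    rng = np.random.default_rng(14)
    reg = _rtv_registry(400, rng)
    spec = ModelSpec(outcome="rtv_bin", candidate_covariates=["preop_volume_ml"])
    result = fit_ordered(reg, spec, screen=False)
    n_biopsy = int((reg.df["biopsy_only"] == 1).sum())
    assert result.n_used <= 400 - n_biopsy
    assert any(why == "biopsy only" for _, why in result.excluded)
    # larger preoperative tumors leave larger residuals
    assert result.odds_ratio("preop_volume_ml") > 1.0
    lo, hi = result.summary.loc["preop_volume_ml", ["ci_low", "ci_high"]]
    assert lo > 1.0 or (lo <= 1.0 <= hi)


def test_ordered_null_covariate_ci_covers_one():
    rng = np.random.default_rng(40)
    reg = _rtv_registry(500, rng)
    spec = ModelSpec(outcome="rtv_bin", candidate_covariates=["age_years"])
    result = fit_ordered(reg, spec, screen=False)
    lo, hi = result.summary.loc["age_years", ["ci_low", "ci_high"]]
    assert lo <= 1.0 <= hi


def test_ordered_single_bin_is_degenerate():
    rng = np.random.default_rng(3)
    df = make_registry_frame(30, rng=rng, biopsy_only=np.zeros(30, dtype=int))
    df["residual_ce_volume_ml"] = 1.0  # everyone in the first bin
    from tumoratlas.cohort import CohortRegistry

    reg = CohortRegistry.from_dataframe(df)
    spec = ModelSpec(outcome="rtv_bin", candidate_covariates=["age_years"])
    with pytest.raises(ValueError, match="occupied"):
        fit_ordered(reg, spec, screen=False)
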