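"""Case construction and lognormal AFT fitting, effects, and screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from morbtraj import (
    build_cases,
    fit_aft,
    fit_trajectory_models,
    fold_change,
    normalize_records,
    results_frame,
    screen_high_risk,
)
from morbtraj.survival import HORIZON_DAYS, MORTALITY, REHOSP
from morbtraj.trajectories import Trajectory


@pytest.fixture()
def six_patient_cohort(catalog):
    """Hand-written outcome fixture around a presenting I20 diagnosis.

    s1: only the presenting admission, long follow-up, alive
    s2: dies 100 days post-presentation, no later admission
    s3: readmitted at day 30, alive
    s4: prior history (E10), readmitted day 400 (beyond horizon)
    s5: dies day 10; readmission record at day 20 must be impossible -> none
    s6: presents on its second admission day, co-presenting diagnosis
    """
    rows = [
        ("s1", "female", "I20", "2010-01-01"),
        ("s2", "female", "I20", "2010-01-01"),
        ("s3", "female", "I20", "2010-01-01"),
        ("s3", "female", "J45", "2010-01-31"),  # readmission day 30
        ("s4", "female", "E10", "2009-01-01"),
        ("s4", "female", "I20", "2010-01-01"),
        ("s4", "female", "K21", "2011-02-05"),  # day 400
        ("s5", "female", "I20", "2010-01-01"),
        ("s6", "female", "M54", "2009-06-01"),
        ("s6", "female", "I20", "2010-01-01"),
        ("s6", "female", "E10", "2010-01-01"),  # co-presenting
    ]
    raw = pd.DataFrame(rows, columns=["patient_id", "sex", "icd10_code", "diagnosis_date"])
    meta = pd.DataFrame(
        {
            "patient_id": [f"s{i}" for i in range(1, 7)],
            "sex": ["female"] * 6,
            "age_at_assessment": [50] * 6,
            "assessment_date": ["2010-01-01"] * 6,
            "death_date": [pd.NaT, "2010-04-11", pd.NaT, pd.NaT, "2010-01-11", pd.NaT],
            "followup_end": ["2011-02-05", "2012-01-01", "2012-01-01", "2012-01-01", "2010-01-11", "2012-01-01"],
        }
    )
    return normalize_records(raw, catalog, tie_seed=0, meta=meta)


class TestBuildCases:
    def test_mortality_tabulation(self, six_patient_cohort):
        cases = build_cases(six_patient_cohort, "I20-I25", MORTALITY).set_index("patient_id")
        # s2 dies at day 100 -> event
        assert cases.loc["s2", "event"] and cases.loc["s2", "time_days"] == 100
        # s1 censored at min(followup=400, horizon=365.25)
        assert not cases.loc["s1", "event"]
        assert cases.loc["s1", "time_days"] == pytest.approx(HORIZON_DAYS)
        # s5 dies day 10
        assert cases.loc["s5", "event"] and cases.loc["s5", "time_days"] == 10

    def test_rehospitalisation_tabulation(self, six_patient_cohort):
        cases = build_cases(six_patient_cohort, "I20-I25", REHOSP).set_index("patient_id")
        # s3 readmitted at day 30
        assert cases.loc["s3", "event"] and cases.loc["s3", "time_days"] == 30
        # s4's next admission is at day 400, beyond the horizon -> censored
        assert not cases.loc["s4", "event"]
        assert cases.loc["s4", "time_days"] == pytest.approx(HORIZON_DAYS)
        # s2 dies at day 100 with no readmission -> censored at death
        assert not cases.loc["s2", "event"]
        assert cases.loc["s2", "time_days"] == 100
        # full-follow-up mode sees s4's day-400 readmission
        full = build_cases(six_patient_cohort, "I20-I25", REHOSP, horizon_days=None).set_index("patient_id")
        assert full.loc["s4", "event"] and full.loc["s4", "time_days"] == 400

    def test_n_prior_counts_and_history_adjustment(self, six_patient_cohort):
        cases = build_cases(six_patient_cohort, "I20-I25", MORTALITY).set_index("patient_id")
        assert cases.loc["s1", "n_prior"] == 0
        assert cases.loc["s4", "n_prior"] == 1  # E10 history
        assert cases.loc["s6", "n_prior"] == 2  # M54 history + co-presenting E10
        with_hist = build_cases(
            six_patient_cohort, "I20-I25", MORTALITY, histories=("E10-E14",)
        ).set_index("patient_id")
        assert with_hist.loc["s4", "hist_E10-E14"] == 1
        assert with_hist.loc["s4", "n_prior"] == 0  # history no longer double-counted
        assert with_hist.loc["s6", "hist_E10-E14"] == 1  # co-presenting counts
        assert with_hist.loc["s6", "n_prior"] == 1

    def test_rehosp_events_never_after_death(self, six_patient_cohort):
        cases = build_cases(six_patient_cohort, "I20-I25", REHOSP).set_index("patient_id")
        meta = six_patient_cohort.meta.set_index("patient_id")
        for pid, row in cases.iterrows():
            death = meta.loc[pid, "death_date"]
            if pd.notna(death) and row["event"]:
                pres = pd.Timestamp("2010-01-01")
                assert pres + pd.Timedelta(days=row["time_days"]) <= death


@pytest.mark.parametrize(
    "beta, expected",
    [(0.0, 1.0), (-np.log(1.5), 1.5), (np.log(2.0), 0.5)],
)
def test_fold_change_point_estimates(beta, expected):
    fold, lo, hi = fold_change(beta, 0.0)
    assert fold == pytest.approx(expected)
    assert lo <= fold <= hi


def test_fold_change_ci_formula():
    fold, lo, hi = fold_change(-0.2, 0.05)
    z = stats.norm.ppf(0.975)
    assert lo == pytest.approx(np.exp(0.2 - z * 0.05))
    assert hi == pytest.approx(np.exp(0.2 + z * 0.05))
    # sign convention: risk-raising covariate (beta < 0) has fold > 1
    assert fold > 1


def _random_censored_cases(rng, n=80, beta=(-0.3, 0.2)):
    x1, x2 = rng.normal(size=n), rng.binomial(1, 0.4, n).astype(float)
    log_t = 5.0 + beta[0] * x1 + beta[1] * x2 + 0.8 * rng.standard_normal(n)
    t = np.exp(log_t)
    c = np.exp(5.0 + 0.8 * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "time_days": np.minimum(t, c),
            "event": t <= c,
            "sex": "female",
        }
    )


def lognormal_aft_mle(df, covariates):
    """Independent oracle: direct optimisation of the right-censored
    lognormal log-likelihood with scipy (no lifelines)."""
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in covariates])
    t = df["time_days"].to_numpy()
    d = df["event"].to_numpy().astype(bool)

    def nll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        z = (np.log(t) - X @ beta) / sigma
        ll = np.where(d, stats.norm.logpdf(z) - np.log(sigma * t), stats.norm.logsf(z))
        return -ll.sum()

    theta0 = np.zeros(X.shape[1] + 1)
    theta0[0] = np.log(t).mean()
    res = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return res.x[1:-1]  # slopes only


class TestFitAFT:
    def test_matches_independent_likelihood_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            df = _random_censored_cases(rng)
            ours = fit_aft(df, ("x1", "x2"))
            oracle = lognormal_aft_mle(df, ["x1", "x2"])
            got = ours.coefficients["beta"].to_numpy()
            # 1e-4 relative, with an equal absolute floor for near-zero slopes
            np.testing.assert_allclose(got, oracle, rtol=1e-4, atol=1e-4)

    def test_duplicated_data_halves_variance(self):
        rng = np.random.default_rng(1)
        df = _random_censored_cases(rng, n=150)
        doubled = pd.concat([df, df], ignore_index=True)
        r1 = fit_aft(df, ("x1", "x2"))
        r2 = fit_aft(doubled, ("x1", "x2"))
        np.testing.assert_allclose(
            r1.coefficients["beta"], r2.coefficients["beta"], rtol=1e-5
        )
        np.testing.assert_allclose(
            r2.coefficients["se"], r1.coefficients["se"] / np.sqrt(2), rtol=1e-4
        )

    def test_intercept_only_reduces_to_closed_form(self):
        rng = np.random.default_rng(2)
        t = np.exp(4.0 + 0.5 * rng.standard_normal(200))
        df = pd.DataFrame({"time_days": t, "event": True, "sex": "female"})
        res = fit_aft(df, ())
        # no censoring: MLE is the sample mean / (biased) SD of log times
        assert res.intercept == pytest.approx(np.log(t).mean(), abs=1e-4)
        assert res.sigma == pytest.approx(np.log(t).std(), rel=1e-3)
        assert np.exp(res.intercept) == pytest.approx(np.median(t), rel=0.1)

    def test_sign_convention_risk_covariate_shortens_time(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = np.exp(5.0 - 0.7 * x + 0.5 * rng.standard_normal(n))
        df = pd.DataFrame({"x1": x, "time_days": t, "event": True, "sex": "female"})
        res = fit_aft(df, ("x1",))
        assert res.coefficients.loc["x1", "beta"] < 0
        assert res.coefficients.loc["x1", "fold"] > 1

    def test_no_events_raises(self):
        df = pd.DataFrame({"x1": [0.0, 1.0], "time_days": [10.0, 20.0], "event": [False, False]})
        with pytest.raises(ValueError):
            fit_aft(df, ("x1",))


class TestTrajectoryModels:
    def test_multi_history_n_prior_adjustment(self, six_patient_cohort):
        # length-3 history: a patient with both histories has 2 (histories)
        # + 1 (presenting) subtracted from raw prior count
        cases = build_cases(
            six_patient_cohort, "I20-I25", MORTALITY, histories=("M40-M54", "E10-E14")
        ).set_index("patient_id")
        raw_prior = {"s6": 3}  # M54, E10 and I20 itself by presentation date
        assert cases.loc["s6", "hist_M40-M54"] == 1
        assert cases.loc["s6", "hist_E10-E14"] == 1
        assert cases.loc["s6", "n_prior"] == raw_prior["s6"] - 3

    def test_planted_history_fold_recovered(self, catalog):
        from morbtraj.simulate import (
            AFTTruth, PlantedPair, SimConfig, apply_outcomes, generate_records,
            simulate_outcomes,
        )

        truth = {
            "I20-I25": {
                MORTALITY: AFTTruth(beta_history={"I10-I15": -np.log(2.0)}),
            }
        }
        cfg = SimConfig(
            n_female=6000, n_male=0, death_lognormal=None,
            planted_pairs=[PlantedPair("I10-I15", "I20-I25", 0.15, 0.9, 300.0)],
            aft_truth=truth, seed=41,
        )
        sim = generate_records(cfg)
        cohort = normalize_records(sim.raw_events, catalog, tie_seed=0, meta=sim.meta)
        out = simulate_outcomes(cohort, truth, seed=41, horizon_days=None)
        cohort = apply_outcomes(cohort, out[out["outcome"] == MORTALITY])
        traj = Trajectory(("I10-I15", "I20-I25"), support=0, step_p_adjusted=(0.01,), median_gaps_years=(0.5,))
        results = fit_trajectory_models(cohort, [traj], MORTALITY)
        assert len(results) == 1
        row = results[0].coefficients.loc["hist_I10-I15"]
        assert row["ci_low"] <= 2.0 <= row["ci_high"]
        assert row["fold"] == pytest.approx(2.0, rel=0.35)


class TestScreening:
    def _frame(self, folds, ps, outcome=REHOSP):
        results_rows = []
        for i, (f, p) in enumerate(zip(folds, ps)):
            results_rows.append(
                {
                    "presenting_block": "I20-I25",
                    "outcome": outcome,
                    "sex": "female",
                    "covariate": f"hist_B{i:02d}-B{i:02d}",
                    "beta": -np.log(f),
                    "se": 0.1,
                    "p": p,
                    "fold": f,
                    "ci_low": f * 0.9,
                    "ci_high": f * 1.1,
                    "n": 100,
                    "n_events": 40,
                    "converged": True,
                    "p_adj": p,
                }
            )
        return pd.DataFrame(results_rows)

    def test_threshold_filtering(self):
        frame = self._frame([1.4, 1.6], [0.001, 0.001])
        kept = screen_high_risk(frame)
        assert list(kept["fold"]) == [1.6]

    def test_zero_threshold_keeps_all_significant(self):
        frame = self._frame([1.4, 1.6], [0.001, 0.5])
        kept = screen_high_risk(frame, rehosp_fold_min=0.0)
        assert list(kept["fold"]) == [1.4]  # the 1.6 row is not significant

    def test_empty_input(self):
        assert screen_high_risk(pd.DataFrame()).empty

    def test_cancer_flag(self):
        frame = self._frame([3.0], [0.001], outcome=MORTALITY)
        frame.loc[0, "covariate"] = "hist_C76-C80"
        kept = screen_high_risk(frame)
        assert kept["cancer_history"].tolist() == [True]
        frame.loc[0, "covariate"] = "hist_I10-I15"
        kept = screen_high_risk(frame)
        assert kept["cancer_history"].tolist() == [False]
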