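"""Lognormal accelerated-failure-time screening of prior-multimorbidity risk.

For each presenting diagnosis, outcome (1-year mortality or
re-hospitalisation) and sex, a lognormal AFT model is fitted to the time from
presentation to the outcome, right-censored at end of follow-up (and at death
for re-hospitalisation) and administratively at a 1-year horizon:

    log T = mu + beta_age * age + beta_mm * n_prior + sum_h beta_h * I_h + eps,
    eps ~ Normal(0, sigma^2)

``n_prior`` is the count of distinct prior/co-presenting diagnosis blocks
minus one for the presenting diagnosis (and minus one per tested history a
patient carries, when history indicators are included, so burden is not
double-counted).  A negative coefficient shortens time-to-event; effects are
reported as the per-unit fold increase in risk exp(-beta) with Wald CIs.
Multi-history effects (with pairwise interactions for trajectories longer
than 2) are combined by summing coefficients before exponentiating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import LogNormalAFTFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .records import Cohort, age_at_diagnosis
from .trajectories import Trajectory, holm_adjust

__all__ = [
    "build_cases",
    "fit_aft",
    "fold_change",
    "fit_trajectory_models",
    "screen_high_risk",
    "results_frame",
    "AFTResult",
    "HORIZON_DAYS",
]

logger = logging.getLogger(__name__)

#: Administrative 1-year horizon in days.
HORIZON_DAYS = 365.25
#: Same-day events are shifted to half a day to keep log-times finite.
MIN_TIME_DAYS = 0.5

MORTALITY, REHOSP = "mortality", "rehospitalisation"


def build_cases(
    cohort: Cohort,
    presenting_block: str,
    outcome: str,
    horizon_days: float | None = HORIZON_DAYS,
    histories: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One row per patient presenting with *presenting_block*.

    Columns: ``age`` (years at presentation), ``n_prior`` (distinct blocks
    dated at or before presentation, minus 1 for the presenting diagnosis and
    minus 1 per carried tested history), one ``hist_<block>`` indicator per
    requested history, ``time_days`` and ``event``.

    Mortality time runs to death, censored at follow-up end and the horizon;
    re-hospitalisation time runs to the first admission strictly after the
    presentation date (from the unfiltered admission stream), censored at
    death, follow-up end and the horizon.  ``horizon_days=None`` disables the
    administrative horizon (full-follow-up mode).
    """
    if outcome not in (MORTALITY, REHOSP):
        raise ValueError(f"outcome must be {MORTALITY!r} or {REHOSP!r}")
    ev = cohort.events
    pres = ev[ev["block_id"] == presenting_block]
    if pres.empty:
        return pd.DataFrame()
    meta = cohort.meta.set_index("patient_id")
    pres = pres.set_index("patient_id")
    pids = pres.index
    pres_date = pd.DatetimeIndex(pres["diagnosis_date"])
    m = meta.loc[pids]

    age = age_at_diagnosis(
        m["age_at_assessment"].to_numpy(),
        pd.DatetimeIndex(m["assessment_date"]),
        pres_date,
    )

    sub = ev[ev["patient_id"].isin(pids)].merge(
        pres["diagnosis_date"].rename("presentation_date"), on="patient_id"
    )
    prior = sub[sub["diagnosis_date"] <= sub["presentation_date"]]
    n_prior = (
        prior.groupby("patient_id")["block_id"].nunique().reindex(pids).fillna(1) - 1
    )
    hist_cols = {}
    for h in histories:
        carried = prior.loc[prior["block_id"] == h, "patient_id"].unique()
        hist_cols[f"hist_{h}"] = pids.isin(carried).astype(float)
        n_prior = n_prior - hist_cols[f"hist_{h}"]

    followup = (pd.DatetimeIndex(m["followup_end"]) - pres_date).days.astype(float)
    death = (pd.DatetimeIndex(m["death_date"]) - pres_date).days.astype(float)
    censor = followup.copy()
    if horizon_days is not None:
        censor = np.minimum(censor, horizon_days)
    if outcome == MORTALITY:
        time = np.where(np.isnan(death), censor, np.minimum(death, censor))
        event = ~np.isnan(death) & (death <= censor)
    else:
        if cohort.admissions is None:
            raise ValueError("cohort has no admission stream for re-hospitalisation")
        adm = cohort.admissions[cohort.admissions["patient_id"].isin(pids)].merge(
            pres["diagnosis_date"].rename("presentation_date"), on="patient_id"
        )
        nxt = (
            adm[adm["admission_date"] > adm["presentation_date"]]
            .groupby("patient_id")["admission_date"]
            .min()
        )
        readmit = (pd.DatetimeIndex(nxt.reindex(pids)) - pres_date).days.astype(float)
        censor = np.where(np.isnan(death), censor, np.minimum(death, censor))
        time = np.where(np.isnan(readmit), censor, np.minimum(readmit, censor))
        event = ~np.isnan(readmit) & (readmit <= censor)

    n_shifted = int((time < MIN_TIME_DAYS).sum())
    if n_shifted:
        logger.info(
            "%s/%s: %d non-positive event times shifted to %.1f days",
            presenting_block, outcome, n_shifted, MIN_TIME_DAYS,
        )
    cases = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": m["sex"].to_numpy(),
            "age": np.asarray(age, dtype=float),
            "n_prior": np.maximum(n_prior.to_numpy(dtype=float), 0.0),
            **hist_cols,
            "time_days": np.maximum(time, MIN_TIME_DAYS),
            "event": event.astype(bool),
        }
    )
    cases.attrs["presenting_block"] = presenting_block
    cases.attrs["outcome"] = outcome
    return cases.reset_index(drop=True)


@dataclass
class AFTResult:
    """Fitted lognormal AFT model for one (presenting block, outcome, sex)."""

    presenting_block: str
    outcome: str
    sex: str
    coefficients: pd.DataFrame  # index covariate: beta, se, p, fold, ci_low, ci_high
    intercept: float
    log_scale: float
    n: int
    n_events: int
    converged: bool
    log_likelihood: float = np.nan
    combined: dict[str, tuple[float, float]] = field(default_factory=dict)
    # combined multi-history effects: name -> (summed beta, fold)

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_scale))


def fold_change(beta: float, se: float, alpha_ci: float = 0.05) -> tuple[float, float, float]:
    """Per-unit fold increase in risk exp(-beta) with a Wald CI (ordered)."""
    z = stats.norm.ppf(1 - alpha_ci / 2)
    fold = np.exp(-beta)
    lo, hi = np.exp(-beta - z * se), np.exp(-beta + z * se)
    return float(fold), float(min(lo, hi)), float(max(lo, hi))


def fit_aft(
    cases: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "n_prior"),
    alpha_ci: float = 0.05,
    presenting_block: str | None = None,
    outcome: str | None = None,
    sex: str | None = None,
) -> AFTResult:
    """Maximum-likelihood lognormal AFT fit of right-censored case times.

    Collinear covariate columns are dropped with a log entry before fitting;
    non-convergence yields a flagged (``converged=False``) result with NaN
    coefficients rather than an exception, so batch screening can skip it.
    """
    if cases.empty or int(cases["event"].sum()) < 1:
        raise ValueError("need at least one observed event to fit an AFT model")
    covariates = list(covariates)
    X = cases[covariates].to_numpy(float)
    design = np.column_stack([np.ones(len(cases)), X])
    rank = np.linalg.matrix_rank(design)
    while rank < design.shape[1] and covariates:
        dropped = covariates.pop()  # drop trailing (interaction) columns first
        logger.info("dropping collinear covariate %s", dropped)
        design = np.column_stack([np.ones(len(cases))] + [cases[c].to_numpy(float) for c in covariates])
        rank = np.linalg.matrix_rank(design)

    stratum = dict(
        presenting_block=presenting_block or cases.attrs.get("presenting_block", ""),
        outcome=outcome or cases.attrs.get("outcome", ""),
        sex=sex or (cases["sex"].iloc[0] if "sex" in cases and cases["sex"].nunique() == 1 else "pooled"),
    )
    df = cases[covariates + ["time_days", "event"]].copy()
    fitter = LogNormalAFTFitter()
    try:
        fitter.fit(df, duration_col="time_days", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("AFT fit failed for %s: %s", stratum, exc)
        coef = pd.DataFrame(
            np.nan, index=covariates, columns=["beta", "se", "p", "fold", "ci_low", "ci_high"]
        )
        return AFTResult(
            **stratum, coefficients=coef, intercept=np.nan, log_scale=np.nan,
            n=len(cases), n_events=int(cases["event"].sum()), converged=False,
        )

    params = fitter.params_["mu_"]
    ses = fitter.standard_errors_["mu_"]
    pvals = fitter.summary.loc["mu_"]["p"]
    rows = {}
    for cov in covariates:
        beta, se = float(params[cov]), float(ses[cov])
        fold, lo, hi = fold_change(beta, se, alpha_ci)
        rows[cov] = dict(beta=beta, se=se, p=float(pvals[cov]), fold=fold, ci_low=lo, ci_high=hi)
    cols = ["beta", "se", "p", "fold", "ci_low", "ci_high"]
    coef = (
        pd.DataFrame.from_dict(rows, orient="index")[cols]
        if rows
        else pd.DataFrame(columns=cols, dtype=float)
    )
    return AFTResult(
        **stratum,
        coefficients=coef,
        intercept=float(params["Intercept"]),
        log_scale=float(fitter.params_["sigma_"]["Intercept"]),
        n=len(cases),
        n_events=int(cases["event"].sum()),
        converged=True,
        log_likelihood=float(fitter.log_likelihood_),
    )


def fit_trajectory_models(
    cohort: Cohort,
    trajectories: list[Trajectory],
    outcome: str,
    horizon_days: float | None = HORIZON_DAYS,
    min_events: int = 2,
    sex: str | None = None,
) -> list[AFTResult]:
    """Fit one history-augmented AFT model per trajectory.

    The trajectory's final block is the presenting diagnosis; earlier blocks
    enter as history indicators (with ``n_prior`` adjusted so neither the
    presenting diagnosis nor tested histories are double-counted).  For
    trajectories longer than 2, pairwise interactions between history
    indicators test for non-multiplicative joint effects, and the combined
    effect of carrying every history is the exponentiated coefficient sum.
    Strata with fewer than *min_events* events are skipped with a log entry.
    """
    results = []
    for traj in trajectories:
        presenting = traj.blocks[-1]
        histories = tuple(traj.blocks[:-1])
        cases = build_cases(
            cohort, presenting, outcome, horizon_days=horizon_days, histories=histories
        )
        if cases.empty or int(cases["event"].sum()) < min_events:
            logger.info("skipping %s (%s): <%d events", traj, outcome, min_events)
            continue
        covs = ["age", "n_prior"] + [f"hist_{h}" for h in histories]
        inter_cols = []
        if len(histories) > 1:
            for h1, h2 in combinations(histories, 2):
                col = f"hist_{h1}*hist_{h2}"
                cases[col] = cases[f"hist_{h1}"] * cases[f"hist_{h2}"]
                inter_cols.append(col)
        res = fit_aft(
            cases, tuple(covs + inter_cols),
            presenting_block=presenting, outcome=outcome, sex=sex,
        )
        if res.converged and len(histories) > 1:
            hist_covs = [f"hist_{h}" for h in histories]
            kept = [c for c in hist_covs + inter_cols if c in res.coefficients.index]
            total = float(res.coefficients.loc[kept, "beta"].sum())
            res.combined["+".join(histories)] = (total, float(np.exp(-total)))
        results.append(res)
    return results


def results_frame(results: list[AFTResult], adjust: bool = True) -> pd.DataFrame:
    """Long-format coefficient table over many fitted models.

    With ``adjust=True``, history and interaction coefficients get Holm
    adjusted p-values within each (outcome, sex) family, matching the
    family-wise correction applied across all screened histories.
    """
    rows = []
    for res in results:
        for cov, r in res.coefficients.iterrows():
            rows.append(
                {
                    "presenting_block": res.presenting_block,
                    "outcome": res.outcome,
                    "sex": res.sex,
                    "covariate": cov,
                    "beta": r["beta"],
                    "se": r["se"],
                    "p": r["p"],
                    "fold": r["fold"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "n": res.n,
                    "n_events": res.n_events,
                    "converged": res.converged,
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["p_adj"] = np.nan
    if adjust:
        is_hist = frame["covariate"].str.startswith("hist_") & frame["converged"]
        for _, idx in frame[is_hist].groupby(["outcome", "sex"]).groups.items():
            frame.loc[idx, "p_adj"] = holm_adjust(frame.loc[idx, "p"].to_numpy())
    return frame


def screen_high_risk(
    frame: pd.DataFrame,
    mortality_fold_min: float = 2.5,
    rehosp_fold_min: float = 1.5,
    alpha: float = 0.05,
    cancer_chapter: str = "C00-D48",
) -> pd.DataFrame:
    """Filter history effects to significant, outcome-specific high folds.

    Keeps rows with Holm-adjusted p < *alpha* whose fold exceeds 2.5 (1-year
    mortality) or 1.5 (re-hospitalisation); a ``cancer_history`` flag marks
    histories in the neoplasm chapter so cancer and non-cancer findings can
    be reported separately.
    """
    if frame.empty:
        return frame
    hist = frame[frame["covariate"].str.startswith("hist_") & ~frame["covariate"].str.contains(r"\*")]
    thr = hist["outcome"].map({MORTALITY: mortality_fold_min, REHOSP: rehosp_fold_min})
    keep = hist[(hist["p_adj"] < alpha) & (hist["fold"] > thr)].copy()
    from .catalog import _code_key

    lo, hi = (_code_key(c) for c in cancer_chapter.split("-"))

    def _in_cancer(cov: str) -> bool:
        start = cov.removeprefix("hist_").split("-")[0]
        return lo <= _code_key(start) <= hi

    keep["cancer_history"] = [_in_cancer(c) for c in keep["covariate"]]
    return keep.reset_index(drop=True)
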