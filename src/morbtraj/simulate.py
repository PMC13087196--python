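"""Synthetic longitudinal diagnosis cohorts with planted, recoverable structure.

The generator emulates the shape of sex-stratified inpatient diagnosis data:
patients aged 40–69 at first diagnosis accrue ICD-10 block diagnoses over
follow-up with exponential inter-diagnosis gaps; block carriage is mutually
independent given sex except for explicitly *planted pairs*, which receive an
elevated joint-carriage probability (targeting a configured Jaccard uplift
over independence) and a directional ordering bias (the first-listed block
precedes the second with probability ``p_order`` among dual carriers).
Outcome (death / re-hospitalisation) event times follow lognormal
accelerated-failure-time models with configurable coefficients for age, total
prior multimorbidity and specific history indicators, under administrative
censoring.  Every planted parameter is returned as ground truth so recovery
can be scored without re-simulation.

Two named random streams are used — one for diagnosis structure, one for
outcomes — so re-simulating outcomes never perturbs the diagnosis records.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .records import DAYS_PER_YEAR, Cohort

__all__ = [
    "PlantedPair",
    "AFTTruth",
    "SimConfig",
    "GroundTruth",
    "SimulatedCohort",
    "independence_jaccard",
    "generate_records",
    "simulate_outcomes",
    "apply_outcomes",
]

#: Default 30-block universe: common disease blocks spanning chapters A–N.
DEFAULT_BLOCKS = [
    "A00-A09", "A30-A49", "B15-B19", "B25-B34", "C15-C26", "C43-C44",
    "C50-C50", "C76-C80", "D10-D36", "D50-D53", "D60-D64", "E10-E14",
    "E65-E68", "E70-E90", "F10-F19", "F30-F39", "G40-G47", "H25-H28",
    "I10-I15", "I20-I25", "I30-I52", "I60-I69", "J09-J18", "J40-J47",
    "K20-K31", "K40-K46", "K80-K87", "L20-L30", "M00-M25", "N17-N19",
]


def independence_jaccard(p_a: float, p_b: float) -> float:
    """Expected Jaccard of two independent carriage processes,
    p_A·p_B / (p_A + p_B − p_A·p_B)."""
    return p_a * p_b / (p_a + p_b - p_a * p_b)


@dataclass(frozen=True)
class PlantedPair:
    """A diagnosis pair with elevated coincidence and ordering bias."""

    block_a: str
    block_b: str
    excess_jaccard: float = 0.0  # target Jaccard uplift over independence
    p_order: float = 0.5  # P(A diagnosed strictly before B | both carried)
    mean_gap_days: float = 365.0  # mean of the exponential A-to-B gap


@dataclass(frozen=True)
class AFTTruth:
    """True lognormal AFT coefficients for one presenting block and outcome.

    ``log T = intercept + beta_age*age + beta_mm*n_prior
    + sum_h beta_history[h]*I(history h) + interaction terms + sigma*Z``,
    with T in days post-presentation.  Negative coefficients accelerate the
    event; the implied per-unit fold increase in risk is ``exp(-beta)``.
    """

    intercept: float = 8.0
    beta_age: float = -0.02
    beta_mm: float = -np.log(1.3)
    beta_history: dict[str, float] = field(default_factory=dict)
    beta_interaction: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma: float = 1.5


@dataclass
class SimConfig:
    """Study conditions for one simulated two-sex cohort."""

    n_female: int = 2000
    n_male: int = 2000
    block_prevalence: dict[str, float] = field(default_factory=dict)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    accrual_rate: float = 0.6  # mean diagnoses per year after the first
    # spread of per-block onset propensities: blocks differ in how early in a
    # record they tend to appear (0 makes all blocks exchangeable in order)
    onset_spread: float = 2.0
    age_range: tuple[float, float] = (40.0, 69.0)
    first_date_range: tuple[str, str] = ("2000-01-01", "2010-12-31")
    followup_years_range: tuple[float, float] = (5.0, 15.0)
    # background death process (lognormal in days since first diagnosis);
    # None disables deaths during accrual
    death_lognormal: tuple[float, float] | None = (9.7, 1.0)
    aft_truth: dict[str, dict[str, AFTTruth]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_prevalence:
            # log-spaced marginals 0.02–0.25 over the default universe; their
            # sum (~2.7 expected blocks/patient) makes most patients multimorbid
            prevs = np.geomspace(0.02, 0.25, len(DEFAULT_BLOCKS))
            self.block_prevalence = dict(zip(DEFAULT_BLOCKS, np.round(prevs, 4)))
        for b, p in self.block_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence of {b} must be in (0,1), got {p}")
        for pair in self.planted_pairs:
            for b in (pair.block_a, pair.block_b):
                if b not in self.block_prevalence:
                    raise ValueError(f"planted pair block {b} not in block universe")
            if not 0 <= pair.p_order <= 1:
                raise ValueError(f"p_order must be in [0,1] for {pair.block_a}/{pair.block_b}")

    @property
    def blocks(self) -> list[str]:
        return list(self.block_prevalence)


@dataclass
class GroundTruth:
    """Planted parameters plus realised statistics, sufficient for scoring."""

    config: SimConfig
    pair_stats: pd.DataFrame  # per sex and planted pair: realised counts
    latent_times: pd.DataFrame | None = None  # per presentation, pre-censoring

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "pair_stats": self.pair_stats.to_dict(orient="records"),
        }
        if self.latent_times is not None:
            payload["latent_times"] = self.latent_times.to_dict(orient="records")
        return json.dumps(payload, indent=2, default=str)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["aft_truth"] = {
        blk: {
            out: {**asdict(t), "beta_interaction": {f"{a}*{b}": v for (a, b), v in t.beta_interaction.items()}}
            for out, t in per_out.items()
        }
        for blk, per_out in config.aft_truth.items()
    }
    return d


@dataclass
class SimulatedCohort:
    """Raw event stream + metadata in the normaliser's input schema."""

    raw_events: pd.DataFrame  # patient_id, sex, icd10_code, diagnosis_date
    meta: pd.DataFrame
    truth: GroundTruth


def _joint_prob(p_a: float, p_b: float, excess: float, pair: PlantedPair) -> float:
    """Joint carriage probability hitting the target Jaccard uplift."""
    j_target = independence_jaccard(p_a, p_b) + excess
    p_ab = j_target * (p_a + p_b) / (1.0 + j_target)
    if p_ab > min(p_a, p_b) + 1e-12:
        raise ValueError(
            f"unsatisfiable coincidence target for pair "
            f"{pair.block_a}/{pair.block_b}: joint {p_ab:.4f} exceeds "
            f"min marginal {min(p_a, p_b):.4f}"
        )
    return p_ab


def _simulate_sex(
    config: SimConfig, sex: str, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    blocks = config.blocks
    prev = np.array([config.block_prevalence[b] for b in blocks])
    idx = {b: i for i, b in enumerate(blocks)}
    planted_cols = {i for p in config.planted_pairs for i in (idx[p.block_a], idx[p.block_b])}

    carriage = rng.random((n, len(blocks))) < prev
    # planted pairs: redraw with the inflated joint-carriage probability.
    # A block already fixed by an earlier pair (chain planting) keeps its
    # draw; its partner is drawn conditionally, preserving all marginals and
    # the earlier pair's joint.
    fixed: set[int] = set()
    for pair in config.planted_pairs:
        ia, ib = idx[pair.block_a], idx[pair.block_b]
        p_a, p_b = prev[ia], prev[ib]
        p_ab = _joint_prob(p_a, p_b, pair.excess_jaccard, pair)
        if ia in fixed and ib in fixed:
            raise ValueError(
                f"both blocks of planted pair {pair.block_a}/{pair.block_b} "
                "already constrained by earlier pairs"
            )
        if ib in fixed:  # draw A conditionally on B instead
            ia, ib, p_a, p_b = ib, ia, p_b, p_a
        if ia in fixed:
            u = rng.random(n)
            cond = np.where(carriage[:, ia], p_ab / p_a, (p_b - p_ab) / (1.0 - p_a))
            carriage[:, ib] = u < cond
        else:
            u = rng.random(n)
            carriage[:, ia] = u < p_a
            carriage[:, ib] = (u < p_ab) | ((u >= p_a) & (u < p_a + (p_b - p_ab)))
        fixed.update({ia, ib})

    ages = rng.uniform(*config.age_range, size=n)
    start, end = (pd.Timestamp(d) for d in config.first_date_range)
    first_dates = start + pd.to_timedelta(
        rng.integers(0, (end - start).days + 1, size=n), unit="D"
    )
    followup_days = rng.uniform(*config.followup_years_range, size=n) * DAYS_PER_YEAR
    if config.death_lognormal is not None:
        mu_d, sd_d = config.death_lognormal
        death_days = np.exp(rng.normal(mu_d, sd_d, size=n))
    else:
        death_days = np.full(n, np.inf)

    gap_scale_days = DAYS_PER_YEAR / config.accrual_rate
    # deterministic per-block onset propensity in [-0.5, 0.5]: blocks with a
    # lower score tend to be diagnosed earlier (Gumbel-noise ranking), giving
    # blocks distinct typical positions/times as in real accrual data
    onset = np.array(
        [zlib.crc32(b.encode()) / 2**32 - 0.5 for b in blocks]
    ) * config.onset_spread
    rows, meta_rows, pair_stats = [], [], []
    pair_tallies = {
        (pair.block_a, pair.block_b): {"n_both": 0, "n_a_first": 0, "n_b_first": 0, "n_equal": 0}
        for pair in config.planted_pairs
    }
    for i in range(n):
        pid = f"{sex[0].upper()}{i:06d}"
        carried = np.flatnonzero(carriage[i])
        order = carried[np.argsort(onset[carried] + rng.gumbel(size=carried.size))]
        gaps = rng.exponential(gap_scale_days, size=max(len(carried) - 1, 0))
        times = np.concatenate([[0.0], np.cumsum(gaps)]) if len(carried) else np.array([])
        t_of = dict(zip(order.tolist(), times))
        for pair in config.planted_pairs:
            ia, ib = idx[pair.block_a], idx[pair.block_b]
            if carriage[i, ia] and carriage[i, ib]:
                a_first = rng.random() < pair.p_order
                gap = 1.0 + rng.exponential(pair.mean_gap_days)
                # anchor the earlier block, push the later one; a >=1-day gap
                # survives day-flooring, so p_order is realised exactly
                if a_first:
                    t_of[ib] = t_of[ia] + gap
                else:
                    t_of[ia] = t_of[ib] + gap
        # death terminates accrual
        cutoff = min(death_days[i], followup_days[i])
        death_date = (
            first_dates[i] + pd.Timedelta(days=int(np.floor(death_days[i])))
            if death_days[i] <= followup_days[i]
            else pd.NaT
        )
        kept_any = False
        for j, t in t_of.items():
            if t > cutoff and t > 0:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "sex": sex,
                    "icd10_code": blocks[j],
                    "diagnosis_date": first_dates[i] + pd.Timedelta(days=int(np.floor(t))),
                }
            )
            kept_any = True
        for pair in config.planted_pairs:
            ia, ib = idx[pair.block_a], idx[pair.block_b]
            if carriage[i, ia] and carriage[i, ib] and t_of[ia] <= cutoff and t_of[ib] <= cutoff:
                tal = pair_tallies[(pair.block_a, pair.block_b)]
                tal["n_both"] += 1
                da, db = int(np.floor(t_of[ia])), int(np.floor(t_of[ib]))
                key = "n_a_first" if da < db else ("n_b_first" if db < da else "n_equal")
                tal[key] += 1
        meta_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "age_at_assessment": float(np.floor(ages[i])),
                "assessment_date": first_dates[i],
                "death_date": death_date,
                "followup_end": first_dates[i] + pd.Timedelta(days=int(np.ceil(followup_days[i]))),
                "has_record": kept_any,
            }
        )
    for pair in config.planted_pairs:
        tal = pair_tallies[(pair.block_a, pair.block_b)]
        pair_stats.append({"sex": sex, "block_a": pair.block_a, "block_b": pair.block_b, **tal})
    return pd.DataFrame(rows), pd.DataFrame(meta_rows), pair_stats


def generate_records(config: SimConfig) -> SimulatedCohort:
    """Generate the raw two-sex event stream, metadata and ground truth.

    The output round-trips through :func:`morbtraj.records.normalize_records`
    unchanged except for same-date tie ordering.  Patients whose simulated
    carriage is empty appear in the metadata (they exist in the population)
    but contribute no events.
    """
    root = np.random.SeedSequence([int(config.seed), 0])  # structure stream
    rng_f, rng_m = (np.random.default_rng(s) for s in root.spawn(2))
    ev_f, meta_f, ps_f = _simulate_sex(config, "female", config.n_female, rng_f)
    ev_m, meta_m, ps_m = _simulate_sex(config, "male", config.n_male, rng_m)
    raw = pd.concat([ev_f, ev_m], ignore_index=True)
    meta = pd.concat([meta_f, meta_m], ignore_index=True)
    truth = GroundTruth(config=config, pair_stats=pd.DataFrame(ps_f + ps_m))
    return SimulatedCohort(raw_events=raw, meta=meta, truth=truth)


def _linear_predictor(truth: AFTTruth, age, n_prior, hist: dict[str, np.ndarray]):
    lp = truth.intercept + truth.beta_age * age + truth.beta_mm * n_prior
    for h, beta in truth.beta_history.items():
        lp = lp + beta * hist[h]
    for (h1, h2), beta in truth.beta_interaction.items():
        lp = lp + beta * hist[h1] * hist[h2]
    return lp


def simulate_outcomes(
    cohort: Cohort,
    aft_truth: dict[str, dict[str, AFTTruth]],
    seed: int = 0,
    horizon_days: float | None = None,
) -> pd.DataFrame:
    """Draw latent death / re-hospitalisation times for every presentation.

    For each presenting block in *aft_truth* and each patient carrying it,
    log event time is Normal(linear predictor, sigma²); the observed time is
    the minimum of the latent time, remaining follow-up, the optional horizon
    and (for re-hospitalisation) death.  Returns one row per
    (patient, presenting block, outcome) with latent and observed times and
    the covariates used, i.e. the per-presentation ground truth.
    """
    from .records import age_at_diagnosis  # local import avoids cycle at module load

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))  # outcome stream
    ev = cohort.events
    meta = cohort.meta.set_index("patient_id")
    out_rows = []
    for block in sorted(aft_truth):
        pres = ev[ev["block_id"] == block]
        if pres.empty:
            continue
        pids = pres["patient_id"].to_numpy()
        pres_date = pres["diagnosis_date"].to_numpy()
        m = meta.loc[pids]
        age = age_at_diagnosis(
            m["age_at_assessment"].to_numpy(),
            pd.DatetimeIndex(m["assessment_date"]),
            pd.DatetimeIndex(pres_date),
        )
        # prior diagnoses: distinct blocks dated <= presentation, minus the
        # presenting diagnosis itself
        merged = ev[ev["patient_id"].isin(pids)].merge(
            pres[["patient_id", "diagnosis_date"]].rename(
                columns={"diagnosis_date": "presentation_date"}
            ),
            on="patient_id",
        )
        prior = merged[merged["diagnosis_date"] <= merged["presentation_date"]]
        n_prior = (prior.groupby("patient_id")["block_id"].nunique() - 1).reindex(pids).fillna(0)
        hist_blocks = sorted(
            {h for t in aft_truth[block].values() for h in t.beta_history}
        )
        hist = {
            h: prior[prior["block_id"] == h].groupby("patient_id").size().reindex(pids).notna().astype(float).to_numpy()
            for h in hist_blocks
        }
        # histories enter through their own indicators, so they are removed
        # from the burden covariate — the same no-double-counting adjustment
        # the risk models apply, making planted history effects the estimand
        for h in hist_blocks:
            n_prior = n_prior - hist[h]
        n_prior = n_prior.clip(lower=0.0)
        censor = (pd.DatetimeIndex(m["followup_end"]) - pd.DatetimeIndex(pres_date)).days.to_numpy().astype(float)
        if horizon_days is not None:
            censor = np.minimum(censor, horizon_days)
        latent = {}
        for outcome, truth in sorted(aft_truth[block].items()):
            lp = _linear_predictor(truth, age.to_numpy() if hasattr(age, "to_numpy") else age, n_prior.to_numpy(), hist)
            latent[outcome] = np.exp(lp + truth.sigma * rng.standard_normal(len(pids)))
        death_latent = latent.get("mortality", np.full(len(pids), np.inf))
        for outcome in sorted(aft_truth[block]):
            t_lat = latent[outcome]
            limit = censor if outcome == "mortality" else np.minimum(censor, death_latent)
            t_obs = np.minimum(t_lat, limit)
            event = t_lat <= limit
            for k, pid in enumerate(pids):
                out_rows.append(
                    {
                        "patient_id": pid,
                        "sex": m["sex"].iloc[k],
                        "presenting_block": block,
                        "presentation_date": pd.Timestamp(pres_date[k]),
                        "outcome": outcome,
                        "age_at_presentation": float(np.asarray(age)[k]),
                        "n_prior": float(n_prior.iloc[k]),
                        **{f"hist_{h}": float(hist[h][k]) for h in hist_blocks},
                        "latent_days": float(t_lat[k]),
                        "time_days": float(max(t_obs[k], 0.5)),
                        "event": bool(event[k]),
                    }
                )
    return pd.DataFrame(out_rows)


def apply_outcomes(cohort: Cohort, outcomes: pd.DataFrame) -> Cohort:
    """Write simulated outcomes back into the cohort as calendar dates.

    Death events update ``meta.death_date``; re-hospitalisation events are
    appended to the unfiltered admission stream.  Requires outcomes for a
    single presenting block (one death process per patient).
    """
    if outcomes["presenting_block"].nunique() > 1:
        raise ValueError("apply_outcomes supports a single presenting block")
    meta = cohort.meta.copy()
    admissions = cohort.admissions.copy() if cohort.admissions is not None else pd.DataFrame(
        columns=["patient_id", "admission_date"]
    )
    deaths = outcomes[(outcomes["outcome"] == "mortality") & outcomes["event"]]
    death_dates = deaths.set_index("patient_id").apply(
        lambda r: r["presentation_date"] + pd.Timedelta(days=int(np.floor(r["time_days"]))), axis=1
    )
    meta["death_date"] = pd.to_datetime(
        meta["patient_id"].map(death_dates).fillna(meta["death_date"])
    )
    rehosp = outcomes[(outcomes["outcome"] == "rehospitalisation") & outcomes["event"]]
    if not rehosp.empty:
        new_adm = pd.DataFrame(
            {
                "patient_id": rehosp["patient_id"].to_numpy(),
                "admission_date": rehosp["presentation_date"]
                + pd.to_timedelta(np.maximum(rehosp["time_days"].round(), 1.0), unit="D"),
            }
        )
        admissions = (
            pd.concat([admissions, new_adm], ignore_index=True)
            .drop_duplicates()
            .sort_values(["patient_id", "admission_date"], kind="stable")
            .reset_index(drop=True)
        )
    from dataclasses import replace

    return replace(cohort, meta=meta, admissions=admissions)
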