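# Methods

`morbtraj` analyses time-stamped, ICD-10 coded inpatient diagnosis records:
it characterises how diagnoses accrue over time, clusters multimorbidity
states across follow-up, mines statistically significant time-ordered
diagnosis trajectories, and screens the 1-year mortality and
re-hospitalisation risk associated with total and specific prior
multimorbidity, separately for females and males. This note documents the
models, the conventions the implementation fixes where a choice was open,
and what the synthetic validation does and does not establish.

## Record preparation

Codes are analysed at the level of WHO ICD-10 *blocks* (e.g. `I20-I25`),
mapped from 3- or 4-character codes via the 3-character prefix against a
packaged catalog covering the disease chapters A00–N99. Blocks in chapters
O–Z (obstetric, perinatal, congenital, symptom, injury and
healthcare-contact codes) are excluded from analysis; the unfiltered
admission-date stream is retained separately because re-hospitalisation
outcomes are defined over *all* admissions, including excluded and rare
codes.

Per patient, only the earliest instance of each block is kept. Events are
ordered by date; same-date ties carry no usable order and are broken by a
seeded deterministic shuffle (a CRC of `(tie_seed, patient, block)`), so
results are reproducible and independent of input row order. The tie seed
is recorded in the run manifest. Blocks with carrier prevalence not
exceeding 1% within a sex (strict `>` rule; configurable) are dropped, and
positions/days-since-first are recomputed on the surviving events.

Age at a diagnosis is reconstructed from the integer recorded age at
assessment as `age + (days_from_assessment + 182.625)/365.25`; the
182.625-day offset is the leap-aware half year correcting the floor of the
recorded age.

Unmapped dialect codes are dropped with a logged count rather than raised,
since real extracts routinely contain them; malformed code *syntax* is an
error.

## Accrual statistics

Per block and sex we compute the median (and quartiles) of the position in
the diagnosis order and of the days since first diagnosis, and pooled
quantiles (default 25/50/75/90%, linear interpolation between order
statistics) of days-since-first over all non-first diagnoses. A straight
line is fitted to (median position, median days); blocks are projected onto
the orthonormal basis parallel/perpendicular to the line and flagged when
their perpendicular coordinate lies beyond one or two SDs of its mean. A
block *below* the line is reached after unusually fast accrual (more
multimorbidity than its order position implies), and vice versa.

Two open choices are fixed here: the line is ordinary least squares of days
on position (orthogonal regression is available via `method="orthogonal"`),
and the SD is of the perpendicular coordinate only — deviation from the
trend — with the parallel coordinate exposed in the output. The flags are
deliberately scale-dependent (days vs. positions have incommensurate
units); they are deterministic for a given input.

## Multimorbidity-state clustering

Multimorbid patients (≥ 2 blocks) are snapshotted at t = 0 (immediately
after first presentation) and at the four timing quantiles; each snapshot
is a binary patient × block matrix of diagnoses accrued by that time. A
patient whose death or end of follow-up falls at or before a timepoint is
absorbed into `died` / `no_followup` and excluded from later matrices. The
number of snapshots (with or without t = 0) is configurable because either
convention is defensible.

Rows are pooled over both sexes and all timepoints and embedded with
multiple correspondence analysis: each block is a two-category variable
(absent/present), giving the complete disjunctive table `Z = [X, 1−X]`, and
row principal coordinates come from the SVD of the centred, mass-weighted
correspondence matrix. For an all-binary table the total inertia is exactly
1, which the tests use as an identity check. The retained component count
defaults to 5 with the explained-inertia scree exported for elbow
inspection. k-means (best of 25 restarts, squared Euclidean, mandatory
seed) is run over a grid of k with within-cluster dispersion and the
Calinski–Harabasz index reported; the final k defaults to 6. Transitions
between clusters across timepoints, with the two absorbing states, are
exported as a `source,target,value` table whose flows conserve occupancy —
ready for any Sankey renderer. Cluster labelling is a reporting step over
the per-cluster block-prevalence-ratio enrichment table, not an algorithmic
claim.

## Trajectory mining

For each block pair (A, B) in a sex stratum, coincidence is the Jaccard
index N(A∩B)/N(A∪B) over carrier sets. Significance is assessed against a
bootstrap null that resamples independent carriage at the observed marginal
prevalences. Two equivalent samplers are provided: the literal counting
bootstrap, `p = (1 + #{J* ≥ J_obs})/(B+1)` with B = 1000 by default, and a
Rao–Blackwellised variant that draws only the marginal counts
(`n_A* ~ Binomial`, overlap `~ Hypergeometric`) and averages exact
hypergeometric overlap tails. The two agree in distribution; the miner uses
the Rao–Blackwellised form because a counting p-value is floored at
1/(B+1) and can never clear a Holm step-down over hundreds of pairs,
whereas the averaged-tail p is continuous. A permutation-style null would
also be defensible; the scheme is isolated in one function and swappable.

Ordering between A and B is tested among dual carriers with double
one-tailed binomial tests: with counts (A first, B first, same date),
`p(A first) = P(X ≥ n_A_first)` for `X ~ Binomial(n_total, ½)` — ties count
against the tested direction — and symmetrically for B. Same-date pairs are
ties by construction of the tie-break rule.

Mining proceeds breadth-first. Length-2 trajectories are pairs that pass
both the coincidence test (Holm over all pairs per sex) and one ordering
direction (Holm over all ordering p-values per sex and length), with
support (patients carrying both blocks) of at least 20. Candidate
(k+1)-sets are unions of two length-k trajectories sharing k−1 blocks; in
the sub-population carrying every member block, *all* pairwise orderings
are re-tested (Holm per length), and a candidate is emitted when a total
order exists whose consecutive pairs are all significant and which no
significant ordering contradicts. The default maximum length is 3. Only
maximal trajectories (not an ordered subsequence of a longer one) are
reported. Whether each extension step should gate on raw or adjusted
p-values is not externally determined; adjusted is the default.

## Outcome risk models

For a presenting block, outcome ∈ {mortality, re-hospitalisation} and sex,
a lognormal accelerated-failure-time model is fitted (lifelines
`LogNormalAFTFitter`, maximum likelihood on right-censored times):

    log T = μ + β_age·age + β_mm·n_prior + Σ_h β_h·I_h + ε,  ε ~ N(0, σ²)

`n_prior` counts distinct blocks diagnosed at or before the presentation
date, minus one for the presenting diagnosis itself and minus one per
tested history a patient carries (no double counting of burden). Mortality
time runs to death, censored at end of follow-up; re-hospitalisation time
runs to the first admission strictly after presentation in the unfiltered
stream, censored additionally at death. A 1-year horizon is implemented as
administrative censoring at 365.25 days (a full-follow-up mode exists,
since "1-year risk" could also be read as a full-model summary). Same-day
events are shifted to 0.5 days.

Effects are reported as the per-unit fold increase in risk `exp(−β)` with
Wald CIs: under a lognormal AFT there is no proportional-hazards
representation, and the reciprocal time-ratio is the convention used
throughout, chosen so risk-raising covariates give folds above 1. The
synthetic generator plants its effects under the same convention and the
same covariate adjustment, so the planted fold is exactly the estimand the
fit recovers. For trajectories longer than 2, pairwise interactions between
history indicators are included and combined multi-history effects are the
exponentiated coefficient sums. History p-values are Holm-adjusted per
(outcome, sex) family; screening keeps significant histories with folds
above 2.5 (mortality) or 1.5 (re-hospitalisation), with neoplasm-chapter
histories flagged for separate reporting. Sex contrasts use CI non-overlap
of matched strata rather than interaction tests, mirroring the reporting
convention for sex differences.

## Synthetic cohorts and what validation shows

The generator emulates the structure of the data, not any real cohort:
two sex strata; first-diagnosis age uniform on 40–69; 30 blocks with
log-spaced marginal prevalences 0.02–0.25 (expected ≈ 2.7 blocks/patient,
so most patients are multimorbid); exponential inter-diagnosis gaps at 0.6
diagnoses/year, with deterministic per-block onset propensities
(Gumbel-noise ranking) so blocks occupy distinct typical positions and
times, as real accrual scatters do; follow-up uniform 5–15 years; an optional background
lognormal death process that truncates accrual. Carriage is mutually
independent given sex except for planted pairs, which receive a joint
probability hitting a target Jaccard uplift and, among dual carriers, an
ordering bias `p_order` with an exponential inter-diagnosis gap of at least
one day (so day-flooring cannot create ties). Chains are planted by letting
a pair share a block, with the shared block's draw held fixed and the
partner drawn conditionally, preserving all marginals. Outcome times are
lognormal AFT draws with configurable coefficients; structure and outcomes
use separate named random streams so re-simulating one cannot perturb the
other.

Validation therefore establishes internal correctness: exact agreement of
the statistical primitives with independent oracles; approximate uniformity
of the coincidence p-value and ≤ 5% (+3 Monte-Carlo SE) family-wise
false positives of the miner under a truly independent null; recovery of
planted pairs, chains, and AFT folds (1.3 per prior diagnosis, 2.0 per
history) with calibrated CI coverage. Problem sizes are 2 000 patients per
null/recovery cohort over 20 seeds, ~2 000 presentation cases (~40% 1-year
events) for the fold estimate, 200 replicates of ~200 cases for coverage,
and a 5 000-patient two-sex cohort for the end-to-end run. What passing
does **not** show: robustness to coding noise, non-independent background
comorbidity, informative censoring, or cohort-specific prevalence
structure — none of which the generator emulates — and no numeric result
from any real cohort is reproduced here.

## Numerical conventions and limitations

- Quantiles interpolate linearly between order statistics.
- Bootstrap and k-means seeds are mandatory inputs; a single run seed is
  expanded into named per-stage streams, so toggling one stage never
  perturbs another.
- Degenerate inputs: zero-variance carriage gives coincidence p = 1 with a
  warning; an all-collinear accrual scatter flags nothing (with a warning);
  MCA drops constant columns and clamps the component count to the rank;
  collinear AFT design columns are dropped (interactions first); a
  non-converged AFT fit is returned flagged and excluded from screening.
- The miner's breadth-first extension tests all pairwise orderings within a
  candidate sub-population, which is quadratic in trajectory length — fine
  at the default maximum length 3.
- Mortality models with very few events in a stratum are skipped, not
  force-fitted.
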