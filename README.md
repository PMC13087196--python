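# morbtraj

Sex-stratified analysis of multimorbidity accrual from time-stamped, ICD-10
coded inpatient diagnosis records: how diagnoses accumulate, which
combinations of conditions patients move through, which time-ordered
diagnosis sequences ("trajectories") recur more often than chance, and how
much total and specific prior multimorbidity raise the 1-year mortality and
re-hospitalisation risk of a presenting diagnosis. It is aimed at
epidemiologists and biostatisticians working with longitudinal hospital
diagnosis extracts (long tables of patient id, sex, ICD-10 code, date).

Because such extracts are access-controlled, the package ships a synthetic
cohort generator with planted, fully known structure — coincident and
time-ordered diagnosis pairs, chains, and survival effects — so every stage
can be validated end to end by parameter recovery.

## What it computes

Diagnoses are analysed at the level of WHO ICD-10 blocks (codes `I20` and
`I25` both map to `I20-I25`, ischaemic heart diseases), keeping only each
patient's earliest diagnosis per block, excluding non-disease chapters
(O–Z) and blocks under 1% prevalence per sex.

1. **Accrual** — per-block median order and time-to-diagnosis; blocks far
   from the best-fit line (beyond 1 or 2 SD of the perpendicular
   projection) mark patient groups accruing multimorbidity faster or
   slower than expected.
2. **Clustering** — multimorbid patients' accrued diagnosis sets at t = 0
   and the 25/50/75/90% timing quantiles, embedded with multiple
   correspondence analysis, clustered with k-means (Calinski–Harabasz
   guided), and tabulated as Sankey-ready cluster-transition flows with
   absorbing death / lost-to-follow-up states.
3. **Trajectory mining** — diagnosis pairs with a significant Jaccard
   coincidence (bootstrap test against independent carriage at the observed
   marginals) and a significant temporal ordering (double one-tailed
   binomial tests, J = N(A∩B)/N(A∪B), ties counted against the tested
   direction), extended breadth-first into longer ordered trajectories with
   support ≥ 20; all p-values Holm-adjusted.
4. **Risk screening** — per presenting block, outcome and sex, lognormal
   accelerated-failure-time models

       log T = μ + β_age·age + β_mm·n_prior + Σ_h β_h·I_h + σ·ε

   of 1-year mortality and re-hospitalisation, with effects reported as the
   per-unit fold increase in risk exp(−β); history-augmented models for
   mined trajectories (with interactions beyond length 2), screening of
   high-risk histories (folds > 2.5 / 1.5), and sex contrasts by CI
   non-overlap.

## Worked example

```python
import numpy as np
from morbtraj import load_catalog, normalize_records, prevalence_filter, mine_trajectories
from morbtraj.simulate import SimConfig, PlantedPair, generate_records

config = SimConfig(
    n_female=2000, n_male=0,
    planted_pairs=[
        PlantedPair("I10-I15", "I20-I25", excess_jaccard=0.25, p_order=0.9, mean_gap_days=200),
        PlantedPair("I20-I25", "I60-I69", excess_jaccard=0.25, p_order=0.9, mean_gap_days=200),
    ],
    seed=5,
)
sim = generate_records(config)
cohort = normalize_records(sim.raw_events, load_catalog(), tie_seed=1, meta=sim.meta)
cohort, _ = prevalence_filter(cohort)

result = mine_trajectories(cohort.by_sex("female"), seed=11)
for t in result.trajectories:
    print(t, "support", t.support, "step p", [f"{p:.2g}" for p in t.step_p_adjusted])
```

prints

```
I10-I15 -> I20-I25 -> I60-I69 support 44 step p ['1.3e-05', '5.1e-05']
```

the planted hypertension → ischaemic heart disease → cerebrovascular chain,
recovered in the correct order: 44 patients carry all three blocks, and
both consecutive orderings are Holm-significant within the sub-population
carrying the full chain. Of the 435 tested pairs only the two planted ones
pass the coincidence screen; nothing spurious is emitted. The full pipeline (simulation or CSV input →
normalisation → accrual → clustering → mining → risk screening, with a run
manifest and per-stage seeds) runs as

```bash
morbtraj all --config run.yaml --seed 7 --out results/
```

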