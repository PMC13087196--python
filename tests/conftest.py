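import numpy as np
import pandas as pd
import pytest

from morbtraj import load_catalog, normalize_records
from morbtraj.simulate import SimConfig, PlantedPair, generate_records


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture()
def tiny_raw():
    """Three patients with hand-written code streams exercising the
    O–Z exclusion, within-block deduplication and same-date ties."""
    return pd.DataFrame(
        [
            # p1: I20 and I25 map to the same block; Z01 must be dropped
            ("p1", "female", "I20", "2001-03-01"),
            ("p1", "female", "Z01", "2002-06-01"),
            ("p1", "female", "I25", "2003-09-01"),
            ("p1", "female", "E11", "2004-01-15"),
            # p2: single event
            ("p2", "female", "J45", "2005-05-05"),
            # p3: two same-date diagnoses (tie) plus a later one
            ("p3", "male", "I10", "2002-02-02"),
            ("p3", "male", "E10", "2002-02-02"),
            ("p3", "male", "K21", "2006-08-30"),
        ],
        columns=["patient_id", "sex", "icd10_code", "diagnosis_date"],
    )


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3"],
            "sex": ["female", "female", "male"],
            "age_at_assessment": [50, 61, 44],
            "assessment_date": ["2001-03-01", "2005-05-05", "2002-02-02"],
            "death_date": [pd.NaT, pd.NaT, "2008-01-01"],
            "followup_end": ["2010-01-01", "2010-01-01", "2008-01-01"],
        }
    )


@pytest.fixture()
def tiny_cohort(tiny_raw, tiny_meta, catalog):
    return normalize_records(tiny_raw, catalog, tie_seed=42, meta=tiny_meta)


@pytest.fixture(scope="session")
def planted_cohort(catalog):
    """A 2000-patient single-sex cohort with one strongly coincident,
    strongly ordered planted pair on high-prevalence blocks."""
    cfg = SimConfig(
        n_female=2000,
        n_male=0,
        planted_pairs=[PlantedPair("I10-I15", "I20-I25", 0.25, 0.9, 200.0)],
        seed=20,
    )
    sim = generate_records(cfg)
    cohort = normalize_records(sim.raw_events, catalog, tie_seed=1, meta=sim.meta)
    return cohort, sim.truth


@pytest.fixture(scope="session")
def planted_mining(planted_cohort):
    from morbtraj import mine_trajectories

    cohort, _ = planted_cohort
    return mine_trajectories(cohort.by_sex("female"), seed=3)
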