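"""Shared fixtures: small hand-built cohorts and a default synthetic one."""

import numpy as np
import pandas as pd
import pytest

from msvlot import REGIONS, CohortConfig, LongitudinalCohort, generate_cohort


def build_cohort(patients: dict, ages: dict | None = None) -> LongitudinalCohort:
    """Build a cohort from {patient_id: [(t, {region: vol or None}), ...]}.

    Regions omitted from a visit's dict default to 1.0; an explicit None
    marks a missing volume.
    """
    visit_rows = []
    for pid, visits in patients.items():
        for t, vols in visits:
            row = {"patient_id": pid, "t_years": float(t)}
            for region in REGIONS:
                v = vols.get(region, 1.0)
                row[region] = np.nan if v is None else float(v)
            visit_rows.append(row)
    ages = ages or {}
    patient_rows = [
        {"patient_id": pid, "baseline_age": float(ages.get(pid, 40.0))}
        for pid in patients
    ]
    return LongitudinalCohort(
        visits=pd.DataFrame(visit_rows), patients=pd.DataFrame(patient_rows)
    )


def constant_volume_visits(n_visits=3, value=1.0):
    return [(t, {r: value for r in REGIONS}) for t in range(n_visits)]


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (published group sizes and profiles)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
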