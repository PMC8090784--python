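"""Annualized regional volume-change rates and age residualization.

The per-patient rate of a region is the arithmetic mean, over all
consecutive pairs of complete MRI sessions, of the annualized percent
change 100 * (V_next - V_prev) / (V_prev * dt). To remove the shared
effect of aging, each region's rates are then residualized on baseline
age by ordinary least squares across patients; the residuals carry the
between-structure pattern that the downstream PCA decomposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import REGIONS, LongitudinalCohort


@dataclass
class ExclusionReport:
    """Accounting of sessions and patients removed by the cohort filter."""

    n_sessions_in: int = 0
    n_sessions_incomplete: int = 0
    n_patients_in: int = 0
    patients_dropped: list = field(default_factory=list)

    @property
    def n_patients_dropped(self) -> int:
        return len(self.patients_dropped)

    @property
    def n_patients_out(self) -> int:
        return self.n_patients_in - self.n_patients_dropped


@dataclass
class ResidualTable:
    """Age-adjusted rates plus the per-region OLS fits.

    ``residuals`` is patients x regions (%/year); ``fits`` has one row
    per region with the fitted intercept and age slope.
    """

    residuals: pd.DataFrame
    fits: pd.DataFrame

    @property
    def patient_ids(self) -> list:
        return list(self.residuals.index)

    def matrix(self) -> np.ndarray:
        return self.residuals[list(REGIONS)].to_numpy(float)


def exclusion_filter(
    cohort: LongitudinalCohort, min_visits: int = 2
) -> tuple[LongitudinalCohort, ExclusionReport]:
    """Apply the session- and patient-level exclusion rules.

    A session is unusable if any of the six region volumes is missing
    (whole-session removal); patients with fewer than ``min_visits``
    usable sessions are then excluded.
    """
    report = ExclusionReport(
        n_sessions_in=cohort.n_visits, n_patients_in=cohort.n_patients
    )
    complete = cohort.complete_visits()
    report.n_sessions_incomplete = cohort.n_visits - len(complete)

    counts = complete.groupby("patient_id").size()
    keep = set(counts[counts >= min_visits].index)
    report.patients_dropped = sorted(set(cohort.patient_ids) - keep)
    if not keep:
        raise ValueError("no analyzable patients after exclusion filtering")

    filtered = LongitudinalCohort(
        visits=complete[complete["patient_id"].isin(keep)].reset_index(drop=True),
        patients=cohort.patients[cohort.patients["patient_id"].isin(keep)].reset_index(
            drop=True
        ),
    )
    return filtered, report


def annualized_rates(cohort: LongitudinalCohort) -> pd.DataFrame:
    """Mean annualized percent change per patient and region (%/year).

    Expects an already-filtered cohort (every patient has >= 2 complete
    visits). Returns a DataFrame indexed by patient_id with one column
    per region plus ``n_pairs``, the number of consecutive session
    pairs averaged.
    """
    visits = cohort.complete_visits()
    out = {}
    for pid, grp in visits.groupby("patient_id", sort=False):
        grp = grp.sort_values("t_years")
        t = grp["t_years"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"patient {pid!r} has fewer than 2 complete visits")
        dt = np.diff(t)
        if (dt == 0).any():
            raise ValueError(f"duplicate timepoint for patient {pid!r}")
        row = {}
        for region in REGIONS:
            v = grp[region].to_numpy(float)
            pair_rates = 100.0 * np.diff(v) / (v[:-1] * dt)
            row[region] = pair_rates.mean()
        row["n_pairs"] = len(dt)
        out[pid] = row
    rates = pd.DataFrame.from_dict(out, orient="index")
    rates.index.name = "patient_id"
    rates["n_pairs"] = rates["n_pairs"].astype(int)
    return rates


def age_residuals(
    rates: pd.DataFrame, cohort: LongitudinalCohort
) -> ResidualTable:
    """Residualize each region's rates on baseline age (OLS, per region).

    If the ages have zero variance the regression is degenerate and the
    residuals reduce to the centered rates (slope 0).
    """
    if len(rates) < 3:
        raise ValueError(
            f"age residualization needs >= 3 patients, got {len(rates)}"
        )
    ages = (
        cohort.patients.set_index("patient_id")["baseline_age"]
        .reindex(rates.index)
    )
    if ages.isna().any():
        missing = list(ages[ages.isna()].index)
        raise ValueError(f"missing baseline_age for patients: {missing}")
    a = ages.to_numpy(float)

    resid = pd.DataFrame(index=rates.index, columns=list(REGIONS), dtype=float)
    fits = []
    degenerate = np.ptp(a) == 0
    X = np.column_stack([np.ones_like(a), a])
    for region in REGIONS:
        y = rates[region].to_numpy(float)
        if degenerate:
            intercept, slope = y.mean(), 0.0
        else:
            (intercept, slope), *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[region] = y - (intercept + slope * a)
        fits.append({"region": region, "intercept": intercept, "age_slope": slope})
    resid.index.name = "patient_id"
    return ResidualTable(residuals=resid, fits=pd.DataFrame(fits).set_index("region"))


def to_long(table: pd.DataFrame, value_name: str = "value") -> pd.DataFrame:
    """Tidy (patient_id, region, value) view of a wide rates table."""
    wide = table[list(REGIONS)]
    long = wide.reset_index().melt(
        id_vars="patient_id", var_name="region", value_name=value_name
    )
    return long.sort_values(["patient_id", "region"]).reset_index(drop=True)
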