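"""Longitudinal cohort container and CSV input/output.

A cohort is stored at two granularities, mirroring how longitudinal
volumetry studies record their data: a *visits* table with one row per
MRI session (region volumes plus optional clinical measures) and a
*patients* table with one row per patient (baseline covariates).

The six quantified CNS regions are, in canonical order: spinal cord,
striatum, globus pallidus, thalamus, cortical gray matter, and brain
white matter. Volumes are assumed to be already segmented and head-size
normalized upstream; rates are unit-invariant, so cm^3 and mm^3 are both
accepted as long as each region is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical region identifiers, in the order used throughout the package.
REGIONS: tuple[str, ...] = (
    "spinal_cord",
    "striatum",
    "globus_pallidus",
    "thalamus",
    "cortical_gm",
    "brain_wm",
)

#: Default visit-CSV column for each region.
REGION_COLUMNS: dict[str, str] = {
    "spinal_cord": "sc_vol",
    "striatum": "striatum_vol",
    "globus_pallidus": "gp_vol",
    "thalamus": "thalamus_vol",
    "cortical_gm": "cgm_vol",
    "brain_wm": "wm_vol",
}

#: Optional clinical columns recognized in the visits table.
CLINICAL_COLUMNS: tuple[str, ...] = (
    "edss",
    "t25fwt",
    "d9hpt",
    "nd9hpt",
    "snfl",
    "t2lv",
    "relapses_since_last_visit",
)

#: Required patient-covariate columns.
PATIENT_COLUMNS: tuple[str, ...] = ("patient_id", "baseline_age")


class CohortValidationError(ValueError):
    """Raised when a cohort fails validation; carries all row-level errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n  ".join(errors[:20])
        more = "" if len(errors) <= 20 else f"\n  ... and {len(errors) - 20} more"
        super().__init__(f"{len(errors)} cohort validation error(s):\n  {preview}{more}")


@dataclass
class LongitudinalCohort:
    """Per-visit region volumes plus per-patient covariates.

    Attributes
    ----------
    visits : pandas.DataFrame
        Columns ``patient_id``, ``t_years`` (years from that patient's
        baseline), one column per region (see :data:`REGIONS`), and any
        of the optional clinical columns. Missing volumes are NaN.
    patients : pandas.DataFrame
        Columns ``patient_id``, ``baseline_age`` and optionally ``sex``,
        ``disease_duration``, ``phenotype``, ``treated``.
    """

    visits: pd.DataFrame
    patients: pd.DataFrame

    @property
    def patient_ids(self) -> list:
        return list(self.patients["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`CohortValidationError`.

        Collected checks: required columns present, every visit's patient
        has a covariate record, no duplicated (patient, time) pair,
        strictly increasing visit times per patient, positive volumes
        where present, non-negative times.
        """
        errors: list[str] = []
        for col in ("patient_id", "t_years"):
            if col not in self.visits.columns:
                errors.append(f"visits table missing required column {col!r}")
        for col in PATIENT_COLUMNS:
            if col not in self.patients.columns:
                errors.append(f"patients table missing required column {col!r}")
        if errors:
            raise CohortValidationError(errors)

        known = set(self.patients["patient_id"])
        orphans = set(self.visits["patient_id"]) - known
        for pid in sorted(orphans):
            errors.append(f"visit for unknown patient {pid!r}")

        dup = self.visits.duplicated(subset=["patient_id", "t_years"], keep=False)
        for _, row in self.visits[dup].drop_duplicates(["patient_id", "t_years"]).iterrows():
            errors.append(
                f"duplicated visit (patient {row['patient_id']!r}, t={row['t_years']})"
            )

        if (self.visits["t_years"] < 0).any():
            bad = self.visits.loc[self.visits["t_years"] < 0, "patient_id"]
            for pid in bad.unique():
                errors.append(f"negative visit time for patient {pid!r}")

        if not dup.any():
            for pid, grp in self.visits.groupby("patient_id", sort=False):
                t = grp["t_years"].to_numpy()
                if len(t) > 1 and not (np.diff(np.sort(t)) > 0).all():
                    errors.append(f"non-increasing visit times for patient {pid!r}")

        for region in REGIONS:
            if region not in self.visits.columns:
                continue
            v = self.visits[region]
            bad = v.notna() & (v <= 0)
            for _, row in self.visits[bad].iterrows():
                errors.append(
                    f"non-positive {region} volume for patient "
                    f"{row['patient_id']!r} at t={row['t_years']}"
                )

        if errors:
            raise CohortValidationError(errors)

    def complete_visits(self) -> pd.DataFrame:
        """Visits with all six region volumes present."""
        present = [r for r in REGIONS if r in self.visits.columns]
        if len(present) < len(REGIONS):
            missing = set(REGIONS) - set(present)
            raise CohortValidationError(
                [f"visits table missing region column {m!r}" for m in sorted(missing)]
            )
        mask = self.visits[list(REGIONS)].notna().all(axis=1)
        return self.visits[mask]

    def subset(self, patient_ids) -> "LongitudinalCohort":
        """Restrict to the given patients, preserving row order."""
        keep = set(patient_ids)
        return LongitudinalCohort(
            visits=self.visits[self.visits["patient_id"].isin(keep)].reset_index(drop=True),
            patients=self.patients[self.patients["patient_id"].isin(keep)].reset_index(drop=True),
        )


def read_cohort_csv(
    visits_path: str | Path,
    patients_path: str | Path,
    region_mapping: dict[str, str] | None = None,
) -> LongitudinalCohort:
    """Read a cohort from the canonical two-CSV layout and validate it.

    Parameters
    ----------
    visits_path, patients_path
        Visit-level and patient-level CSV files.
    region_mapping
        Maps canonical region names to the CSV column holding that
        region's volumes; defaults to :data:`REGION_COLUMNS`.
    """
    mapping = dict(region_mapping or REGION_COLUMNS)
    visits = pd.read_csv(visits_path)
    patients = pd.read_csv(patients_path)

    missing = [c for c in mapping.values() if c not in visits.columns]
    if missing:
        raise CohortValidationError(
            [f"visits CSV missing region column {c!r}" for c in missing]
        )
    rename = {csv_col: region for region, csv_col in mapping.items()}
    visits = visits.rename(columns=rename)

    cohort = LongitudinalCohort(visits=visits, patients=patients)
    cohort.validate()
    return cohort


def write_cohort_csv(
    cohort: LongitudinalCohort,
    visits_path: str | Path,
    patients_path: str | Path,
    region_mapping: dict[str, str] | None = None,
) -> None:
    """Write the cohort in the canonical two-CSV layout (round-trips with
    :func:`read_cohort_csv`)."""
    mapping = dict(region_mapping or REGION_COLUMNS)
    visits = cohort.visits.rename(columns=mapping)
    visits.to_csv(visits_path, index=False)
    cohort.patients.to_csv(patients_path, index=False)
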