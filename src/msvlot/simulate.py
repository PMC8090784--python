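"""Synthetic longitudinal MS cohorts with planted atrophy-pattern groups.

The generator emulates the statistical structure the clustering pipeline
assumes: a mixture of latent patient groups, each with its own profile
of mean annual percent volume change (and spread) across the six CNS
regions; geometric volume trajectories V(t) = V0 * (1 + r/100)^t;
multiplicative log-normal measurement noise; a linear effect of baseline
age on rates; and session-level missingness. Ground-truth group labels
and planted rates are returned alongside the cohort so that recovery of
the planted partition can be scored.

The default four group profiles carry the published group sizes
(14/59/141/11), per-region rate means and SDs, follow-up counts and
annual relapse rates of a deeply phenotyped single-center MS cohort;
baseline volumes and ages use the pooled cohort values. The geometric
trajectory makes the consecutive-pair rate estimator exactly unbiased at
zero noise, so the simulator doubles as an oracle for the rate module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import REGIONS, LongitudinalCohort

#: Truth label used for the optional injected unclassifiable patient.
OUTLIER_LABEL = "OUTLIER"


@dataclass
class GroupProfile:
    """Planted per-group generative profile.

    Attributes
    ----------
    label : str
        Group name carried into the truth table.
    n_patients : int
        Number of patients drawn from this profile.
    rate_mean, rate_sd : dict
        Per-region mean and SD of the planted annual percent volume
        change (%/year). SDs describe true between-patient
        heterogeneity within the group.
    mean_followups, sd_followups : float
        Mean/SD of the number of MRI sessions per patient (baseline
        included); draws are rounded and clipped to [2, max sessions].
    relapse_rate : float
        Poisson intensity of clinical relapses (events/year).
    baseline_edss : float
        Central baseline EDSS used when clinical fields are generated.
    """

    label: str
    n_patients: int
    rate_mean: dict[str, float]
    rate_sd: dict[str, float]
    mean_followups: float = 4.0
    sd_followups: float = 1.5
    relapse_rate: float = 0.3
    baseline_edss: float = 3.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError(f"group {self.label!r}: n_patients must be >= 1")
        if self.mean_followups < 1:
            raise ValueError(f"group {self.label!r}: mean_followups must be >= 1")
        for region in REGIONS:
            if region not in self.rate_mean or region not in self.rate_sd:
                raise ValueError(f"group {self.label!r}: missing rate for {region!r}")
            if self.rate_sd[region] < 0:
                raise ValueError(f"group {self.label!r}: negative rate_sd for {region!r}")


def _profile(label, n, means, sds, followups, sd_fu, relapse, edss) -> GroupProfile:
    return GroupProfile(
        label=label,
        n_patients=n,
        rate_mean=dict(zip(REGIONS, means)),
        rate_sd=dict(zip(REGIONS, sds)),
        mean_followups=followups,
        sd_followups=sd_fu,
        relapse_rate=relapse,
        baseline_edss=edss,
    )


def default_group_profiles() -> list[GroupProfile]:
    """The four published group profiles (sizes 14/59/141/11).

    Region order: spinal cord, striatum, globus pallidus, thalamus,
    cortical gray matter, brain white matter; rates in %/year. Group A
    shows pronounced spinothalamic loss, B pallidal loss, C small
    between-structure differences, and D a paradoxical spinal-cord and
    cortical volume increase with marked white-matter loss.
    """
    return [
        _profile(
            "A", 14,
            means=(-3.82, -1.27, -1.65, -2.65, -1.03, -1.50),
            sds=(1.97, 1.04, 2.37, 1.59, 1.42, 1.61),
            followups=3.00, sd_fu=1.18, relapse=0.42, edss=3.75,
        ),
        _profile(
            "B", 59,
            means=(-0.67, -0.54, -1.61, -0.67, -1.28, -0.40),
            sds=(0.97, 0.84, 1.09, 0.87, 1.05, 1.01),
            followups=4.19, sd_fu=1.82, relapse=0.45, edss=3.0,
        ),
        _profile(
            "C", 141,
            means=(-0.18, 0.15, -0.33, 0.05, -0.06, 0.03),
            sds=(0.66, 0.53, 0.79, 0.57, 0.61, 0.54),
            followups=5.34, sd_fu=1.43, relapse=0.24, edss=2.5,
        ),
        _profile(
            "D", 11,
            means=(1.29, -0.58, -0.55, -0.28, 2.82, -1.37),
            sds=(1.32, 0.80, 1.50, 1.10, 1.41, 1.02),
            followups=2.64, sd_fu=0.81, relapse=0.22, edss=3.0,
        ),
    ]


#: Pooled baseline volume means/SDs per region (cm^3).
DEFAULT_BASELINE_VOLUME_MEAN: dict[str, float] = dict(
    zip(REGIONS, (2.38, 20.9, 3.21, 13.1, 645.0, 733.0))
)
DEFAULT_BASELINE_VOLUME_SD: dict[str, float] = dict(
    zip(REGIONS, (0.32, 2.40, 0.35, 2.00, 54.0, 50.0))
)


@dataclass
class CohortConfig:
    """Full configuration of the synthetic-cohort generator.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal measurement error on each observed volume. ``age_slope``
    adds ``age_slope * (age - age_mean)`` %/year to every region's
    planted rate (atrophy accelerating slightly with age by default).
    ``p_session_missing`` independently removes non-baseline sessions,
    emulating segmentation failures; the default matches the excluded
    session fraction of the emulated study (162/1271).
    """

    group_profiles: list[GroupProfile] = field(default_factory=default_group_profiles)
    age_mean: float = 44.6
    age_sd: float = 10.8
    baseline_volume_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_VOLUME_MEAN)
    )
    baseline_volume_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_VOLUME_SD)
    )
    noise_cv: float = 0.005
    age_slope: float = -0.02
    visit_spacing: float = 1.0
    max_followup: float = 6.0
    p_session_missing: float = 0.127
    include_clinical: bool = True
    outlier_archetype: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0 <= self.p_session_missing < 1):
            raise ValueError("p_session_missing must be in [0, 1)")
        if sum(p.n_patients for p in self.group_profiles) <= 0:
            raise ValueError("total number of patients must be positive")
        if self.visit_spacing <= 0:
            raise ValueError("visit_spacing must be positive")

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, **kwargs)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def _draw_positive(rng, mean, sd, what, max_tries=100):
    """Draw Normal(mean, sd) until positive; bounded retries."""
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError(
        f"could not draw a positive {what} from N({mean}, {sd}) "
        f"after {max_tries} tries; check baseline volume configuration"
    )


def _outlier_rates(profiles: list[GroupProfile]) -> dict[str, float]:
    # >= 4 SD above every profile's mean in every region
    rates = {}
    for region in REGIONS:
        rates[region] = max(
            p.rate_mean[region] + 4.0 * p.rate_sd[region] for p in profiles
        ) + max(p.rate_sd[region] for p in profiles)
    return rates


def generate_cohort(config: CohortConfig) -> tuple[LongitudinalCohort, pd.DataFrame]:
    """Generate a cohort and its ground truth; deterministic given seed.

    Returns
    -------
    cohort : LongitudinalCohort
        Visit volumes (with noise and missingness applied) plus patient
        covariates.
    truth : pandas.DataFrame
        One row per patient: ``patient_id``, ``group``, and the planted
        per-region true rate columns ``true_rate_<region>`` (%/year,
        age effect included).
    """
    rng = np.random.default_rng(config.seed)
    phenotypes = np.array(["RR", "SP", "PP", "transitional"])
    phen_p = np.array([0.69, 0.17, 0.04, 0.10])

    max_sessions = int(np.floor(config.max_followup / config.visit_spacing)) + 1

    patient_rows, visit_rows, truth_rows = [], [], []
    specs: list[tuple[str, GroupProfile | None]] = []
    idx = 0
    for profile in config.group_profiles:
        for _ in range(profile.n_patients):
            idx += 1
            specs.append((f"P{idx:04d}", profile))
    if config.outlier_archetype:
        idx += 1
        specs.append((f"P{idx:04d}", None))
    outlier_rates = _outlier_rates(config.group_profiles) if config.outlier_archetype else None

    for pid, profile in specs:
        age = rng.normal(config.age_mean, config.age_sd)
        if profile is None:
            label = OUTLIER_LABEL
            true_rates = dict(outlier_rates)
            n_vis, relapse_rate, edss0 = 3, 0.3, 3.0
        else:
            label = profile.label
            true_rates = {
                r: rng.normal(profile.rate_mean[r], profile.rate_sd[r])
                + config.age_slope * (age - config.age_mean)
                for r in REGIONS
            }
            n_vis = int(np.clip(
                np.rint(rng.normal(profile.mean_followups, profile.sd_followups)),
                2, max_sessions,
            ))
            relapse_rate = profile.relapse_rate
            edss0 = profile.baseline_edss

        v0 = {
            r: _draw_positive(
                rng, config.baseline_volume_mean[r], config.baseline_volume_sd[r],
                f"baseline {r} volume",
            )
            for r in REGIONS
        }

        patient_rows.append({
            "patient_id": pid,
            "baseline_age": age,
            "sex": "F" if rng.random() < 0.667 else "M",
            "disease_duration": max(rng.normal(13.0, 9.0), 0.0),
            "phenotype": rng.choice(phenotypes, p=phen_p),
            "treated": bool(rng.random() < 0.65),
        })
        truth_rows.append({"patient_id": pid, "group": label,
                           **{f"true_rate_{r}": true_rates[r] for r in REGIONS}})

        edss = edss0
        for j in range(n_vis):
            t = j * config.visit_spacing
            row = {"patient_id": pid, "t_years": t}
            noise = _lognormal_factor(rng, config.noise_cv, len(REGIONS))
            for r, nz in zip(REGIONS, noise):
                row[r] = v0[r] * (1.0 + true_rates[r] / 100.0) ** t * nz
            if config.include_clinical:
                if j > 0 and rng.random() < 0.12:
                    edss = min(edss + 0.5, 10.0)
                row["edss"] = round(max(edss, 0.0) * 2) / 2
                row["t25fwt"] = max(rng.normal(7.0 + 0.8 * edss, 2.0), 2.0)
                row["d9hpt"] = max(rng.normal(20.0 + 1.2 * edss, 4.0), 10.0)
                row["nd9hpt"] = max(rng.normal(22.0 + 1.2 * edss, 4.0), 10.0)
                row["snfl"] = max(rng.normal(30.0, 12.0), 2.0)
                row["relapses_since_last_visit"] = (
                    0 if j == 0 else int(rng.poisson(relapse_rate * config.visit_spacing))
                )
            visit_rows.append(row)

    cohort = LongitudinalCohort(
        visits=pd.DataFrame(visit_rows),
        patients=pd.DataFrame(patient_rows),
    )
    truth = pd.DataFrame(truth_rows)

    if config.p_session_missing > 0:
        cohort = apply_missingness(cohort, config.p_session_missing, rng)
    return cohort, truth


def apply_missingness(
    cohort: LongitudinalCohort, p_session_missing: float, rng: np.random.Generator
) -> LongitudinalCohort:
    """Remove non-baseline sessions independently with probability p.

    Emulates whole-session exclusion for segmentation failures: the
    baseline visit is always retained, and patients left with fewer than
    two visits stay in the table (the exclusion filter is downstream).
    """
    if not (0 <= p_session_missing <= 1):
        raise ValueError("p_session_missing must be in [0, 1]")
    if p_session_missing == 0:
        return cohort
    visits = cohort.visits
    is_baseline = visits.groupby("patient_id")["t_years"].transform("min") == visits["t_years"]
    drop = (~is_baseline) & (rng.random(len(visits)) < p_session_missing)
    return LongitudinalCohort(
        visits=visits[~drop].reset_index(drop=True),
        patients=cohort.patients.copy(),
    )
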