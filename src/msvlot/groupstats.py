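"""Downstream group summaries: paired effect sizes, within-group
structure comparisons, clinical transforms, relapse rates, and the
EDSS-progression event rule.

Everything here is descriptive or bespoke; ordinary model fits (mixed
models, Cox regression, ANCOVA) are deliberately left to stock
statistical routines, for which these functions emit tidy tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import REGIONS, LongitudinalCohort
from .cluster import OUTLIER, Partition


@dataclass
class EffectSize:
    """Paired Cohen's d with a 95% normal-approximation CI."""

    d: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class ProgressionEvent:
    """Confirmed-progression outcome for one patient."""

    event: bool
    time_years: float


def paired_cohens_d(x, y) -> EffectSize:
    """Paired Cohen's d: mean(x - y) / sd(x - y), sample SD (n-1).

    The 95% CI uses the normal approximation d +- 1.96*sqrt(1/n +
    d^2/(2n)). Identical inputs give d = 0 (a well-defined no-effect
    limit); a constant non-zero difference has zero SD and no defined
    standardized effect, which raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("paired_cohens_d needs n >= 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return EffectSize(d=0.0, ci_low=0.0, ci_high=0.0, n=n)
        raise ValueError(
            "zero difference SD with non-zero mean: effect size undefined"
        )
    d = diff.mean() / sd
    se = np.sqrt(1.0 / n + d**2 / (2.0 * n))
    return EffectSize(d=float(d), ci_low=float(d - 1.96 * se),
                      ci_high=float(d + 1.96 * se), n=n)


#: Region pair order used in the comparison table (first minus second).
_PAIR_ORDER = ("brain_wm", "cortical_gm", "thalamus", "globus_pallidus",
               "striatum", "spinal_cord")


def region_pairs() -> list[tuple[str, str]]:
    """The 15 ordered region pairs, later-listed structure first."""
    pairs = []
    for i in range(1, len(_PAIR_ORDER)):
        for j in range(i):
            pairs.append((_PAIR_ORDER[i], _PAIR_ORDER[j]))
    return pairs


def within_group_structure_comparisons(
    rates: pd.DataFrame, partition: Partition
) -> pd.DataFrame:
    """Paired t-tests and paired Cohen's d between all region pairs,
    separately per non-outlier group.

    Returns one row per group x region pair (k_effective * 15 rows):
    mean difference in %/year with a 95% t-based CI, the paired t
    statistic and p-value, and the paired Cohen's d with its CI.
    Groups with fewer than 2 patients are skipped with a warning.
    """
    rows = []
    labels = partition.labels
    for group in sorted(labels[labels != OUTLIER].unique()):
        members = labels.index[labels == group]
        sub = rates.loc[rates.index.intersection(members)]
        if len(sub) < 2:
            warnings.warn(f"group {group} has < 2 patients; skipped")
            continue
        n = len(sub)
        tcrit = stats.t.ppf(0.975, n - 1)
        for ra, rb in region_pairs():
            a = sub[ra].to_numpy(float)
            b = sub[rb].to_numpy(float)
            diff = a - b
            mean = diff.mean()
            sd = diff.std(ddof=1)
            se = sd / np.sqrt(n)
            if sd > 0:
                t_stat, p_val = stats.ttest_rel(a, b)
                es = paired_cohens_d(a, b)
                d, d_lo, d_hi = es.d, es.ci_low, es.ci_high
            else:
                t_stat, p_val = (0.0, 1.0) if mean == 0 else (np.nan, np.nan)
                d = 0.0 if mean == 0 else np.nan
                d_lo = d_hi = d
            rows.append({
                "group": group,
                "comparison": f"{ra} - {rb}",
                "n": n,
                "mean_diff": mean,
                "ci_low": mean - tcrit * se,
                "ci_high": mean + tcrit * se,
                "t": float(t_stat),
                "p_value": float(p_val),
                "cohens_d": d,
                "d_ci_low": d_lo,
                "d_ci_high": d_hi,
            })
    return pd.DataFrame(rows)


def transform_clinical(values, kind: str):
    """Normality-improving transforms of clinical scores.

    EDSS -> log(EDSS + 1) (the +1 offset keeps EDSS 0 defined); the
    9-hole peg tests -> log(seconds); T25fwt -> 1/seconds (order
    reversing). All transforms are strictly monotone on their domains.
    """
    v = np.asarray(values, float)
    kind_u = kind.upper()
    if kind_u == "EDSS":
        if (v < 0).any():
            raise ValueError("EDSS must be >= 0")
        return np.log1p(v)
    if kind_u in ("D9HPT", "ND9HPT"):
        if (v <= 0).any():
            raise ValueError(f"{kind} must be > 0 for a log transform")
        return np.log(v)
    if kind_u == "T25FWT":
        if (v <= 0).any():
            raise ValueError("T25fwt must be > 0 for an inverse transform")
        return 1.0 / v
    raise ValueError(f"unknown clinical measure {kind!r}")


def annual_relapse_rate(relapse_counts, followup_years) -> float:
    """Relapses per year over a patient's follow-up span."""
    followup_years = float(followup_years)
    if followup_years <= 0:
        raise ValueError("follow-up span must be positive")
    return float(np.sum(relapse_counts) / followup_years)


def group_relapse_rates(
    cohort: LongitudinalCohort, partition: Partition
) -> pd.DataFrame:
    """Per-group mean +- SD of per-patient annual relapse rates.

    The group mean is the mean of per-patient rates, not a pooled
    count-over-time ratio.
    """
    if "relapses_since_last_visit" not in cohort.visits.columns:
        raise ValueError("cohort has no relapse counts")
    per_patient = {}
    for pid, grp in cohort.visits.groupby("patient_id"):
        span = grp["t_years"].max() - grp["t_years"].min()
        if span <= 0:
            continue
        per_patient[pid] = annual_relapse_rate(
            grp["relapses_since_last_visit"].fillna(0), span
        )
    rows = []
    labels = partition.labels
    for group in sorted(labels[labels != OUTLIER].unique()):
        members = [i for i in labels.index[labels == group] if i in per_patient]
        r = np.array([per_patient[i] for i in members])
        rows.append({
            "group": group,
            "n": len(r),
            "relapse_rate_mean": r.mean() if len(r) else np.nan,
            "relapse_rate_sd": r.std(ddof=1) if len(r) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def progression_events(
    edss_series: pd.DataFrame,
    relapse_times,
    baseline_edss: float | None = None,
) -> ProgressionEvent:
    """First confirmed EDSS progression, relapse-independent.

    A visit qualifies when the EDSS increase from baseline reaches 1.0
    point (baseline <= 5.5) or 0.5 point (baseline > 5.5) AND no relapse
    occurred in the 12 months before that visit. Returns the event flag
    and the time of the first qualifying visit, or censoring at the
    last visit.

    ``edss_series`` needs columns ``t_years`` and ``edss``, time-ordered;
    ``relapse_times`` are event times in years on the same clock.
    """
    s = edss_series.sort_values("t_years")
    t = s["t_years"].to_numpy(float)
    e = s["edss"].to_numpy(float)
    if len(t) == 0:
        raise ValueError("empty EDSS series")
    if baseline_edss is None:
        baseline_edss = e[0]
    threshold = 1.0 if baseline_edss <= 5.5 else 0.5
    relapse_times = np.asarray(list(relapse_times), float)

    for ti, ei in zip(t, e):
        if np.isnan(ei):
            warnings.warn(f"missing EDSS at t={ti}; visit skipped")
            continue
        if ei - baseline_edss >= threshold:
            recent = (relapse_times > ti - 1.0) & (relapse_times <= ti)
            if not recent.any():
                return ProgressionEvent(event=True, time_years=float(ti))
    return ProgressionEvent(event=False, time_years=float(t[-1]))


def group_rate_summary(rates: pd.DataFrame, partition: Partition) -> pd.DataFrame:
    """Per-group, per-region rate mean, SD and range (%/year)."""
    rows = []
    labels = partition.labels
    for group in sorted(labels[labels != OUTLIER].unique()):
        members = labels.index[labels == group]
        sub = rates.loc[rates.index.intersection(members)]
        for region in REGIONS:
            v = sub[region].to_numpy(float)
            rows.append({
                "group": group,
                "region": region,
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "min": v.min(),
                "max": v.max(),
            })
    return pd.DataFrame(rows)


def baseline_clinical_summary(
    cohort: LongitudinalCohort, partition: Partition
) -> pd.DataFrame:
    """Per-group summaries of baseline covariates and clinical scores."""
    baseline = (
        cohort.visits.sort_values("t_years").groupby("patient_id").first()
    )
    merged = cohort.patients.set_index("patient_id").join(
        baseline, how="left", rsuffix="_visit"
    )
    rows = []
    labels = partition.labels
    numeric = ["baseline_age", "disease_duration"] + [
        c for c in ("edss", "t25fwt", "d9hpt", "nd9hpt", "snfl") if c in merged
    ]
    for group in sorted(labels[labels != OUTLIER].unique()):
        members = labels.index[labels == group]
        sub = merged.loc[merged.index.intersection(members)]
        row = {"group": group, "n": len(sub)}
        for col in numeric:
            v = sub[col].dropna().to_numpy(float)
            row[f"{col}_mean"] = v.mean() if len(v) else np.nan
            row[f"{col}_sd"] = v.std(ddof=1) if len(v) > 1 else 0.0
        if "sex" in sub:
            row["n_female"] = int((sub["sex"] == "F").sum())
        rows.append(row)
    return pd.DataFrame(rows)


def progression_table(
    cohort: LongitudinalCohort, partition: Partition | None = None
) -> pd.DataFrame:
    """Per-patient progression events, ready for survival model fits."""
    if "edss" not in cohort.visits.columns:
        raise ValueError("cohort has no EDSS records")
    has_relapses = "relapses_since_last_visit" in cohort.visits.columns
    rows = []
    for pid, grp in cohort.visits.groupby("patient_id"):
        grp = grp.sort_values("t_years")
        relapse_times = []
        if has_relapses:
            # place each interval's relapses at the reporting visit
            for _, r in grp.iterrows():
                k = r.get("relapses_since_last_visit", 0)
                if pd.notna(k):
                    relapse_times.extend([r["t_years"]] * int(k))
        ev = progression_events(grp[["t_years", "edss"]], relapse_times)
        row = {"patient_id": pid, "event": ev.event, "time_years": ev.time_years}
        if partition is not None and pid in partition.labels.index:
            row["group"] = partition.labels.loc[pid]
        rows.append(row)
    return pd.DataFrame(rows)
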