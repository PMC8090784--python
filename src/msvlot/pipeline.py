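"""End-to-end orchestration: cohort in, stratification artifacts out.

Stage order: exclusion filter -> annualized rates -> age residuals ->
uniform-weight PCA -> component retention -> Ward clustering -> cut ->
outlier flagging -> weighted-resampling stability -> group summaries.
Every output lands under the configured directory; a JSON run manifest
(config echo, versions, per-stage counts) is written atomically at the
end.
"""

from __future__ import annotations

import dataclasses
import json
import os
import platform
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .cluster import (Partition, choose_k, cut_dendrogram, flag_outliers,
                      to_newick, ward_linkage)
from .cohort import LongitudinalCohort, read_cohort_csv
from .groupstats import (baseline_clinical_summary, group_rate_summary,
                         group_relapse_rates, progression_table,
                         within_group_structure_comparisons)
from .pca import RetentionCriteria, select_components, variable_stats, weighted_pca
from .rates import age_residuals, annualized_rates, exclusion_filter, to_long
from .stability import WeightScheme, run_stability


@dataclass
class PipelineConfig:
    """Everything a full run needs; JSON-serializable.

    ``k`` fixes the number of clusters; when None the max-gap heuristic
    chooses it within ``k_range``. ``n_reps`` = 0 skips the stability
    stage.
    """

    visits_csv: str | None = None
    patients_csv: str | None = None
    out_dir: str = "msvlot_out"
    min_visits: int = 2
    criteria: RetentionCriteria = field(default_factory=RetentionCriteria)
    k: int | None = None
    k_range: tuple[int, int] = (2, 8)
    min_size: int = 2
    scheme: WeightScheme = field(default_factory=WeightScheme)
    n_reps: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("criteria"), dict):
            d["criteria"] = RetentionCriteria(**d["criteria"])
        if isinstance(d.get("scheme"), dict):
            d["scheme"] = WeightScheme(**d["scheme"])
        if isinstance(d.get("k_range"), list):
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _write_json_atomic(obj: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, default=str)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _pca_table(pca, m: int) -> pd.DataFrame:
    """Published-style PCA table: eigenvalue/percent header block, then
    coordinate / cos2 / contribution rows per variable, PC columns."""
    comps = [f"PC{j + 1}" for j in range(m)]
    rows = [
        {"variable": "", "statistic": "percent_variance",
         **dict(zip(comps, pca.percent_variance[:m]))},
        {"variable": "", "statistic": "eigenvalue",
         **dict(zip(comps, pca.eigenvalues[:m]))},
    ]
    for var in pca.variable_coordinates.index:
        for stat, table in (("coordinate", pca.variable_coordinates),
                            ("cos2", pca.cos2),
                            ("contribution", pca.contributions)):
            rows.append({"variable": var, "statistic": stat,
                         **{c: table.loc[var, c] for c in comps}})
    return pd.DataFrame(rows)


def run_all(
    config: PipelineConfig, cohort: LongitudinalCohort | None = None
) -> dict:
    """Execute the full pipeline and write all artifacts.

    A cohort object may be passed directly (e.g. fresh from the
    simulator); otherwise it is read from the configured CSV paths.
    Returns the run manifest. Deterministic given the config seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "msvlot": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    stage = "read_cohort"
    try:
        if cohort is None:
            if not (config.visits_csv and config.patients_csv):
                raise ValueError("no cohort given and no CSV paths configured")
            cohort = read_cohort_csv(config.visits_csv, config.patients_csv)
        manifest["stages"]["read_cohort"] = {
            "n_patients": cohort.n_patients, "n_visits": cohort.n_visits,
        }

        stage = "exclusion_filter"
        filtered, report = exclusion_filter(cohort, config.min_visits)
        manifest["stages"][stage] = {
            "n_sessions_in": report.n_sessions_in,
            "n_sessions_incomplete": report.n_sessions_incomplete,
            "n_patients_dropped": report.n_patients_dropped,
            "patients_dropped": report.patients_dropped,
            "n_patients_out": report.n_patients_out,
        }

        stage = "annualized_rates"
        rates = annualized_rates(filtered)
        rates.to_csv(out / "rates.csv")
        to_long(rates, "rate").to_csv(out / "rates_long.csv", index=False)
        manifest["stages"][stage] = {"n_patients": len(rates)}

        stage = "age_residuals"
        residuals = age_residuals(rates, filtered)
        residuals.residuals.to_csv(out / "residuals.csv")
        residuals.fits.to_csv(out / "age_fits.csv")
        manifest["stages"][stage] = {
            "age_slopes": residuals.fits["age_slope"].to_dict()
        }

        stage = "pca"
        pca = weighted_pca(residuals)
        m, diagnostics = select_components(pca, config.criteria)
        _pca_table(pca, pca.n_components).to_csv(out / "pca_table.csv", index=False)
        pca.scores.to_csv(out / "scores.csv")
        manifest["stages"][stage] = {
            "eigenvalues": pca.eigenvalues.tolist(),
            "percent_variance": pca.percent_variance.tolist(),
            "n_retained": m,
            "diagnostics": diagnostics,
        }

        stage = "ward_cluster"
        dendro = ward_linkage(pca.scores.iloc[:, :m])
        (out / "dendrogram.newick").write_text(to_newick(dendro) + "\n")
        dendro.merges().to_csv(out / "merges.csv", index=False)
        k = config.k if config.k is not None else choose_k(
            dendro, range(config.k_range[0], config.k_range[1] + 1)
        )
        partition = flag_outliers(cut_dendrogram(dendro, k), config.min_size)
        partition.to_frame().to_csv(out / "partition.csv", index=False)
        manifest["stages"][stage] = {
            "k_cut": k,
            "k_effective": partition.k_effective,
            "group_sizes": {int(g): int(s) for g, s in partition.sizes().items()},
            "n_outliers": len(partition.outlier_ids),
            "outlier_ids": partition.outlier_ids,
        }

        stage = "stability"
        if config.n_reps > 0:
            stab = run_stability(
                residuals, partition, criteria=config.criteria, k=k,
                min_size=config.min_size, n_reps=config.n_reps,
                scheme=config.scheme, seed=config.seed,
            )
            _write_json_atomic(stab.summary(), out / "stability.json")
            manifest["stages"][stage] = stab.summary()
        else:
            manifest["stages"][stage] = {"skipped": True}

        stage = "group_stats"
        group_rate_summary(rates, partition).to_csv(
            out / "group_rate_summary.csv", index=False
        )
        comparisons = within_group_structure_comparisons(rates, partition)
        comparisons.to_csv(out / "within_group_comparisons.csv", index=False)
        gs: dict = {"n_comparison_rows": len(comparisons)}
        if "relapses_since_last_visit" in filtered.visits.columns:
            group_relapse_rates(filtered, partition).to_csv(
                out / "group_relapse_rates.csv", index=False
            )
        if "edss" in filtered.visits.columns:
            events = progression_table(filtered, partition)
            events.to_csv(out / "progression_events.csv", index=False)
            gs["n_events"] = int(events["event"].sum())
        baseline_clinical_summary(filtered, partition).to_csv(
            out / "baseline_summary.csv", index=False
        )
        manifest["stages"][stage] = gs
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["finished"] = datetime.now(timezone.utc).isoformat()
        _write_json_atomic(manifest, out / "manifest.json")
        raise
    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    _write_json_atomic(manifest, out / "manifest.json")
    return manifest
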