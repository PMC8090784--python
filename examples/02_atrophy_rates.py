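"""Annualized atrophy rates and age residualization on a tiny cohort.

The per-patient rate of each region is the mean of the annualized
percent changes between consecutive complete MRI sessions; each
region's rates are then residualized on baseline age by OLS.
"""

import pandas as pd

from msvlot import (REGIONS, LongitudinalCohort, age_residuals,
                    annualized_rates, exclusion_filter)

# three patients; P3 has a session with a missing spinal-cord volume
visits = []
trajectories = {
    "P1": [(0, 2.00), (1, 1.90), (2, 1.70)],   # shrinking cord
    "P2": [(0, 2.40), (1, 2.40), (2, 2.40)],   # stable
    "P3": [(0, 2.20), (1, None), (2, 2.10), (3, 2.05)],
}
for pid, points in trajectories.items():
    for t, sc in points:
        row = {"patient_id": pid, "t_years": float(t)}
        for region in REGIONS:
            row[region] = sc if region == "spinal_cord" else 10.0
        visits.append(row)
cohort = LongitudinalCohort(
    visits=pd.DataFrame(visits),
    patients=pd.DataFrame({"patient_id": ["P1", "P2", "P3"],
                           "baseline_age": [35.0, 45.0, 55.0]}),
)

filtered, report = exclusion_filter(cohort)
print(f"sessions dropped as incomplete: {report.n_sessions_incomplete}")

rates = annualized_rates(filtered)
print("\nspinal cord rates (%/year):")
print(rates["spinal_cord"].round(3))

residuals = age_residuals(rates, filtered)
print("\nage-adjusted residual rates (%/year):")
print(residuals.residuals["spinal_cord"].round(3))
print("\nfitted age slope (%/year per year of age):",
      round(residuals.fits.loc['spinal_cord', 'age_slope'], 4))
print("\nP1 loses cord volume at ~7.8%/year (mean of -5.0 and -10.5 over "
      "its two intervals); residuals are what remains after the shared "
      "age trend is removed.")
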