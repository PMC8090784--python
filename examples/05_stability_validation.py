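"""Validate cluster stability by weighted-resampling cross-validation.

Each repetition nearly silences a random 10% of patients (PCA weight
0.0001), doubles another 10% (weight 2), re-runs PCA + Ward, and scores
agreement with the reference partition by the adjusted Rand index
(1 = identical, ~0 = chance) and the base-10 variation-of-information
distance (0 = identical, log10(n) = maximal disagreement).
"""

import warnings

import numpy as np

from msvlot import (CohortConfig, age_residuals, annualized_rates,
                    cut_dendrogram, exclusion_filter, flag_outliers,
                    generate_cohort, run_stability, select_components,
                    ward_linkage, weighted_pca)

cohort, _ = generate_cohort(CohortConfig(seed=42))
filtered, _ = exclusion_filter(cohort)
residuals = age_residuals(annualized_rates(filtered), filtered)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    pca = weighted_pca(residuals)
    m, _ = select_components(pca)
reference = flag_outliers(cut_dendrogram(ward_linkage(pca.scores.iloc[:, :m]), 4))

result = run_stability(residuals, reference, k=4, n_reps=200, seed=0)
print(f"repetitions: {result.n_reps} ({result.n_failures} failed)")
print(f"ARI: {result.ari_mean:.2f} +- {result.ari_sd:.2f}")
print(f"VI:  {result.vi_mean:.2f} +- {result.vi_sd:.2f} "
      f"(maximum possible {np.log10(len(reference.labels)):.2f})")
print("\nA mean ARI well above 0 with moderate SD indicates the grouping "
      "largely survives contribution perturbations; lower values flag "
      "boundary patients that migrate between adjacent groups.")
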