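"""Decompose between-structure volume-loss patterns with weighted PCA.

Each principal component of the age-adjusted rates captures one pattern
of covariation across the six CNS regions; the retention rule keeps the
leading components covering >=90% of variance with eigenvalues above
0.7, with broken-stick and scree-elbow diagnostics on the side.
"""

import numpy as np

from msvlot import (CohortConfig, age_residuals, annualized_rates,
                    broken_stick, exclusion_filter, generate_cohort,
                    select_components, variable_stats, weighted_pca)

cohort, _ = generate_cohort(CohortConfig(seed=42))
filtered, _ = exclusion_filter(cohort)
residuals = age_residuals(annualized_rates(filtered), filtered)

pca = weighted_pca(residuals)  # uniform patient weights
print("eigenvalues:        ", np.round(pca.eigenvalues, 3))
print("percent variance:   ", np.round(pca.percent_variance, 1))
print("broken-stick (p=6): ", np.round(100 * broken_stick(6), 1))

m, diagnostics = select_components(pca)
print(f"\nretained components: {m} "
      f"(cumulative {diagnostics['cumulative_percent'][m - 1]:.1f}%, "
      f"elbow diagnostic at k={diagnostics.get('elbow_k')})")

stats = variable_stats(pca)
pc1 = stats[stats.component == "PC1"].set_index("variable")
print("\nPC1 variable statistics:")
print(pc1[["coordinate", "cos2", "contribution"]].round(2))
print("\n'cos2' is the share of a region's rate variance captured by the "
      "component; 'contribution' is the region's share (%) of the "
      "component's inertia.")
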