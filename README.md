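# msvlot

Stratification of multiple sclerosis (MS) patients by their patterns of
CNS **volume loss over time (VLOT)**, from longitudinal MRI volumetry.

MS damages different central nervous system compartments at different
speeds in different patients: some lose spinal cord and thalamic volume
fast, some mainly deep gray nuclei, some show little regional
dissociation, and a small group even shows paradoxical spinal-cord and
cortical volume *increase* with marked white-matter loss. `msvlot`
implements a reproducible pipeline that turns per-visit volumes of six
CNS regions (spinal cord, striatum, globus pallidus, thalamus, cortical
gray matter, brain white matter) into a data-driven patient grouping,
for researchers working on biologic (rather than purely clinical)
MS subtyping.

## Method

For patient *i*, region *j*, with complete MRI sessions at times
*t₁ < … < t_m* and volumes *V₁ … V_m*, the annualized rate is the mean
of consecutive-pair percent changes

> r_ij = mean over pairs of 100 · (V_{k+1} − V_k) / (V_k · (t_{k+1} − t_k))  [%/year]

Sessions missing any region are dropped whole; patients with fewer than
two complete sessions are excluded. Each region's rates are
residualized on baseline age by OLS, and the residual matrix **X**
(patients × 6) enters a **row-weighted covariance-metric PCA** via SVD
of diag(√w) (X − μ_w): eigenvalues λ_k, patient scores, and variable
coordinates c_jk = e_jk·√λ_k with the derived statistics
cos²_jk = c²_jk / Σ_k c²_jk (quality of representation) and
ctr_jk = 100·c²_jk / Σ_j c²_jk (contribution). Components are retained
while the cumulative variance is below 90% and eigenvalues stay above
0.7; the broken-stick rule and scree elbow are reported as diagnostics.
Patients are clustered on the retained scores with **Ward's
minimum-variance criterion** (Lance–Williams on squared Euclidean
distances, square-root heights); the dendrogram is cut at k (explicit
or largest-height-gap), and clusters below a minimum size are excluded
as outliers.

Stability is validated by **weighted resampling**: each repetition
gives a random 10% of patients PCA weight 0.0001 and another 10%
weight 2, re-runs PCA → retention → Ward → cut, and scores agreement
with the reference partition by the **adjusted Rand index** (1 =
identical, ~0 = chance) and **Meilă's variation of information** in
base-10 logarithms (0 = identical, log₁₀(n) = maximal disagreement).

Because clinical MRI datasets of this kind are not freely deposited,
the package ships a synthetic-cohort generator that plants four latent
groups (sizes 14/59/141/11) with published per-region rate profiles,
geometric volume trajectories, log-normal measurement noise, an age
effect, and session-level missingness — together with ground-truth
labels for recovery testing.

## Worked example

```sh
python examples/05_stability_validation.py
```

```
repetitions: 200 (0 failed)
ARI: 0.81 +- 0.08
VI:  0.17 +- 0.05 (maximum possible 2.35)
```

A default synthetic cohort (225 patients) is generated, clustered into
k = 4 groups, and perturbed 200 times with the 10%/10%/80% weight
scheme. The mean adjusted Rand index of 0.81 says the grouping largely
survives contribution perturbations; the VI of 0.17 is far below the
maximal 2.35 = log₁₀(225). The other `examples/` scripts walk through
simulation, rate estimation, the PCA pattern table, clustering with
outlier exclusion, and the group-level clinical summaries. The same
steps are scriptable from the shell:

```sh
msvlot simulate --seed 42 --out cohort/
msvlot run-all --visits cohort/visits.csv --patients cohort/patients.csv \
    --k 4 --reps 1000 --seed 0 --out run/
```

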