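# Methods

## Pipeline model and assumptions

The pipeline assumes the input volumes are already segmented,
quality-controlled and head-size normalized upstream; it treats them as
exact measurements of six CNS regions at known times relative to each
patient's baseline. All downstream inference is cross-sectional over
patients: a patient's longitudinal information is compressed into one
number per region — the mean annualized percent change over
consecutive complete-session pairs — before any multivariate step.

Choices embedded in the rate estimator:

- **Consecutive pairs, unweighted.** "All available time-points" is
  read as the chain of successive sessions, not all pairwise
  combinations, and pairs are averaged without interval-length weights.
  Under a geometric trajectory (constant percent rate) with annual
  visits this estimator is exactly unbiased; with skipped sessions the
  pair over a longer interval estimates the annualized compound rate,
  which is slightly attenuated relative to the per-year rate for large
  |r|.
- **Forward percent change.** The denominator is the earlier session's
  volume.
- **Session completeness.** A session missing any region is removed
  whole, so every retained patient contributes all six regions and the
  residual matrix has no missing cells.
- **Age residualization** uses baseline age, per-region simple OLS.
  Residuals are centered and age-orthogonal by construction; with
  degenerate (constant) ages the fit falls back to centering.

## Weighted PCA

The PCA is a duality-diagram/SVD formulation: row weights w (normalized
to sum 1) define weighted column means and the weighted covariance
C = Xᶜᵀ diag(w) Xᶜ, whose eigenstructure comes from the SVD of
diag(√w) Xᶜ. Variables enter **unstandardized** (covariance metric):
the published eigenvalue-to-percent ratios imply a total inertia of
≈ 6.9, which a 6-variable correlation PCA (inertia exactly 6) cannot
produce, so the covariance metric is the only reading consistent with
the table arithmetic this package mirrors.

Variable coordinates use c_jk = e_jk·√λ_k. The published coordinates
square-sum to ≈ 3.07 on component 1 against an eigenvalue of 2.69,
which is inconsistent with any single scaling convention; the ratio
definitions cos² = c²/Σ_k c² and ctr = 100·c²/Σ_j c² are internally
consistent with the published table and are therefore what
`variable_stats` implements (they are scale-free in each direction, so
the coordinate-convention ambiguity does not propagate).

Eigenvector signs are fixed by making each component's
largest-magnitude loading positive, so output is reproducible across
linear-algebra backends. Zero-weight (or near-zero-weight) patients do
not influence the fit but still receive scores by projection — this is
what lets the stability loop cluster *all* patients each repetition.

Retention: the smallest m with cumulative variance ≥ 90% *and*
λ_m > 0.7; if the two floors cannot be met jointly the
cumulative-variance rule alone applies, with a warning. The 0.7
eigenvalue floor is applied as an absolute threshold even though such
rules usually presume unit-variance variables, because that is how the
emulated analysis states it. Broken stick and scree elbow are
diagnostics only: the emulated analysis retained a first component
whose variance share (38.9%) is *below* the p = 6 broken-stick
expectation (≈ 40.8%), so the broken stick cannot have been a hard
filter there, and it is not one here.

## Ward clustering

`ward_linkage` delegates to `scipy.cluster.hierarchy.linkage(method="ward")`,
which implements the Lance–Williams update on squared Euclidean
distances with square-root heights ("ward.D2" semantics): two
singletons merge at their Euclidean distance and each height is
√(2·ΔESS). This is the dialect that genuinely minimizes within-cluster
variance on the component scores. The test suite verifies merge-by-merge
equivalence with an independent exhaustive-pair-search minimum-variance
agglomerator on hundreds of small random datasets. Exact merge ties
follow scipy's nearest-neighbor-chain order; ties have measure zero for
continuous scores.

The visual dendrogram cut is replaced by a reproducible largest-gap
heuristic over successive merge heights, always overridable by an
explicit k — the recommended usage, since the gap heuristic merges
adjacent groups when cluster separations are comparable to within-group
spread. Clusters smaller than `min_size` (default 2) are flagged as
outliers and excluded from group statistics; remaining groups are
relabelled by decreasing size (ties broken by smallest patient id).
Patients are unweighted in the clustering even when the upstream PCA
was weight-perturbed: the perturbation weights are *contribution
weights to the PCA*, entering the clustering only through the scores.

## Stability validation

Each repetition draws disjoint random subsets of round(0.10·n) patients
for down-weighting (0.0001 — near-silencing while keeping weighted
means defined) and up-weighting (2), reruns PCA, re-applies the
retention rule (the retained count may legitimately differ from the
reference run), re-clusters, cuts at the reference k, and flags
undersized clusters. Agreement with the reference is scored over the
patients non-outlier in both partitions.

- **ARI** from the pair-counting contingency formula; two trivial
  partitions (denominator zero) return 1.
- **VI** = H(P) + H(Q) − 2·I(P,Q) in **base-10 logarithms** — the only
  base under which the published maximum for 225 items, 2.35, equals
  log(225) (natural logs would give 5.42). Contingency terms are summed
  in sorted order so both metrics are bit-exactly symmetric in their
  arguments.

Per-repetition RNG substreams are spawned from the seed
(`SeedSequence.spawn`), so any contiguous repetition range reproduces
exactly the values it would contribute to a full run; disjoint ranges
concatenate to the full result. Repetitions that fail (degenerate PCA)
are recorded and skipped; more than 1% failures aborts the run.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed to the published cohort description:

| parameter | default | basis |
|---|---|---|
| group sizes | 14 / 59 / 141 / 11 | published group sizes |
| rate means, SDs (%/yr) | per group × region | published group profiles |
| follow-up count mean/SD | 3.00/1.18, 4.19/1.82, 5.34/1.43, 2.64/0.81 | published per group |
| baseline volumes (cm³) | pooled means/SDs per region | published baseline table |
| baseline age | 44.6 ± 10.8 y | pooled published values |
| `noise_cv` | 0.005 | no published value; ~0.5% scan–rescan error |
| `age_slope` | −0.02 %/yr per year of age | no published value; small aging acceleration, removed by residualization |
| `p_session_missing` | 0.127 | published excluded-session fraction (162/1271) |
| relapse rates (events/yr) | 0.42, 0.45, 0.24, 0.22 | published per group |

Trajectories are geometric, V(t) = V₀·(1 + r/100)ᵗ, so the
consecutive-pair estimator recovers the planted rate exactly at zero
noise — the generator doubles as an oracle for the rate module.
Measurement noise is multiplicative log-normal with mean 1 and CV
`noise_cv` (volume error scales with structure size). Each patient's
planted rate is constant over time (no within-patient drift — a known
simplification). EDSS trajectories, timed motor scores and sNfL values
are generated as plausible but *uncalibrated* plumbing so the
downstream clinical operations can be exercised; only the relapse
intensities carry published values. An optional `outlier_archetype`
flag injects one patient ≥ 4 SD from every profile in every region,
emulating a single unclassifiable case.

### What passing tests do and do not show

The planted within-group SDs equal the *observed* within-group spreads
of a grouping that was itself produced by clustering. Re-planting them
as Gaussian spreads makes the two largest groups overlap substantially
(≈ 9% Bayes error in each direction with oracle knowledge of the
mixture). Consequently, full-pipeline recovery of the planted partition
on the default cohort plateaus around ARI 0.55–0.77 — bounded by that
overlap, not by implementation error — and even the Bayes-optimal
assignment averages only ≈ 0.85. Recovery tests on the default cohort
therefore characterize behaviour under realistic overlap; clean
parameter-recovery checks use explicitly well-separated profiles. None
of this validates the pipeline against real scanner artifacts,
non-Gaussian group shapes, or informative missingness, which the
generator does not model.

## Numerical and design choices

- Rates are unit-invariant per region (mm³ vs cm³ both accepted).
- Paired Cohen's d uses the sample SD (n−1) of the differences and the
  normal-approximation CI d ± 1.96·√(1/n + d²/(2n)). All-zero
  differences return d = 0 (no-effect limit); constant non-zero
  differences have no defined standardized effect and raise.
- EDSS is log-transformed as log(EDSS + 1) since the scale includes 0;
  the 9-hole peg tests use log(s), the timed walk 1/s.
- Confirmed progression: first visit with an EDSS increase ≥ 1.0 point
  (baseline ≤ 5.5) or ≥ 0.5 (baseline > 5.5) and no relapse in the 12
  months preceding that visit; otherwise censored at the last visit.
  Relapses reported per interval are placed at the reporting visit.
- Mean annual relapse rate divides total relapses by the patient's
  follow-up span; group values average per-patient rates.
- Ordinary model fits (mixed models, Cox regression, ANCOVA, Welch
  t-tests) are out of scope by design: the pipeline emits tidy
  per-patient tables ready for stock routines.

## Problem sizes

Default test and validation runs use the full 225-patient cohort;
stability checks use 100–200 repetitions (each repetition is one
225×6 SVD plus one 225-leaf linkage, ≈ 2 ms), and Ward-oracle
equivalence uses 200 random datasets of ≤ 7 points, where exhaustive
pair search is exact and fast. A full 10,000-repetition stability run
at this cohort size completes in well under a minute.

## Known limitations

- The consecutive-pair rate estimator ignores pair-interval length and
  within-patient measurement-error correlation; a mixed-effects slope
  would be more efficient but is deliberately not what this pipeline
  defines.
- The largest-gap k heuristic is a stand-in for a visual cut and merges
  overlapping groups; fix k explicitly for confirmatory analyses.
- The coordinate-scaling ambiguity in the emulated PCA table is
  unresolved; only the ratio statistics (cos², contribution) are
  asserted against published values.
- Synthetic clinical trajectories are structural placeholders, not
  calibrated natural-history models.
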