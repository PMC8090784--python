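"""Partition-agreement metrics and the weighted-resampling validation."""

import numpy as np
import pandas as pd
import pytest

from msvlot import (GroupProfile, Partition, WeightScheme,
                    adjusted_rand_index, age_residuals, annualized_rates,
                    cut_dendrogram, exclusion_filter, flag_outliers,
                    generate_cohort, run_stability, sample_weights,
                    variation_of_information, ward_linkage, weighted_pca)
from msvlot.cohort import REGIONS
from msvlot.simulate import CohortConfig


def random_partition(rng, n, max_k=5):
    return rng.integers(0, max_k, size=n)


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self, rng):
        p = random_partition(rng, 50)
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)

    def test_label_permutation_invariance(self, rng):
        p = random_partition(rng, 60, 4)
        q = random_partition(rng, 60, 4)
        remap = {0: 7, 1: 3, 2: 9, 3: 0}
        q2 = np.array([remap[int(x)] for x in q])
        assert adjusted_rand_index(p, q) == pytest.approx(
            adjusted_rand_index(p, q2), abs=1e-12
        )

    def test_crossed_pairs_give_minus_half(self):
        """p = {1,1,2,2}, q = {1,2,1,2}: all 6 item pairs disagree in a
        maximally balanced way, giving ARI = -0.5."""
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_symmetry_exact(self, rng):
        for _ in range(20):
            p = random_partition(rng, 30)
            q = random_partition(rng, 30)
            assert adjusted_rand_index(p, q) == adjusted_rand_index(q, p)

    def test_matches_reference_implementation(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(25):
            p = random_partition(rng, 40)
            q = random_partition(rng, 40)
            assert adjusted_rand_index(p, q) == pytest.approx(
                sklearn_metrics.adjusted_rand_score(p, q), abs=1e-12
            )

    def test_trivial_partitions_return_one(self):
        assert adjusted_rand_index([0, 0, 0], [1, 1, 1]) == 1.0

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1], [1])


class TestVariationOfInformation:
    def test_extreme_partitions_reach_log10_n(self):
        n = 225
        vi = variation_of_information(np.arange(n), np.zeros(n))
        assert vi == pytest.approx(np.log10(n), abs=1e-12)
        assert round(vi, 2) == 2.35

    def test_identical_partitions_score_zero(self, rng):
        p = random_partition(rng, 50)
        assert variation_of_information(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_contingency_2x2(self):
        """p = {A,A,B,B}, q = {A,A,A,B}: entropies and mutual information
        from the 2x2 contingency table, base 10."""
        p = ["A", "A", "B", "B"]
        q = ["A", "A", "A", "B"]
        h_p = -2 * (0.5 * np.log10(0.5))
        h_q = -(0.75 * np.log10(0.75) + 0.25 * np.log10(0.25))
        mi = (0.5 * np.log10(0.5 / (0.5 * 0.75))
              + 0.25 * np.log10(0.25 / (0.5 * 0.75))
              + 0.25 * np.log10(0.25 / (0.5 * 0.25)))
        expected = h_p + h_q - 2 * mi
        assert variation_of_information(p, q) == pytest.approx(expected, abs=1e-12)

    def test_metric_properties_on_random_triples(self, rng):
        """Symmetry exact; triangle inequality on 100 random triples of
        30 items; upper bound log10(n) everywhere."""
        n = 30
        for _ in range(100):
            p, q, r = (random_partition(rng, n) for _ in range(3))
            d_pq = variation_of_information(p, q)
            d_qp = variation_of_information(q, p)
            assert d_pq == d_qp
            d_qr = variation_of_information(q, r)
            d_pr = variation_of_information(p, r)
            assert d_pr <= d_pq + d_qr + 1e-12
            assert max(d_pq, d_qr, d_pr) <= np.log10(n) + 1e-12

    def test_log_base_choice(self):
        n = 16
        vi2 = variation_of_information(np.arange(n), np.zeros(n), log_base=2)
        assert vi2 == pytest.approx(4.0)


class TestSampleWeights:
    def test_default_scheme_counts_for_ten_patients(self, rng):
        w = sample_weights(10, WeightScheme(), rng)
        values, counts = np.unique(w, return_counts=True)
        assert dict(zip(values, counts)) == {1e-4: 1, 1.0: 8, 2.0: 1}

    def test_null_scheme_gives_uniform_weights(self, rng):
        scheme = WeightScheme(frac_down=0.0, frac_up=0.0)
        np.testing.assert_array_equal(sample_weights(12, scheme, rng), 1.0)

    def test_empirical_down_weight_frequency(self, rng):
        """Each patient down-weighted with frequency ~= 0.10 over many
        draws (n = 225, defaults)."""
        n, reps = 225, 400
        hits = np.zeros(n)
        for _ in range(reps):
            hits += sample_weights(n, WeightScheme(), rng) == 1e-4
        freq = hits / reps
        # per-patient binomial(400, 0.1): 4 SD band
        sd = np.sqrt(0.1 * 0.9 / reps)
        assert (np.abs(freq - 0.10) < 4 * sd + 1e-9).all()
        assert freq.mean() == pytest.approx(22.0 / 225, abs=1e-12)

    def test_exhausting_fractions_rejected(self, rng):
        with pytest.raises(ValueError):
            WeightScheme(frac_down=0.6, frac_up=0.6)
        with pytest.raises(ValueError):
            sample_weights(2, WeightScheme(), rng)


def _pipeline_reference(residuals, k):
    pca = weighted_pca(residuals)
    dendro = ward_linkage(pca.scores)
    return flag_outliers(cut_dendrogram(dendro, k))


def separated_cohort(seed=42):
    """Three clearly separated planted groups (tight within-group SDs)."""
    profiles = [
        GroupProfile("A", 20, dict(zip(REGIONS, [-4.0, -1.0, -1.5, -2.5, -1.0, -1.5])),
                     dict(zip(REGIONS, [0.15] * 6)), mean_followups=4),
        GroupProfile("B", 30, dict(zip(REGIONS, [-0.5, -0.5, -1.5, -0.5, -1.2, -0.4])),
                     dict(zip(REGIONS, [0.15] * 6)), mean_followups=4),
        GroupProfile("C", 40, dict(zip(REGIONS, [0.0, 0.1, -0.3, 0.0, 0.0, 0.0])),
                     dict(zip(REGIONS, [0.15] * 6)), mean_followups=4),
    ]
    config = CohortConfig(group_profiles=profiles, noise_cv=0.001,
                          p_session_missing=0.0, seed=seed)
    cohort, truth = generate_cohort(config)
    filtered, _ = exclusion_filter(cohort)
    residuals = age_residuals(annualized_rates(filtered), filtered)
    return residuals, truth


class TestRunStability:
    def test_unperturbed_scheme_reproduces_reference_exactly(self):
        residuals, _ = separated_cohort()
        reference = _pipeline_reference(residuals, 3)
        scheme = WeightScheme(frac_down=0.0, frac_up=0.0)
        result = run_stability(residuals, reference, k=3, n_reps=20,
                               scheme=scheme, seed=1)
        assert result.ari_mean == pytest.approx(1.0)
        assert result.ari_sd == 0.0
        assert result.vi_mean == pytest.approx(0.0, abs=1e-12)
        assert result.n_failures == 0

    def test_well_separated_groups_remain_stable_under_perturbation(self):
        residuals, _ = separated_cohort()
        reference = _pipeline_reference(residuals, 3)
        result = run_stability(residuals, reference, k=3, n_reps=200, seed=2)
        assert result.ari_mean >= 0.9
        assert result.vi_mean <= 0.2

    def test_single_repetition_reports_zero_sd(self):
        residuals, _ = separated_cohort()
        reference = _pipeline_reference(residuals, 3)
        result = run_stability(residuals, reference, k=3, n_reps=1, seed=3)
        assert result.ari_sd == 0.0 and result.vi_sd == 0.0

    def test_same_seed_reproduces_and_ranges_concatenate(self):
        residuals, _ = separated_cohort()
        reference = _pipeline_reference(residuals, 3)
        full = run_stability(residuals, reference, k=3, n_reps=30, seed=9)
        again = run_stability(residuals, reference, k=3, n_reps=30, seed=9)
        np.testing.assert_array_equal(full.ari, again.ari)
        np.testing.assert_array_equal(full.vi, again.vi)
        first = run_stability(residuals, reference, k=3, n_reps=30, seed=9,
                              rep_range=(0, 12))
        rest = run_stability(residuals, reference, k=3, n_reps=30, seed=9,
                             rep_range=(12, 30))
        np.testing.assert_array_equal(np.r_[first.ari, rest.ari], full.ari)
        np.testing.assert_array_equal(np.r_[first.vi, rest.vi], full.vi)

    def test_agreement_restricted_to_shared_non_outliers(self):
        p = Partition(labels=pd.Series([1, 1, 2, 2, 0],
                                       index=list("abcde")))
        q = Partition(labels=pd.Series([0, 1, 2, 2, 1],
                                       index=list("abcde")))
        from msvlot.stability import _agreement
        ari, vi = _agreement(p, q)
        # shared non-outliers b, c, d: p = (1,2,2), q = (1,2,2)
        assert ari == pytest.approx(1.0)
        assert vi == pytest.approx(0.0, abs=1e-12)
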