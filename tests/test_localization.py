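import numpy as np
import pytest
from scipy.stats import binom

from voct import simulate
from voct.localization import (
    FrequencyScanResult,
    clustering_accuracy,
    cohort_matrix,
    locate_distinguishing_frequency,
    svc_leave_one_frequency_out,
    vbgmm_frequency_scan,
)


class TestClusteringAccuracy:
    def test_perfect_clustering(self):
        assert clustering_accuracy([0, 0, 1, 1], ["h", "h", "p", "p"]) == 1.0

    def test_inverted_labels_score_perfectly(self):
        assert clustering_accuracy([1, 1, 0, 0], ["h", "h", "p", "p"]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering_accuracy([0, 1], [0, 1, 1])

    def test_random_assignment_matches_permutation_max_oracle(self):
        """Random clusterings on balanced classes score slightly above 0.5;
        the exact expectation is E[max(K, n-K)]/n with K ~ Binomial(n, 1/2)."""
        n = 40
        k = np.arange(n + 1)
        oracle = float(np.sum(binom.pmf(k, n, 0.5) * np.maximum(k, n - k)) / n)
        rng = np.random.default_rng(0)
        true = np.repeat([0, 1], n // 2)
        accs = [
            clustering_accuracy(rng.integers(0, 2, n), true) for _ in range(3000)
        ]
        assert np.mean(accs) == pytest.approx(oracle, abs=0.01)
        assert np.min(accs) >= 0.5


class TestVbgmmScan:
    def test_argmax_localizes_110(self, species_cohort_small):
        curve = vbgmm_frequency_scan(species_cohort_small, n_repeats=3, seed=0)
        report = locate_distinguishing_frequency(curve, "vbgmm_scan")
        assert report.distinguishing_frequency == 110.0

    def test_seeded_determinism(self, species_cohort_small):
        a = vbgmm_frequency_scan(species_cohort_small, n_repeats=2, seed=3)
        b = vbgmm_frequency_scan(species_cohort_small, n_repeats=2, seed=3)
        assert [r.mean_accuracy for r in a] == [r.mean_accuracy for r in b]

    def test_single_species_has_no_signal(self):
        """With no species contrast, no frequency separates arbitrary
        balanced labels meaningfully above chance."""
        cohort = simulate.generate_species_cohort(
            8, 8, seed=5, porcine_110_scale=1.0
        )
        labels = np.repeat([0, 1], 8)
        curve = vbgmm_frequency_scan(cohort, n_repeats=3, seed=1, labels=labels)
        assert max(r.mean_accuracy for r in curve) < 0.8

    def test_degenerate_frequency_flagged_at_chance(self, species_cohort_small):
        cohort = [s for s in species_cohort_small]
        X, grid, y = cohort_matrix(cohort)
        # a synthetic constant column cannot arise from the generator; feed
        # a doctored cohort where one frequency is identical for every eye
        from dataclasses import replace
        from voct.spectra import normalize_unit_max

        doctored = []
        for s in cohort:
            u = normalize_unit_max(s)
            d = u.displacements.copy()
            d[0] = 1.0  # 50 Hz identical everywhere; max stays 1
            doctored.append(replace(u, displacements=d))
        curve = vbgmm_frequency_scan(doctored, n_repeats=2, seed=0)
        assert curve[0].degenerate and curve[0].mean_accuracy == 0.5


class TestSvcAblation:
    def test_argmin_localizes_110(self, species_cohort_small):
        curve = svc_leave_one_frequency_out(species_cohort_small, n_repeats=3, seed=0)
        report = locate_distinguishing_frequency(curve, "svc_ablation")
        assert report.distinguishing_frequency == 110.0

    def test_uninformative_exclusions_cost_little(self):
        """Removing the informative 110 Hz column costs accuracy; removing
        a noise column does not.  A noisier cohort is used so that the
        classifier is not saturated at 100% with or without 110 Hz."""
        cohort = simulate.generate_species_cohort(10, 10, seed=7, noise_sd=0.12)
        curve = svc_leave_one_frequency_out(cohort, n_repeats=3, seed=1)
        by_f = {r.frequency: r.mean_accuracy for r in curve}
        assert by_f[110.0] < min(by_f[200.0], by_f[170.0])
        assert abs(by_f[200.0] - by_f[170.0]) < 0.1

    def test_no_contrast_means_chance_accuracy(self):
        cohort = simulate.generate_species_cohort(
            10, 10, seed=2, porcine_110_scale=1.0
        )
        labels = np.repeat([0, 1], 10)
        curve = svc_leave_one_frequency_out(
            cohort, n_repeats=3, seed=2, labels=labels
        )
        assert np.mean([r.mean_accuracy for r in curve]) < 0.7

    def test_too_few_samples_for_folds_rejected(self):
        cohort = simulate.generate_species_cohort(3, 3, seed=0)
        with pytest.raises(ValueError):
            svc_leave_one_frequency_out(cohort, n_folds=5, n_repeats=1, seed=0)

    def test_curves_invariant_to_uniform_rescaling(self, species_cohort_small):
        from dataclasses import replace

        scaled = [
            replace(s, displacements=3.0 * s.displacements)
            for s in species_cohort_small
        ]
        a, _, _ = cohort_matrix(species_cohort_small)
        b, _, _ = cohort_matrix(scaled)
        assert np.allclose(a, b)


class TestLocateDistinguishingFrequency:
    def _curve(self, accs, method="vbgmm_scan"):
        return [
            FrequencyScanResult(50.0 + 10.0 * i, a, 0.0, method)
            for i, a in enumerate(accs)
        ]

    def test_unique_maximum(self):
        curve = self._curve([0.5, 0.6, 0.5, 0.5, 0.5, 0.5, 0.95])
        rep = locate_distinguishing_frequency(curve, "vbgmm_scan")
        assert rep.distinguishing_frequency == 110.0 and not rep.tie

    def test_constant_curve_ties_to_lowest_frequency(self):
        rep = locate_distinguishing_frequency(self._curve([0.7] * 5), "vbgmm_scan")
        assert rep.distinguishing_frequency == 50.0 and rep.tie

    def test_two_point_curve_argmax(self):
        curve = [
            FrequencyScanResult(60.0, 0.9, 0.0, "vbgmm_scan"),
            FrequencyScanResult(70.0, 0.7, 0.0, "vbgmm_scan"),
        ]
        assert (
            locate_distinguishing_frequency(curve, "vbgmm_scan").distinguishing_frequency
            == 60.0
        )

    def test_ablation_uses_argmin(self):
        curve = self._curve([0.9, 0.95, 0.6, 0.9], method="svc_ablation")
        rep = locate_distinguishing_frequency(curve, "svc_ablation")
        assert rep.distinguishing_frequency == 70.0 and rep.rule == "argmin"

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            locate_distinguishing_frequency([], "vbgmm_scan")
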