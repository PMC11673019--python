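import numpy as np
import pytest

from voct import simulate
from voct.simulate import (
    CohortDesign,
    SpectrumProfile,
    expected_spectrum,
    generate_cohort,
    generate_speaker_baseline,
    generate_species_cohort,
    generate_spectrum,
    make_grid,
)


class TestSpeakerBaseline:
    def test_grid_arithmetic_and_positivity(self):
        b = generate_speaker_baseline((50.0, 250.0, 10.0), seed=0)
        assert b.frequencies.size == 21
        assert np.all(b.displacements > 0)

    def test_seeded_determinism(self):
        a = generate_speaker_baseline((50.0, 250.0, 10.0), seed=5)
        b = generate_speaker_baseline((50.0, 250.0, 10.0), seed=5)
        assert np.array_equal(a.displacements, b.displacements)

    def test_zero_noise_is_smooth_component(self):
        a = generate_speaker_baseline((50.0, 250.0, 10.0), seed=1, noise_sd=0.0)
        b = generate_speaker_baseline((50.0, 250.0, 10.0), seed=2, noise_sd=0.0)
        assert np.array_equal(a.displacements, b.displacements)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_speaker_baseline((50.0, 250.0, -10.0), seed=0)


class TestGenerateSpectrum:
    def test_zero_peaks_zero_noise_gives_zero_spectrum(self):
        prof = SpectrumProfile(peaks=(), noise_sd=0.0)
        s = generate_spectrum(prof, seed=0)
        assert np.array_equal(s.displacements, np.zeros(21))

    def test_porcine_110_height_below_human(self, human_noiseless, porcine_noiseless):
        i110 = np.flatnonzero(human_noiseless.frequencies == 110.0)[0]
        assert (
            porcine_noiseless.displacements[i110]
            < human_noiseless.displacements[i110]
        )

    def test_metadata_copied_from_profile(self):
        s = generate_spectrum(simulate.kc_profile(stage=3), seed=0, eye_id="x")
        assert (s.species, s.group, s.stage, s.eye_id) == ("human", "kc", 3, "x")

    def test_off_grid_peak_warns_but_contributes_tail(self):
        prof = SpectrumProfile(
            peaks=(simulate.PeakSpec(300.0, 1.0),), noise_sd=0.0
        )
        with pytest.warns(UserWarning, match="outside"):
            s = generate_spectrum(prof, seed=0)
        assert s.displacements[-1] > 0

    def test_raw_measurement_round_trips_through_speaker_division(self):
        from voct.spectra import normalize_by_speaker

        base = generate_speaker_baseline((50.0, 250.0, 10.0), seed=3)
        prof = simulate.human_profile(noise_sd=0.0)
        raw = simulate.generate_raw_measurement(prof, base, seed=4)
        weighted = generate_spectrum(prof, seed=4)
        recovered = normalize_by_speaker(raw, base)
        assert np.allclose(recovered.displacements, weighted.displacements)


class TestCohorts:
    def test_default_design_counts(self):
        cohort = generate_cohort(CohortDesign(seed=0))
        assert len(cohort) == 63
        assert sum(s.group == "control" for s in cohort) == 41
        stage_counts = [sum(s.stage == k for s in cohort) for k in (1, 2, 3, 4)]
        assert stage_counts == [2, 9, 3, 8]

    def test_empty_design_gives_empty_list(self):
        design = CohortDesign(n_control=0, n_kc_by_stage=(0, 0, 0, 0), seed=0)
        assert generate_cohort(design) == []

    def test_seeded_determinism(self):
        a = generate_cohort(CohortDesign(n_control=3, n_kc_by_stage=(1, 0, 0, 0), seed=9))
        b = generate_cohort(CohortDesign(n_control=3, n_kc_by_stage=(1, 0, 0, 0), seed=9))
        for x, y in zip(a, b):
            assert np.array_equal(x.displacements, y.displacements)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_control=-1)

    def test_kc_central_resonance_below_control(self):
        """The KC central-stroma peak encodes a softer, thinner central
        cornea through the calibration inverse: its programmed resonance
        sits well below the control one."""
        control = simulate.human_profile()
        kc = simulate.kc_profile(stage=2)
        f_control = sorted(p.center_frequency for p in control.peaks)[2]
        f_kc = sorted(p.center_frequency for p in kc.peaks)[2]
        assert f_control == pytest.approx(150.4, abs=0.5)
        assert f_kc == pytest.approx(114.1, abs=0.5)


class TestSpeciesCohort:
    def test_counts_and_common_grid(self):
        cohort = generate_species_cohort(20, 20, seed=0)
        assert len(cohort) == 40
        assert all(s.frequencies.size == 21 for s in cohort)
        assert sum(s.species == "human" for s in cohort) == 20

    def test_minimal_cohort_shares_grid(self):
        a, b = generate_species_cohort(1, 1, seed=0)
        assert a.same_grid(b)

    def test_at_least_one_eye_required(self):
        with pytest.raises(ValueError):
            generate_species_cohort(0, 5, seed=0)

    def test_contrast_confined_to_110_band(self):
        """In the noiseless limit the expected human−porcine difference
        peaks at 110 Hz and is negligible away from the band."""
        hp = simulate.human_profile(noise_sd=0.0)
        pp = simulate.porcine_profile(noise_sd=0.0, grid=simulate.HUMAN_GRID)
        diff = expected_spectrum(hp) - expected_spectrum(pp)
        f = make_grid(*hp.grid)
        assert f[np.argmax(diff)] == 110.0
        far = np.abs(f - 110.0) >= 30.0
        assert np.all(diff[far] <= 0.05 * diff.max())

    def test_human_mean_exceeds_porcine_at_110_only(self):
        cohort = generate_species_cohort(40, 40, seed=11, noise_sd=0.0)
        X = np.vstack([s.displacements for s in cohort])
        human = X[:40].mean(axis=0)
        porcine = X[40:].mean(axis=0)
        f = cohort[0].frequencies
        i110 = np.flatnonzero(f == 110.0)[0]
        assert human[i110] > 2.0 * porcine[i110]
        far = np.abs(f - 110.0) >= 30.0
        assert np.allclose(human[far], porcine[far], rtol=0.15, atol=0.03)
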