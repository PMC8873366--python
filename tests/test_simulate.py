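import numpy as np
import pytest
from scipy import signal as sps

import nirsprint as nz


@pytest.fixture(scope="module")
def paradigm():
    return nz.ParadigmConfig(n_subjects=4)


class TestSubjectProfile:
    def test_zero_effect_gives_identity_covariance(self, paradigm):
        prof = nz.sample_subject_profile(paradigm, 3, subject_effect=0.0)
        assert np.array_equal(prof.latent_covariance, np.eye(paradigm.n_channels))

    def test_minimum_eigenvalue_at_least_one(self, paradigm):
        for seed in range(5):
            prof = nz.sample_subject_profile(paradigm, seed, subject_effect=2.0)
            assert np.linalg.eigvalsh(prof.latent_covariance).min() >= 1.0 - 1e-10

    def test_distinct_seeds_give_distinct_covariances(self, paradigm):
        a = nz.sample_subject_profile(paradigm, 1, subject_effect=1.0)
        b = nz.sample_subject_profile(paradigm, 2, subject_effect=1.0)
        assert not np.allclose(a.latent_covariance, b.latent_covariance)

    def test_negative_effect_rejected(self, paradigm):
        with pytest.raises(ValueError):
            nz.sample_subject_profile(paradigm, 0, subject_effect=-1.0)

    def test_null_cohort_gains_identical_across_channels(self, paradigm):
        prof = nz.sample_subject_profile(paradigm, 5, subject_effect=0.0)
        for g in prof.task_gains.values():
            assert np.allclose(g, g[0])


class TestSimulateRecording:
    def test_default_paradigm_shape_near_30003x20(self):
        """The default 75-trial paradigm spans ~2250 s at ~13.33 Hz."""
        p = nz.ParadigmConfig()
        prof = nz.sample_subject_profile(p, 0, subject_effect=1.0)
        sched = nz.make_trial_schedule(p, 0)
        rec = nz.simulate_recording(prof, sched, p, nz.NoiseModel(), nz.OXY, 0)
        assert rec.data.shape[1] == 20
        assert abs(rec.data.shape[0] - 30003) < 270  # random rest durations

    def test_no_signal_sources_gives_all_zero_data(self, paradigm):
        prof = nz.sample_subject_profile(
            paradigm, 0, subject_effect=0.0, evoked_amplitude=0.0
        )
        sched = nz.make_trial_schedule(paradigm, 0)
        silent = nz.NoiseModel(
            component_amplitudes=(0, 0, 0), white_noise_sd=0, drift_sd=0
        )
        rec = nz.simulate_recording(
            prof, sched, paradigm, silent, nz.OXY, 0, latent_amplitude=0.0
        )
        assert np.all(rec.data == 0.0)

    def test_bit_identical_under_same_seed(self, paradigm):
        prof = nz.sample_subject_profile(paradigm, 1, subject_effect=1.0)
        sched = nz.make_trial_schedule(paradigm, 1)
        a = nz.simulate_recording(prof, sched, paradigm, nz.NoiseModel(), nz.OXY, 9)
        b = nz.simulate_recording(prof, sched, paradigm, nz.NoiseModel(), nz.OXY, 9)
        assert np.array_equal(a.data, b.data)
        c = nz.simulate_recording(prof, sched, paradigm, nz.NoiseModel(), nz.OXY, 10)
        assert not np.array_equal(a.data, c.data)

    def test_rest_covariance_recovers_latent_structure(self):
        """With subject_effect >> noise the empirical rest-sample covariance
        reproduces the latent covariance (off-diagonal correlation > 0.9)."""
        p = nz.ParadigmConfig(n_subjects=2)
        prof = nz.sample_subject_profile(p, 7, subject_effect=5.0, subject_id="S01")
        sched = nz.make_trial_schedule(p, 3)
        quiet = nz.NoiseModel(
            component_amplitudes=(0.02, 0.02, 0.02), white_noise_sd=0.02, drift_sd=0.0
        )
        rec = nz.simulate_recording(prof, sched, p, quiet, nz.OXY, 11)
        rest = np.vstack(
            [s.data for s in nz.segment_trials(rec) if s.state == "REST"]
        )
        emp = np.cov(rest, rowvar=False)
        iu = np.triu_indices(p.n_channels, 1)
        r = np.corrcoef(emp[iu], prof.latent_covariance[iu])[0, 1]
        assert r > 0.9

    def test_deoxy_is_anticorrelated_scaled_copy_without_distortion(self, paradigm):
        prof = nz.sample_subject_profile(paradigm, 2, subject_effect=1.0)
        sched = nz.make_trial_schedule(paradigm, 2)
        silent = nz.NoiseModel(
            component_amplitudes=(0, 0, 0),
            white_noise_sd=0,
            drift_sd=0,
            view_distortion=0.0,
            deoxy_scale=0.5,
        )
        oxy = nz.simulate_recording(prof, sched, paradigm, silent, nz.OXY, 4)
        deoxy = nz.simulate_recording(prof, sched, paradigm, silent, nz.DEOXY, 4)
        assert np.allclose(deoxy.data, -0.5 * oxy.data)

    def test_invalid_view_rejected(self, paradigm):
        prof = nz.sample_subject_profile(paradigm, 0)
        sched = nz.make_trial_schedule(paradigm, 0)
        with pytest.raises(ValueError, match="view"):
            nz.simulate_recording(prof, sched, paradigm, nz.NoiseModel(), "HBX", 0)


class TestCohort:
    def test_cohort_counts_and_determinism(self, paradigm):
        cohort = nz.simulate_cohort(paradigm, master_seed=3)
        assert len(cohort) == paradigm.n_subjects
        assert all(len(pair) == 2 for pair in cohort)
        assert {r.view for pair in cohort for r in pair} == {nz.OXY, nz.DEOXY}
        again = nz.simulate_cohort(paradigm, master_seed=3)
        for pair_a, pair_b in zip(cohort, again):
            for a, b in zip(pair_a, pair_b):
                assert np.array_equal(a.data, b.data)

    def test_two_subject_cohort(self):
        p = nz.ParadigmConfig(n_subjects=2, n_sessions=1, trials_per_session=6)
        cohort = nz.simulate_cohort(p, master_seed=0)
        assert len(cohort) == 2
        assert cohort[0][0].subject_id != cohort[1][0].subject_id

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            nz.simulate_cohort(nz.ParadigmConfig(n_subjects=1), master_seed=0)


def test_power_spectrum_peaks_at_physiological_frequencies():
    """Channel-averaged Welch spectrum of a ~600-s simulation has local
    maxima within one frequency bin of 0.1, 0.25 and 1.0 Hz."""
    p = nz.ParadigmConfig(n_subjects=2, n_sessions=1, trials_per_session=21)
    sched = nz.make_trial_schedule(p, 2)
    prof = nz.sample_subject_profile(p, 5, subject_effect=1.0)
    rec = nz.simulate_recording(prof, sched, p, nz.NoiseModel(), nz.OXY, 7)
    assert rec.duration > 600.0
    f, pxx = sps.welch(rec.data, fs=p.sampling_rate, nperseg=512, axis=0)
    power = pxx.mean(axis=1)
    for target in (0.1, 0.25, 1.0):
        i = int(np.argmin(np.abs(f - target)))
        window = slice(max(i - 3, 0), i + 4)
        peak = int(np.argmax(power[window])) + max(i - 3, 0)
        assert abs(peak - i) <= 1, f"no local maximum near {target} Hz"


def test_subject_separability_of_rest_covariances():
    """Split-half rest-state covariances are closer within than between
    subjects (permutation test on the between-within gap, p < 0.05)."""
    p = nz.ParadigmConfig(n_subjects=10, n_sessions=1, trials_per_session=12)
    cohort = nz.simulate_cohort(p, subject_effect=1.0, master_seed=4, views=(nz.OXY,))
    iu = np.triu_indices(p.n_channels, 1)
    halves = []
    for (rec,) in cohort:
        rest = [s.data for s in nz.segment_trials(rec) if s.state == "REST"]
        halves.append(np.cov(np.vstack(rest[0::2]), rowvar=False)[iu])
        halves.append(np.cov(np.vstack(rest[1::2]), rowvar=False)[iu])
    halves = np.array(halves)
    labels = np.repeat(np.arange(10), 2)

    def gap(lab):
        d = np.linalg.norm(halves[:, None, :] - halves[None, :, :], axis=-1)
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        return d[~same].mean() - d[same & off].mean()

    observed = gap(labels)
    rng = np.random.default_rng(0)
    null = [gap(rng.permutation(labels)) for _ in range(199)]
    p_value = (1 + sum(g >= observed for g in null)) / 200
    assert observed > 0
    assert p_value < 0.05
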