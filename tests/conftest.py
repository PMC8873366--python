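import numpy as np
import pytest

import nirsprint as nz


@pytest.fixture(scope="session")
def small_paradigm():
    """One 12-trial session, 6 subjects: smallest balanced design that is
    still long enough (~360 s) for stable 0.01-Hz filtering."""
    return nz.ParadigmConfig(n_subjects=6, n_sessions=1, trials_per_session=12)


@pytest.fixture(scope="session")
def small_recording(small_paradigm):
    profile = nz.sample_subject_profile(
        small_paradigm, 11, subject_effect=2.0, subject_id="S01"
    )
    schedule = nz.make_trial_schedule(small_paradigm, 12)
    return nz.simulate_recording(
        profile, schedule, small_paradigm, nz.NoiseModel(), nz.OXY, 5
    )


@pytest.fixture(scope="session")
def small_cohort_sets(small_paradigm):
    """Fingerprint sets (both views) of a well-separated 6-subject cohort."""
    return nz.cohort_fingerprints(small_paradigm, subject_effect=3.0, master_seed=7)


@pytest.fixture(scope="session")
def default_recording():
    """One subject at the full default paradigm (75 trials, ~2250 s)."""
    paradigm = nz.ParadigmConfig()
    profile = nz.sample_subject_profile(
        paradigm, 1, subject_effect=1.0, subject_id="S01"
    )
    schedule = nz.make_trial_schedule(paradigm, 2)
    recording = nz.simulate_recording(
        profile, schedule, paradigm, nz.NoiseModel(), nz.OXY, 3
    )
    return paradigm, recording


def make_segment(data, state="REST", subject="S01", view=nz.OXY, fs=10.0, trial=0):
    return nz.Segment(
        subject_id=subject,
        view=view,
        state=state,
        trial_index=trial,
        data=np.asarray(data, dtype=float),
        sampling_rate=fs,
        start=0,
    )


def make_bfn(upper, subject="S01", view=nz.OXY, label="REST", n_avg=1):
    """Build a BFN from its strictly-upper-triangular off-diagonal values."""
    upper = np.asarray(upper, dtype=float)
    n = int((1 + np.sqrt(1 + 8 * upper.size)) / 2)
    w = np.eye(n)
    iu = np.triu_indices(n, k=1)
    w[iu] = upper
    w = w + np.triu(w, k=1).T
    return nz.BFN(
        weights=w,
        class_label=label,
        subject_id=subject,
        view=view,
        n_segments_averaged=n_avg,
    )
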