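"""Synthetic multi-subject fNIRS cohort generator.

Emulates the statistical structure the fingerprinting analysis relies on,
without any physical optics: each subject carries an intrinsic
(state-independent) spatial covariance across channels, task blocks evoke a
canonical hemodynamic response, and physiological nuisance rides on top
(Mayer wave ~0.1 Hz, respiration ~0.25 Hz, heartbeat ~1 Hz, white sensor
noise, slow drift).  Signals are concentration-change values in arbitrary
units.

The generative model, per channel c and time t:

    y[t, c] = a_lat * (slow band-limited noise with Cov = latent_covariance)
            + sum_tasks gain[task][c] * (HRF * task boxcar)[t]
            + physiological oscillations + white noise + drift

The de-oxyhemoglobin view is the oxy latent/evoked component scaled by
``-kappa`` (the known Oxy/Deoxy anticorrelation) plus an independent,
spatially structured view-distortion process and its own nuisance draws.

Two deliberate departures from the most literal generative model:

* **Epoch exchangeability.**  Every stochastic component (intrinsic signal,
  physiological oscillations, view distortion) is drawn independently per
  trial phase, by slicing well-separated windows out of one stationary
  realization and crossfading at phase boundaries.  A temporally continuous
  low-frequency process would share its realization between a task epoch
  and the adjacent mid-rest window through the 0.01-0.1 Hz band-pass, which
  makes even a cohort of statistically identical subjects partially
  identifiable — a session-level artifact that would confound chance-level
  validation of the identification stage.
* **Narrowband oscillations.**  The Mayer/respiration/heartbeat components
  are narrowband Gaussian processes (default 0.05 Hz bandwidth) rather than
  fixed-phase sinusoids: their spectra still peak at the nominal
  frequencies, but inter-channel phase relations decorrelate across trials,
  as they do physiologically — a phase pattern locked over a 37-min session
  would itself act as a biometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .paradigm import (
    DEOXY,
    OXY,
    VIEWS,
    ParadigmConfig,
    TrialSchedule,
    make_trial_schedule,
)

#: Band of the intrinsic (connectivity-bearing) signal, Hz.  It spans the
#: full low-frequency hemodynamic range; the analysis band-pass later
#: selects its 0.01-0.1 Hz portion.
LATENT_BAND = (0.01, 0.4)


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance and view-coupling parameters of the generator.

    component_amplitudes are the standard deviations (signal units) of the
    Mayer, respiration and heartbeat oscillations, in that order; each
    oscillation is a narrowband Gaussian process of ``component_bandwidth``
    Hz around its nominal frequency.  ``deoxy_scale`` is kappa, the
    magnitude of the Deoxy/Oxy anticorrelated coupling.  ``view_distortion``
    in [0, 1] mixes a view-specific structured process into the DEOXY
    latent signal (0: DEOXY is an exact scaled copy; 1: fully independent
    structure), modelling view-specific physiology that makes cross-view
    matching harder than cross-task matching.
    """

    mayer_freq: float = 0.1
    respiration_freq: float = 0.25
    heartbeat_freq: float = 1.0
    component_amplitudes: tuple[float, float, float] = (0.5, 0.5, 0.5)
    component_bandwidth: float = 0.05
    white_noise_sd: float = 0.3
    drift_sd: float = 0.02
    deoxy_scale: float = 0.5
    view_distortion: float = 0.9

    def __post_init__(self) -> None:
        for f in (self.mayer_freq, self.respiration_freq, self.heartbeat_freq):
            if f <= 0:
                raise ValueError("oscillation frequencies must be positive")
        if any(a < 0 for a in self.component_amplitudes):
            raise ValueError("component_amplitudes must be non-negative")
        if self.component_bandwidth <= 0:
            raise ValueError("component_bandwidth must be positive")
        if self.white_noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.view_distortion <= 1.0:
            raise ValueError("view_distortion must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectProfile:
    """Latent parameters of one simulated subject."""

    subject_id: str
    latent_covariance: np.ndarray  # (channels, channels), SPD
    task_gains: dict[str, np.ndarray]  # task -> per-channel evoked amplitude
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.latent_covariance)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("latent_covariance must be square")
        if not np.allclose(c, c.T):
            raise ValueError("latent_covariance must be symmetric")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("latent_covariance must be positive definite")
        for task, g in self.task_gains.items():
            if not np.all(np.isfinite(g)):
                raise ValueError(f"task_gains[{task!r}] contains non-finite values")


@dataclass
class Recording:
    """One subject x one view concentration-change series with its schedule."""

    subject_id: str
    view: str
    data: np.ndarray  # (time, channels)
    sampling_rate: float
    schedule: TrialSchedule
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x channels)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[1]} channels but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.schedule.n_samples > self.data.shape[0]:
            raise ValueError(
                f"schedule spans {self.schedule.n_samples} samples but data has "
                f"only {self.data.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def canonical_hrf(sampling_rate: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s).

    Gamma-density difference with unit scale; shapes 7 and 17 place the modes
    at 6 s and 16 s.  Normalized to unit peak.
    """
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    h = spstats.gamma.pdf(t, 7.0) - spstats.gamma.pdf(t, 17.0) / 6.0
    return h / h.max()


def sample_subject_profile(
    paradigm: ParadigmConfig,
    seed: int,
    subject_effect: float = 1.0,
    rank: int = 4,
    evoked_amplitude: float = 0.5,
    gain_sd: float = 0.3,
    subject_id: str | None = None,
) -> SubjectProfile:
    """Draw one subject's intrinsic covariance and evoked gains.

    The intrinsic spatial covariance is low-rank-plus-identity,
    ``I + subject_effect * L @ L.T`` with ``L`` a (channels x rank) loading
    matrix of N(0, 1/rank) entries, so it is symmetric positive-definite by
    construction and reduces to the identity at ``subject_effect = 0``.

    Evoked gains per task are ``evoked_amplitude * (1 + subject_effect *
    gain_sd * z_c)``: channel-gain heterogeneity scales with the same
    subject-individuality dial, so a null cohort (subject_effect 0) has
    identical statistics for every subject.
    """
    if subject_effect < 0:
        raise ValueError("subject_effect must be >= 0")
    rng = np.random.default_rng(seed)
    c = paradigm.n_channels
    loadings = rng.normal(size=(c, rank)) / math.sqrt(rank)
    cov = np.eye(c) + subject_effect * loadings @ loadings.T
    cov = (cov + cov.T) / 2.0
    gains = {
        task: evoked_amplitude
        * (1.0 + subject_effect * gain_sd * rng.normal(size=c))
        for task in paradigm.task_labels
    }
    return SubjectProfile(
        subject_id=subject_id if subject_id is not None else f"seed{seed}",
        latent_covariance=cov,
        task_gains=gains,
        seed=int(seed),
    )


def _phase_bounds(schedule: TrialSchedule, n_samples: int) -> list[tuple[int, int]]:
    """Half-open sample ranges of every trial phase, covering [0, n_samples)."""
    cuts = {0, n_samples}
    for trial in schedule.trials:
        task_start = trial.onset + schedule.intro_samples
        task_stop = task_start + schedule.task_samples
        for c in (trial.onset, task_start, task_stop):
            if 0 < c < n_samples:
                cuts.add(c)
    edges = sorted(cuts)
    return list(zip(edges[:-1], edges[1:]))


def _sliced_process(
    rng: np.random.Generator,
    schedule: TrialSchedule,
    n_samples: int,
    n_cols: int,
    fs: float,
    band: tuple[float, float],
    buffer_s: float = 20.0,
    blend_s: float = 1.0,
) -> np.ndarray:
    """Epoch-exchangeable stationary band-limited noise, unit variance.

    One long realization of Butterworth-band-limited Gaussian noise is cut
    into per-trial-phase chunks separated by ``buffer_s`` (chosen beyond the
    band's decorrelation length, so chunks are effectively independent
    draws), which are then concatenated with an energy-preserving
    raised-cosine crossfade of ``blend_s`` at each phase boundary.
    """
    phases = _phase_bounds(schedule, n_samples)
    blend = max(int(round(blend_s * fs)), 1)
    gap = int(math.ceil(buffer_s * fs))
    chunk_lens = [(stop - start) + blend for start, stop in phases]
    total = sum(chunk_lens) + gap * len(phases)
    white = rng.normal(size=(total, n_cols))
    lo = max(band[0], 1e-4)
    hi = min(band[1], 0.499 * fs)
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    long = sps.sosfiltfilt(sos, white, axis=0)
    sd = long.std()
    if sd > 0:
        long = long / sd

    out = np.empty((n_samples, n_cols))
    pos = 0
    prev_tail: np.ndarray | None = None
    for k, (start, stop) in enumerate(phases):
        length = stop - start
        chunk = long[pos : pos + length + blend]
        pos += length + blend + gap
        out[start:stop] = chunk[:length]
        if prev_tail is not None:
            b = min(blend, length)
            theta = (np.arange(b) + 1.0) / (b + 1.0) * (np.pi / 2.0)
            out[start : start + b] = (
                np.cos(theta)[:, None] * prev_tail[:b]
                + np.sin(theta)[:, None] * chunk[:b]
            )
        prev_tail = chunk[length : length + blend]
    return out


def _evoked_component(
    profile: SubjectProfile,
    schedule: TrialSchedule,
    paradigm: ParadigmConfig,
    n_samples: int,
) -> np.ndarray:
    """HRF-convolved task boxcars scaled by the subject's per-channel gains."""
    hrf = canonical_hrf(paradigm.sampling_rate)
    # scale so a sustained block saturates near gain * 1, independent of fs
    hrf = hrf / hrf.clip(min=0.0).sum()
    out = np.zeros((n_samples, paradigm.n_channels))
    for task in paradigm.task_labels:
        box = np.zeros(n_samples)
        for trial in schedule.trials:
            if trial.task != task:
                continue
            start = trial.onset + schedule.intro_samples
            box[start : start + schedule.task_samples] = 1.0
        if not box.any():
            continue
        drive = sps.fftconvolve(box, hrf)[:n_samples]
        out += np.outer(drive, profile.task_gains[task])
    return out


def simulate_recording(
    profile: SubjectProfile,
    schedule: TrialSchedule,
    paradigm: ParadigmConfig,
    noise: NoiseModel,
    view: str,
    seed: int,
    latent_amplitude: float = 1.0,
) -> Recording:
    """Simulate one subject x view recording.

    The intrinsic and evoked components are drawn from a seed stream shared
    between views, so calling with the same ``seed`` but different ``view``
    yields the anticorrelated Oxy/Deoxy pair; nuisance components come from a
    per-view stream.  Deterministic: identical arguments give bit-identical
    output.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    n_samples = schedule.n_samples
    fs = paradigm.sampling_rate
    if abs(fs - schedule.sampling_rate) > 1e-9:
        raise ValueError("schedule and paradigm sampling rates disagree")
    c = paradigm.n_channels

    shared_ss, oxy_ss, deoxy_ss = np.random.SeedSequence(seed).spawn(3)
    rng_shared = np.random.default_rng(shared_ss)

    # Intrinsic signal with the subject's spatial covariance.
    latent = np.zeros((n_samples, c))
    if latent_amplitude != 0.0:
        base = _sliced_process(rng_shared, schedule, n_samples, c, fs, LATENT_BAND)
        chol = np.linalg.cholesky(profile.latent_covariance)
        latent = latent_amplitude * base @ chol.T

    evoked = _evoked_component(profile, schedule, paradigm, n_samples)

    rng_view = np.random.default_rng(deoxy_ss if view == DEOXY else oxy_ss)
    if view == DEOXY:
        rho = noise.view_distortion
        if rho > 0 and latent_amplitude != 0.0:
            # view-specific structure: same spectrum (rotated covariance),
            # variance-preserving mix with the shared latent component
            q, r = np.linalg.qr(rng_view.normal(size=(c, c)))
            q = q * np.sign(np.diag(r))  # deterministic sign convention
            cov_v = q @ profile.latent_covariance @ q.T
            cov_v = (cov_v + cov_v.T) / 2.0
            base_v = _sliced_process(rng_view, schedule, n_samples, c, fs, LATENT_BAND)
            distortion = latent_amplitude * base_v @ np.linalg.cholesky(cov_v).T
            latent = math.sqrt(1.0 - rho**2) * latent + rho * distortion
        data = -noise.deoxy_scale * (latent + evoked)
    else:
        data = latent + evoked

    for amp, freq in zip(
        noise.component_amplitudes,
        (noise.mayer_freq, noise.respiration_freq, noise.heartbeat_freq),
    ):
        if amp > 0:
            half = noise.component_bandwidth / 2.0
            osc = _sliced_process(
                rng_view, schedule, n_samples, c, fs, (freq - half, freq + half)
            )
            data = data + amp * osc
    if noise.white_noise_sd > 0:
        data = data + noise.white_noise_sd * rng_view.normal(size=(n_samples, c))
    if noise.drift_sd > 0:
        steps = rng_view.normal(size=(n_samples, c)) * (noise.drift_sd / math.sqrt(fs))
        data = data + np.cumsum(steps, axis=0)

    return Recording(
        subject_id=profile.subject_id,
        view=view,
        data=data,
        sampling_rate=fs,
        schedule=schedule,
        channel_labels=tuple(paradigm.channel_labels()),
        meta={"seed": int(seed), "latent_amplitude": latent_amplitude},
    )


def simulate_cohort(
    paradigm: ParadigmConfig,
    noise: NoiseModel | None = None,
    subject_effect: float = 1.0,
    master_seed: int = 0,
    views: tuple[str, ...] = VIEWS,
    latent_amplitude: float = 1.0,
    **profile_kwargs,
) -> list[tuple[Recording, ...]]:
    """Simulate a cohort; returns one tuple of per-view Recordings per subject.

    Each subject gets an independent profile, schedule and recording seed,
    all derived reproducibly from ``master_seed``; the views of one subject
    share the same recording seed and therefore the same latent and evoked
    components.
    """
    if paradigm.n_subjects < 2:
        raise ValueError("a cohort needs n_subjects >= 2")
    if noise is None:
        noise = NoiseModel()
    cohort = []
    children = np.random.SeedSequence(master_seed).spawn(paradigm.n_subjects)
    for i, child in enumerate(children):
        prof_seed, sched_seed, rec_seed = (
            int(s) & 0x7FFFFFFF for s in child.generate_state(3)
        )
        profile = sample_subject_profile(
            paradigm,
            prof_seed,
            subject_effect=subject_effect,
            subject_id=f"S{i + 1:02d}",
            **profile_kwargs,
        )
        schedule = make_trial_schedule(paradigm, sched_seed)
        cohort.append(
            tuple(
                simulate_recording(
                    profile,
                    schedule,
                    paradigm,
                    noise,
                    view,
                    rec_seed,
                    latent_amplitude=latent_amplitude,
                )
                for view in views
            )
        )
    return cohort
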