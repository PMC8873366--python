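"""Preprocessing: Butterworth band-pass and global-signal baseline correction.

The pipeline order is fixed: filter first, then subtract the global signal
(the per-timepoint mean over all channels).  Filtering is zero-phase by
default (forward-backward), because the downstream networks are built from
inter-channel correlations and a causal filter would introduce identical but
non-zero group delay that interacts badly with any channel-specific
processing; a ``causal=True`` switch restores single-pass behavior.  In
zero-phase mode the effective amplitude response is the squared Butterworth
magnitude response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .simulate import Recording


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter parameters (third-order Butterworth, 0.01-0.1 Hz)."""

    low_cut: float = 0.01
    high_cut: float = 0.1
    order: int = 3
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError(
                f"need 0 < low_cut < high_cut, got {self.low_cut}, {self.high_cut}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.family.lower() != "butterworth":
            raise ValueError(f"unsupported filter family {self.family!r}")

    def settle_samples(self, sampling_rate: float) -> int:
        """Settling length: one full period of the low cut-off."""
        return int(math.ceil(sampling_rate / self.low_cut))

    def sos(self, sampling_rate: float) -> np.ndarray:
        if self.high_cut >= sampling_rate / 2.0:
            raise ValueError(
                f"high_cut {self.high_cut} Hz violates the Nyquist limit of "
                f"sampling_rate {sampling_rate} Hz"
            )
        return sps.butter(
            self.order,
            [self.low_cut, self.high_cut],
            btype="bandpass",
            fs=sampling_rate,
            output="sos",
        )

    def magnitude_response(self, freqs, sampling_rate: float, zero_phase: bool = True):
        """Analytic amplitude response of the designed filter at ``freqs`` (Hz).

        In zero-phase mode the filter runs forward and backward, so the
        amplitude response is the magnitude response squared.
        """
        _, h = sps.sosfreqz(self.sos(sampling_rate), worN=np.atleast_1d(freqs), fs=sampling_rate)
        mag = np.abs(h)
        return mag**2 if zero_phase else mag


def bandpass_array(
    data: np.ndarray, sampling_rate: float, spec: FilterSpec, causal: bool = False
) -> np.ndarray:
    """Band-pass filter each column of ``data`` independently.

    The array is reflect-padded by one settling length at each end before
    filtering and trimmed after, suppressing start-up transients in the
    0.01-Hz band.
    """
    data = np.asarray(data, dtype=float)
    pad = spec.settle_samples(sampling_rate)
    if data.shape[0] < 3 * pad:
        raise ValueError(
            f"recording of {data.shape[0]} samples is too short for stable "
            f"filtering at low_cut={spec.low_cut} Hz (need >= {3 * pad} samples, "
            f"3x the settling length)"
        )
    sos = spec.sos(sampling_rate)
    padded = np.pad(data, ((pad, pad), (0, 0)), mode="reflect")
    if causal:
        out = sps.sosfilt(sos, padded, axis=0)
    else:
        out = sps.sosfiltfilt(sos, padded, axis=0, padlen=0)
    return np.ascontiguousarray(out[pad:-pad])


def bandpass(recording: Recording, spec: FilterSpec | None = None, causal: bool = False) -> Recording:
    """Band-pass filter a Recording channel-wise; records the spec in meta."""
    if spec is None:
        spec = FilterSpec()
    out = bandpass_array(recording.data, recording.sampling_rate, spec, causal=causal)
    meta = dict(recording.meta)
    meta["filter"] = {
        "family": spec.family,
        "low_cut": spec.low_cut,
        "high_cut": spec.high_cut,
        "order": spec.order,
        "zero_phase": not causal,
    }
    return replace(recording, data=out, meta=meta)


def remove_global_signal(recording: Recording) -> Recording:
    """Subtract the global signal (per-timepoint mean over channels).

    After correction the cross-channel mean is exactly zero at every time
    point; this constrains the channel correlations (they cannot all be
    positive), which is inherent to this baseline-correction choice.
    """
    if recording.n_channels < 2:
        raise ValueError(
            "global-signal removal needs >= 2 channels; "
            f"got {recording.n_channels}"
        )
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    meta = dict(recording.meta)
    meta["global_signal_removed"] = True
    return replace(recording, data=data, meta=meta)


def preprocess(
    recording: Recording, spec: FilterSpec | None = None, causal: bool = False
) -> Recording:
    """Full preprocessing: band-pass first, then global-signal removal."""
    return remove_global_signal(bandpass(recording, spec, causal=causal))
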