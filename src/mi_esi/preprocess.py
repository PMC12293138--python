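"""Mu-band filtering and epoch extraction.

The sensorimotor mu rhythm (8-13 Hz) carries the event-related
desynchronization that distinguishes hand from foot motor imagery, so the
pipeline band-passes every channel to that band before source imaging, and
cuts a fixed 0.5-2.5 s post-cue window out of each trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core_io import ConfigurationError, Trial

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: Butterworth, applied forward-backward."""

    band: tuple[float, float] = (8.0, 13.0)
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ConfigurationError(f"invalid band {self.band}")
        if high >= fs / 2:
            raise ConfigurationError(
                f"band edge {high} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


def bandpass(data: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass each channel of a channels x samples matrix.

    Zero-phase (forward-backward) application doubles the effective order
    and leaves the phase untouched, so covariance structure downstream is
    not distorted. Dimensions are unchanged.
    """
    spec.validate(fs)
    data = np.asarray(data, dtype=float)
    sos = butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    if spec.zero_phase:
        return sosfiltfilt(sos, data, axis=-1)
    from scipy.signal import sosfilt

    return sosfilt(sos, data, axis=-1)


def bandpass_trial(trial: Trial, spec: FilterSpec = FilterSpec()) -> Trial:
    return Trial(bandpass(trial.data, trial.fs, spec), trial.label, trial.fs, trial.channel_names)


def epoch(
    continuous: np.ndarray,
    fs: float,
    cue_samples: np.ndarray,
    window: tuple[float, float],
    labels: list[str] | None = None,
    channel_names: list[str] | None = None,
) -> list[Trial]:
    """Cut one trial per cue from a continuous channels x samples recording.

    Each trial covers the half-open sample interval
    ``[cue + round(start*fs), cue + round(end*fs))`` so the sample count is
    unambiguous: at fs=100 and window (0.5, 2.5) every trial has exactly 200
    samples. Cues whose window does not fit inside the recording are dropped
    with a logged warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_samples = continuous.shape[1]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(continuous.shape[0])]
    if labels is None:
        labels = ["unknown"] * len(cue_samples)
    start_s, end_s = window
    if not end_s > start_s:
        raise ConfigurationError(f"empty epoch window {window}")
    off0 = int(round(start_s * fs))
    off1 = int(round(end_s * fs))
    trials: list[Trial] = []
    dropped = 0
    for cue, label in zip(np.asarray(cue_samples, dtype=int), labels):
        lo, hi = cue + off0, cue + off1
        if lo < 0 or hi > n_samples:
            dropped += 1
            continue
        trials.append(Trial(continuous[:, lo:hi].copy(), label, fs, channel_names))
    if dropped:
        logger.warning(
            "dropped %d of %d cues whose %s s window exceeds the recording",
            dropped, len(cue_samples), window,
        )
    return trials
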