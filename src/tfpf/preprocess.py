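"""EEG trial containers, band-pass filtering and sliding-window segmentation.

The decoding pipeline operates on short epochs of multichannel EEG.  Each
trial is band-pass filtered to the sensorimotor rhythms (8–30 Hz, spanning
the alpha and beta bands) and then cut into overlapping windows.  Windowing
serves two purposes: it tracks the non-stationary dynamics of the signal,
and it multiplies the number of training samples (each window becomes one
sample for the classifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = ["EEGTrial", "SegmentSet", "bandpass", "segment_trial"]

#: Default analysis band in Hz (alpha + beta rhythms).
DEFAULT_BAND = (8.0, 30.0)


@dataclass(frozen=True)
class EEGTrial:
    """One labeled multichannel EEG epoch.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or arbitrary units for simulated data).
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per row of ``data``.
    label : object
        Class identifier (e.g. ``0``/``1`` or ``"left"``/``"right"``).
    trial_id : str
        Unique identifier within a dataset.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple = ()
    label: object = None
    trial_id: str = "trial-0"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"trial data must be 2-D (channels x samples), got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError(f"trial {self.trial_id!r} contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "data", data)
        if not self.channel_labels:
            object.__setattr__(
                self, "channel_labels", tuple(f"ch{i}" for i in range(data.shape[0]))
            )
        elif len(self.channel_labels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {data.shape[0]} channels"
            )
        else:
            object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class SegmentSet:
    """Ordered sliding windows cut from one trial.

    Window ``k`` starts at sample ``round(k * step_s * fs)``; trailing
    samples that do not fill a complete window are discarded, so the number
    of windows is ``floor((T - window_s) / step_s) + 1`` for a trial of
    duration ``T``.
    """

    trial_id: str
    fs: float
    window_s: float
    step_s: float
    segments: tuple = field(default_factory=tuple)
    label: object = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, k):
        return self.segments[k]


def bandpass(trial: EEGTrial, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1], order: int = 4) -> EEGTrial:
    """Zero-phase Butterworth band-pass filter.

    A 4th-order Butterworth is applied forward and backward
    (:func:`scipy.signal.filtfilt`), doubling the effective order and
    cancelling the phase response.  Zero phase distortion matters here
    because the phase-locking value downstream is computed from the
    instantaneous phase of the filtered signal.

    Raises
    ------
    ValueError
        If the band is empty or extends to/beyond the Nyquist frequency.
    """
    nyq = trial.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={trial.fs} Hz "
            f"(need 0 < low < high < Nyquist={nyq})"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=trial.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trial.data, axis=1)
    return replace(trial, data=filtered)


def segment_trial(trial: EEGTrial, window_s: float = 2.0, step_s: float = 0.25) -> SegmentSet:
    """Cut a trial into overlapping sliding windows.

    With the default 2-s window and 0.25-s step, a 4-s trial yields 9
    windows and a 3-s trial yields 5.  Fractional sample counts are rounded
    to the nearest sample so non-integer ``step_s * fs`` does not crash.
    """
    if step_s <= 0:
        raise ValueError(f"step_s must be positive, got {step_s}")
    if window_s > trial.duration + 1e-12:
        raise ValueError(
            f"window ({window_s} s) longer than trial {trial.trial_id!r} ({trial.duration} s)"
        )
    win = int(round(window_s * trial.fs))
    step = int(round(step_s * trial.fs))
    if win < 1 or step < 1:
        raise ValueError(f"window/step too short for fs={trial.fs}: {window_s}s/{step_s}s")
    n_seg = (trial.n_samples - win) // step + 1
    segments = tuple(trial.data[:, k * step:k * step + win].copy() for k in range(n_seg))
    return SegmentSet(
        trial_id=trial.trial_id, fs=trial.fs, window_s=window_s, step_s=step_s,
        segments=segments, label=trial.label,
    )
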