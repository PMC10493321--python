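"""Readers and writers for EEG trials: EDF/EDF+ and plain-text matrices.

EDF reading is delegated to :mod:`mne`.  Writing uses a small built-in
EDF writer (16-bit, one data record per second) so that simulated trials
can be round-tripped through the same reader a real recording would use.
"""

from __future__ import annotations

import os
import struct
from datetime import datetime

import numpy as np

from .preprocess import EEGTrial

__all__ = ["read_edf", "write_edf", "read_text_matrix", "write_text_matrix"]

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(trial: EEGTrial, path: str) -> str:
    """Write one trial to an EDF file (16-bit quantized).

    Each channel is scaled to its own physical min/max, so values
    round-trip within one quantization step of ``(max - min) / 65535``.
    Sample counts are padded with the channel mean to a whole number of
    1-second data records.
    """
    data = trial.data
    n_ch = trial.n_channels
    fs = trial.fs
    if fs != int(fs):
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(fs)
    n_records = int(np.ceil(trial.n_samples / fs))
    padded = np.empty((n_ch, n_records * fs))
    for c in range(n_ch):
        padded[c, : trial.n_samples] = data[c]
        padded[c, trial.n_samples:] = data[c].mean()

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # avoid zero dynamic range for constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    now = datetime(2000, 1, 1)
    header = b"".join([
        _edf_field(0, 8),                                  # version
        _edf_field(f"trial {trial.trial_id}", 80),         # patient id
        _edf_field("tfpf synthetic recording", 80),        # recording id
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 + 256 * n_ch, 8),                   # header length
        _edf_field("", 44),                                # reserved
        _edf_field(n_records, 8),
        _edf_field(1, 8),                                  # record duration (s)
        _edf_field(n_ch, 4),
    ])
    header += b"".join(_edf_field(lbl, 16) for lbl in trial.channel_labels)
    header += b"".join(_edf_field("EEG", 80) for _ in range(n_ch))      # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{phys_min[c]:.6g}"[:8], 8) for c in range(n_ch))
    header += b"".join(_edf_field(f"{phys_max[c]:.6g}"[:8], 8) for c in range(n_ch))
    header += b"".join(_edf_field(_EDF_DIGITAL_MIN, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(_EDF_DIGITAL_MAX, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))         # prefilter
    header += b"".join(_edf_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))         # reserved

    # physical min/max were truncated to 8 ASCII chars; quantize against the
    # values the header actually stores so the round-trip is exact
    pmin = np.array([float(f"{phys_min[c]:.6g}"[:8]) for c in range(n_ch)])
    pmax = np.array([float(f"{phys_max[c]:.6g}"[:8]) for c in range(n_ch)])
    pmax = np.where(pmax - pmin < 1e-12, pmin + 1.0, pmax)
    clipped = np.clip(padded, pmin[:, None], pmax[:, None])
    scale = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (pmax - pmin)
    digital = np.rint(
        (clipped - pmin[:, None]) * scale[:, None] + _EDF_DIGITAL_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * fs:(rec + 1) * fs]
            fh.write(block.tobytes())  # channel-major within a record
    return path


def read_edf(path: str, label=None, trial_id: str | None = None) -> EEGTrial:
    """Read an EDF/EDF+ file into a single :class:`EEGTrial` (in µV).

    Annotation channels are dropped.  For multi-trial recordings use
    :mod:`mne` directly for epoching and wrap each epoch yourself.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty EDF file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt header, truncated records, ...
        raise ValueError(f"could not parse EDF file {path!r}: {exc}") from exc
    picks = [i for i, t in enumerate(raw.get_channel_types()) if t != "stim"]
    data = raw.get_data(picks=picks) * 1e6  # mne returns volts
    labels = tuple(raw.ch_names[i] for i in picks)
    return EEGTrial(
        data=data, fs=float(raw.info["sfreq"]), channel_labels=labels,
        label=label, trial_id=trial_id or os.path.splitext(os.path.basename(path))[0],
    )


def write_text_matrix(trial: EEGTrial, path: str) -> str:
    """Write a trial as a whitespace-separated matrix, one row per channel.

    A comment header records fs and channel labels so the file is
    self-describing.
    """
    header = f"fs={trial.fs} channels={','.join(trial.channel_labels)}"
    np.savetxt(path, trial.data, header=header)
    return path


def read_text_matrix(path: str, fs: float | None = None, label=None,
                     trial_id: str | None = None) -> EEGTrial:
    """Read a plain-text matrix (rows = channels) written by
    :func:`write_text_matrix` or any whitespace-separated source.

    ``fs`` may be omitted if the file carries the ``# fs=...`` header.
    """
    labels = ()
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "fs=" in first:
        parts = dict(
            kv.split("=", 1) for kv in first.lstrip("# ").split() if "=" in kv
        )
        fs = fs if fs is not None else float(parts["fs"])
        if "channels" in parts:
            labels = tuple(parts["channels"].split(","))
    if fs is None:
        raise ValueError(f"{path!r} has no fs header; pass fs= explicitly")
    data = np.loadtxt(path, ndmin=2)
    return EEGTrial(
        data=data, fs=fs, channel_labels=labels, label=label,
        trial_id=trial_id or os.path.splitext(os.path.basename(path))[0],
    )
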