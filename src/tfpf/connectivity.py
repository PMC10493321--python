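"""Pairwise functional-connectivity features: PCC, COH and PLV.

Three complementary measures are computed per channel pair on each
band-limited window:

* **PCC** — Pearson correlation coefficient, ``(1/N) * sum(x_z * y_z)`` on
  z-scored signals: time-domain linear dependence, in [-1, 1].
* **COH** — magnitude-squared coherence ``|S_xy|^2 / (S_xx * S_yy)``
  estimated by Welch-averaged periodograms and averaged over the analysis
  band: frequency-specific linear dependence, in [0, 1].
* **PLV** — phase-locking value ``|<exp(i * dphi(t))>|`` of the relative
  instantaneous phase (analytic-signal phases, time average within the
  window): amplitude-independent phase synchronization, in [0, 1].

Each feature fills a symmetric channels-by-channels matrix with unit
diagonal; the three matrices are the slices of the 3D feature voxel built
by :mod:`tfpf.features`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FEATURE_KINDS", "ConnectivityMatrix", "PhaseSeries",
    "compute_pcc", "compute_coherence_band", "extract_phase", "compute_plv",
    "connectivity_matrix",
]

FEATURE_KINDS = ("PCC", "COH", "PLV")

#: fraction of samples trimmed from each end of a window before the PLV
#: time average, to discard analytic-signal edge bias
EDGE_TRIM_FRACTION = 0.1


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric channels x channels feature matrix for one window."""

    values: np.ndarray
    feature_kind: str
    band: tuple = (8.0, 30.0)
    segment_index: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_edge_table(self):
        """Long-format edge table (channel_i, channel_j, feature, band_low,
        band_high, segment, value) as a :class:`pandas.DataFrame`."""
        import pandas as pd

        i, j = np.triu_indices(self.n_channels, k=1)
        return pd.DataFrame({
            "channel_i": i, "channel_j": j,
            "feature": self.feature_kind,
            "band_low": self.band[0], "band_high": self.band[1],
            "segment": self.segment_index,
            "value": self.values[i, j],
        })


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) per channel."""

    phases: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", p)


def compute_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length sample vectors.

    Inputs are z-scored (population sd) and the mean product taken, which
    is algebraically the standard Pearson estimate.  Constant input has no
    defined correlation and raises.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant input: correlation undefined for zero-variance signal")
    xz = (x - x.mean()) / sx
    yz = (y - y.mean()) / sy
    return float(np.clip(np.mean(xz * yz), -1.0, 1.0))


def _welch_params(n: int, n_subwindows: int = 4):
    """Sub-window length for Welch estimation: ~1/4 of the segment with 50%
    overlap (a single full-length segment would give coherence ≡ 1)."""
    nperseg = max(8, n // n_subwindows)
    return nperseg, nperseg // 2


def compute_coherence_band(x: np.ndarray, y: np.ndarray, fs: float,
                           band: tuple = (8.0, 30.0)) -> float:
    """Band-averaged magnitude-squared coherence of two sample vectors.

    Welch cross- and auto-spectra (Hann taper, 50% overlap, sub-window =
    1/4 of the segment) give ``COH(f)``; the scalar feature is the mean of
    ``COH(f)`` over frequency bins inside ``band``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nperseg, noverlap = _welch_params(x.size)
    f, cxy = sps.coherence(x, y, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap)
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError(
            f"band {band} Hz contains no frequency bins at fs={fs}, "
            f"segment length {x.size} (bin spacing {fs / nperseg:.3g} Hz)"
        )
    return float(np.clip(np.mean(cxy[in_band]), 0.0, 1.0))


def extract_phase(segment: np.ndarray) -> PhaseSeries:
    """Instantaneous phase of each (band-limited) channel via the analytic
    signal (Hilbert transform)."""
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    zero = np.all(seg == 0, axis=1)
    if np.any(zero):
        raise ValueError(
            f"channel(s) {np.nonzero(zero)[0].tolist()} are all-zero: phase undefined"
        )
    analytic = sps.hilbert(seg, axis=1)
    return PhaseSeries(phases=np.angle(analytic))


def compute_plv(phase_x: np.ndarray, phase_y: np.ndarray,
                edge_trim: float = 0.0) -> float:
    """Phase-locking value of two phase time series.

    ``|mean(exp(i * (phase_x - phase_y)))|`` over time: 1 for a constant
    phase difference, near 0 for independent phases.  ``edge_trim`` drops
    that fraction of samples from each end first (used when the phases come
    from an analytic signal, whose edges are biased).
    """
    px = np.asarray(phase_x, dtype=float).ravel()
    py = np.asarray(phase_y, dtype=float).ravel()
    if px.shape != py.shape:
        raise ValueError(f"length mismatch: {px.shape} vs {py.shape}")
    if px.size < 2:
        raise ValueError("need at least 2 samples")
    if edge_trim:
        k = int(px.size * edge_trim)
        if k:
            px, py = px[k:-k], py[k:-k]
    return float(np.abs(np.mean(np.exp(1j * (px - py)))))


def _pcc_matrix(seg: np.ndarray) -> np.ndarray:
    sd = seg.std(axis=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"constant channel(s) {bad}: correlation undefined")
    z = (seg - seg.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (z @ z.T) / seg.shape[1]
    return np.clip(r, -1.0, 1.0)


def _coh_matrix(seg: np.ndarray, fs: float, band: tuple) -> np.ndarray:
    """All-pairs band-averaged coherence from one set of Welch frames.

    Matches the pairwise estimator (Hann taper, 50% overlap, per-frame
    constant detrend) but computes each channel's windowed FFT once.
    """
    n = seg.shape[1]
    nperseg, noverlap = _welch_params(n)
    step = nperseg - noverlap
    frames = np.lib.stride_tricks.sliding_window_view(seg, nperseg, axis=1)[:, ::step]
    frames = frames - frames.mean(axis=2, keepdims=True)
    taper = sps.get_window("hann", nperseg)
    spec = np.fft.rfft(frames * taper, axis=2)          # (C, n_frames, n_bins)
    f = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError(
            f"band {band} Hz contains no frequency bins at fs={fs}, "
            f"segment length {n} (bin spacing {fs / nperseg:.3g} Hz)"
        )
    spec = spec[:, :, in_band]
    sxy = np.einsum("ifb,jfb->ijb", spec, spec.conj()) / spec.shape[1]
    sxx = np.real(np.einsum("iib->ib", sxy))
    coh = np.abs(sxy) ** 2 / (sxx[:, None, :] * sxx[None, :, :])
    return np.clip(coh.mean(axis=2), 0.0, 1.0)


def _plv_matrix(seg: np.ndarray) -> np.ndarray:
    phases = extract_phase(seg).phases
    k = int(phases.shape[1] * EDGE_TRIM_FRACTION)
    if k:
        phases = phases[:, k:-k]
    u = np.exp(1j * phases)
    plv = np.abs(u @ u.conj().T) / phases.shape[1]
    return np.clip(plv, 0.0, 1.0)


def connectivity_matrix(segment: np.ndarray, fs: float, band: tuple = (8.0, 30.0),
                        feature_kind: str = "PLV",
                        segment_index: int = 0) -> ConnectivityMatrix:
    """Apply one pairwise feature to all unordered channel pairs.

    Returns a symmetric matrix with unit diagonal (any signal is perfectly
    self-connected under all three measures).  Computed with shared
    per-channel spectra/phases, which is algebraically identical to looping
    :func:`compute_pcc` / :func:`compute_coherence_band` /
    :func:`compute_plv` over all pairs.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    n_ch = seg.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    try:
        if feature_kind == "PCC":
            values = _pcc_matrix(seg)
        elif feature_kind == "COH":
            values = _coh_matrix(seg, fs, band)
        elif feature_kind == "PLV":
            values = _plv_matrix(seg)
        else:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}, got {feature_kind!r}")
    except ValueError as exc:
        raise ValueError(f"{feature_kind} matrix (segment {segment_index}): {exc}") from exc
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return ConnectivityMatrix(values=values, feature_kind=feature_kind,
                              band=tuple(band), segment_index=segment_index)
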