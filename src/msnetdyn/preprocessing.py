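"""Deterministic EEG conditioning: average reference and zero-phase FIR filtering.

The filter chain mirrors a standard resting/task EEG pipeline: common
average reference, a broad 0.5-60 Hz band-pass with a 49-51 Hz notch
against line interference, then a narrow theta (4-7 Hz) band for the
phase analyses.  Filters are odd-length windowed-sinc (Hamming) FIR
designs whose symmetric kernel is applied once with group-delay
compensation, so the net response is exactly zero-phase and microstate
timing is not shifted.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .io import EEGRecording

#: transition width of the windowed-sinc designs, Hz
TRANSITION_HZ = 1.0


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous mean across channels.

    Idempotent; requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    sig = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return rec.copy_with(signal=sig)


def fir_order(fs: float, transition: float = TRANSITION_HZ) -> int:
    """Hamming-window FIR length for a given transition width (odd)."""
    n = int(np.ceil(3.3 * fs / transition))
    return n + 1 if n % 2 == 0 else n


def _apply_zero_phase(sig: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # linear-phase FIR with delay compensation: the symmetric kernel applied
    # once via FFT convolution, centered, is exactly zero-phase; reflect
    # padding of one filter length keeps startup transients off the data
    if len(taps) % 2 == 0:
        raise ValueError("zero-phase application needs an odd FIR length")
    pad = min(len(taps), sig.shape[1] - 1)
    padded = np.pad(sig, ((0, 0), (pad, pad)), mode="reflect")
    out = sps.oaconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, pad:-pad]


def bandpass(
    rec: EEGRecording,
    low: float,
    high: float,
    notch: tuple | None = None,
    order: int | None = None,
) -> EEGRecording:
    """Zero-phase FIR band-pass, optionally followed by a band-stop notch.

    Parameters
    ----------
    low, high : float
        Pass-band edges in Hz; must satisfy 0 < low < high < fs/2.
    notch : (f1, f2) or None
        Stop-band interval in Hz, e.g. ``(49, 51)`` for line noise.
    order : int, optional
        FIR length; defaults to a 1 Hz transition width at the recording's
        sampling rate.
    """
    fs = rec.fs
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={fs}")
    ntaps = order if order is not None else fir_order(fs)
    taps = sps.firwin(ntaps, [low, high], pass_zero=False, window="hamming", fs=fs)
    sig = _apply_zero_phase(rec.signal, taps)
    if notch is not None:
        f1, f2 = notch
        if not (0 < f1 < f2 < fs / 2):
            raise ValueError(f"invalid notch interval {notch} for fs={fs}")
        stop = sps.firwin(ntaps, [f1, f2], pass_zero=True, window="hamming", fs=fs)
        sig = _apply_zero_phase(sig, stop)
    return rec.copy_with(signal=sig)


def broadband(rec: EEGRecording, order: int | None = None) -> EEGRecording:
    """0.5-60 Hz band-pass with 49-51 Hz notch."""
    return bandpass(rec, 0.5, 60.0, notch=(49.0, 51.0), order=order)


def theta_band(rec: EEGRecording, order: int | None = None) -> EEGRecording:
    """4-7 Hz band extraction."""
    return bandpass(rec, 4.0, 7.0, order=order)


def ica_clean(rec: EEGRecording) -> EEGRecording:
    """Artifact-removal hook. No-op: synthetic data carry no artifacts."""
    return rec


def csd_transform(rec: EEGRecording) -> EEGRecording:
    """Surface-Laplacian hook. No-op: no volume conduction is simulated."""
    return rec
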