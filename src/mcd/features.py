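"""Temporal feature extraction: windowing and generating currents.

The decoder consumes the signal one 59-sample window at a time.  Two
routes turn a raw window into the "generating currents" injected into the
spiking network:

* **shift** — per-channel amplitude shift so the calibration minimum maps
  to zero (raw-signal route);
* **morlet** — squared magnitude of the complex Morlet wavelet convolution
  at a fundamental frequency, i.e. time-resolved band power.  The standard
  bank spans 10–150 Hz in 10 Hz steps (15 fundamentals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import ECoGSession, WINDOW_LEN

__all__ = [
    "FeatureWindow",
    "frequency_bank",
    "make_windows",
    "shift_features",
    "morlet_features",
    "session_features",
]


@dataclass
class FeatureWindow:
    """Generating currents for one decoder window.

    ``currents`` is ``(n_feature_channels, window_len)``; for the morlet
    approach all entries are squared magnitudes and therefore >= 0.
    """

    currents: np.ndarray
    window_index: int = 0
    approach: str = "shift"
    fundamental_frequency: float | None = None


def frequency_bank() -> np.ndarray:
    """The 15 Morlet fundamental frequencies: 10, 20, ..., 150 Hz."""
    return np.arange(10.0, 151.0, 10.0)


def make_windows(
    session: ECoGSession, window_len: int = WINDOW_LEN, overlap: int = 0
) -> np.ndarray:
    """Cut the session into consecutive windows.

    Returns ``(n_windows, n_channels, window_len)``.  Windows are
    non-overlapping by default (the pseudo-online reader consumes "the next
    portion" of samples); the trailing partial window is dropped, so
    ``n_windows * step + leftover == n_samples`` for ``overlap == 0``.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not 0 <= overlap < window_len:
        raise ValueError("overlap must be in [0, window_len)")
    n = session.n_samples
    if window_len > n:
        raise ValueError(f"window_len {window_len} exceeds n_samples {n}")
    step = window_len - overlap
    n_win = (n - window_len) // step + 1
    idx = np.arange(window_len)[None, :] + step * np.arange(n_win)[:, None]
    return session.signal[:, idx].transpose(1, 0, 2)


def shift_features(
    window: np.ndarray, window_index: int = 0, offsets: np.ndarray | None = None
) -> FeatureWindow:
    """Amplitude-shift route: subtract each channel's minimum.

    By default the minimum is taken over the window itself, which makes the
    output invariant to per-channel additive offsets.  Passing ``offsets``
    (one value per channel, e.g. a per-session calibration minimum) uses a
    fixed reference instead; in that mode values may stay negative if the
    signal drops below the calibration minimum.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    if offsets is None:
        offsets = window.min(axis=-1, keepdims=True)
    else:
        offsets = np.asarray(offsets, dtype=float).reshape(-1, 1)
    return FeatureWindow(
        currents=window - offsets, window_index=window_index, approach="shift"
    )


def _morlet_wavelet(f0: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet at f0 (zero-mean correction omitted; n_cycles
    of 7 keeps the DC leakage negligible), L2-normalised per mne."""
    from mne.time_frequency import morlet

    return morlet(fs, [f0], n_cycles=n_cycles)[0]


def morlet_features(
    window: np.ndarray,
    f0: float,
    fs: float,
    n_cycles: float = 7.0,
    window_index: int = 0,
) -> FeatureWindow:
    """Squared-magnitude Morlet band power at ``f0``, per channel per sample.

    The window is reflection-padded to the wavelet half-length before the
    convolution so the 59 retained samples carry no zero-padding edge bias.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if not 0 < f0 < fs / 2:
        raise ValueError(f"f0 must lie in (0, {fs / 2}) Hz, got {f0}")
    wav = _morlet_wavelet(f0, fs, n_cycles)
    power = _morlet_power(window[None, :, :], wav)[0]
    return FeatureWindow(
        currents=power,
        window_index=window_index,
        approach="morlet",
        fundamental_frequency=f0,
    )


def _morlet_power(windows: np.ndarray, wav: np.ndarray) -> np.ndarray:
    """|conv|^2 along the last axis with reflection padding, batched."""
    pad = len(wav) // 2
    n = windows.shape[-1]
    padded = np.pad(windows, [(0, 0)] * (windows.ndim - 1) + [(pad, pad)], mode="reflect")
    conv = fftconvolve(padded, wav[(None,) * (windows.ndim - 1) + (slice(None),)],
                       mode="same", axes=-1)
    core = conv[..., pad:pad + n]
    return np.abs(core) ** 2


def session_features(
    session: ECoGSession,
    approach: str = "morlet",
    f0: float | None = None,
    n_cycles: float = 7.0,
    window_len: int = WINDOW_LEN,
    overlap: int = 0,
    chunk: int = 256,
) -> np.ndarray:
    """Features for every window of a session: ``(n_windows, n_channels, L)``.

    Semantically identical to calling :func:`shift_features` /
    :func:`morlet_features` per window; the morlet route is batched in
    chunks to keep the FFT work and memory bounded.
    """
    windows = make_windows(session, window_len=window_len, overlap=overlap)
    if approach == "shift":
        return windows - windows.min(axis=-1, keepdims=True)
    if approach != "morlet":
        raise ValueError(f"unknown approach {approach!r}")
    if f0 is None:
        raise ValueError("morlet approach requires f0")
    if not 0 < f0 < session.fs / 2:
        raise ValueError(f"f0 must lie in (0, {session.fs / 2}) Hz, got {f0}")
    wav = _morlet_wavelet(f0, session.fs, n_cycles)
    out = np.empty_like(windows)
    for start in range(0, windows.shape[0], chunk):
        block = windows[start:start + chunk]
        out[start:start + chunk] = _morlet_power(block, wav)
    return out
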