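"""Synthetic ECoG sessions with state-dependent spectral structure.

Real epidural ECoG from implanted participants is private, so every stage
of the decoder is exercised on surrogate sessions built to the same shape:
32–64 channels at 585.6 Hz, minutes long, one label per 59-sample decoder
window, for three task layouts —

* ``runner``  — 2 states (idle / walk), satisfaction labels;
* ``sixdof``  — 3 states (idle / left hand / right hand) plus per-hand 3D
  trajectory targets;
* ``fivedof`` — 5 states plus satisfaction labels and the three per-window
  update flags.

Each channel carries 1/f (pink) background noise; a configurable channel
subset additionally carries band-limited oscillations whose power rises by
``effect_size`` (fractionally) whenever the matching movement state is
active.  Distinct movement states load distinct channel groups, mimicking
spatial selectivity of the motor cortex.  The generator makes no claim of
biophysical realism — it provides controllable, spatially and spectrally
structured signal for end-to-end testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DEFAULT_FS, WINDOW_LEN, ECoGSession, write_edf

__all__ = ["SynthSpec", "generate_session", "write_edf", "task_n_states"]

_TASK_STATES = {"runner": 2, "sixdof": 3, "fivedof": 5}


def task_n_states(task: str) -> int:
    try:
        return _TASK_STATES[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}") from None


@dataclass
class SynthSpec:
    """Conditions of a synthetic session.

    ``effect_size`` is the fractional band-power increase of the carrier in
    the active state (1.0 doubles the power); ``state_dwell`` is the mean
    number of consecutive windows a state persists; ``noise_sd`` the pink
    noise amplitude in microvolts; ``carrier_amp`` the baseline carrier
    amplitude in microvolts (present in every state, so only the state
    modulation — not mere carrier presence — is decodable).
    """

    n_channels: int = 32
    fs: float = DEFAULT_FS
    task: str = "runner"
    session_minutes: float = 5.0
    state_dwell: float = 20.0
    carrier_bands: tuple = (30.0,)
    effect_size: float = 1.0
    noise_sd: float = 20.0
    carrier_amp: float = 10.0
    satisfaction_error_rate: float = 0.1
    seed: int = 0
    window_len: int = WINDOW_LEN
    grid_pitch: float = 4.5

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.satisfaction_error_rate <= 1:
            raise ValueError("satisfaction_error_rate must be in [0, 1]")
        if self.carrier_bands and self.fs <= 2 * max(self.carrier_bands):
            raise ValueError("fs must exceed twice the highest carrier band")
        if self.session_minutes <= 0:
            raise ValueError("session duration must be positive")
        if self.state_dwell < 1:
            raise ValueError("state_dwell must be >= 1 window")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float) -> np.ndarray:
    """1/f-amplitude noise, unit-free shape scaled to per-channel SD ``sd``."""
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = (
        rng.normal(size=(n_channels, freqs.size))
        + 1j * rng.normal(size=(n_channels, freqs.size))
    ) * shaping
    noise = np.fft.irfft(spectrum, n=n_samples, axis=1)
    noise *= sd / noise.std(axis=1, keepdims=True)
    return noise


def _markov_states(rng: np.random.Generator, n_windows: int, n_states: int,
                   dwell: float) -> np.ndarray:
    """State sequence with geometric dwell times of mean ``dwell`` windows."""
    p_stay = 1.0 - 1.0 / dwell
    states = np.empty(n_windows, dtype=int)
    s = 0
    for w in range(n_windows):
        states[w] = s
        if rng.random() >= p_stay and n_states > 1:
            others = [k for k in range(n_states) if k != s]
            s = others[rng.integers(len(others))]
    return states


def _active_channel_groups(n_channels: int, n_states: int) -> list[np.ndarray]:
    """Channel group loaded by each movement state (state 0 = idle = none).

    Groups tile one half of the array (roughly one grid quadrant per
    movement state), so electrode selection and spatial readout matter.
    """
    n_active = max(1, n_states - 1)
    half = np.arange(n_channels // 2) if n_channels >= 2 else np.arange(n_channels)
    return [np.array([], dtype=int)] + list(np.array_split(half, n_active))


def _grid_positions(n_channels: int, pitch: float) -> np.ndarray:
    n_cols = int(np.ceil(np.sqrt(n_channels)))
    n_rows = int(np.ceil(n_channels / n_cols))
    r, c = np.divmod(np.arange(n_channels), n_cols)
    return np.column_stack([c * pitch, r * pitch, np.zeros(n_channels)])


def _smooth_trajectories(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-hand 3D targets: smooth Lissajous arcs while the matching hand
    state (1=left, 2=right) is active, zero during idle."""
    n = len(states)
    traj = np.zeros((n, 2, 3))
    phase = rng.uniform(0, 2 * np.pi, size=2)
    for hand, state in ((0, 1), (1, 2)):
        active = states == state
        t = np.cumsum(active) * 0.15
        curve = np.column_stack([
            np.sin(t + phase[hand]),
            np.cos(0.7 * t + phase[hand]),
            0.5 * np.sin(0.4 * t),
        ])
        traj[active, hand, :] = curve[active]
    return traj


def _default_flags(task: str, n_windows: int) -> np.ndarray:
    """(reinforcement, supervised motor, satisfaction-decoder) per window."""
    flags = np.zeros((n_windows, 3), dtype=bool)
    flags[:, 1] = True
    if task in ("runner", "fivedof"):
        flags[:, 2] = True
    if task == "fivedof":
        flags[:, 0] = True
    return flags


def generate_session(spec: SynthSpec) -> ECoGSession:
    """Generate one labelled synthetic session (byte-identical under seed)."""
    rng = np.random.default_rng(spec.seed)
    n_states = task_n_states(spec.task)
    n_samples = int(round(spec.fs * 60 * spec.session_minutes))
    if n_samples < spec.window_len:
        raise ValueError("session shorter than one window")
    n_windows = n_samples // spec.window_len

    states = _markov_states(rng, n_windows, n_states, spec.state_dwell)
    signal = _pink_noise(rng, spec.n_channels, n_samples, spec.noise_sd)

    # per-sample gain of the carrier: sqrt(1 + effect) while the channel's
    # state is active, 1 otherwise (power ratio = 1 + effect_size)
    groups = _active_channel_groups(spec.n_channels, n_states)
    sample_state = np.repeat(states, spec.window_len)
    sample_state = np.pad(sample_state, (0, n_samples - sample_state.size),
                          mode="edge")
    t = np.arange(n_samples) / spec.fs
    active_gain = np.sqrt(1.0 + spec.effect_size)
    for f_c in spec.carrier_bands:
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        base = np.sin(2 * np.pi * f_c * t[None, :] + phases[:, None])
        gain = np.ones((spec.n_channels, n_samples))
        for s in range(1, n_states):
            idx = groups[s]
            if idx.size:
                gain[np.ix_(idx, np.flatnonzero(sample_state == s))] = active_gain
        signal += spec.carrier_amp * gain * base

    satisfaction = None
    if spec.task in ("runner", "fivedof"):
        satisfaction = np.ones(n_windows, dtype=int)
        flips = rng.random(n_windows) < spec.satisfaction_error_rate
        satisfaction[flips] = 0

    trajectory = _smooth_trajectories(states, rng) if spec.task == "sixdof" else None

    return ECoGSession(
        signal=signal,
        fs=spec.fs,
        channel_positions=_grid_positions(spec.n_channels, spec.grid_pitch),
        state_labels=states,
        trajectory_targets=trajectory,
        satisfaction_labels=satisfaction,
        update_flags=_default_flags(spec.task, n_windows),
    )
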