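"""Reading and writing ECoG sessions.

Signals live in a channels x samples matrix of microvolts together with
per-window labels (movement state, optional 3D hand-trajectory targets,
optional satisfaction labels, optional update flags).  The on-disk formats
are EDF/EDF+ for signals and plain CSV for the signal fallback and for the
per-window label tables.

EDF reading goes through :mod:`mne`.  EDF writing is implemented here
directly against the EDF 16-bit specification (ASCII header blocks plus
little-endian int16 data records); it exists so that synthetic sessions can
be round-tripped through the same input path as recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ECoGSession",
    "read_edf",
    "write_edf",
    "read_csv_session",
    "write_csv_session",
    "checkerboard_select",
    "attach_labels",
    "read_label_table",
    "write_label_table",
]

#: nominal sampling rate of the recording hardware (Hz)
DEFAULT_FS = 585.6

#: decoder step length in samples ("one portion of records")
WINDOW_LEN = 59


@dataclass
class ECoGSession:
    """A multichannel ECoG recording with per-window annotations.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz (nominally 585.6 Hz).
    channel_positions
        Optional ``(n_channels, 3)`` electrode coordinates in mm.
    state_labels
        Optional integer state per decoder window.
    trajectory_targets
        Optional ``(n_windows, 2, 3)`` target hand positions (left, right).
    satisfaction_labels
        Optional binary per-window satisfaction feedback.
    update_flags
        Optional ``(n_windows, 3)`` booleans: columns are
        (reinforcement update, supervised motor update, satisfaction-decoder
        update).
    """

    signal: np.ndarray
    fs: float = DEFAULT_FS
    channel_positions: np.ndarray | None = None
    state_labels: np.ndarray | None = None
    trajectory_targets: np.ndarray | None = None
    satisfaction_labels: np.ndarray | None = None
    update_flags: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def n_windows(self, window_len: int = WINDOW_LEN) -> int:
        return self.n_samples // window_len

    def select_channels(self, indices) -> "ECoGSession":
        """Return a new session restricted to ``indices`` (order preserved)."""
        indices = list(indices)
        n = self.n_channels
        for i in indices:
            if not (-n <= i < n):
                raise IndexError(f"channel index {i} out of range for {n} channels")
        pos = None
        if self.channel_positions is not None:
            pos = self.channel_positions[indices]
        return ECoGSession(
            signal=self.signal[indices],
            fs=self.fs,
            channel_positions=pos,
            state_labels=self.state_labels,
            trajectory_targets=self.trajectory_targets,
            satisfaction_labels=self.satisfaction_labels,
            update_flags=self.update_flags,
            channel_names=[self.channel_names[i] for i in indices],
        )


def checkerboard_select(n_rows: int, n_cols: int) -> list[int]:
    """Indices of alternating cells of a row-major electrode grid.

    The pattern starts at cell (0, 0) and keeps every cell whose row+column
    parity is even, i.e. ``ceil(n_rows*n_cols/2)`` electrodes — the scheme
    used to halve the channel count of a 64-electrode implant to 32 under a
    limited radio-link budget.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    out = []
    for r in range(n_rows):
        for c in range(n_cols):
            if (r + c) % 2 == 0:
                out.append(r * n_cols + c)
    return out


def read_edf(path, channel_subset=None) -> ECoGSession:
    """Read an EDF/EDF+ file into an :class:`ECoGSession`.

    Signals are returned in microvolts, in acquisition order, with the
    sampling rate taken from the header.  Labels are empty until attached.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file is not a readable EDF file.
    IndexError
        If ``channel_subset`` contains an out-of-range index.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # corrupt header, truncated records, ...
        raise ValueError(f"not a readable EDF file: {path}: {exc}") from None
    data = raw.get_data() * 1e6  # mne returns volts
    session = ECoGSession(
        signal=np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )
    if channel_subset is not None:
        session = session.select_channels(channel_subset)
    return session


def _edf_ascii(value, width: int) -> bytes:
    """Format a header field as exactly ``width`` ASCII bytes."""
    s = str(value)
    if len(s) > width:
        if isinstance(value, float):
            # shrink precision until it fits
            for p in range(10, -1, -1):
                s = f"{value:.{p}g}"
                if len(s) <= width:
                    break
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _record_geometry(fs: float, max_duration: float = 10.0):
    """Smallest record duration (in 0.5 s steps) giving an integer number of
    samples per record.  585.6 Hz needs 5 s records (2928 samples)."""
    for k in range(1, int(max_duration * 2) + 1):
        dur = k / 2.0
        spr = fs * dur
        if abs(spr - round(spr)) < 1e-6:
            return dur, int(round(spr))
    raise ValueError(f"sampling rate {fs} Hz has no integer samples/record <= {max_duration}s")


def write_edf(session: ECoGSession, path) -> None:
    """Write a session as a 16-bit EDF file.

    Each channel is scaled to its own physical min/max, so the round-trip
    error is at most one quantization step of the 16-bit range.  The last
    data record is zero-padded if the session length is not a whole number
    of records.
    """
    path = Path(path)
    sig = np.asarray(session.signal, dtype=float)
    if not np.isfinite(sig).all():
        raise ValueError("signal contains non-finite values")
    n_ch, n_samp = sig.shape
    dur, spr = _record_geometry(session.fs)
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = sig

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # avoid a degenerate scale on constant channels
    flat = phys_max - phys_min < 1e-9
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.rint((padded - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_edf_ascii("0", 8))
        fh.write(_edf_ascii("X X X X", 80))           # patient id (anonymous)
        fh.write(_edf_ascii("Startdate X X X X", 80))  # recording id
        fh.write(_edf_ascii("01.01.01", 8))
        fh.write(_edf_ascii("00.00.00", 8))
        fh.write(_edf_ascii(header_bytes, 8))
        fh.write(_edf_ascii("", 44))
        fh.write(_edf_ascii(n_rec, 8))
        fh.write(_edf_ascii(dur, 8))
        fh.write(_edf_ascii(n_ch, 4))
        for name in session.channel_names:
            fh.write(_edf_ascii(name, 16))
        for _ in range(n_ch):
            fh.write(_edf_ascii("", 80))              # transducer
        for _ in range(n_ch):
            fh.write(_edf_ascii("uV", 8))
        for v in phys_min:
            fh.write(_edf_ascii(float(v), 8))
        for v in phys_max:
            fh.write(_edf_ascii(float(v), 8))
        for _ in range(n_ch):
            fh.write(_edf_ascii(dig_min, 8))
        for _ in range(n_ch):
            fh.write(_edf_ascii(dig_max, 8))
        for _ in range(n_ch):
            fh.write(_edf_ascii("", 80))              # prefiltering
        for _ in range(n_ch):
            fh.write(_edf_ascii(spr, 8))
        for _ in range(n_ch):
            fh.write(_edf_ascii("", 32))
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def write_csv_session(session: ECoGSession, path) -> None:
    """Signal fallback format: one column per channel, header row, microvolts."""
    df = pd.DataFrame(session.signal.T, columns=session.channel_names)
    df.to_csv(path, index=False)


def read_csv_session(path, fs: float = DEFAULT_FS, channel_subset=None) -> ECoGSession:
    """Read the CSV signal fallback (one column per channel, header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    session = ECoGSession(
        signal=df.to_numpy(dtype=float).T,
        fs=fs,
        channel_names=[str(c) for c in df.columns],
    )
    if channel_subset is not None:
        session = session.select_channels(channel_subset)
    return session


def write_label_table(session: ECoGSession, path) -> None:
    """Sidecar label CSV keyed by window index."""
    n_win = None
    for arr in (session.state_labels, session.satisfaction_labels):
        if arr is not None:
            n_win = len(arr)
            break
    if n_win is None:
        raise ValueError("session has no labels to write")
    data: dict[str, np.ndarray] = {"window": np.arange(n_win)}
    if session.state_labels is not None:
        data["state"] = np.asarray(session.state_labels)
    if session.trajectory_targets is not None:
        traj = np.asarray(session.trajectory_targets).reshape(n_win, 6)
        for j, name in enumerate(
            ["traj_lx", "traj_ly", "traj_lz", "traj_rx", "traj_ry", "traj_rz"]
        ):
            data[name] = traj[:, j]
    if session.satisfaction_labels is not None:
        data["satisfaction"] = np.asarray(session.satisfaction_labels)
    if session.update_flags is not None:
        flags = np.asarray(session.update_flags, dtype=int)
        data["flag_rl"] = flags[:, 0]
        data["flag_supervised"] = flags[:, 1]
        data["flag_satisfaction"] = flags[:, 2]
    pd.DataFrame(data).to_csv(path, index=False)


def read_label_table(path) -> dict:
    """Read a sidecar label CSV into arrays keyed like the session fields."""
    df = pd.read_csv(path)
    out: dict = {}
    if "state" in df:
        out["state_labels"] = df["state"].to_numpy(dtype=int)
    traj_cols = ["traj_lx", "traj_ly", "traj_lz", "traj_rx", "traj_ry", "traj_rz"]
    if all(c in df for c in traj_cols):
        out["trajectory_targets"] = df[traj_cols].to_numpy(dtype=float).reshape(-1, 2, 3)
    if "satisfaction" in df:
        out["satisfaction_labels"] = df["satisfaction"].to_numpy(dtype=int)
    if all(c in df for c in ("flag_rl", "flag_supervised", "flag_satisfaction")):
        out["update_flags"] = df[
            ["flag_rl", "flag_supervised", "flag_satisfaction"]
        ].to_numpy(dtype=bool)
    return out


def attach_labels(session: ECoGSession, path, window_len: int = WINDOW_LEN) -> ECoGSession:
    """Attach a sidecar label table to a session (validated against its length)."""
    labels = read_label_table(path)
    n_win = session.n_windows(window_len)
    for key, arr in labels.items():
        if len(arr) > n_win:
            raise ValueError(
                f"{key}: {len(arr)} windows labeled but session has only {n_win}"
            )
        setattr(session, key, arr)
    return session
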