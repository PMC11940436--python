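"""Pseudo-online decoding loop, per-frequency model banks and voting.

One decoder step: read a 59-sample window -> generating currents (shift or
Morlet) -> spiking network simulation (with continuous STDP) -> spike-rate
features of the electrode-mapped neurons -> echo-state reservoir update ->
linear heads -> argmax / regression decode.  Per-window update flags then
choose which learning rules run: supervised RLS on the state, trajectory
and satisfaction heads, and/or the satisfaction-gated reinforcement rule
on the state head.

A model *bank* runs one decoder per Morlet fundamental frequency; the bank
members' state decisions are combined by threshold voting (the plurality
label wins when enough members agree, otherwise a fallback label — idle by
default — is emitted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import esn as esn_mod
from . import snn as snn_mod
from .features import session_features
from .io import WINDOW_LEN, ECoGSession
from .synth import task_n_states

__all__ = [
    "SNNConfig",
    "ESNConfig",
    "RunConfig",
    "VotingSpec",
    "DecodedStep",
    "run_online",
    "run_bank",
    "vote",
    "select_voting_threshold",
    "write_outputs",
    "read_outputs",
    "load_config",
]

logger = logging.getLogger(__name__)

#: the "voting chosen" member frequencies (Hz)
CHOSEN_FREQUENCIES = (10.0, 30.0, 50.0, 70.0, 100.0, 110.0)


@dataclass
class SNNConfig:
    """Spiking-stage hyper-parameters.

    ``gain`` maps one standardized feature unit to pA; ``i_base`` is the
    operating-point current (pA) injected regardless of the feature value,
    chosen just above rheobase so the median feature drives ~20 Hz firing
    in an isolated neuron.  ``calib_windows`` initial windows fix the
    per-channel feature standardization.
    """

    n_neurons: int = 100
    w0: float = 1.0
    sigma_d: float = 5.0
    d_cut: float = 15.0
    p_long: float = 0.01
    gain: float = 40.0
    i_base: float = 126.0
    calib_windows: int = 50
    lambda_rate: float = 0.001
    t_ref: float = 0.0
    V_th: float = -65.0
    dt: float = 0.1
    reset_between_windows: bool = False


@dataclass
class ESNConfig:
    N: int = 1000
    a: float = 0.5
    sparsity: float = 0.5
    rho: float = 0.95
    input_scale: float = 1.0
    eps: float = 1e-2
    forgetting: float = 1.0
    alpha: float = 1e-4
    delta: float = 0.9
    rate_scale: float = 0.01  # spike-rate (Hz) -> ESN input units


@dataclass
class RunConfig:
    """Everything needed to reproduce one decoding run."""

    task: str = "runner"
    approach: str = "morlet"
    frequencies: tuple = (30.0,)
    window_len: int = WINDOW_LEN
    overlap: int = 0
    n_cycles: float = 7.0
    snn: SNNConfig = field(default_factory=SNNConfig)
    esn: ESNConfig = field(default_factory=ESNConfig)
    training: str = "auto"  # rls | rl | auto (follow session flags)
    seed: int = 0

    def __post_init__(self) -> None:
        task_n_states(self.task)
        if self.approach not in ("shift", "morlet"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.training not in ("rls", "rl", "auto"):
            raise ValueError(f"unknown training mode {self.training!r}")


@dataclass
class VotingSpec:
    member_frequencies: tuple = CHOSEN_FREQUENCIES
    threshold: int = 3
    fallback: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= len(self.member_frequencies):
            raise ValueError("threshold must be within 1..members")


@dataclass
class DecodedStep:
    """Decoder output for one window."""

    window_index: int
    state: int
    state_scores: np.ndarray
    trajectory: np.ndarray | None = None  # (2 hands, 3 coords)
    satisfaction: int | None = None


def _member_seed(seed: int, idx: int) -> int:
    return int((seed * 1_000_003 + 7919 * idx + 1) % (2**31 - 1))


def _grid_positions(n_channels: int, pitch: float = 4.5) -> np.ndarray:
    n_cols = int(np.ceil(np.sqrt(n_channels)))
    r, c = np.divmod(np.arange(n_channels), n_cols)
    return np.column_stack([c * pitch, r * pitch, np.zeros(n_channels)])


def _build_member(config: RunConfig, session: ECoGSession, member_idx: int) -> dict:
    seed = _member_seed(config.seed, member_idx)
    epos = session.channel_positions
    if epos is None:
        epos = _grid_positions(session.n_channels)
    positions = snn_mod.template_positions(epos, config.snn.n_neurons, seed=seed)
    lif = snn_mod.LIFParams(
        V_th=config.snn.V_th, t_ref=config.snn.t_ref, dt=config.snn.dt
    )
    stdp = snn_mod.STDPParams(
        lambda_rate=config.snn.lambda_rate, w_max=2.0 * config.snn.w0
    )
    net = snn_mod.build_network(
        positions, epos,
        w0=config.snn.w0, sigma_d=config.snn.sigma_d, d_cut=config.snn.d_cut,
        p_long=config.snn.p_long, seed=seed, lif=lif, stdp=stdp,
    )
    heads = {"state": task_n_states(config.task)}
    if config.task == "sixdof":
        heads["trajectory"] = 6
    if config.task in ("runner", "fivedof"):
        heads["satisfaction"] = 2
    e = config.esn
    esn = esn_mod.esn_init(
        N=e.N, K=session.n_channels, a=e.a, sparsity=e.sparsity, rho=e.rho,
        input_scale=e.input_scale, seed=seed + 1, heads=heads,
        eps=e.eps, forgetting=e.forgetting, alpha=e.alpha, delta=e.delta,
    )
    return {"snn": net, "esn": esn, "calib": None}


def _window_flags(config: RunConfig, session: ECoGSession, n_windows: int) -> np.ndarray:
    """Resolve per-window (reinforcement, supervised, satisfaction) flags."""
    if config.training == "auto" and session.update_flags is not None:
        flags = np.asarray(session.update_flags, dtype=bool)
        if len(flags) < n_windows:
            flags = np.vstack(
                [flags, np.zeros((n_windows - len(flags), 3), dtype=bool)]
            )
        return flags[:n_windows]
    flags = np.zeros((n_windows, 3), dtype=bool)
    has_labels = session.state_labels is not None
    if config.training in ("rls", "auto") and has_labels:
        flags[: len(session.state_labels), 1] = True
        if session.satisfaction_labels is not None:
            flags[: len(session.satisfaction_labels), 2] = True
    if config.training == "rl":
        flags[:, 0] = True
    return flags


def _one_hot(label: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[int(label)] = 1.0
    return v


def run_online(
    config: RunConfig,
    session: ECoGSession,
    models: dict | None = None,
    member_idx: int = 0,
    f0: float | None = None,
) -> tuple[list[DecodedStep], dict]:
    """Run the pseudo-online loop for one bank member over a session.

    ``models`` continues a previous run (its SNN weights, reservoir state,
    readouts and feature calibration are reused and further adapted);
    otherwise a fresh member is built deterministically from the config
    seed.  Returns one :class:`DecodedStep` per window plus the updated
    models.  The SNN adapts by STDP on every window regardless of flags;
    the readouts only move on flagged windows.
    """
    if f0 is None:
        f0 = config.frequencies[member_idx] if config.approach == "morlet" else None
    feats = session_features(
        session, approach=config.approach, f0=f0, n_cycles=config.n_cycles,
        window_len=config.window_len, overlap=config.overlap,
    )
    n_windows = feats.shape[0]
    if models is None:
        models = _build_member(config, session, member_idx)
    net: snn_mod.SNNetwork = models["snn"]
    esn: esn_mod.ESNModel = models["esn"]
    if models["calib"] is None:
        calib = feats[: max(1, min(config.snn.calib_windows, n_windows))]
        mu = calib.mean(axis=(0, 2))
        sd = np.maximum(calib.std(axis=(0, 2)), 1e-9)
        models["calib"] = (mu, sd)
    mu, sd = models["calib"]

    flags = _window_flags(config, session, n_windows)
    n_states = task_n_states(config.task)
    labels = session.state_labels
    sats = session.satisfaction_labels
    trajs = session.trajectory_targets
    if flags[:, 1].any() and labels is None:
        raise ValueError("supervised update flagged but session has no state labels")

    if config.snn.reset_between_windows:
        net.reset_state()
    steps: list[DecodedStep] = []
    for w in range(n_windows):
        z = (feats[w] - mu[:, None]) / sd[:, None]
        rec = snn_mod.simulate_window(
            net, z, gain=config.snn.gain, i_offset=config.snn.i_base, fs=session.fs
        )
        snn_mod.stdp_step(net, rec)
        rates = snn_mod.spike_rate_features(rec, net.electrode_map)
        in_t = rates * config.esn.rate_scale
        esn_mod.esn_step(esn, in_t)
        x = esn_mod.concat_state(esn, in_t)

        state_scores = esn.heads["state"].W_out @ x
        step = DecodedStep(
            window_index=w,
            state=esn_mod.decode_state(state_scores),
            state_scores=state_scores,
        )
        if "trajectory" in esn.heads:
            step.trajectory = (esn.heads["trajectory"].W_out @ x).reshape(2, 3)
        if "satisfaction" in esn.heads:
            step.satisfaction = esn_mod.decode_satisfaction(
                esn.heads["satisfaction"].W_out @ x
            )
        steps.append(step)

        rl_flag, sup_flag, sat_flag = flags[w]
        if sup_flag and labels is not None and w < len(labels):
            esn_mod.rls_update(
                esn.heads["state"], x, _one_hot(labels[w], n_states)
            )
            if "trajectory" in esn.heads and trajs is not None and w < len(trajs):
                esn_mod.rls_update(
                    esn.heads["trajectory"], x, np.asarray(trajs[w]).ravel()
                )
        if sat_flag and "satisfaction" in esn.heads and sats is not None and w < len(sats):
            esn_mod.rls_update(
                esn.heads["satisfaction"], x, _one_hot(sats[w], 2)
            )
        if rl_flag:
            if sats is not None and w < len(sats):
                satisfaction = int(sats[w])
            else:
                satisfaction = step.satisfaction if step.satisfaction is not None else 1
            esn_mod.rl_update(esn.heads["state"], x, state_scores, satisfaction)
        if w % 500 == 0:
            logger.info(
                "window %d: state=%d spikes=%d", w, step.state,
                sum(len(s) for s in rec.spikes),
            )
    return steps, models


def run_bank(
    config: RunConfig, session: ECoGSession, bank: dict | None = None
) -> tuple[dict, dict]:
    """Run every bank member over a session.

    Returns ``(steps_by_member, models_by_member)`` keyed by fundamental
    frequency (or ``"shift"``).  Each member has its own SNN (the features
    differ per frequency, so the spike patterns adapt differently) and its
    own ESN, all seeded from the config seed.
    """
    members = (
        [(i, f) for i, f in enumerate(config.frequencies)]
        if config.approach == "morlet"
        else [(0, "shift")]
    )
    bank = bank if bank is not None else {}
    all_steps: dict = {}
    for idx, key in members:
        f0 = key if config.approach == "morlet" else None
        steps, models = run_online(
            config, session, models=bank.get(key), member_idx=idx, f0=f0
        )
        bank[key] = models
        all_steps[key] = steps
    return all_steps, bank


def vote(predictions, spec: VotingSpec):
    """Threshold voting across equal-length member label sequences.

    Per window the plurality label wins when its supporter count reaches
    ``spec.threshold``; plurality ties and under-threshold pluralities both
    resolve to ``spec.fallback``.
    """
    arr = np.asarray([list(p) for p in predictions])
    if arr.size == 0 or arr.ndim != 2:
        raise ValueError("need at least one member with at least one window")
    n_members, n_windows = arr.shape
    out = np.empty(n_windows, dtype=arr.dtype)
    for w in range(n_windows):
        labels, counts = np.unique(arr[:, w], return_counts=True)
        top = counts.max()
        winners = labels[counts == top]
        if len(winners) > 1 or top < spec.threshold:
            out[w] = spec.fallback
        else:
            out[w] = winners[0]
    return out


def select_voting_threshold(
    member_predictions, truth, candidate_thresholds, fallback: int = 0
) -> int:
    """Pick the voting threshold maximizing balanced accuracy on validation
    truth; ties break toward the smaller threshold."""
    from .metrics import balanced_accuracy

    candidates = sorted(set(int(t) for t in candidate_thresholds))
    if not candidates:
        raise ValueError("no candidate thresholds")
    n_members = len(member_predictions)
    best_t, best_acc = None, -np.inf
    for t in candidates:
        if not 1 <= t <= n_members:
            raise ValueError(f"threshold {t} outside 1..{n_members}")
        voted = vote(
            member_predictions,
            VotingSpec(
                member_frequencies=tuple(range(n_members)),
                threshold=t,
                fallback=fallback,
            ),
        )
        acc = balanced_accuracy(truth, voted)
        if acc > best_acc:
            best_t, best_acc = t, acc
    return best_t


_OUTPUT_COLUMNS = [
    "window", "state",
    "traj_lx", "traj_ly", "traj_lz", "traj_rx", "traj_ry", "traj_rz",
    "satisfaction",
]


def write_outputs(steps, path) -> None:
    """One CSV row per decoded window (fixed header; lossless round-trip)."""
    rows = []
    for s in steps:
        traj = (
            np.asarray(s.trajectory, dtype=float).ravel()
            if s.trajectory is not None
            else np.full(6, np.nan)
        )
        rows.append(
            [s.window_index, s.state, *traj,
             s.satisfaction if s.satisfaction is not None else np.nan]
        )
    pd.DataFrame(rows, columns=_OUTPUT_COLUMNS).to_csv(path, index=False)


def read_outputs(path) -> list[DecodedStep]:
    df = pd.read_csv(path)
    steps = []
    for _, row in df.iterrows():
        traj = row[_OUTPUT_COLUMNS[2:8]].to_numpy(dtype=float)
        sat = row["satisfaction"]
        steps.append(
            DecodedStep(
                window_index=int(row["window"]),
                state=int(row["state"]),
                state_scores=None,
                trajectory=None if np.isnan(traj).all() else traj.reshape(2, 3),
                satisfaction=None if pd.isna(sat) else int(sat),
            )
        )
    return steps


def load_config(path) -> RunConfig:
    """Load a RunConfig from a nested YAML mapping (documented schema:
    top-level RunConfig fields, with ``snn:`` and ``esn:`` sub-mappings)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    snn = SNNConfig(**raw.pop("snn", {}))
    esn = ESNConfig(**raw.pop("esn", {}))
    if "frequencies" in raw:
        raw["frequencies"] = tuple(float(f) for f in raw["frequencies"])
    return RunConfig(snn=snn, esn=esn, **raw)


def save_config(config: RunConfig, path) -> None:
    import yaml

    d = asdict(config)
    d["frequencies"] = list(d["frequencies"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
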