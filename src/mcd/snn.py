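"""3D spiking network: LIF dynamics, small-world wiring, STDP.

The network sits between the feature extractor and the echo state
decoder.  Feature currents drive the neurons mapped to the ECoG electrode
positions; the network's distance-decay ("small-world") synapses adapt
continuously by spike-timing-dependent plasticity; the features passed on
downstream are the spiking frequencies of the electrode-mapped neurons
over one decoder window,

    rate_i = n_spikes_i / t_window.

Membrane dynamics follow the leaky integrate-and-fire model

    dV/dt = -(V - E_L)/tau_m + (I_syn + I_e)/C_m,

integrated by forward Euler; a spike is emitted when V crosses V_th, after
which V is held at V_reset for the refractory period.  Synapses deliver a
delta charge ``weight * q_syn`` to the postsynaptic membrane after a
uniform conduction delay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = [
    "LIFParams",
    "STDPParams",
    "SNNetwork",
    "SpikeRecord",
    "build_network",
    "template_positions",
    "simulate_window",
    "stdp_step",
    "spike_rate_features",
    "save_network",
    "load_network",
    "read_positions_csv",
]


@dataclass
class LIFParams:
    """Leaky integrate-and-fire neuron parameters.

    V_th is 5 mV above rest with the defaults below; t_ref defaults to 0 ms.
    Units: mV, ms, pF.
    """

    V_th: float = -65.0
    E_L: float = -70.0
    V_reset: float = -70.0
    tau_m: float = 10.0
    C_m: float = 250.0
    t_ref: float = 0.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.V_th <= self.V_reset:
            raise ValueError("V_th must exceed V_reset")
        if self.tau_m <= 0 or self.C_m <= 0 or self.dt <= 0:
            raise ValueError("tau_m, C_m, dt must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")


@dataclass
class STDPParams:
    """Additive, nearest-neighbour pair-based STDP.

    Pre-before-post by dt potentiates by ``lambda_rate*w_max*exp(-dt/tau_plus)``;
    post-before-pre depresses by the same magnitude scaled by ``asymmetry``.
    Weights are clipped to [0, w_max].
    """

    lambda_rate: float = 0.001
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    asymmetry: float = 1.05
    w_max: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda_rate < 0:
            raise ValueError("lambda_rate must be >= 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("trace time constants must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")


@dataclass
class SpikeRecord:
    """Per-neuron sorted spike times (ms) within one simulated window."""

    spikes: list
    window_duration: float

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])


@dataclass
class SNNetwork:
    """Wired LIF network plus its mutable simulation state.

    ``weights`` is dense internally (networks are small); ``mask`` freezes
    the synapse set so STDP changes strengths, never topology.  Membrane
    potential, refractory counters and the in-flight synaptic charge buffer
    persist across consecutive windows.
    """

    positions: np.ndarray
    weights: np.ndarray
    mask: np.ndarray
    electrode_map: np.ndarray
    lif: LIFParams
    stdp: STDPParams
    delay: float = 1.0       # ms, uniform conduction delay
    q_syn: float = 0.05      # pC delivered per unit weight per spike
    V: np.ndarray = field(default=None, repr=False)
    ref_left: np.ndarray = field(default=None, repr=False)
    buf: np.ndarray = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    def reset_state(self) -> None:
        n = self.n_neurons
        self.V = np.full(n, self.lif.E_L)
        self.ref_left = np.zeros(n, dtype=np.int64)
        self.buf = np.zeros((max(1, int(round(self.delay / self.lif.dt))), n))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.V is None:
            self.reset_state()


def build_network(
    positions: np.ndarray,
    electrode_positions: np.ndarray,
    w0: float = 1.0,
    sigma_d: float = 5.0,
    d_cut: float = 15.0,
    p_long: float = 0.01,
    seed: int = 0,
    lif: LIFParams | None = None,
    stdp: STDPParams | None = None,
    **net_kwargs,
) -> SNNetwork:
    """Wire a network by the distance-decay small-world rule.

    Connection strength is ``w0 * exp(-d/sigma_d)`` for pairs within
    ``d_cut`` mm; beyond the cutoff, sparse long-range links appear with
    probability ``p_long`` at the cutoff strength.  Each electrode is
    mapped to its nearest neuron.  Deterministic under ``seed``.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    electrode_positions = np.asarray(electrode_positions, dtype=float).reshape(-1, 3)
    n = positions.shape[0]
    m = electrode_positions.shape[0]
    if n == 0:
        raise ValueError("empty neuron positions")
    if m == 0 or m > n:
        raise ValueError("need 1 <= n_electrodes <= n_neurons")
    if sigma_d <= 0 or d_cut <= 0:
        raise ValueError("sigma_d and d_cut must be positive")
    rng = np.random.default_rng(seed)
    d = cdist(positions, positions)
    off_diag = ~np.eye(n, dtype=bool)
    near = (d <= d_cut) & off_diag
    weights = np.where(near, w0 * np.exp(-d / sigma_d), 0.0)
    far = (d > d_cut) & off_diag
    long_links = far & (rng.random((n, n)) < p_long)
    weights[long_links] = w0 * np.exp(-d_cut / sigma_d)
    mask = weights > 0
    emap = np.argmin(cdist(electrode_positions, positions), axis=1)
    stdp = stdp if stdp is not None else STDPParams(w_max=2.0 * w0)
    return SNNetwork(
        positions=positions,
        weights=weights,
        mask=mask,
        electrode_map=emap.astype(np.int64),
        lif=lif if lif is not None else LIFParams(),
        stdp=stdp,
        **net_kwargs,
    )


def template_positions(
    electrode_positions: np.ndarray,
    n_total: int,
    seed: int = 0,
    depth: float = 10.0,
    jitter: float = 0.5,
) -> np.ndarray:
    """Default 3D template: the electrode sites plus filler neurons.

    Filler neurons sit on a jittered grid filling the electrode bounding
    box extended ``depth`` mm inward (negative z), standing in for a
    volumetric brain template when no individual scan is available.
    """
    electrode_positions = np.asarray(electrode_positions, dtype=float).reshape(-1, 3)
    m = electrode_positions.shape[0]
    if n_total < m:
        raise ValueError("n_total must be >= number of electrodes")
    n_fill = n_total - m
    if n_fill == 0:
        return electrode_positions.copy()
    rng = np.random.default_rng(seed)
    lo = electrode_positions.min(axis=0)
    hi = electrode_positions.max(axis=0)
    lo[2] -= depth
    span = np.maximum(hi - lo, 1e-6)
    # near-cubic grid with at least n_fill cells
    k = int(np.ceil(n_fill ** (1 / 3)))
    axes = [np.linspace(lo[i] + span[i] / (2 * k), hi[i] - span[i] / (2 * k), k)
            for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    chosen = rng.choice(grid.shape[0], size=n_fill, replace=False)
    filler = grid[chosen] + rng.normal(scale=jitter, size=(n_fill, 3))
    return np.vstack([electrode_positions, filler])


@njit(cache=True)
def _lif_kernel(V, ref_left, buf, W, emap, currents, sample_of_step,
                V_th, E_L, V_reset, tau_m, C_m, ref_steps, dt,
                q_over_C, spike_n, spike_t):
    n = V.shape[0]
    m = emap.shape[0]
    n_steps = sample_of_step.shape[0]
    delay_steps = buf.shape[0]
    leak = dt / tau_m
    n_spk = 0
    for t in range(n_steps):
        slot = t % delay_steps
        s = sample_of_step[t]
        for i in range(n):
            if ref_left[i] > 0:
                ref_left[i] -= 1
                V[i] = V_reset
                buf[slot, i] = 0.0
            else:
                V[i] += leak * (E_L - V[i]) + buf[slot, i]
                buf[slot, i] = 0.0
        for k in range(m):
            i = emap[k]
            if ref_left[i] == 0:
                V[i] += dt * currents[k, s] / C_m
        for i in range(n):
            if ref_left[i] == 0 and V[i] >= V_th:
                if n_spk < spike_n.shape[0]:
                    spike_n[n_spk] = i
                    spike_t[n_spk] = t * dt
                    n_spk += 1
                V[i] = V_reset
                ref_left[i] = ref_steps
                for j in range(n):
                    if W[i, j] != 0.0:
                        buf[slot, j] += W[i, j] * q_over_C
    return n_spk


def simulate_window(
    net: SNNetwork,
    currents,
    gain: float = 1.0,
    i_offset: float = 0.0,
    duration: float | None = None,
    fs: float = 585.6,
) -> SpikeRecord:
    """Advance the network through one window of feature currents.

    ``currents`` is a :class:`~mcd.features.FeatureWindow` or an
    ``(n_electrodes, n_samples)`` array in feature units; the injected
    current at the electrode-mapped neurons is ``i_offset + gain * value``
    (pA), piecewise-constant over each 1/fs interval.  Membrane state,
    refractory counters and in-flight synaptic charge persist across calls.
    """
    cur = getattr(currents, "currents", currents)
    cur = np.atleast_2d(np.asarray(cur, dtype=float))
    m, n_samp = cur.shape
    if m != len(net.electrode_map):
        raise ValueError(
            f"{m} feature channels but network maps {len(net.electrode_map)} electrodes"
        )
    if duration is None:
        duration = n_samp * 1000.0 / fs
    if duration <= 0:
        raise ValueError("duration must be positive")
    lif = net.lif
    n_steps = int(round(duration / lif.dt))
    sample_of_step = np.minimum(
        (np.arange(n_steps) * lif.dt * fs / 1000.0).astype(np.int64), n_samp - 1
    )
    cap = net.n_neurons * (n_steps // 2 + 1)
    spike_n = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap, dtype=np.float64)
    n_spk = _lif_kernel(
        net.V, net.ref_left, net.buf, net.weights, net.electrode_map,
        i_offset + gain * cur, sample_of_step,
        lif.V_th, lif.E_L, lif.V_reset, lif.tau_m, lif.C_m,
        int(round(lif.t_ref / lif.dt)), lif.dt,
        net.q_syn / lif.C_m, spike_n, spike_t,
    )
    spikes: list[list[float]] = [[] for _ in range(net.n_neurons)]
    for k in range(n_spk):
        spikes[spike_n[k]].append(float(spike_t[k]))
    return SpikeRecord(spikes=spikes, window_duration=float(duration))


def stdp_step(net: SNNetwork, record: SpikeRecord) -> SNNetwork:
    """Apply one window of nearest-neighbour pair STDP to the weights.

    Spikes are replayed in time order; each spike potentiates its incoming
    synapses against the presynaptic partner's latest spike and depresses
    its outgoing synapses against the postsynaptic partner's latest spike.
    Weights are clipped to [0, w_max]; synapses absent from the wiring mask
    are never created.
    """
    p = net.stdp
    if p.lambda_rate == 0:
        return net
    neuron_ids = []
    times = []
    for i, st in enumerate(record.spikes):
        neuron_ids.extend([i] * len(st))
        times.extend(st)
    if not times:
        return net
    order = np.lexsort((neuron_ids, times))
    neuron_ids = np.asarray(neuron_ids)[order]
    times = np.asarray(times)[order]
    n = net.n_neurons
    last = np.full(n, -np.inf)
    W = net.weights
    mask = net.mask
    a_plus = p.lambda_rate * p.w_max
    a_minus = p.asymmetry * p.lambda_rate * p.w_max
    for i, t in zip(neuron_ids, times):
        seen = np.isfinite(last)
        pre = mask[:, i] & seen
        if pre.any():
            W[pre, i] += a_plus * np.exp(-(t - last[pre]) / p.tau_plus)
        post = mask[i, :] & seen
        if post.any():
            W[i, post] -= a_minus * np.exp(-(t - last[post]) / p.tau_minus)
        last[i] = t
    np.clip(W, 0.0, p.w_max, out=W)
    return net


def spike_rate_features(record: SpikeRecord, selected) -> np.ndarray:
    """Spiking frequency (Hz) of the selected neurons over the window."""
    if record.window_duration <= 0:
        raise ValueError("window_duration must be positive")
    sec = record.window_duration / 1000.0
    return np.array([len(record.spikes[i]) for i in selected], dtype=float) / sec


def save_network(net: SNNetwork, path) -> None:
    """Snapshot as text: JSON header plus (row, col, weight) triplets."""
    rows, cols = np.nonzero(net.mask)
    header = {
        "n_neurons": int(net.n_neurons),
        "positions": net.positions.tolist(),
        "electrode_map": net.electrode_map.tolist(),
        "delay": net.delay,
        "q_syn": net.q_syn,
        "lif": vars(net.lif),
        "stdp": vars(net.stdp),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r} {c} {net.weights[r, c]:.17g}\n")


def load_network(path) -> SNNetwork:
    with open(path) as fh:
        header = json.loads(fh.readline())
        n = header["n_neurons"]
        weights = np.zeros((n, n))
        mask = np.zeros((n, n), dtype=bool)
        for line in fh:
            r, c, w = line.split()
            r, c = int(r), int(c)
            weights[r, c] = float(w)
            mask[r, c] = True
    return SNNetwork(
        positions=np.asarray(header["positions"], dtype=float),
        weights=weights,
        mask=mask,
        electrode_map=np.asarray(header["electrode_map"], dtype=np.int64),
        lif=LIFParams(**header["lif"]),
        stdp=STDPParams(**header["stdp"]),
        delay=header["delay"],
        q_syn=header["q_syn"],
    )


def read_positions_csv(path) -> np.ndarray:
    """Coordinate CSV: columns x,y,z in mm, one row per neuron."""
    import pandas as pd

    df = pd.read_csv(path)
    return df[["x", "y", "z"]].to_numpy(dtype=float)
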