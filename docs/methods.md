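# Methods

This note records the model the package implements, the defaults it ships
with and why, what the synthetic data can and cannot show, and the
numerical choices that affect reproducibility.

## Decoding model

The decoder consumes multichannel epidural ECoG (nominally 585.6 Hz) in
consecutive, non-overlapping 59-sample windows (≈ 100.75 ms) and emits one
decision per window: a movement state, optionally 3D target coordinates
per hand, and a binary satisfaction estimate. Three stages:

**1. Generating currents.** Either the raw trace shifted per channel so
its calibration minimum maps to zero (`shift`), or time-resolved band
power: the squared magnitude of a complex Morlet convolution at a
fundamental frequency f₀ (`morlet`). The standard bank is 10–150 Hz in
10 Hz steps. The Morlet carrier uses n_cycles = 7 (σ_t = n_cycles/2πf₀);
windows are reflection-padded to the wavelet half-length so the 59
retained samples carry no zero-edge bias. Band power is kept per sample
(not decimated per window) before current injection. Both routes are
exposed per window and, batched, per session; the two are numerically
identical (tested).

**2. Spiking network.** Leaky integrate-and-fire neurons,

    dV/dt = −(V − E_L)/τ_m + (I_syn + I_e)/C_m,

forward-Euler at dt = 0.1 ms, spike at V ≥ V_th, reset to V_reset for
t_ref. Neurons occupy 3D positions: the electrode sites plus filler
neurons on a jittered grid extending the electrode plane 10 mm inward — a
stand-in volumetric template when no individual brain scan is available
(a coordinate CSV can replace it). Wiring follows a distance-decay
small-world rule, w(i,j) = w₀·exp(−d_ij/σ_d) within d_cut, plus sparse
long-range links (probability p_long) at the cutoff strength. Synapses
deliver a delta charge `weight·q_syn` to the postsynaptic membrane after
a uniform 1 ms conduction delay. Every window, the wired synapses adapt
by additive nearest-neighbour pair STDP (potentiation
λ·w_max·exp(−Δt/τ₊), depression scaled by an asymmetry factor, clipped to
[0, w_max]); the synapse set itself never changes. The features passed
downstream are the spiking frequencies of the electrode-mapped neurons
over the window, `n_spikes / t_window`.

Feature-to-current mapping: features are z-scored per channel against a
calibration segment (the first 50 windows by default, then frozen), and
injected as `I = i_base + gain·z` pA at the electrode-mapped neurons,
piecewise-constant over each 1/fs interval. With the default LIF values
the rheobase is C_m(V_th−E_L)/τ_m = 125 pA; i_base = 126 pA puts the
median feature just above it (≈ 20 Hz in an isolated neuron) and
gain = 40 pA/z-unit spans silence to ≈ 140 Hz over ±3 z — the window is
short (≈ 0.1 s), so rates quantize in ≈ 10 Hz steps and the steep f–I
region is where they discriminate best.

**3. Echo state network.** Reservoir update

    R(t) = (1 − a)·R(t−1) + a·tanh(W_in·in(t) + W_res·R(t−1)),

with leaking rate a, W_in uniform in ±input_scale, and W_res holding
exactly ⌊sparsity·N²⌋ random weights rescaled to spectral radius ρ < 1
(echo-state property). Spike rates are scaled by 0.01 (Hz → order-one
units) before entering the reservoir. Each head reads out
out(t) = W_out·[R(t); in(t)], reservoir block first. Training is online:

- *Recursive least squares* per labelled window, shared inverse-correlation
  matrix P across a head's output rows, P₀ = I/ε with ε = 10⁻², forgetting
  1.0 — equivalent to batch ridge regression with penalty ε (tested to
  1e-6 after 200 pairs). State and satisfaction heads regress one-hot
  targets and decode by argmax (lowest index on ties); the trajectory head
  regresses raw coordinates with no argmax.
- *Satisfaction-gated reinforcement* on the state head: an eligibility
  trace E ← δE + (1−δ)·out⊗[R;in] integrates recent output/regressor
  products (the outer product is the only shape-consistent reading of the
  trace update), and W_out ← W_out − α(1−satisfaction)·E moves the readout
  away from the traced outputs on dissatisfaction and is exactly inert
  while satisfied. One reinforcement step per flagged window; α = 10⁻⁴,
  δ = 0.9 by default. The ground-truth satisfaction label is used when
  present, otherwise the decoded one.

Per-window update flags bind to rules as: flag 1 → reinforcement on the
state head; flag 2 → RLS on the state and trajectory heads; flag 3 → RLS
on the satisfaction head. The binding is configurable. The SNN adapts by
STDP on every window regardless of flags; membrane, synaptic-buffer and
reservoir state persist across windows (continuous adaptation), with an
explicit reset switch.

**Voting.** A bank runs one full decoder (own SNN and ESN) per Morlet
fundamental. Decisions combine per window: the plurality label wins when
its supporter count reaches the threshold; plurality ties and
under-threshold pluralities fall back to a configurable label (idle).
Threshold 1 is plain plurality, threshold = members is
unanimity-or-fallback. The threshold can be selected by exhaustive
balanced-accuracy maximization on validation data (ties toward the
smaller threshold). The default "chosen" member set is
{10, 30, 50, 70, 100, 110} Hz.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| window length | 59 samples | one decoder step at 585.6 Hz |
| V_th / E_L / V_reset | −65 / −70 / −70 mV | threshold 5 mV above a conventional resting potential |
| τ_m, C_m, t_ref | 10 ms, 250 pF, 0 ms | conventional cortical LIF values |
| dt | 0.1 ms | spike counts change ≤ 2% on halving (tested) |
| w₀, σ_d, d_cut, p_long | 1, 5 mm, 15 mm, 0.01 | decay length ≈ electrode pitch (4–4.5 mm); cutoff ≈ 3σ |
| q_syn | 0.05 pC | weak coupling (ΔV ≈ 0.2 mV/spike): recurrence modulates, input drives |
| STDP λ, τ±, asymmetry, w_max | 0.001, 20 ms, 1.05, 2w₀ | slow continuous adaptation; mild depression bias keeps weights bounded away from the ceiling |
| SNN size | 100 neurons | desk scale; electrode count sets the floor |
| ESN N, a, sparsity, ρ | 1000, 0.5, 0.5, 0.95 | desk-scale reservoir; larger N (e.g. 15,000) accepted via config |
| RLS ε, forgetting | 10⁻², 1.0 | weak ridge prior, no forgetting (order-invariant) |
| RL α, δ | 10⁻⁴, 0.9 | gentle correction; trace remembers ≈ 10 windows |

## Synthetic sessions

The generator emulates the *shape* of implanted-ECoG experiments — 32–64
channels, minutes-long sessions, one label per window, three task layouts
(2-state runner with satisfaction labels; 3-state with per-hand
trajectories; 5-state with satisfaction and all three update flags) — not
their biophysics. Per channel: 1/f ("pink") background noise (SD 20 µV)
plus a sinusoidal carrier (10 µV baseline) at the configured bands. While
a movement state is active, the carrier amplitude on that state's channel
group rises by √(1+effect_size), i.e. band power rises by the factor
(1+effect_size); the carrier is present in *every* state so only the
modulation, not mere carrier presence, is decodable. Movement states load
disjoint groups tiling one half of the array (spatial selectivity), the
state sequence is Markov with geometric dwell (mean 20 windows),
satisfaction labels are 1 flipped to 0 at a configurable rate, and
trajectory targets are smooth Lissajous arcs active only during the
matching hand state.

What passing tests on this data do **not** show: robustness to
non-stationarity, artifacts, cross-channel correlated noise, or broadband/
multi-band movement signatures. Two specific consequences are visible in
the reported numbers: the amplitude-shift route performs far better here
than on real recordings (the carrier amplitude is state-coded directly in
the raw trace), and bank members at carrier-free fundamentals contribute
only noise, so multi-frequency voting cannot beat the single informative
member on single-carrier sessions. Trajectory *content* is not encoded in
the signal at all — only which hand moves — so trajectory cosine
similarity measures plumbing, not attainable regression quality.

## Numerical choices

- Euler threshold crossings resolve at step granularity; spikes reset the
  membrane in the same step, so V never exceeds V_th at window
  boundaries. Refractoriness holds V at V_reset and drops arriving
  charge.
- The spectral-radius rescale uses an ARPACK largest-magnitude eigenvalue
  with a *fixed* start vector: runs must be bit-reproducible, and the
  default randomized start vector breaks that at the last ulp.
- Feature calibration statistics freeze after the calibration segment;
  a degenerate (constant) channel gets an SD floor of 10⁻⁹.
- EDF output picks the smallest record duration (0.5 s steps) making
  samples-per-record integral — 5 s at 585.6 Hz — and pads the final
  record with zeros; 16-bit quantization bounds the round-trip error at
  one step of the per-channel physical range.
- Degenerate voting (empty member set, out-of-range threshold) and
  metrics inputs (empty sequences, all-zero trajectory truth) raise or
  report missing rather than guessing.
- Problem sizes in the test suite and acceptance script (100-neuron SNN,
  1000-neuron reservoir, 5-minute sessions, 70/30 train/test split) are
  the package's desk-scale defaults; everything scales through config.

## Known limitations

- Delta-current synapses and uniform delays; no conductance synapses,
  no per-connection delay learning.
- The trace/variance behaviour of RLS with forgetting < 1 is implemented
  but not characterized here.
- Satisfaction decoding on synthetic sessions learns the label prior
  (satisfaction is not encoded in the signal); it exercises the
  machinery, not the science of error-related signals.
- Accuracy values on synthetic sessions are not comparable to values
  measured on patient recordings.
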