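import numpy as np
import pytest

from mcd.snn import (
    LIFParams,
    STDPParams,
    SpikeRecord,
    build_network,
    load_network,
    save_network,
    simulate_window,
    spike_rate_features,
    stdp_step,
    template_positions,
)

FS = 585.6


def _isolated_neuron(dt=0.1, **lif_kwargs):
    lif = LIFParams(dt=dt, **lif_kwargs)
    net = build_network(
        np.zeros((1, 3)), np.zeros((1, 3)), p_long=0.0, lif=lif
    )
    net.weights[:] = 0.0
    return net


class TestBuildNetwork:
    def test_zero_distance_gives_w0_both_directions(self):
        pos = np.zeros((2, 3))
        net = build_network(pos, pos[:1], w0=0.7, p_long=0.0)
        assert net.weights[0, 1] == pytest.approx(0.7)
        assert net.weights[1, 0] == pytest.approx(0.7)
        assert net.weights[0, 0] == 0.0  # no self-connections

    def test_exponential_distance_decay(self):
        d = 2.0
        pos = np.array([[0, 0, 0], [d, 0, 0], [2 * d, 0, 0]], float)
        net = build_network(pos, pos[:1], w0=1.0, sigma_d=3.0, d_cut=100.0, p_long=0.0)
        ratio = net.weights[0, 2] / net.weights[0, 1]
        assert ratio == pytest.approx(np.exp(-d / 3.0))

    def test_cutoff_removes_connection(self):
        pos = np.array([[0, 0, 0], [50.0, 0, 0]])
        net = build_network(pos, pos[:1], d_cut=10.0, p_long=0.0)
        assert net.weights[0, 1] == 0.0

    def test_long_range_links_at_cutoff_strength(self):
        pos = np.array([[0, 0, 0], [50.0, 0, 0]])
        net = build_network(pos, pos[:1], w0=1.0, sigma_d=5.0, d_cut=10.0, p_long=1.0)
        assert net.weights[0, 1] == pytest.approx(np.exp(-10.0 / 5.0))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 30, size=(40, 3))
        a = build_network(pos, pos[:4], p_long=0.2, seed=9)
        b = build_network(pos, pos[:4], p_long=0.2, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_empty_positions_rejected(self):
        with pytest.raises(ValueError):
            build_network(np.empty((0, 3)), np.zeros((1, 3)))

    def test_electrode_maps_to_nearest_neuron(self):
        pos = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], float)
        net = build_network(pos, np.array([[9.0, 0, 0]]), p_long=0.0)
        assert net.electrode_map[0] == 1

    def test_template_contains_electrodes_first(self):
        epos = np.array([[0, 0, 0], [4.5, 0, 0]], float)
        pos = template_positions(epos, 20, seed=1)
        assert pos.shape == (20, 3)
        np.testing.assert_allclose(pos[:2], epos)


class TestLIFDynamics:
    def test_subthreshold_current_never_spikes(self):
        net = _isolated_neuron()
        lif = net.lif
        i_rheo = lif.C_m * (lif.V_th - lif.E_L) / lif.tau_m  # 125 pA
        rec = simulate_window(net, np.full((1, 1), 0.95 * i_rheo), duration=1000.0)
        assert rec.counts()[0] == 0

    def test_zero_input_stays_at_rest(self):
        net = _isolated_neuron()
        rec = simulate_window(net, np.zeros((1, 59)), fs=FS)
        assert rec.counts()[0] == 0
        assert net.V[0] == pytest.approx(net.lif.E_L)

    def test_interspike_interval_matches_closed_form(self):
        net = _isolated_neuron(dt=0.01)
        lif = net.lif
        I = 180.0
        rec = simulate_window(net, np.full((1, 1), I), duration=400.0)
        isi = np.diff(rec.spikes[0])
        x = I * lif.tau_m / lif.C_m
        T = lif.tau_m * np.log(x / (x - (lif.V_th - lif.E_L)))
        assert abs(isi.mean() - T) / T < 0.01

    def test_refractory_period_enforced(self):
        net = _isolated_neuron(t_ref=5.0)
        rec = simulate_window(net, np.full((1, 1), 500.0), duration=300.0)
        assert rec.counts()[0] > 1
        assert np.diff(rec.spikes[0]).min() >= net.lif.t_ref

    def test_membrane_capped_at_threshold(self):
        net = _isolated_neuron()
        simulate_window(net, np.full((1, 1), 400.0), duration=200.0)
        assert net.V[0] <= net.lif.V_th

    def test_state_persists_across_windows(self):
        """A current split over two consecutive windows charges the membrane
        exactly as the same current in one double-length window."""
        net_a = _isolated_neuron()
        simulate_window(net_a, np.full((1, 1), 100.0), duration=30.0)
        v_mid = net_a.V[0]
        simulate_window(net_a, np.full((1, 1), 100.0), duration=30.0)
        net_b = _isolated_neuron()
        simulate_window(net_b, np.full((1, 1), 100.0), duration=60.0)
        assert net_a.V[0] == pytest.approx(net_b.V[0], abs=1e-12)
        assert v_mid != pytest.approx(net_b.V[0])

    def test_zero_weights_neurons_are_independent(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 20, size=(6, 3))
        currents = rng.uniform(100, 220, size=(6, 59))
        coupled = build_network(pos, pos, p_long=0.0, seed=1)
        coupled.weights[:] = 0.0
        rec_c = simulate_window(coupled, currents, fs=FS)
        for i in range(6):
            alone = _isolated_neuron()
            rec_i = simulate_window(alone, currents[i:i + 1], fs=FS)
            assert rec_c.spikes[i] == rec_i.spikes[0]

    def test_integration_converges_in_dt(self):
        """Halving dt changes the total spike count of a 50-neuron driven
        network by at most 2%."""
        rng = np.random.default_rng(8)
        pos = rng.uniform(0, 25, size=(50, 3))
        currents = rng.uniform(80, 250, size=(50, 59))
        counts = {}
        for dt in (0.1, 0.05):
            net = build_network(pos, pos, p_long=0.01, seed=3,
                                lif=LIFParams(dt=dt))
            rec = simulate_window(net, currents, fs=FS)
            counts[dt] = rec.counts().sum()
        assert counts[0.1] > 50
        assert abs(counts[0.1] - counts[0.05]) / counts[0.05] <= 0.02

    def test_channel_count_mismatch(self):
        net = _isolated_neuron()
        with pytest.raises(ValueError):
            simulate_window(net, np.zeros((2, 59)))

    def test_synaptic_drive_excites_postsynaptic_neuron(self):
        pos = np.zeros((2, 3))
        net = build_network(pos, pos[:1], w0=1.0, p_long=0.0, q_syn=600.0)
        rec = simulate_window(net, np.full((1, 1), 300.0), duration=500.0)
        assert rec.counts()[0] > 0
        # neuron 1 receives only synaptic charge, and enough of it to fire
        assert rec.counts()[1] > 0
        # delayed by the conduction delay
        assert rec.spikes[1][0] >= rec.spikes[0][0] + net.delay


class TestSTDP:
    def _pair_net(self, w=0.5):
        pos = np.array([[0, 0, 0], [1.0, 0, 0]])
        net = build_network(pos, pos[:1], w0=1.0, sigma_d=5.0, p_long=0.0)
        net.weights[:] = 0.0
        net.mask[:] = False
        net.weights[0, 1] = w
        net.mask[0, 1] = True
        return net

    def test_no_spikes_no_change(self):
        net = self._pair_net()
        before = net.weights.copy()
        stdp_step(net, SpikeRecord(spikes=[[], []], window_duration=100.0))
        np.testing.assert_array_equal(net.weights, before)

    def test_pre_before_post_potentiates_exactly(self):
        net = self._pair_net(w=0.5)
        p = net.stdp
        stdp_step(net, SpikeRecord(spikes=[[10.0], [15.0]], window_duration=100.0))
        expected = 0.5 + p.lambda_rate * p.w_max * np.exp(-5.0 / p.tau_plus)
        assert net.weights[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_post_before_pre_depresses(self):
        net = self._pair_net(w=0.5)
        stdp_step(net, SpikeRecord(spikes=[[15.0], [10.0]], window_duration=100.0))
        assert net.weights[0, 1] < 0.5

    def test_depression_magnitude_and_asymmetry(self):
        net = self._pair_net(w=0.5)
        p = net.stdp
        stdp_step(net, SpikeRecord(spikes=[[15.0], [10.0]], window_duration=100.0))
        expected = 0.5 - p.asymmetry * p.lambda_rate * p.w_max * np.exp(-5.0 / p.tau_minus)
        assert net.weights[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_synapse_stays_clipped_at_zero(self):
        net = self._pair_net(w=0.0)
        stdp_step(net, SpikeRecord(spikes=[[15.0], [10.0]], window_duration=100.0))
        assert net.weights[0, 1] == 0.0

    def test_weights_bounded_over_random_windows(self, rng):
        pos = rng.uniform(0, 20, size=(12, 3))
        net = build_network(pos, pos[:3], p_long=0.05, seed=2,
                            stdp=STDPParams(lambda_rate=0.05))
        for _ in range(200):
            spikes = [
                sorted(rng.uniform(0, 100, size=rng.integers(0, 5)).tolist())
                for _ in range(12)
            ]
            stdp_step(net, SpikeRecord(spikes=spikes, window_duration=100.0))
            assert (net.weights >= 0).all()
            assert (net.weights <= net.stdp.w_max).all()
        # topology never grows
        assert not net.weights[~net.mask].any()


class TestSpikeRates:
    def test_zero_spikes_zero_rate(self):
        rec = SpikeRecord(spikes=[[]], window_duration=100.8)
        assert spike_rate_features(rec, [0])[0] == 0.0

    def test_ten_spikes_in_decoder_window(self):
        rec = SpikeRecord(spikes=[list(np.linspace(1, 99, 10))], window_duration=100.8)
        assert spike_rate_features(rec, [0])[0] == pytest.approx(99.21, abs=0.01)

    def test_rate_halves_with_doubled_duration(self):
        spikes = [list(np.linspace(1, 99, 10))]
        r1 = spike_rate_features(SpikeRecord(spikes, 100.8), [0])[0]
        r2 = spike_rate_features(SpikeRecord(spikes, 201.6), [0])[0]
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            spike_rate_features(SpikeRecord([[]], 0.0), [0])


def test_snapshot_round_trip(tmp_path, rng):
    pos = rng.uniform(0, 20, size=(10, 3))
    net = build_network(pos, pos[:2], p_long=0.1, seed=4)
    path = tmp_path / "net.txt"
    save_network(net, path)
    back = load_network(path)
    np.testing.assert_allclose(back.weights, net.weights)
    np.testing.assert_array_equal(back.mask, net.mask)
    np.testing.assert_array_equal(back.electrode_map, net.electrode_map)
    assert back.lif == net.lif
    assert back.stdp == net.stdp
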