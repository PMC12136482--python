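"""Spiking network: construction, spike detection, synapses, decoupling."""

import numpy as np
import pytest

from hybridbrain import (CellParams, NetworkConfig, SynapseParams,
                         build_network, detect_spikes, simulate_cell,
                         simulate_network)


def make_config(**kw):
    defaults = dict(N=5, f=0.2, K_bath_healthy=9.5, K_bath_path=17.0,
                    synapse=SynapseParams(), connectivity="all_to_all")
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestBuildNetwork:
    def test_five_cell_mixture_and_edge_count(self):
        net = build_network(make_config(N=5, f=0.2))
        assert net.healthy_mask.sum() == 1
        assert (~net.healthy_mask).sum() == 4
        assert len(net.edges()) == 20  # N(N-1) directed, no self loops
        assert all(i != j for i, j in net.edges())

    def test_no_connectivity_means_no_edges(self):
        net = build_network(make_config(connectivity="none"))
        assert net.edges() == []

    def test_hundred_cell_eighty_twenty_split(self):
        net = build_network(make_config(N=100, f=0.8))
        assert net.healthy_mask.sum() == 80
        assert (~net.healthy_mask).sum() == 20
        baths = [p.K_bath for p in net.cell_params]
        assert set(baths[:80]) == {9.5}
        assert set(baths[80:]) == {17.0}

    def test_rounding_half_up(self):
        assert build_network(make_config(N=5, f=0.5)).healthy_mask.sum() == 3
        assert build_network(make_config(N=4, f=0.375)).healthy_mask.sum() == 2

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_config(f=1.5)


class TestDetectSpikes:
    def test_subthreshold_trace_empty(self):
        t = np.arange(0, 100.0, 0.1)
        assert len(detect_spikes(t, np.full_like(t, -60.0))) == 0

    def test_single_triangular_pulse(self):
        t = np.arange(0, 10.0, 0.1)
        V = np.full_like(t, -70.0)
        V[40:61] = -70.0 + 50.0 * (1 - np.abs(np.arange(-10, 11)) / 10.0)
        spikes = detect_spikes(t, V, -25.0)
        assert len(spikes) == 1
        assert 4.0 <= spikes[0] <= 6.0

    def test_sinusoid_crossing_count(self):
        # 10 Hz sinusoid around -40 mV crossing -25 once per cycle
        t = np.arange(0, 1000.0, 0.05)
        V = -40.0 + 20.0 * np.sin(2 * np.pi * t / 100.0)
        assert len(detect_spikes(t, V, -25.0)) == 10

    def test_rearm_requires_return_below_threshold(self):
        t = np.arange(0, 5.0, 0.1)
        V = np.full_like(t, -20.0)  # starts above threshold, never re-arms
        V[0] = -60.0
        assert len(detect_spikes(t, V, -25.0)) == 1


class TestSimulateNetwork:
    def test_unconnected_network_matches_isolated_cells_bitwise(self):
        cfg = make_config(N=3, f=0.34, connectivity="none")
        net = build_network(cfg)
        res = simulate_network(net, T=500.0, dt=0.0125, record_every=1)
        for i, p in enumerate(net.cell_params):
            tr = simulate_cell(p, T=500.0, dt=0.0125)
            np.testing.assert_array_equal(res.V[:, i], tr.V)

    def test_zero_weight_equals_unconnected(self):
        syn0 = SynapseParams(weight=0.0)
        a = simulate_network(build_network(make_config(N=4, synapse=syn0)),
                             T=300.0, dt=0.0125)
        b = simulate_network(build_network(make_config(N=4, connectivity="none")),
                             T=300.0, dt=0.0125)
        np.testing.assert_array_equal(a.V, b.V)

    def test_epsp_scales_linearly_at_small_weight(self):
        """Passive response to one event: peak ~ w, decay tau_syn."""
        from dataclasses import replace

        passive = replace(CellParams(), g0_Na=0.0, gl_Na=0.0, gamma_ion=0.0, epsilon=0.0)
        cfg = make_config(N=1, f=1.0, K_bath_healthy=4.0, connectivity="none",
                          cell_params=passive)
        net = build_network(cfg)

        def run(g):
            return simulate_network(net, T=80.0, dt=0.0125,
                                    external_events=[(20.0, 0, g)])

        base = simulate_network(net, T=80.0, dt=0.0125)
        r1 = run(0.001)
        r2 = run(0.002)
        d1 = r1.V[:, 0] - base.V[:, 0]
        d2 = r2.V[:, 0] - base.V[:, 0]
        assert d1.max() > 0.005  # visible EPSP
        assert d2.max() == pytest.approx(2 * d1.max(), rel=0.02)
        # decay time constant of the EPSP tail ~ tau_syn
        t = r1.t
        peak = np.argmax(d1)
        tail = d1[peak:]
        tt = t[peak:] - t[peak]
        m = (tail > 0.05 * tail.max()) & (tt < 10.0)
        slope = np.polyfit(tt[m], np.log(tail[m]), 1)[0]
        tau_eff = -1.0 / slope
        assert tau_eff == pytest.approx(cfg.synapse.tau_syn, rel=0.35)

    def test_label_permutation_equivariance(self):
        # permuting cell identities permutes outputs identically
        cfgA = make_config(N=4, f=0.5, connectivity="all_to_all")
        resA = simulate_network(build_network(cfgA), T=400.0, dt=0.0125)
        # same mixture with healthy/pathological labels swapped in blocks:
        # cells are identical up to relabeling {0,1}<->{2,3}
        cfgB = make_config(N=4, f=0.5, K_bath_healthy=17.0, K_bath_path=9.5)
        resB = simulate_network(build_network(cfgB), T=400.0, dt=0.0125)
        perm = [2, 3, 0, 1]
        np.testing.assert_array_equal(resB.V[:, perm], resA.V)

    def test_synaptic_conductance_nonnegative_effect(self):
        # on a purely passive (linear RC) cell, excitatory events with
        # e_rev = 0 can only depolarize: the synaptic conductance never
        # goes negative
        from dataclasses import replace

        passive = replace(CellParams(), g0_Na=0.0, gl_Na=0.0, g0_K=0.0,
                          gamma_ion=0.0, epsilon=0.0)
        cfg = make_config(N=1, f=1.0, K_bath_healthy=4.0, connectivity="none",
                          cell_params=passive)
        net = build_network(cfg)
        quiet = simulate_network(net, T=100.0, dt=0.0125)
        driven = simulate_network(net, T=100.0, dt=0.0125,
                                  external_events=[(30.0, 0, 0.02)])
        diff = driven.V[:, 0] - quiet.V[:, 0]
        assert diff.min() > -1e-9

    def test_event_beyond_T_warns_and_is_dropped(self):
        net = build_network(make_config(N=2, connectivity="none"))
        with pytest.warns(UserWarning, match="dropped"):
            simulate_network(net, T=50.0, dt=0.0125,
                             external_events=[(80.0, 0, 0.1)])

    def test_raster_times_sorted_and_within_range(self):
        cfg = make_config(N=10, f=0.5)
        res = simulate_network(build_network(cfg), T=2000.0, dt=0.0125,
                               record_every=8)
        assert np.all(np.diff(res.raster.times) >= 0)
        if len(res.raster):
            assert res.raster.times.min() >= 0
            assert res.raster.times.max() <= 2000.0
        for gid in range(10):
            per_cell = res.raster.for_cell(gid)
            assert np.all(np.diff(per_cell) > 0)

    def test_chunked_segments_equal_monolithic(self):
        # a no-op switch at 150 ms must not change the arithmetic
        cfg = make_config(N=3, f=0.4)
        mono = simulate_network(build_network(cfg), T=300.0, dt=0.0125)
        chun = simulate_network(build_network(cfg), T=300.0, dt=0.0125,
                                switch_schedule=[(150.0, True)])
        np.testing.assert_array_equal(mono.V, chun.V)
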