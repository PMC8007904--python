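"""Circuit construction, ground-truth labels, and simulation dynamics."""

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pytest

from spiketree import netsim as ns


def small_params(**kw):
    defaults = dict(
        n_subcircuits=1, n_exc_per_sub=3, n_inh_per_sub=1, m_out=1, duration=1.0, seed=0
    )
    defaults.update(kw)
    return ns.CircuitParams(**defaults)


class TestCircuitParams:
    def test_ratio_and_bounds_are_enforced(self):
        with pytest.raises(ValueError, match="3:1"):
            ns.CircuitParams(n_exc_per_sub=30, n_inh_per_sub=5)
        with pytest.raises(ValueError, match="m_out"):
            small_params(m_out=0)
        with pytest.raises(ValueError, match="delays"):
            ns.CircuitParams(exc_delay_range=(1, 7))
        with pytest.raises(ValueError, match="duration"):
            ns.CircuitParams(duration=0)


class TestBuildCircuit:
    def test_default_circuit_shape(self):
        c = ns.build_circuit(ns.CircuitParams(seed=3), rng_seed=3)
        assert len(c.neurons) == 80
        assert len(c.synapses) == 400
        sub = {n.id: n.subcircuit for n in c.neurons}
        assert all(sub[s.pre] == sub[s.post] for s in c.synapses)

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_structural_invariants(self, seed):
        p = ns.CircuitParams(seed=seed)
        c = ns.build_circuit(p, rng_seed=seed)
        kind = {n.id: n.kind for n in c.neurons}
        out_deg = {}
        for s in c.synapses:
            out_deg[s.pre] = out_deg.get(s.pre, 0) + 1
            assert s.pre != s.post
            if kind[s.pre] == "inhibitory":
                assert kind[s.post] == "excitatory"
                assert s.delay == p.inh_delay
                assert s.weight == p.inh_weight
            else:
                assert p.exc_delay_range[0] <= s.delay <= p.exc_delay_range[1]
                assert 0 <= s.weight <= p.s_max
        assert all(out_deg[n.id] == p.m_out for n in c.neurons)
        tgt = c.neuron(c.target)
        assert tgt.kind == "excitatory" and tgt.subcircuit == 0

    def test_smallest_legal_circuit(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny circuit cannot reach 4 inputs
            c = ns.build_circuit(small_params(), rng_seed=0)
        assert len(c.neurons) == 4
        assert len(c.synapses) == 4
        kind = {n.id: n.kind for n in c.neurons}
        (inh_edge,) = [s for s in c.synapses if kind[s.pre] == "inhibitory"]
        assert kind[inh_edge.post] == "excitatory"

    def test_same_seed_reproduces_synapse_list(self):
        p = ns.CircuitParams(seed=11)
        assert ns.build_circuit(p, 11).synapses == ns.build_circuit(p, 11).synapses

    def test_m_out_exceeding_candidates_is_rejected(self):
        # 4 neurons -> an excitatory neuron has only 3 eligible partners
        with pytest.raises(ValueError, match="eligible"):
            ns.build_circuit(small_params(m_out=4), rng_seed=0)


class TestGroundTruth:
    def test_chain_path_lengths(self):
        # hand-built chain A -> B -> target plus padding to keep m_out honest
        p = small_params()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = ns.build_circuit(p, rng_seed=0)
        target = c.target
        others = [n.id for n in c.neurons if n.id != target and n.kind == "excitatory"]
        a, b = others[0], others[1]
        c.synapses = [
            ns.Synapse(a, b, 1.0, 1),
            ns.Synapse(b, target, 1.0, 1),
        ]
        labels = ns.ground_truth(c)
        assert labels[b] == "monosynaptic"
        assert labels[a] == "disynaptic"
        assert labels[target] == "target"

    def test_second_subcircuit_is_disconnected(self):
        c = ns.build_circuit(ns.CircuitParams(seed=5), rng_seed=5)
        labels = ns.ground_truth(c)
        sub1 = [n.id for n in c.neurons if n.subcircuit == 1]
        assert all(labels[u] == "disconnected" for u in sub1)

    @pytest.mark.parametrize("seed", [2, 9])
    def test_labels_match_networkx_bfs_oracle(self, seed):
        c = ns.build_circuit(ns.CircuitParams(seed=seed), rng_seed=seed)
        g = nx.DiGraph()
        g.add_nodes_from(c.unit_ids)
        g.add_edges_from((s.post, s.pre) for s in c.synapses)  # reversed
        dist = nx.single_source_shortest_path_length(g, c.target)
        expect = {0: "target", 1: "monosynaptic", 2: "disynaptic", 3: "trisynaptic"}
        labels = ns.ground_truth(c)
        for u in c.unit_ids:
            if u not in dist:
                assert labels[u] == "disconnected"
            else:
                assert labels[u] == expect.get(dist[u], "other_connected")


class TestUncertaintyLevels:
    def test_recipient_sets(self):
        c = ns.build_circuit(ns.CircuitParams(seed=4), rng_seed=4)
        all_ids = set(c.unit_ids)
        presyn = set(c.presynaptic(c.target))
        high = ns.uncertainty_level(c, "high").input_recipients
        med = ns.uncertainty_level(c, "medium").input_recipients
        low = ns.uncertainty_level(c, "low").input_recipients
        assert high == all_ids
        assert med == all_ids - {c.target}
        assert low == all_ids - {c.target} - presyn
        with pytest.raises(ValueError, match="unknown uncertainty"):
            ns.uncertainty_level(c, "extreme")


class TestSimulate:
    def test_silent_network_produces_no_spikes(self):
        c = ns.build_circuit(ns.CircuitParams(seed=0, duration=2.0), rng_seed=0)
        c.synapses = [dataclasses.replace(s, weight=0.0) for s in c.synapses]
        level = ns.UncertaintyLevel("low", frozenset())
        spikes = ns.simulate(c, level, rng_seed=0)
        assert all(t.size == 0 for t in spikes.trains.values())

    def test_bitwise_determinism(self):
        p = ns.CircuitParams(seed=6, duration=5.0)
        c = ns.build_circuit(p, 6)
        level = ns.uncertainty_level(c, "high")
        a = ns.simulate(c, level, p, rng_seed=6)
        b = ns.simulate(c, level, p, rng_seed=6)
        for u in a.units:
            np.testing.assert_array_equal(a.trains[u], b.trains[u])

    def test_two_input_coincidence_requirement(self):
        # a single maximal-strength input must not fire a resting cell,
        # two simultaneous ones must — for every calibratable s_max
        for s_max in (10.0, 12.0, 14.0, 16.0):
            assert not ns.single_pulse_fires(s_max, 1)
            assert ns.single_pulse_fires(s_max, 2)
        assert ns.single_pulse_fires(40.0, 1)  # sanity: strong drive does fire

    def test_stdp_keeps_excitatory_weights_bounded(self):
        p = ns.CircuitParams(seed=8, duration=20.0, s_max=12.0)
        c = ns.build_circuit(p, 8)
        n, m = len(c.neurons), p.m_out
        is_exc = np.array([nr.kind == "excitatory" for nr in c.neurons])
        post = np.zeros((n, m), np.int32)
        delay = np.zeros((n, m), np.int32)
        s = np.zeros((n, m))
        fill = np.zeros(n, np.int64)
        for syn in c.synapses:
            i = c.index(syn.pre)
            post[i, fill[i]], delay[i, fill[i]], s[i, fill[i]] = (
                c.index(syn.post), syn.delay, syn.weight,
            )
            fill[i] += 1
        recipients = np.arange(n, dtype=np.int64)
        ns._run_network(20_000, is_exc, post, delay, s, p.s_max, recipients,
                        1.0, p.input_strength, 8, 500_000)
        assert np.all(s[is_exc] >= 0.0) and np.all(s[is_exc] <= p.s_max)
        assert np.all(s[~is_exc] == p.inh_weight)

    def test_calibrated_target_rate_in_band(self, low80):
        rate = low80.spikes.rate(low80.circuit.target)
        assert 0.5 <= rate <= 3.0


class TestExportSubset:
    def test_restriction_and_identity(self, low80):
        sub = ns.export_subset(low80.spikes, ["U1", "U5", "U60"])
        assert sub.units == ["U1", "U5", "U60"]
        assert sub.duration == low80.spikes.duration
        ident = ns.export_subset(low80.spikes, low80.spikes.units)
        assert ident.units == low80.spikes.units
        twice = ns.export_subset(ns.export_subset(low80.spikes, ["U1", "U5"]), ["U5"])
        np.testing.assert_array_equal(twice.trains["U5"], low80.spikes.trains["U5"])

    def test_unknown_unit_is_named(self, low80):
        with pytest.raises(KeyError, match="U999"):
            ns.export_subset(low80.spikes, ["U1", "U999"])

    def test_reduced_panel_is_deterministic_and_typed(self, low80):
        panel = ns.reduced_panel(low80.circuit)
        assert len(panel) == 13
        assert panel == ns.reduced_panel(low80.circuit)
        assert set(panel) >= low80.mono
        kinds = {low80.circuit.neuron(u).kind for u in panel}
        assert kinds == {"excitatory"}


class TestDisconnectionProperty:
    def test_parallel_circuit_has_no_correlogram_peak(self, low80):
        """Sub-1 units show no cross-correlogram peak vs the target beyond a
        uniform-surrogate null at alpha=0.01 (lags 1..50 ms)."""
        from spiketree.evaluation import crosscorrelogram

        rng = np.random.default_rng(0)
        target_train = low80.spikes.trains[low80.circuit.target][:300]
        sub1 = [n.id for n in low80.circuit.neurons if n.subcircuit == 1][:3]
        for u in sub1:
            other = low80.spikes.trains[u]
            centers, counts = crosscorrelogram(target_train, other, 1.0, 50.0)
            obs = counts[(centers > 0)].max()  # positive lags 1..50 ms
            null_max = []
            for _ in range(300):
                surrogate = np.sort(
                    rng.uniform(0, low80.spikes.duration, size=other.size)
                )
                _, cnt = crosscorrelogram(target_train, surrogate, 1.0, 50.0)
                null_max.append(cnt[(centers > 0)].max())
            # alpha = 0.01, Bonferroni across the 3 tested units
            assert obs <= np.quantile(null_max, 1 - 0.01 / 3)
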