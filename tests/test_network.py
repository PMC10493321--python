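"""Surrogate pruning and brain-graph structural metrics."""

import itertools

import networkx as nx
import numpy as np
import pytest

import tfpf
from tfpf.network import (count_cycles, count_triangles, phase_randomize,
                          prune_graph, surrogate_ensembles, surrogate_null)

FS = 160.0
BAND = (8.0, 30.0)


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved_exactly(self, rng):
        x = rng.standard_normal(320)
        s = phase_randomize(x, rng)
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)),
                                   np.abs(np.fft.rfft(x)), atol=1e-8)

    def test_mean_preserved(self, rng):
        x = rng.standard_normal(321) + 5.0
        s = phase_randomize(x, rng)
        assert s.mean() == pytest.approx(x.mean(), abs=1e-8)

    def test_output_is_real_and_different(self, rng):
        x = rng.standard_normal(320)
        s = phase_randomize(x, rng)
        assert np.isrealobj(s)
        assert not np.allclose(s, x)

    def test_autocorrelation_preserved_on_average(self, rng):
        # Wiener-Khinchin: same power spectrum -> same autocorrelation
        x = tfpf.bandpass(tfpf.EEGTrial(data=rng.standard_normal((1, 640)),
                                        fs=FS)).data[0]

        def acf(v, lags=20):
            v = v - v.mean()
            full = np.correlate(v, v, "full")[len(v) - 1:len(v) - 1 + lags]
            return full / full[0]

        draws = np.mean([acf(phase_randomize(x, rng)) for _ in range(100)], axis=0)
        np.testing.assert_allclose(draws, acf(x), atol=0.1)

    def test_too_short_or_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            phase_randomize(np.ones(3), rng)
        with pytest.raises(ValueError, match="finite"):
            phase_randomize(np.array([1.0, np.nan, 2.0, 3.0]), rng)


def _coupled_segment(kappa=1000.0, seed=0, n_channels=2, duration=2.0):
    spec = tfpf.SimulationSpec(
        n_channels=n_channels, fs=FS, duration=duration,
        coupled_pairs=((0, 1, 12.0, kappa, 0.0),), noise_sd=0.3, seed=seed)
    return tfpf.bandpass(tfpf.simulate(spec)).data


class TestSurrogateNull:
    def test_strong_coupling_beats_every_null(self):
        seg = _coupled_segment(kappa=1000.0)
        ens = surrogate_null(seg, (0, 1), "PLV", FS, BAND, n_surrogates=200, seed=1)
        assert ens.observed > ens.null_values.max()
        assert ens.p_value == pytest.approx(1 / 201, abs=1e-12)

    def test_uncoupled_pair_falls_inside_null(self, rng):
        inside = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            seg = r.standard_normal((2, 320))
            ens = surrogate_null(seg, (0, 1), "PCC", FS, BAND,
                                 n_surrogates=60, seed=seed)
            inside += ens.p_value > 0.05
        assert inside >= 33  # ~95% of calibrated nulls, binomial slack

    def test_single_surrogate_ensemble(self):
        seg = _coupled_segment()
        ens = surrogate_null(seg, (0, 1), "PCC", FS, BAND, n_surrogates=1, seed=0)
        assert ens.n_surrogates == 1

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            surrogate_null(_coupled_segment(), (0, 0), "PCC", FS)


class TestPruneGraph:
    def _graph_from(self, seg, feature="PLV", alpha=0.05, n_surrogates=200,
                    seed=0, **kw):
        matrix = tfpf.connectivity_matrix(seg, FS, BAND, feature)
        ens = surrogate_ensembles(seg, feature, FS, BAND,
                                  n_surrogates=n_surrogates, seed=seed)
        return prune_graph(matrix, ens, alpha=alpha, **kw)

    def test_coupled_edge_survives_uncoupled_mostly_removed(self):
        seg = _coupled_segment(n_channels=4)
        g = self._graph_from(seg, n_surrogates=100)
        assert g.graph.has_edge(0, 1)

    def test_alpha_zero_empty_graph(self):
        seg = _coupled_segment(n_channels=3)
        g = self._graph_from(seg, alpha=0.0, n_surrogates=50)
        assert g.n_edges == 0

    def test_pruning_monotone_in_alpha(self):
        seg = _coupled_segment(n_channels=4, seed=3)
        g1 = self._graph_from(seg, alpha=0.01, n_surrogates=100)
        g2 = self._graph_from(seg, alpha=0.2, n_surrogates=100)
        assert set(g1.graph.edges) <= set(g2.graph.edges)

    def test_missing_ensemble_rejected(self):
        seg = _coupled_segment(n_channels=3)
        matrix = tfpf.connectivity_matrix(seg, FS, BAND, "PCC")
        with pytest.raises(ValueError, match="missing"):
            prune_graph(matrix, {}, alpha=0.05)

    def test_null_edge_survival_rate_calibrated(self):
        # uncoupled white noise: the fraction of edges surviving at alpha
        # must not exceed alpha by more than binomial fluctuation
        rng = np.random.default_rng(0)
        n_edges, survived = 500, 0
        for e in range(n_edges):
            seg = rng.standard_normal((2, 320))
            ens = surrogate_null(seg, (0, 1), "PCC", FS, BAND,
                                 n_surrogates=200, seed=e)
            survived += ens.p_value <= 0.05
        rate = survived / n_edges
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_edges)


class TestGraphMetrics:
    def _random_graph(self, seed, n=10, p=0.35):
        return nx.gnp_random_graph(n, p, seed=seed)

    def test_complete_graph_triangles(self):
        assert count_triangles(nx.complete_graph(4)) == 4

    def test_tree_has_no_triangles(self):
        assert count_triangles(nx.random_labeled_tree(12, seed=1)) == 0

    def test_triangles_match_exhaustive_enumeration(self):
        for seed in range(50):
            g = self._random_graph(seed)
            brute = sum(
                1 for trio in itertools.combinations(g.nodes, 3)
                if g.has_edge(trio[0], trio[1]) and g.has_edge(trio[1], trio[2])
                and g.has_edge(trio[0], trio[2])
            )
            assert count_triangles(g) == brute

    def test_square_and_triangle_cycle_counts(self):
        assert count_cycles(nx.cycle_graph(4)) == {3: 0, 4: 1}
        assert count_cycles(nx.cycle_graph(3), max_len=3) == {3: 1}

    def test_cycle_length3_equals_triangle_count(self):
        for seed in range(50):
            g = self._random_graph(seed)
            assert count_cycles(g, max_len=4)[3] == count_triangles(g)

    def test_max_len_below_three_rejected(self):
        with pytest.raises(ValueError, match="max_len"):
            count_cycles(nx.cycle_graph(4), max_len=2)


def _brain_graph(edges, nodes=range(6)):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, p_value=0.01)
    return tfpf.BrainGraph(graph=g, feature_kind="PLV", alpha=0.05)


class TestCompareGraphs:
    def test_self_comparison_all_zero(self):
        g = _brain_graph([(0, 1, 0.9), (1, 2, 0.8), (0, 2, 0.7)])
        diff = tfpf.compare_subject_graphs(g, g)["difference"]
        assert diff["n_edges"] == 0 and diff["triangles"] == 0
        assert diff["total_weight"] == pytest.approx(0.0)
        assert all(v == 0 for v in diff["node_strength"].values())

    def test_supergraph_dominates_subgraph(self):
        sub = _brain_graph([(0, 1, 0.9), (1, 2, 0.8)])
        sup = _brain_graph([(0, 1, 0.9), (1, 2, 0.8), (0, 2, 0.7), (3, 4, 0.5)])
        diff = tfpf.compare_subject_graphs(sup, sub)["difference"]
        assert diff["n_edges"] >= 0 and diff["triangles"] >= 0
        assert diff["total_weight"] >= 0
        assert all(v >= 0 for v in diff["cycles"].values())

    def test_node_set_mismatch_rejected(self):
        a = _brain_graph([(0, 1, 0.5)], nodes=range(3))
        b = _brain_graph([(0, 1, 0.5)], nodes=range(4))
        with pytest.raises(ValueError, match="node set"):
            tfpf.compare_subject_graphs(a, b)

    def test_strongly_coupled_subject_has_more_triangles(self):
        # strong subject: three mutually coupled channels; weak subject: none
        wins = 0
        for seed in range(20):
            pairs_strong = ((0, 1, 12.0, 1000.0, 0.6), (1, 2, 12.0, 1000.0, 0.6),
                            (0, 2, 12.0, 1000.0, 0.6))
            # 8-s recordings: each channel superposes two carriers, so the
            # per-pair PLV needs a longer window to separate from the null
            strong_spec = tfpf.SimulationSpec(
                n_channels=4, fs=FS, duration=8.0, coupled_pairs=pairs_strong,
                noise_sd=0.5, seed=seed)
            weak_spec = tfpf.SimulationSpec(
                n_channels=4, fs=FS, duration=8.0, coupled_pairs=(),
                noise_sd=0.5, seed=seed + 100)
            graphs = []
            for spec in (strong_spec, weak_spec):
                seg = tfpf.bandpass(tfpf.simulate(spec)).data
                m = tfpf.connectivity_matrix(seg, FS, BAND, "PLV")
                ens = surrogate_ensembles(seg, "PLV", FS, BAND,
                                          n_surrogates=60, seed=seed)
                graphs.append(prune_graph(m, ens, alpha=0.05))
            wins += count_triangles(graphs[0]) > count_triangles(graphs[1])
        assert wins >= 18  # >= 90% of runs
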