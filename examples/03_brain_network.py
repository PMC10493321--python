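"""Surrogate-pruned brain graphs: a strongly vs. a weakly connected subject.

The "strong subject" has three mutually phase-locked channels (a genuine
triangle); the "weak subject" has no coupling at all.  For each, every
channel pair's PLV is tested against 100 phase-randomized surrogates and
only significant edges (empirical p <= 0.05) are kept.  Triangle and
cycle counts then quantify how much stable structure survives.
"""

import tfpf
from tfpf.network import count_cycles, count_triangles, prune_graph, surrogate_ensembles

FS, BAND = 160.0, (8.0, 30.0)

triangle = ((0, 1, 12.0, 1000.0, 0.6), (1, 2, 12.0, 1000.0, 0.6),
            (0, 2, 12.0, 1000.0, 0.6))
specs = {
    "strong": tfpf.SimulationSpec(n_channels=5, fs=FS, duration=8.0,
                                  coupled_pairs=triangle, noise_sd=0.5, seed=1),
    "weak": tfpf.SimulationSpec(n_channels=5, fs=FS, duration=8.0,
                                coupled_pairs=(), noise_sd=0.5, seed=2),
}

graphs = {}
for name, spec in specs.items():
    seg = tfpf.bandpass(tfpf.simulate(spec)).data
    matrix = tfpf.connectivity_matrix(seg, FS, BAND, "PLV")
    ensembles = surrogate_ensembles(seg, "PLV", FS, BAND, n_surrogates=100, seed=3)
    graphs[name] = prune_graph(matrix, ensembles, alpha=0.05)
    g = graphs[name]
    print(f"{name} subject: {g.n_edges} significant edges, "
          f"total weight {g.total_weight:.2f}, "
          f"{count_triangles(g)} triangles, cycles {count_cycles(g, 4)}")

diff = tfpf.compare_subject_graphs(graphs["strong"], graphs["weak"])["difference"]
print(f"\nstrong - weak: {diff['n_edges']} edges, {diff['triangles']} triangles")
print("More surviving structure (edges, triangles, cycles) indicates more")
print("stable inter-regional communication — the signature that separates")
print("well-decoded from poorly-decoded subjects.")
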