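"""Surrogate-data pruning of connectivity matrices and brain-graph metrics.

An observed connectivity value between two channels can be produced by
chance from the signals' autocorrelation alone.  Phase-randomized
surrogates keep each channel's amplitude spectrum exactly while replacing
its Fourier phases with independent uniform draws, which destroys genuine
cross-channel coupling; the feature recomputed on surrogate pairs forms a
per-edge null distribution.  Edges whose empirical one-sided p-value
exceeds the significance level are removed, and the surviving graph is
summarized by structural metrics (triangles, short simple cycles, node
strength) that index how stably brain regions communicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import (
    ConnectivityMatrix, compute_coherence_band, compute_pcc, compute_plv,
    extract_phase, EDGE_TRIM_FRACTION,
)

__all__ = ["SurrogateEnsemble", "BrainGraph", "phase_randomize", "surrogate_null",
           "surrogate_ensembles", "prune_graph", "count_triangles", "count_cycles",
           "compare_subject_graphs"]

DEFAULT_N_SURROGATES = 200


def phase_randomize(signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate of a real sample vector.

    The DFT magnitudes (hence power spectrum and, by Wiener–Khinchin, the
    autocorrelation) are preserved exactly: positive-frequency phases are
    replaced by iid uniform draws, the DC bin is untouched and the Nyquist
    bin (present for even length) keeps a random sign, so the inverse
    transform is real.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"need at least 4 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input signal")
    spec = np.fft.rfft(x)
    n_bins = spec.size
    has_nyquist = x.size % 2 == 0
    hi = n_bins - 1 if has_nyquist else n_bins
    phases = rng.uniform(0.0, 2 * np.pi, hi - 1)
    spec[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    if has_nyquist:
        spec[-1] = np.abs(spec[-1]) * rng.choice([-1.0, 1.0])
    return np.fft.irfft(spec, x.size)


def _feature(x: np.ndarray, y: np.ndarray, feature_kind: str, fs: float,
             band: tuple) -> float:
    if feature_kind == "PCC":
        return compute_pcc(x, y)
    if feature_kind == "COH":
        return compute_coherence_band(x, y, fs, band)
    if feature_kind == "PLV":
        ph = extract_phase(np.vstack([x, y])).phases
        return compute_plv(ph[0], ph[1], edge_trim=EDGE_TRIM_FRACTION)
    raise ValueError(f"unknown feature kind {feature_kind!r}")


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Null feature values for one channel pair."""

    pair: tuple
    feature_kind: str
    null_values: np.ndarray
    observed: float
    seed: int = 0

    @property
    def n_surrogates(self) -> int:
        return self.null_values.size

    @property
    def p_value(self) -> float:
        """One-sided empirical p with the +1 correction (never exactly 0):
        ``(1 + #{null >= observed}) / (1 + n_surrogates)``."""
        return float(
            (1 + np.count_nonzero(self.null_values >= self.observed))
            / (1 + self.n_surrogates)
        )


def surrogate_null(segment: np.ndarray, pair: tuple, feature_kind: str,
                   fs: float, band: tuple = (8.0, 30.0),
                   n_surrogates: int = DEFAULT_N_SURROGATES,
                   seed: int = 0) -> SurrogateEnsemble:
    """Null distribution of one feature for one channel pair.

    Both channels are independently phase-randomized for every surrogate
    draw, destroying any genuine cross-channel phase relation while
    keeping each channel's spectrum.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    i, j = pair
    if i == j or not (0 <= i < seg.shape[0] and 0 <= j < seg.shape[0]):
        raise ValueError(f"invalid channel pair {pair} for {seg.shape[0]} channels")
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    observed = _feature(seg[i], seg[j], feature_kind, fs, band)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        xs = phase_randomize(seg[i], rng)
        ys = phase_randomize(seg[j], rng)
        null[s] = _feature(xs, ys, feature_kind, fs, band)
    return SurrogateEnsemble(pair=(i, j), feature_kind=feature_kind,
                             null_values=null, observed=observed, seed=seed)


def surrogate_ensembles(segment: np.ndarray, feature_kind: str, fs: float,
                        band: tuple = (8.0, 30.0),
                        n_surrogates: int = DEFAULT_N_SURROGATES,
                        seed: int = 0) -> dict:
    """Surrogate nulls for every unordered channel pair of a segment."""
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    n_ch = seg.shape[0]
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(n_ch * (n_ch - 1) // 2) % (2**31 - 1)
    ensembles = {}
    idx = 0
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            ensembles[(i, j)] = surrogate_null(
                seg, (i, j), feature_kind, fs, band, n_surrogates,
                seed=int(pair_seeds[idx]),
            )
            idx += 1
    return ensembles


@dataclass(frozen=True)
class BrainGraph:
    """Weighted undirected graph of connections surviving the surrogate test."""

    graph: nx.Graph
    feature_kind: str
    alpha: float

    @property
    def nodes(self):
        return tuple(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def node_strength(self) -> dict:
        """Sum of incident edge weights per node."""
        return {n: float(w) for n, w in self.graph.degree(weight="weight")}

    def to_edge_list(self):
        """(node_i, node_j, weight, p_value) rows as a DataFrame."""
        import pandas as pd

        rows = [(u, v, d["weight"], d["p_value"])
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "p_value"])

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, weight="weight")


def prune_graph(matrix: ConnectivityMatrix, ensembles: dict, alpha: float = 0.05,
                channel_labels: tuple | None = None,
                correction: str | None = None) -> BrainGraph:
    """Keep the edges whose observed value is significant against the null.

    An edge (i, j) survives iff its one-sided empirical p-value is <=
    ``alpha``.  ``correction`` may be ``"bonferroni"`` or ``"fdr"``
    (Benjamini–Hochberg) to adjust across the C*(C-1)/2 edges; default is
    no correction.
    """
    n_ch = matrix.n_channels
    labels = tuple(channel_labels) if channel_labels else tuple(range(n_ch))
    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    missing = [p for p in pairs if p not in ensembles]
    if missing:
        raise ValueError(f"missing surrogate ensembles for pairs {missing[:5]}...")
    pvals = np.array([ensembles[p].p_value for p in pairs])
    if correction == "bonferroni":
        adjusted = np.minimum(pvals * len(pairs), 1.0)
    elif correction == "fdr":
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pairs) / (np.arange(len(pairs)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(pvals)
        adjusted[order] = np.minimum(ranked, 1.0)
    elif correction is None:
        adjusted = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")

    g = nx.Graph()
    g.add_nodes_from(labels)
    for (pair, p) in zip(pairs, adjusted):
        if p <= alpha:
            i, j = pair
            g.add_edge(labels[i], labels[j], weight=float(matrix.values[i, j]),
                       p_value=float(p))
    return BrainGraph(graph=g, feature_kind=matrix.feature_kind, alpha=alpha)


def count_triangles(graph: BrainGraph | nx.Graph) -> int:
    """Number of 3-cliques in the unweighted skeleton."""
    g = graph.graph if isinstance(graph, BrainGraph) else graph
    return sum(nx.triangles(g).values()) // 3


def count_cycles(graph: BrainGraph | nx.Graph, max_len: int = 4) -> dict:
    """Simple-cycle counts by length, for lengths 3..max_len.

    Exhaustive enumeration; intended for the <= 64-node graphs of an EEG
    montage.  ``counts[3]`` always equals :func:`count_triangles`.
    """
    if max_len < 3:
        raise ValueError(f"max_len must be >= 3, got {max_len}")
    g = graph.graph if isinstance(graph, BrainGraph) else graph
    counts = {length: 0 for length in range(3, max_len + 1)}
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        if len(cycle) >= 3:
            counts[len(cycle)] += 1
    return counts


def compare_subject_graphs(graph_a: BrainGraph, graph_b: BrainGraph,
                           max_cycle_len: int = 4) -> dict:
    """Structural comparison of two subjects' pruned graphs.

    Returns per-graph metrics and their (a - b) differences: edge count,
    total connection weight, triangle count, cycle counts and per-node
    strength — the quantities that separate a strongly connected,
    well-classified subject from a weakly connected one.
    """
    if set(graph_a.nodes) != set(graph_b.nodes):
        raise ValueError("graphs must share the same node set")

    def metrics(g: BrainGraph) -> dict:
        return {
            "n_edges": g.n_edges,
            "total_weight": g.total_weight,
            "triangles": count_triangles(g),
            "cycles": count_cycles(g, max_cycle_len),
            "node_strength": g.node_strength(),
        }

    ma, mb = metrics(graph_a), metrics(graph_b)
    diff = {
        "n_edges": ma["n_edges"] - mb["n_edges"],
        "total_weight": ma["total_weight"] - mb["total_weight"],
        "triangles": ma["triangles"] - mb["triangles"],
        "cycles": {L: ma["cycles"][L] - mb["cycles"][L] for L in ma["cycles"]},
        "node_strength": {
            n: ma["node_strength"][n] - mb["node_strength"][n] for n in ma["node_strength"]
        },
    }
    return {"a": ma, "b": mb, "difference": diff}
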