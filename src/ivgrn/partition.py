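"""Graph summaries of a thresholded regulatory network.

The degree of gene i counts regulators and targets, d(i) = sum_j (E_ij +
E_ji); with N the total number of regulations, the modularity of a
partition D is

    Q(D) = (1/2N) * sum over all ordered pairs (i, j) in the same
           community of [E_ij + E_ji - d(i) d(j) / (2N)],

the Newman modularity of the symmetrized graph (self-pairs contribute
only their -d(i)^2/(2N) term). Community structure is found by fast
greedy agglomeration: starting from singletons, repeatedly apply the
merge with the largest modularity gain until no merge improves Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import ThresholdedGraph

__all__ = [
    "Partition",
    "total_degree",
    "subnetworks",
    "modularity",
    "fast_greedy_partition",
    "FastGreedyPartition",
]


@dataclass
class Partition:
    """Community assignment (gene -> integer label) and its modularity."""

    assignment: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[list[str]]:
        groups: dict[int, list[str]] = {}
        for gene, lab in self.assignment.items():
            groups.setdefault(lab, []).append(gene)
        comms = [sorted(v) for v in groups.values()]
        return sorted(comms, key=lambda c: (-len(c), c[0]))


def total_degree(graph: ThresholdedGraph, gene: str) -> int:
    """d(i) = sum_{j != i} (E_ij + E_ji); a reciprocal pair contributes 2."""
    try:
        i = graph.gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"unknown gene {gene!r}") from None
    E = graph.edges
    return int(E[i, :].sum() + E[:, i].sum())


def _degrees(E: np.ndarray) -> np.ndarray:
    return E.sum(axis=1) + E.sum(axis=0)


def subnetworks(graph: ThresholdedGraph) -> list[list[str]]:
    """Weakly connected components, largest first (ties: smallest member id)."""
    G = nx.DiGraph()
    G.add_nodes_from(graph.gene_ids)
    i_idx, j_idx = np.nonzero(graph.edges)
    # E[i, j] = 1 means j regulates i; edge direction regulator -> target
    G.add_edges_from((graph.gene_ids[j], graph.gene_ids[i]) for i, j in zip(i_idx, j_idx))
    comps = [sorted(c) for c in nx.weakly_connected_components(G)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def modularity(graph: ThresholdedGraph, partition: dict[str, int] | Partition) -> float:
    """Evaluate Q(D) exactly, summing over all ordered pairs (incl. i = j)."""
    if isinstance(partition, Partition):
        partition = partition.assignment
    missing = set(graph.gene_ids) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover genes: {sorted(missing)[:5]}")
    E = graph.edges.astype(float)
    N = E.sum()
    if N == 0:
        raise ValueError("modularity undefined on empty graph")
    W = E + E.T
    d = _degrees(graph.edges).astype(float)
    labels = np.array([partition[g] for g in graph.gene_ids])
    same = labels[:, None] == labels[None, :]
    Q = ((W - np.outer(d, d) / (2.0 * N)) * same).sum() / (2.0 * N)
    return float(Q)


def fast_greedy_partition(graph: ThresholdedGraph) -> Partition:
    """Agglomerative (CNM-style) modularity maximization.

    Starts from singletons and repeatedly merges the community pair with
    the largest strictly positive modularity gain; ties break on the
    lowest (label, label) pair, so the result is deterministic. Returns
    the best partition encountered.
    """
    E = graph.edges.astype(float)
    N = E.sum()
    if N == 0:
        raise ValueError("cannot partition an empty graph")
    W = E + E.T
    p = len(graph.gene_ids)
    two_n = 2.0 * N

    # community state: label -> member indices; aggregated weights/degrees
    members: dict[int, list[int]] = {i: [i] for i in range(p)}
    d_all = _degrees(graph.edges).astype(float)
    deg = {i: d_all[i] for i in range(p)}
    w_between: dict[int, dict[int, float]] = {i: {} for i in range(p)}
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                w_between[i][j] = float(W[i, j])
                w_between[j][i] = float(W[i, j])

    def gain(a: int, b: int) -> float:
        return (2.0 * w_between[a].get(b, 0.0) - 2.0 * deg[a] * deg[b] / two_n) / two_n

    best_assignment = {graph.gene_ids[i]: i for i in range(p)}
    current_q = modularity(graph, best_assignment)
    best_q = current_q

    while len(members) > 1:
        best_pair, best_gain = None, 0.0
        for a in sorted(members):
            for b in sorted(w_between[a]):
                if b <= a:
                    continue
                g = gain(a, b)
                if g > best_gain + 1e-15:
                    best_gain, best_pair = g, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        members[a].extend(members[b])
        del members[b]
        deg[a] += deg.pop(b)
        for c, w in w_between.pop(b).items():
            if c == a:
                continue
            w_between[a][c] = w_between[a].get(c, 0.0) + w
            w_between[c][a] = w_between[a][c]
            w_between[c].pop(b, None)
        w_between[a].pop(b, None)
        current_q += best_gain
        if current_q > best_q:
            best_q = current_q
            best_assignment = {}
            for lab, mem in members.items():
                for i in mem:
                    best_assignment[graph.gene_ids[i]] = lab

    # relabel communities 0..K-1, largest first
    groups: dict[int, list[str]] = {}
    for gene, lab in best_assignment.items():
        groups.setdefault(lab, []).append(gene)
    ordered = sorted((sorted(v) for v in groups.values()), key=lambda c: (-len(c), c[0]))
    assignment = {g: k for k, comm in enumerate(ordered) for g in comm}
    return Partition(assignment, modularity(graph, assignment))


class FastGreedyPartition:
    """Estimator-style wrapper: ``fit(graph)`` exposes ``labels_``,
    ``modularity_`` and ``partition_``."""

    def fit(self, graph: ThresholdedGraph, y=None) -> "FastGreedyPartition":
        part = fast_greedy_partition(graph)
        self.partition_ = part
        self.labels_ = np.array([part.assignment[g] for g in graph.gene_ids])
        self.modularity_ = part.modularity
        return self
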