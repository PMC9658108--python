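"""Weighted modularity and an original Louvain implementation.

Modularity (Newman–Girvan, resolution gamma) of a partition c on a weighted
undirected graph:

    Q = (1/2m) * sum_ij (w_ij - gamma * s_i s_j / 2m) * [c_i == c_j]

with s_i the weighted degree and m the total edge weight.  The Louvain
heuristic alternates (1) greedy single-node moves to the neighbouring
community with maximal positive modularity gain and (2) aggregation of
communities into super-nodes, until a full pass yields no improvement.
Node visit order is shuffled by the seed; ties keep the current community,
else take the lowest community id, so a seed fixes the partition exactly.

Edge weights must be non-negative: modularity on signed graphs is a
different objective, and the network builder's default admits positive
correlations only.

A brute-force exact maximizer over all set partitions is provided as the
test oracle for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["Partition", "modularity", "louvain", "louvain_best_of",
           "brute_force_best_partition", "adjusted_rand_index"]


@dataclass(frozen=True)
class Partition:
    """Node -> community assignment (ids contiguous from 0) with its
    modularity score."""

    assignment: dict[str, int]
    q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def communities(self) -> list[list]:
        out: dict[int, list] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return [sorted(out[cid]) for cid in sorted(out)]


def _canonical(assignment: dict, nodes) -> dict:
    """Relabel community ids contiguously by first occurrence over ``nodes``."""
    remap: dict[int, int] = {}
    out = {}
    for node in nodes:
        cid = assignment[node]
        if cid not in remap:
            remap[cid] = len(remap)
        out[node] = remap[cid]
    return out


def _check_weights(net: nx.Graph, weight: str) -> None:
    for u, v, d in net.edges(data=True):
        if d.get(weight, 1.0) < 0:
            raise ValueError(
                f"negative edge weight on ({u}, {v}); signed graphs are "
                f"unsupported — filter to positive correlations first")


def modularity(net: nx.Graph, assignment: dict, resolution: float = 1.0,
               weight: str = "weight") -> float:
    """Weighted modularity of ``assignment`` on ``net``; 0 by convention on
    an edgeless graph."""
    missing = [n for n in net.nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition missing nodes: {missing[:5]}")
    _check_weights(net, weight)
    two_m = 2.0 * net.size(weight=weight)
    if two_m == 0:
        return 0.0
    degree = dict(net.degree(weight=weight))
    q = 0.0
    for u, v, d in net.edges(data=True):
        if assignment[u] == assignment[v]:
            q += 2.0 * d.get(weight, 1.0)  # both (u,v) and (v,u)
    # expected-edge term, including self-pairs i == j
    comm_degree: dict[int, float] = {}
    for node, cid in assignment.items():
        if node in degree:
            comm_degree[cid] = comm_degree.get(cid, 0.0) + degree[node]
    expected = sum(s * s for s in comm_degree.values()) / two_m
    return (q - resolution * expected) / two_m


#: Minimum absolute modularity improvement for a pass to count as progress.
GAIN_TOL = 1e-10


def _local_moves(adj: dict, degree: dict, two_m: float, resolution: float,
                 rng: np.random.Generator) -> tuple[dict, bool]:
    """Phase 1: greedy single-node moves until a full sweep yields no gain.

    ``adj`` maps node -> {neighbor: weight} (no self loops at level 0;
    aggregated levels carry self-weights separately in ``self_w``)."""
    nodes = list(adj)
    comm = {n: i for i, n in enumerate(nodes)}
    comm_degree = {comm[n]: degree[n] for n in nodes}
    improved_any = False
    while True:
        moved = 0
        order = list(nodes)
        rng.shuffle(order)
        for node in order:
            cur = comm[node]
            k_i = degree[node]
            # weight from node to each neighbouring community
            links: dict[int, float] = {}
            for nbr, w in adj[node].items():
                if nbr != node:
                    links[comm[nbr]] = links.get(comm[nbr], 0.0) + w
            comm_degree[cur] -= k_i
            base = links.get(cur, 0.0) - resolution * k_i * comm_degree[cur] / two_m
            # gain of staying put is 0 by definition; ties keep the current
            # community, ties among movers take the lowest community id
            best_cid, best_gain = cur, 0.0
            for cid in sorted(links):
                if cid == cur:
                    continue
                gain = (links[cid]
                        - resolution * k_i * comm_degree.get(cid, 0.0) / two_m
                        ) - base
                if gain > best_gain + GAIN_TOL:
                    best_cid, best_gain = cid, gain
            comm_degree[best_cid] = comm_degree.get(best_cid, 0.0) + k_i
            if best_cid != cur:
                comm[node] = best_cid
                moved += 1
        if moved == 0:
            break
        improved_any = True
    return comm, improved_any


def _aggregate(adj: dict, self_w: dict, comm: dict
               ) -> tuple[dict, dict, dict]:
    """Phase 2: collapse communities to super-nodes; returns new adjacency,
    new self-weights, and the node -> super-node map."""
    new_adj: dict[int, dict[int, float]] = {}
    new_self: dict[int, float] = {}
    for node, w in self_w.items():
        cid = comm[node]
        new_self[cid] = new_self.get(cid, 0.0) + w
    seen = set()
    for u in adj:
        cu = comm[u]
        new_adj.setdefault(cu, {})
        new_self.setdefault(cu, 0.0)
        for v, w in adj[u].items():
            if (v, u) in seen:
                continue
            seen.add((u, v))
            cv = comm[v]
            if cu == cv:
                new_self[cu] = new_self.get(cu, 0.0) + 2.0 * w
            else:
                new_adj.setdefault(cu, {})[cv] = new_adj.get(cu, {}).get(cv, 0.0) + w
                new_adj.setdefault(cv, {})[cu] = new_adj.get(cv, {}).get(cu, 0.0) + w
    return new_adj, new_self, dict(comm)


def _q_from_parts(adj: dict, self_w: dict, degree: dict, comm: dict,
                  two_m: float, resolution: float) -> float:
    intra = 0.0
    for u in adj:
        intra += self_w.get(u, 0.0)
        for v, w in adj[u].items():
            if comm[u] == comm[v]:
                intra += w  # counted from both endpoints -> 2w total
    comm_degree: dict[int, float] = {}
    for n, cid in comm.items():
        comm_degree[cid] = comm_degree.get(cid, 0.0) + degree[n]
    expected = sum(s * s for s in comm_degree.values()) / two_m
    return (intra - resolution * expected) / two_m


def louvain(net: nx.Graph, seed: int = 0, resolution: float = 1.0,
            weight: str = "weight") -> Partition:
    """Louvain community detection; deterministic for a fixed seed.

    Returns a partition whose modularity is at least that of the
    all-singletons start; modularity is non-decreasing across passes
    (asserted), and the aggregated graph's modularity equals the original
    graph's under the induced partition at every level (exact identity up
    to float round-off, asserted)."""
    if net.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    _check_weights(net, weight)
    nodes = list(net.nodes)
    two_m = 2.0 * net.size(weight=weight)
    if two_m == 0:
        assignment = {n: i for i, n in enumerate(nodes)}
        return Partition(assignment=_canonical(assignment, nodes), q=0.0)

    rng = np.random.default_rng(seed)
    adj = {n: {} for n in nodes}
    self_w = {n: 0.0 for n in nodes}
    for u, v, d in net.edges(data=True):
        w = float(d.get(weight, 1.0))
        if u == v:
            self_w[u] += 2.0 * w
        else:
            adj[u][v] = adj[u].get(v, 0.0) + w
            adj[v][u] = adj[v].get(u, 0.0) + w

    final = {n: n for n in nodes}  # node -> current super-node
    degree = {n: self_w[n] + sum(adj[n].values()) for n in adj}
    q_prev = _q_from_parts(adj, self_w, degree, {n: n for n in adj},
                           two_m, resolution)  # all-singletons start
    while True:
        comm, improved = _local_moves(adj, degree, two_m, resolution, rng)
        if not improved:
            break
        q_here = _q_from_parts(adj, self_w, degree, comm, two_m, resolution)
        assert q_here >= q_prev - 1e-9, "modularity decreased across a pass"
        final = {n: comm[final[n]] for n in final}
        adj, self_w, _ = _aggregate(adj, self_w, comm)
        # aggregation consistency: Q of the aggregated graph under the
        # identity partition equals Q of the previous graph under comm
        degree = {n: self_w[n] + sum(adj[n].values()) for n in adj}
        q_agg = _q_from_parts(adj, self_w, degree, {n: n for n in adj},
                              two_m, resolution)
        assert abs(q_agg - q_here) < 1e-9, "aggregation changed modularity"
        if q_here - q_prev < GAIN_TOL:
            break
        q_prev = q_here

    assignment = _canonical(final, nodes)
    q = modularity(net, assignment, resolution=resolution, weight=weight)
    return Partition(assignment=assignment, q=q)


def louvain_best_of(net: nx.Graph, seeds, resolution: float = 1.0,
                    weight: str = "weight") -> Partition:
    """Run Louvain once per seed and keep the highest-modularity partition
    (ties broken by the earliest seed)."""
    best = None
    for s in seeds:
        part = louvain(net, seed=int(s), resolution=resolution, weight=weight)
        if best is None or part.q > best.q + GAIN_TOL:
            best = part
    return best


def _set_partitions(items: list):
    """All set partitions of ``items`` (canonical restricted-growth order)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_best_partition(net: nx.Graph, max_nodes: int = 10,
                               resolution: float = 1.0,
                               weight: str = "weight") -> Partition:
    """Exact maximum-modularity partition by exhaustive enumeration of all
    set partitions; feasible only for tiny graphs (Bell(10) = 115975)."""
    nodes = sorted(net.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(f"{len(nodes)} nodes exceeds max_nodes={max_nodes}")
    if not nodes:
        raise ValueError("graph has no nodes")
    best_q, best_assignment = -np.inf, None
    for blocks in _set_partitions(nodes):
        assignment = {n: i for i, block in enumerate(blocks) for n in block}
        q = modularity(net, assignment, resolution=resolution, weight=weight)
        if q > best_q + 1e-15:
            best_q, best_assignment = q, assignment
    return Partition(assignment=_canonical(best_assignment, nodes),
                     q=float(best_q))


def adjusted_rand_index(a: dict, b: dict) -> float:
    """Chance-corrected agreement between two partitions of the same nodes."""
    nodes = sorted(a)
    if sorted(b) != nodes:
        raise ValueError("partitions cover different node sets")
    la = {}
    lb = {}
    for n in nodes:
        la.setdefault(a[n], []).append(n)
        lb.setdefault(b[n], []).append(n)

    def comb2(x):
        return x * (x - 1) / 2.0

    n_tot = len(nodes)
    sum_ij = 0.0
    for ca in la.values():
        sa = set(ca)
        for cb in lb.values():
            sum_ij += comb2(len(sa & set(cb)))
    sum_a = sum(comb2(len(c)) for c in la.values())
    sum_b = sum(comb2(len(c)) for c in lb.values())
    expected = sum_a * sum_b / comb2(n_tot) if n_tot > 1 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
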