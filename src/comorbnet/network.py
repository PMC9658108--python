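"""Per-stratum disease networks.

Nodes are diseases passing the strict >1% prevalence filter; an edge joins
two diseases whose tetrachoric correlation is statistically significant
(p < alpha, default 0.01), weighted by the correlation.  By default only
positive correlations become edges — comorbidity is co-occurrence, and the
downstream modularity machinery assumes non-negative weights — with a flag
to admit negative correlations carrying |rho| as weight.
"""

from __future__ import annotations

import logging

import networkx as nx

from comorbnet.grouping import DiseaseMatrix
from comorbnet.tetrachoric import EstimationError, estimate

__all__ = ["prevalence_filter", "build_network", "export_network",
           "read_network", "adjacency_frame"]

log = logging.getLogger(__name__)


def prevalence_filter(matrix: DiseaseMatrix, min_prev: float = 0.01
                      ) -> DiseaseMatrix:
    """Restrict to diseases with prevalence strictly greater than
    ``min_prev`` (a disease in exactly 1% of patients is dropped)."""
    if matrix.n_patients == 0:
        raise ValueError("matrix has no patients")
    keep = matrix.prevalences > min_prev
    if not keep.any():
        log.warning("prevalence filter removed every disease in stratum %s",
                    matrix.stratum)
    return matrix.restrict(keep)


def build_network(matrix: DiseaseMatrix, alpha: float = 0.01,
                  edge_sign: str = "positive") -> nx.Graph:
    """Build the stratum's disease network from a (prevalence-filtered)
    matrix.

    Every disease becomes a node (isolated nodes are retained; they turn
    into singleton patterns downstream).  Each of the C(D,2) pairs gets a
    tetrachoric fit; a pair becomes an edge iff p < alpha and the sign
    policy admits it.  Pairs whose fit fails (degenerate margins) are
    skipped and logged, never fatal.  Edge attributes: ``rho``, ``p_value``
    and ``weight`` (= rho, or |rho| under ``edge_sign="both"``).
    """
    if edge_sign not in ("positive", "both"):
        raise ValueError(f"edge_sign must be 'positive' or 'both', got {edge_sign!r}")
    g = nx.Graph()
    g.graph["sex"], g.graph["age_band"] = matrix.stratum
    g.graph["n_patients"] = matrix.n_patients
    prev = matrix.prevalences
    for j, disease in enumerate(matrix.diseases):
        g.add_node(disease, prevalence=float(prev[j]))
    d = len(matrix.diseases)
    for i in range(d):
        for j in range(i + 1, d):
            try:
                res = estimate(matrix.pair_table(i, j))
            except EstimationError as exc:
                log.info("skipping pair (%s, %s): %s",
                         matrix.diseases[i], matrix.diseases[j], exc)
                continue
            if res.p_value >= alpha:
                continue
            if edge_sign == "positive" and res.rho_hat <= 0:
                continue
            g.add_edge(matrix.diseases[i], matrix.diseases[j],
                       rho=float(res.rho_hat), p_value=float(res.p_value),
                       weight=float(abs(res.rho_hat)))
    return g


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or GEXF (both Gephi-readable); node
    attribute ``prevalence`` drives node size, edge ``weight``/``rho``
    drives link width in the usual encodings."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "gexf":
        nx.write_gexf(net, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'gexf'")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        g = nx.read_gexf(path)
        g.graph.pop("mode", None)  # GEXF bookkeeping, not ours
        return g
    raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'gexf'")


def adjacency_frame(net: nx.Graph):
    """Edge list as a DataFrame (disease_a, disease_b, rho, p_value) for
    spreadsheet export."""
    import pandas as pd

    rows = [(u, v, d["rho"], d["p_value"])
            for u, v, d in sorted(net.edges(data=True))]
    return pd.DataFrame(rows, columns=["disease_a", "disease_b", "rho",
                                       "p_value"])
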