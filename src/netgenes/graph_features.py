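"""Explicit per-node graph features: 12 centrality measures, clique number,
clustering coefficient, biconnected-component membership and weighted degree.

Centralities are computed on the unweighted topology (weights enter only
through the weighted degree); path- and spectral-based measures are
evaluated per connected component so that every value is finite on
disconnected graphs, including isolated nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import Interactome
from .refex import node_order

logger = logging.getLogger("netgenes")

CENTRALITY_NAMES = (
    "degree_centrality",
    "betweenness",
    "closeness",
    "harmonic_closeness",
    "eigenvector",
    "pagerank",
    "katz",
    "load",
    "subgraph",
    "information",
    "current_flow_betweenness",
    "laplacian",
)

# "strength" is the standard name for weighted degree; the recursive block
# already owns the plain "weighted_degree" column name.
STRUCTURE_NAMES = ("clique_number", "clustering", "biconnected_count", "strength")

EXPLICIT_FEATURE_NAMES = CENTRALITY_NAMES + STRUCTURE_NAMES


class ConvergenceError(RuntimeError):
    """An iterative centrality failed to converge; names the measure and component."""


@dataclass
class CentralityConfig:
    centralities: tuple[str, ...] = CENTRALITY_NAMES
    tol: float = 1e-8
    max_iter: int = 1000
    damping: float = 0.85
    katz_alpha: float = 0.005
    clique_node_limit: int = 50_000


def _per_component(g: nx.Graph, fn, min_size: int = 1, default: float = 0.0) -> dict:
    """Apply ``fn`` to each connected component of at least ``min_size`` nodes."""
    out: dict = {}
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            out.update({v: default for v in comp})
        else:
            out.update(fn(g.subgraph(comp)))
    return out


def _eigenvector_dense(sub: nx.Graph) -> dict:
    nodes = sorted(sub.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    a = nx.to_numpy_array(sub, nodelist=nodes, weight=None)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of a connected graph is sign-constant
    v /= np.linalg.norm(v)
    return dict(zip(nodes, v))


def _harmonic_normalized(g: nx.Graph) -> dict:
    raw = nx.harmonic_centrality(g)
    out = {}
    for comp in nx.connected_components(g):
        denom = max(len(comp) - 1, 1)
        for v in comp:
            out[v] = raw[v] / denom
    return out


def _katz(g: nx.Graph, alpha: float) -> dict:
    if g.number_of_nodes() < 2:
        return {v: 1.0 for v in g.nodes}
    return nx.katz_centrality_numpy(g, alpha=alpha, weight=None)


def _laplacian(g: nx.Graph) -> dict:
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in g.nodes}
    return nx.laplacian_centrality(g, normalized=True, weight=None)


def centrality_suite(net: Interactome, cfg: CentralityConfig | None = None) -> pd.DataFrame:
    """Compute the 12 canonical centrality columns for every node.

    Raises :class:`ConvergenceError` if an iterative measure fails at the
    configured tolerance, naming the measure and the component size.
    """
    cfg = cfg or CentralityConfig()
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty interactome")
    order = node_order(net)

    computers = {
        "degree_centrality": lambda: nx.degree_centrality(g),
        "betweenness": lambda: nx.betweenness_centrality(g, normalized=True),
        "closeness": lambda: nx.closeness_centrality(g, wf_improved=False),
        "harmonic_closeness": lambda: _harmonic_normalized(g),
        "eigenvector": lambda: _per_component(g, _eigenvector_dense),
        "pagerank": lambda: nx.pagerank(
            g, alpha=cfg.damping, tol=cfg.tol, max_iter=cfg.max_iter, weight=None
        ),
        "katz": lambda: _katz(g, cfg.katz_alpha),
        "load": lambda: nx.load_centrality(g, normalized=True),
        "subgraph": lambda: nx.subgraph_centrality(g),
        "information": lambda: _per_component(
            g, nx.information_centrality, min_size=2
        ),
        "current_flow_betweenness": lambda: _per_component(
            g,
            lambda sub: nx.current_flow_betweenness_centrality(sub, normalized=True),
            min_size=3,
        ),
        "laplacian": lambda: _laplacian(g),
    }

    cols = {}
    for name in cfg.centralities:
        if name not in computers:
            raise ValueError(f"unknown centrality {name!r}")
        try:
            values = computers[name]()
        except nx.PowerIterationFailedConvergence as exc:
            raise ConvergenceError(
                f"{name} failed to converge at tol={cfg.tol} "
                f"(graph of {g.number_of_nodes()} nodes)"
            ) from exc
        cols[name] = [float(values[v]) for v in order]
    return pd.DataFrame(cols, index=order)


def clique_number_per_node(
    net: Interactome, node_limit: int = 50_000
) -> pd.Series:
    """Size of the largest maximal clique containing each node.

    Maximal-clique enumeration is exponential in the worst case, so graphs
    above ``node_limit`` nodes are rejected.
    """
    g = net.graph
    if g.number_of_nodes() > node_limit:
        raise ValueError(
            f"clique enumeration refused on {g.number_of_nodes()} nodes "
            f"(limit {node_limit})"
        )
    best = {v: 1 if g.degree(v) == 0 else 2 for v in g.nodes}
    for clique in nx.find_cliques(g):
        size = len(clique)
        for v in clique:
            if size > best[v]:
                best[v] = size
    return pd.Series(best, name="clique_number").reindex(node_order(net)).astype(float)


def clustering_and_structure(net: Interactome) -> pd.DataFrame:
    """Local clustering coefficient, biconnected-component count, weighted degree."""
    g = net.graph
    order = node_order(net)
    clustering = nx.clustering(g)
    bicount = {v: 0 for v in g.nodes}
    for comp in nx.biconnected_components(g):
        for v in comp:
            bicount[v] += 1
    wdeg = {v: sum(d["weight"] for d in g[v].values()) for v in g.nodes}
    return pd.DataFrame(
        {
            "clustering": [float(clustering[v]) for v in order],
            "biconnected_count": [float(bicount[v]) for v in order],
            "strength": [wdeg[v] for v in order],
        },
        index=order,
    )


def explicit_features(
    net: Interactome, cfg: CentralityConfig | None = None
) -> pd.DataFrame:
    """The 16-column explicit block: 12 centralities then the 4 structure columns."""
    cfg = cfg or CentralityConfig()
    cent = centrality_suite(net, cfg)
    clique = clique_number_per_node(net, cfg.clique_node_limit)
    struct = clustering_and_structure(net)
    out = pd.concat([cent, clique, struct], axis=1)
    return out[list(EXPLICIT_FEATURE_NAMES)] if tuple(cfg.centralities) == CENTRALITY_NAMES else out


def assemble_feature_matrix(
    refex_block: pd.DataFrame, explicit_block: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate the recursive and explicit blocks into the canonical matrix.

    With the default configurations this yields the canonical 283-column
    schema (267 recursive + 16 explicit).
    """
    left, right = set(refex_block.index), set(explicit_block.index)
    if left != right:
        diff = sorted(left.symmetric_difference(right))
        raise ValueError(f"gene sets differ between blocks: {diff[:10]}")
    explicit = explicit_block.reindex(refex_block.index)
    out = pd.concat([refex_block, explicit], axis=1)
    if out.columns.duplicated().any():
        dup = out.columns[out.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names after assembly: {dup}")
    return out
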