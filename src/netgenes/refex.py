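"""Recursive structural feature extraction (ReFeX-style).

Starting from six base features per node (degree, weighted degree, and
egonet internal/boundary edge counts in unweighted and weighted variants),
each recursion appends, for every existing feature, its sum and its mean
over the node's neighbours.  With both aggregators the cumulative width
after ``g`` recursions is ``6 * 3**g``.

Two modes are supported:

* **schema mode** (default): recursion runs to the first depth whose
  cumulative width reaches ``target_width`` and the first ``target_width``
  columns are kept in canonical order.  The column names are a function of
  the configuration only, so every input graph yields the same 267-column
  schema — a requirement for training one model across organisms.
* **research mode** (``prune=True``): each recursion is followed by
  vertical logarithmic binning and correlation pruning, and stops when an
  iteration contributes no surviving feature; the width is data-dependent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import Interactome

logger = logging.getLogger("netgenes")

BASE_FEATURES = (
    "degree",
    "weighted_degree",
    "ego_internal",
    "ego_boundary",
    "ego_internal_w",
    "ego_boundary_w",
)

DEFAULT_TARGET_WIDTH = 267


@dataclass
class RefexConfig:
    bin_fraction: float = 0.5
    similarity_threshold: int = 0
    aggregators: tuple[str, ...] = ("sum", "mean")
    max_iterations: int = 4
    target_width: int = DEFAULT_TARGET_WIDTH
    prune: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.bin_fraction < 1:
            raise ValueError("bin_fraction must lie in (0, 1)")
        if not self.aggregators:
            raise ValueError("at least one aggregator is required")
        unknown = set(self.aggregators) - {"sum", "mean"}
        if unknown:
            raise ValueError(f"unknown aggregators: {sorted(unknown)}")
        if self.target_width < len(BASE_FEATURES):
            raise ValueError("target_width must be >= number of base features")


def node_order(net: Interactome) -> list[str]:
    """Canonical (sorted) row order used by every feature matrix."""
    return sorted(net.graph.nodes)


def base_features(net: Interactome) -> pd.DataFrame:
    """Compute the six base local/egonet features for every node.

    The egonet of ``v`` is ``{v} ∪ N(v)``; internal edges have both
    endpoints inside it, boundary edges exactly one.  Isolated nodes get
    all-zero rows.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty interactome")
    order = node_order(net)
    adj = {v: set(g.neighbors(v)) for v in order}
    rows = np.zeros((len(order), len(BASE_FEATURES)))
    for i, v in enumerate(order):
        nbrs = adj[v]
        ego = nbrs | {v}
        deg = len(nbrs)
        wdeg = sum(g[v][u]["weight"] for u in nbrs)
        internal = internal_w = 0.0
        boundary = boundary_w = 0.0
        for u in ego:
            for w, d in g[u].items():
                if w in ego:
                    if u < w:  # count each internal edge once
                        internal += 1
                        internal_w += d["weight"]
                else:
                    boundary += 1
                    boundary_w += d["weight"]
        rows[i] = (deg, wdeg, internal, boundary, internal_w, boundary_w)
    return pd.DataFrame(rows, index=order, columns=list(BASE_FEATURES))


def _neighbor_aggregates(
    values: np.ndarray, adjacency, degrees: np.ndarray, aggregator: str
) -> np.ndarray:
    sums = adjacency @ values
    if aggregator == "sum":
        return sums
    # mean over an empty neighbourhood is defined as 0, not NaN
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(degrees[:, None] > 0, sums / degrees[:, None], 0.0)
    return means


def recursive_aggregate(
    fm: pd.DataFrame,
    net: Interactome,
    aggregators: Sequence[str] = ("sum", "mean"),
    iterations: int = 1,
    first_iteration: int = 1,
) -> pd.DataFrame:
    """Append neighbour aggregates of every existing column, ``iterations`` times.

    Each iteration takes every column present at its start and appends one
    new column per aggregator, in parent-major, aggregator-minor order, so
    with both default aggregators each iteration triples the width
    (cumulative ``6 * 3**g`` from the six base features).  Column names
    carry the recursion depth (``sum2(degree)`` is the depth-2 aggregate of
    the base degree, distinct from depth-1 ``sum1(degree)``), which keeps
    the enumeration unique even though re-aggregating an old column can
    reproduce an earlier column's values — redundancy that research mode's
    pruning removes.
    """
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    order = list(fm.index)
    if set(order) != set(net.graph.nodes):
        raise ValueError("feature matrix rows do not match interactome nodes")
    adjacency = nx.adjacency_matrix(net.graph, nodelist=order, weight=None).astype(float)
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    current = fm.copy()
    for step in range(iterations):
        depth = first_iteration + step
        values = current.to_numpy(dtype=float)
        new_cols: dict[str, np.ndarray] = {}
        per_agg = {
            agg: _neighbor_aggregates(values, adjacency, degrees, agg)
            for agg in aggregators
        }
        for j, parent in enumerate(current.columns):
            for agg in aggregators:
                new_cols[f"{agg}{depth}({parent})"] = per_agg[agg][:, j]
        current = pd.concat([current, pd.DataFrame(new_cols, index=order)], axis=1)
    return current


def canonical_feature_names(cfg: RefexConfig | None = None) -> list[str]:
    """The input-independent column schema of schema-mode ReFeX.

    Names are generated by the same recursion as the values, so the schema
    can be checked without touching any graph.
    """
    cfg = cfg or RefexConfig()
    depth = _depth_for_width(cfg)
    names = list(BASE_FEATURES)
    for g in range(1, depth + 1):
        new = []
        for parent in names:
            for agg in cfg.aggregators:
                new.append(f"{agg}{g}({parent})")
        names = names + new
    return names[: cfg.target_width]


def _depth_for_width(cfg: RefexConfig) -> int:
    growth = 1 + len(cfg.aggregators)
    width = len(BASE_FEATURES)
    for g in range(cfg.max_iterations + 1):
        if width >= cfg.target_width:
            return g
        width *= growth
    raise ValueError(
        f"target_width={cfg.target_width} unreachable within "
        f"max_iterations={cfg.max_iterations} (max width {width // growth})"
    )


def vertical_log_bin(values: Sequence[float], p: float) -> np.ndarray:
    """Rank-based vertical logarithmic binning.

    Repeatedly assigns the ``ceil(p * remaining)`` smallest unassigned values
    to the current bin, extending the bin through ties, then recurses on the
    remainder with the next bin index.  The result depends only on the
    ordering of the input, so any strictly increasing transform of the
    values yields identical bins.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    arr = np.asarray(values, dtype=float)
    bins = np.zeros(arr.shape, dtype=int)
    if arr.size == 0:
        return bins
    order = np.argsort(arr, kind="stable")
    sorted_vals = arr[order]
    n = arr.size
    start = 0
    b = 0
    while start < n:
        remaining = n - start
        take = math.ceil(p * remaining)
        end = start + take
        # ties always share a bin: extend past the nominal cut
        while end < n and sorted_vals[end] == sorted_vals[end - 1]:
            end += 1
        bins[order[start:end]] = b
        start = end
        b += 1
    return bins


def bin_matrix(fm: pd.DataFrame, p: float) -> pd.DataFrame:
    """Apply vertical log binning column-wise."""
    binned = {col: vertical_log_bin(fm[col].to_numpy(), p) for col in fm.columns}
    return pd.DataFrame(binned, index=fm.index)


def prune_correlated(fm_binned: pd.DataFrame, s: int = 0) -> list[str]:
    """Drop features that agree with an earlier feature to within ``s`` bins.

    Two features are connected when their bin vectors differ by at most
    ``s`` on every node; within each connected component of that feature
    graph only the earliest feature (by column position, then name) is
    retained.  Retained names are returned in original column order.
    """
    cols = list(fm_binned.columns)
    if not cols:
        return []
    mat = fm_binned.to_numpy(dtype=int)
    n_feat = mat.shape[1]
    parent = list(range(n_feat))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_feat):
        for j in range(i + 1, n_feat):
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            if np.max(np.abs(mat[:, i] - mat[:, j])) <= s:
                parent[max(ri, rj)] = min(ri, rj)

    keep: dict[int, tuple[int, str]] = {}
    for idx, name in enumerate(cols):
        root = find(idx)
        if root not in keep or (idx, name) < keep[root]:
            keep[root] = (idx, name)
    retained = sorted(keep.values())
    return [name for _, name in retained]


def refex(net: Interactome, cfg: RefexConfig | None = None) -> pd.DataFrame:
    """Run the full recursive feature extraction on one interactome."""
    cfg = cfg or RefexConfig()
    if cfg.prune:
        return _refex_research(net, cfg)
    depth = _depth_for_width(cfg)
    fm = base_features(net)
    fm = recursive_aggregate(fm, net, cfg.aggregators, depth)
    fm = fm.iloc[:, : cfg.target_width]
    logger.info(
        "refex: %d nodes, depth %d, %d columns (schema mode)",
        len(fm), depth, fm.shape[1],
    )
    return fm


def _refex_research(net: Interactome, cfg: RefexConfig) -> pd.DataFrame:
    fm = base_features(net)
    retained = prune_correlated(bin_matrix(fm, cfg.bin_fraction), cfg.similarity_threshold)
    fm = fm[retained]
    for depth in range(1, cfg.max_iterations + 1):
        grown = recursive_aggregate(fm, net, cfg.aggregators, 1, first_iteration=depth)
        candidates = [c for c in grown.columns if c not in fm.columns]
        binned = bin_matrix(grown, cfg.bin_fraction)
        kept = prune_correlated(binned, cfg.similarity_threshold)
        new_kept = [c for c in kept if c in candidates]
        if not new_kept:
            break
        fm = grown[kept]
    logger.info("refex: %d columns retained (research mode)", fm.shape[1])
    return fm


def write_feature_matrix(fm: pd.DataFrame, path: str | Path) -> None:
    """Serialize as CSV with the gene id as first column."""
    fm.to_csv(path, index_label="gene_id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    fm = pd.read_csv(path, index_col="gene_id")
    fm.index.name = None
    return fm
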