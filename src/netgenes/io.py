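"""Readers and writers for STRING-style networks, essentiality labels and annotations.

The on-disk dialects are deliberately minimal and text-only:

* protein-links files: whitespace-delimited ``protein1 protein2 combined_score``
  with an optional header line and optional gzip compression; the integer
  ``combined_score`` in 1..1000 becomes an edge weight ``score/1000``;
* label files: one gene identifier per line, ``#`` comments ignored;
* annotation tables: tab-separated ``gene_id<TAB>preferred_name<TAB>function``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("netgenes")

UNANNOTATED = ("", "NA")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class EmptyInteractomeError(ValueError):
    """Raised when filtering leaves a network with no nodes."""


@dataclass
class Interactome:
    """One organism's undirected, weighted protein functional-association network.

    Edge weights are STRING combined scores divided by 1000, so they lie in
    (0, 1].  The graph is simple: no self-loops, no parallel edges.
    """

    taxon_id: str
    graph: nx.Graph
    name: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], float]:
        """Edge weights keyed by the sorted endpoint pair."""
        return {
            (u, v) if u <= v else (v, u): d["weight"]
            for u, v, d in self.graph.edges(data=True)
        }

    def validate(self) -> None:
        """Check the simple-graph and weight invariants; raise ValueError on breach."""
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            w = d.get("weight")
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")


@dataclass
class LabelSet:
    """Essential / non-essential gene labels for one organism.

    ``essential`` must be a subset of ``universe``; the non-essential class is
    implied as the complement, mirroring the convention that every gene absent
    from the essentiality database is treated as non-essential.
    """

    organism: str
    essential: set[str]
    universe: set[str]
    version_tag: str = ""
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        if not self.essential <= self.universe:
            extra = sorted(self.essential - self.universe)[:5]
            raise ValueError(f"essential genes outside universe, e.g. {extra}")

    @property
    def non_essential(self) -> set[str]:
        return self.universe - self.essential


@dataclass
class AnnotationTable:
    """Partial mapping gene id -> (preferred name, function).

    Lookups for unknown genes return an explicit "unannotated" marker
    (empty preferred name placeholder, function ``"NA"``) rather than failing.
    """

    records: dict[str, tuple[str, str]] = field(default_factory=dict)

    def lookup(self, gene_id: str) -> tuple[str, str]:
        if gene_id in self.records:
            return self.records[gene_id]
        return (gene_id, "NA")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ValidationReport:
    passed: bool
    n_edges: int
    min_edges: int

    def __bool__(self) -> bool:
        return self.passed


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_header(fields: list[str]) -> bool:
    # A first line whose third field is non-numeric is treated as a header.
    try:
        int(fields[2])
    except ValueError:
        return True
    return False


def read_string_links(
    path: str | Path,
    min_score: int = 0,
    taxon_id: str | None = None,
    name: str = "",
) -> Interactome:
    """Parse a STRING protein-links file into a validated :class:`Interactome`.

    Symmetric duplicate rows are collapsed keeping the maximum score,
    self-loops are dropped with a warning, and rows with
    ``combined_score < min_score`` are filtered out.

    Raises
    ------
    ParseError
        On a malformed line (fewer than 3 fields, or a non-integer or
        out-of-range score), naming the offending line number.
    EmptyInteractomeError
        If no edges survive filtering.
    """
    path = Path(path)
    best: dict[tuple[str, str], int] = {}
    seen_nodes: set[str] = set()
    n_self_loops = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            if lineno == 1 and _is_header(fields):
                continue
            a, b = fields[0], fields[1]
            try:
                score = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer score {fields[2]!r}") from exc
            if not 1 <= score <= 1000:
                raise ParseError(f"{path}:{lineno}: score {score} outside [1, 1000]")
            # endpoints remain nodes even when their row is filtered out
            seen_nodes.update((a, b))
            if a == b:
                n_self_loops += 1
                continue
            if score < min_score:
                continue
            key = (a, b) if a <= b else (b, a)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_self_loops)
    if not seen_nodes:
        raise EmptyInteractomeError(f"{path}: no nodes after filtering")
    g = nx.Graph()
    g.add_nodes_from(seen_nodes)
    for (a, b), score in best.items():
        g.add_edge(a, b, weight=score / 1000.0)
    if taxon_id is None:
        first = next(iter(g.nodes))
        taxon_id = first.split(".", 1)[0] if "." in first else ""
    net = Interactome(taxon_id=taxon_id, graph=g, name=name or path.stem)
    net.validate()
    return net


def write_string_links(net: Interactome, path: str | Path, header: bool = True) -> None:
    """Write an Interactome in the protein-links dialect (round-trips with the reader)."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        if header:
            fh.write("protein1 protein2 combined_score\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            score = int(round(d["weight"] * 1000))
            fh.write(f"{u} {v} {score}\n")


def read_labels(
    path: str | Path,
    universe: set[str],
    version_tag: str = "",
    organism: str = "",
) -> LabelSet:
    """Read a one-id-per-line essential-gene list and intersect it with ``universe``.

    Identifiers not present in the universe are counted as unmapped (reported
    on the returned :class:`LabelSet`) rather than raising; an empty mapped
    set triggers a warning because such an organism contributes no positive
    examples to training.
    """
    path = Path(path)
    listed: set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            # Two-column organism/gene variant: take the last field.
            listed.add(line.split()[-1])
    essential = listed & universe
    n_unmapped = len(listed - universe)
    if n_unmapped:
        logger.info("%s: %d label id(s) not in universe", path, n_unmapped)
    if not essential:
        logger.warning("%s: zero mapped essential genes", path)
    return LabelSet(
        organism=organism or path.stem,
        essential=essential,
        universe=set(universe),
        version_tag=version_tag,
        n_unmapped=n_unmapped,
    )


def write_labels(labels: Iterable[str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for gene in sorted(labels):
            fh.write(gene + "\n")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a tab-separated ``gene_id<TAB>preferred_name<TAB>function`` table."""
    records: dict[str, tuple[str, str]] = {}
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            records[parts[0]] = (parts[1], parts[2])
    return AnnotationTable(records)


def validate_training_interactome(
    net: Interactome, min_edges: int = 50_000
) -> ValidationReport:
    """Check the minimum-edge-count requirement for training interactomes.

    Failure is reported, not raised: small networks are still usable, they
    just may not support a generalizable model.
    """
    passed = net.n_edges >= min_edges
    if not passed:
        logger.warning(
            "interactome %s has %d edges (< %d required for training)",
            net.name or net.taxon_id,
            net.n_edges,
            min_edges,
        )
    return ValidationReport(passed=passed, n_edges=net.n_edges, min_edges=min_edges)
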