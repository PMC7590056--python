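"""Interactome data model, edge-list I/O, merging, and basic graph queries.

The interactome is an undirected simple graph over normalized gene symbols
(trimmed, upper-cased; no alias resolution). Node attributes carry the number
of supporting chemicals (``chemical_count``) and the provenance ``sources``
set; edge-level metadata beyond provenance is dropped at build time.

All outputs are deterministically ordered (sorted symbols) so that written
files are bit-stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import deque
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "EdgeRecord",
    "ColumnSpec",
    "BuildReport",
    "Interactome",
    "read_edge_list",
    "build_interactome",
    "merge",
    "induced_subgraph",
    "connected_components",
    "shortest_path_lengths",
    "write_graph",
    "read_graph",
]


def normalize_symbol(symbol: object) -> str:
    """Trim whitespace and upper-case a gene symbol (idempotent)."""
    s = str(symbol).strip().upper()
    return s


@dataclass(frozen=True)
class EdgeRecord:
    """One parsed interaction row; symbols are already normalized."""

    symbol_a: str
    symbol_b: str
    taxon_a: int | None = None
    taxon_b: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        for t in (self.taxon_a, self.taxon_b):
            if t is not None and (not isinstance(t, int) or t <= 0):
                raise ValueError(f"taxid must be a positive integer, got {t!r}")
        if not self.symbol_a or not self.symbol_b:
            raise ValueError("gene symbols must be non-empty")


@dataclass(frozen=True)
class ColumnSpec:
    """Column mapping for edge-list TSV files. Taxid columns are optional:
    they are used only when present in the file header."""

    gene_a: str = "gene_a"
    gene_b: str = "gene_b"
    taxid_a: str = "taxid_a"
    taxid_b: str = "taxid_b"
    source: str | None = None


@dataclass(frozen=True)
class BuildReport:
    nodes: int
    edges: int
    removed_self: int
    removed_dup: int
    removed_taxon: int


class Interactome:
    """Undirected simple graph over gene symbols, backed by ``networkx``.

    Node attributes: ``chemical_count`` (non-negative int, default 0) and
    ``sources`` (set of provenance strings).
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()
        self.build_report: BuildReport | None = None
        self.n_unmapped: int = 0

    # -- container views -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, symbol: str) -> int:
        return self.graph.degree[symbol]

    def neighbors(self, symbol: str) -> set[str]:
        return set(self.graph[symbol])

    def chemical_count(self, symbol: str) -> int:
        return int(self.graph.nodes[symbol].get("chemical_count", 0))

    def sources(self, symbol: str) -> set[str]:
        return set(self.graph.nodes[symbol].get("sources", set()))

    def set_chemical_counts(self, counts: Mapping[str, int]) -> None:
        for sym, c in counts.items():
            if sym in self.graph:
                self.graph.nodes[sym]["chemical_count"] = int(c)

    def adjacency(self) -> dict[str, list[str]]:
        """Plain adjacency dict (sorted neighbor lists) for tight loops."""
        return {v: sorted(self.graph[v]) for v in self.graph}

    def copy(self) -> "Interactome":
        return Interactome(self.graph.copy())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return all(
            self.chemical_count(v) == other.chemical_count(v)
            and self.sources(v) == other.sources(v)
            for v in self.graph
        )

    def __repr__(self) -> str:
        return (
            f"Interactome({self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges)"
        )


def read_edge_list(
    path: str | Path,
    columns: ColumnSpec | None = None,
    source: str = "",
) -> list[EdgeRecord]:
    """Parse an edge-list TSV into :class:`EdgeRecord` rows.

    Symbols are normalized; taxid columns are carried through when the header
    contains them. Malformed rows (empty symbol, unparseable taxid) are
    counted and logged, never silently dropped without trace. Duplicate rows
    are kept here -- deduplication is the job of :func:`build_interactome`.
    """
    columns = columns or ColumnSpec()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty edge-list file: {path}") from None
    if df.empty:
        raise ValueError(f"edge-list file has a header but no rows: {path}")
    for col in (columns.gene_a, columns.gene_b):
        if col not in df.columns:
            raise ValueError(f"mapped column {col!r} missing from {path} header")
    use_taxids = columns.taxid_a in df.columns and columns.taxid_b in df.columns
    use_source = columns.source is not None and columns.source in df.columns

    records: list[EdgeRecord] = []
    n_malformed = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        a, b = row[columns.gene_a], row[columns.gene_b]
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            n_malformed += 1
            continue
        taxa = taxb = None
        if use_taxids:
            try:
                ta, tb = row[columns.taxid_a], row[columns.taxid_b]
                taxa = int(ta) if pd.notna(ta) and str(ta).strip() else None
                taxb = int(tb) if pd.notna(tb) and str(tb).strip() else None
            except (TypeError, ValueError):
                n_malformed += 1
                continue
        src = str(row[columns.source]) if use_source else source
        try:
            records.append(
                EdgeRecord(
                    normalize_symbol(a), normalize_symbol(b), taxa, taxb, src
                )
            )
        except ValueError:
            n_malformed += 1
    if n_malformed:
        logger.warning("%s: skipped %d malformed rows", path, n_malformed)
    return records


def build_interactome(
    records: Sequence[EdgeRecord],
    taxid_filter: int | None = None,
) -> Interactome:
    """Assemble an :class:`Interactome` from parsed records.

    When ``taxid_filter`` is given, a record passes only if every taxid it
    carries equals the filter; records without taxids always pass (permissive
    union semantics). Self-pairs are removed and unordered duplicates
    collapsed; the removal counts are logged and attached as
    ``Interactome.build_report``.
    """
    if not records:
        raise ValueError("no records to build an interactome from")
    g = nx.Graph()
    removed_self = removed_dup = removed_taxon = 0
    for rec in records:
        if taxid_filter is not None:
            taxa = [t for t in (rec.taxon_a, rec.taxon_b) if t is not None]
            if any(t != taxid_filter for t in taxa):
                removed_taxon += 1
                continue
        a, b = rec.symbol_a, rec.symbol_b
        for sym in (a, b):
            if sym not in g:
                g.add_node(sym, chemical_count=0, sources=set())
            if rec.source:
                g.nodes[sym]["sources"].add(rec.source)
        if a == b:
            removed_self += 1
            continue
        if g.has_edge(a, b):
            removed_dup += 1
            continue
        g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError("all records were filtered out; empty interactome")
    inter = Interactome(g)
    inter.build_report = BuildReport(
        nodes=g.number_of_nodes(),
        edges=g.number_of_edges(),
        removed_self=removed_self,
        removed_dup=removed_dup,
        removed_taxon=removed_taxon,
    )
    logger.info("built interactome: %s", inter.build_report)
    return inter


def merge(interactomes: Sequence[Interactome]) -> Interactome:
    """Union of node and edge sets; ``chemical_count`` merged by max,
    ``sources`` by union. Commutative and idempotent."""
    if not interactomes:
        raise ValueError("need at least one interactome to merge")
    g = nx.Graph()
    for inter in interactomes:
        for v in inter.graph.nodes:
            if v not in g:
                g.add_node(v, chemical_count=0, sources=set())
            g.nodes[v]["chemical_count"] = max(
                g.nodes[v]["chemical_count"], inter.chemical_count(v)
            )
            g.nodes[v]["sources"] |= inter.sources(v)
        g.add_edges_from(inter.graph.edges)
    return Interactome(g)


def induced_subgraph(g: Interactome, genes: Iterable[str]) -> Interactome:
    """Subgraph induced on ``genes`` (absent symbols ignored; their count is
    logged and stored on the result as ``n_unmapped``)."""
    genes = set(genes)
    mapped = genes & set(g.graph.nodes)
    unmapped = len(genes) - len(mapped)
    if unmapped:
        logger.info("induced_subgraph: %d query genes not in interactome", unmapped)
    sub = Interactome(g.graph.subgraph(mapped).copy())
    sub.n_unmapped = unmapped
    return sub


def connected_components(g: Interactome) -> list[list[str]]:
    """Components as sorted member lists, ordered by size descending with
    ties broken by smallest member symbol."""
    comps = [sorted(c) for c in nx.connected_components(g.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def shortest_path_lengths(
    g: Interactome,
    from_nodes: Iterable[str],
    to_nodes: Iterable[str],
) -> dict[str, int]:
    """Unweighted BFS distance from each source to its nearest target.

    Returns ``{source: distance}``; sources that reach no target are absent
    from the result (never reported as a sentinel value). A source that is
    itself a target gets distance 0.
    """
    from_nodes = set(from_nodes)
    to_nodes = set(to_nodes)
    missing = from_nodes - set(g.graph.nodes)
    if missing:
        raise ValueError(f"from_nodes not in interactome: {sorted(missing)[:5]}")
    adj = g.graph
    out: dict[str, int] = {}
    for s in sorted(from_nodes):
        d = _bfs_nearest(adj, s, to_nodes)
        if d is not None:
            out[s] = d
    return out


def _bfs_nearest(adj, source: str, targets: set[str]) -> int | None:
    """Distance from ``source`` to the nearest member of ``targets``."""
    if source in targets:
        return 0
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        u, d = frontier.popleft()
        for v in adj[u]:
            if v in seen:
                continue
            if v in targets:
                return d + 1
            seen.add(v)
            frontier.append((v, d + 1))
    return None


# -- persistence ---------------------------------------------------------

def _sources_to_str(srcs: set[str]) -> str:
    return ";".join(sorted(srcs))


def write_graph(g: Interactome, path: str | Path, format: str = "tsv") -> None:
    """Write the interactome; ``read_graph`` round-trips nodes, edges and
    attributes exactly.

    ``tsv`` writes a two-column edge list plus a ``<stem>.nodes.tsv`` sidecar
    holding isolated nodes and node attributes; ``graphml`` serializes the
    whole graph (sources joined by ``;``).
    """
    path = Path(path)
    if format == "tsv":
        edges = sorted(g.edges)
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        with open(nodes_path, "w") as fh:
            fh.write("symbol\tchemical_count\tsources\n")
            for v in sorted(g.graph.nodes):
                fh.write(
                    f"{v}\t{g.chemical_count(v)}\t{_sources_to_str(g.sources(v))}\n"
                )
    elif format == "graphml":
        h = nx.Graph()
        for v in sorted(g.graph.nodes):
            h.add_node(
                v,
                chemical_count=g.chemical_count(v),
                sources=_sources_to_str(g.sources(v)),
            )
        h.add_edges_from(sorted(g.edges))
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graph(path: str | Path, format: str = "tsv") -> Interactome:
    """Inverse of :func:`write_graph`."""
    path = Path(path)
    if format == "tsv":
        g = nx.Graph()
        nodes_path = path.with_suffix(".nodes.tsv")
        if nodes_path.exists():
            ndf = pd.read_csv(nodes_path, sep="\t", dtype=str).fillna("")
            for row in ndf.itertuples(index=False):
                srcs = set(row.sources.split(";")) - {""} if row.sources else set()
                g.add_node(
                    row.symbol,
                    chemical_count=int(row.chemical_count),
                    sources=srcs,
                )
        edf = pd.read_csv(path, sep="\t", dtype=str)
        for row in edf.itertuples(index=False):
            for sym in (row.gene_a, row.gene_b):
                if sym not in g:
                    g.add_node(sym, chemical_count=0, sources=set())
            g.add_edge(row.gene_a, row.gene_b)
        return Interactome(g)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        for v, data in raw.nodes(data=True):
            srcs = data.get("sources", "")
            g.add_node(
                v,
                chemical_count=int(data.get("chemical_count", 0)),
                sources=set(srcs.split(";")) - {""} if srcs else set(),
            )
        g.add_edges_from(raw.edges)
        return Interactome(g)
    raise ValueError(f"unknown format {format!r}")
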