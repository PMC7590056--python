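"""Molecular Complex Detection (MCODE) dense-module discovery.

Three stages, following the classic plugin:

1. *Vertex weighting*: each vertex v gets w(v) = k* x density(H_{k*}),
   where H_{k*} is the highest k-core of the closed neighborhood graph
   (v, its neighbors, and every edge among them), k* its core number, and
   density = 2|E| / (|V| (|V|-1)). Isolated vertices weigh 0.

2. *Complex prediction*: greedy seeding from the highest-weight unassigned
   vertex; breadth-first outward growth adding neighbors u with
   w(u) >= w(seed) * (1 - node_score_cutoff), never revisiting vertices
   already assigned to a complex, bounded by ``max_depth`` levels.

3. *Post-processing*: complexes without a ``k_core``-core are discarded;
   with ``fluff`` on, boundary neighbors whose closed-neighborhood density
   exceeds ``fluff_density_cutoff`` are added (such vertices may end up in
   several complexes); with ``haircut`` on, degree-1 members are pruned
   iteratively.

Complex score is density x size of the *pre-fluff* membership and drives the
final M1..Mk ranking (ties broken by seed symbol). Haircut defaults to off:
the reference analysis lists fluff, k-core, score cutoff, and depth as its
tuned parameters, and never haircut.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .graph_core import Interactome

__all__ = [
    "McodeParams",
    "NetworkModule",
    "vertex_weights",
    "predict_complexes",
    "postprocess",
    "run_mcode",
    "write_modules",
]


@dataclass(frozen=True)
class McodeParams:
    node_score_cutoff: float = 0.2
    k_core: int = 2
    fluff: bool = True
    fluff_density_cutoff: float = 0.5
    haircut: bool = False
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if not 0.0 <= self.fluff_density_cutoff <= 1.0:
            raise ValueError("fluff_density_cutoff must be in [0, 1]")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass(frozen=True)
class NetworkModule:
    """An MCODE complex. ``label`` ("M1", ...) and ``rank`` are assigned by
    :func:`postprocess` after score ranking; predicted (pre-filter)
    complexes carry an empty label and rank 0."""

    label: str
    members: frozenset[str]
    seed_vertex: str
    mcode_score: float
    rank: int = 0
    # pre-fluff membership: the greedily grown complex before the boundary
    # halo is added; equal to `members` when fluff is off
    core_members: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.members)


def _closed_neighborhood_density(graph: nx.Graph, v: str) -> float:
    h = graph.subgraph(set(graph[v]) | {v})
    return nx.density(h)


def vertex_weights(g: Interactome) -> dict[str, float]:
    """Core-clustering weight for every vertex (stage 1)."""
    graph = g.graph
    weights: dict[str, float] = {}
    for v in graph:
        nbrs = set(graph[v])
        if not nbrs:
            weights[v] = 0.0
            continue
        h = graph.subgraph(nbrs | {v})
        core = nx.core_number(h)
        k_star = max(core.values())
        top_core = h.subgraph([u for u, c in core.items() if c == k_star])
        weights[v] = k_star * nx.density(top_core)
    return weights


def _density(graph: nx.Graph, members: set[str]) -> float:
    return nx.density(graph.subgraph(members))


def predict_complexes(
    g: Interactome,
    weights: dict[str, float],
    params: McodeParams | None = None,
) -> list[NetworkModule]:
    """Greedy complex growth (stage 2); complexes are vertex-disjoint and
    returned in discovery order. Singleton complexes are kept here and left
    for the k-core filter of :func:`postprocess`."""
    params = params or McodeParams()
    graph = g.graph
    missing = set(graph.nodes) - set(weights)
    if missing:
        raise ValueError(f"weights missing for {len(missing)} vertices")
    assigned: set[str] = set()
    complexes: list[NetworkModule] = []
    for seed in sorted(weights, key=lambda v: (-weights[v], v)):
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        assigned.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            next_frontier: list[str] = []
            for u in frontier:
                for v in sorted(graph[u]):
                    if v in assigned:
                        continue
                    if weights[v] >= threshold:
                        members.add(v)
                        assigned.add(v)
                        next_frontier.append(v)
            frontier = next_frontier
            depth += 1
        score = _density(graph, members) * len(members)
        complexes.append(
            NetworkModule(
                label="",
                members=frozenset(members),
                seed_vertex=seed,
                mcode_score=score,
                core_members=frozenset(members),
            )
        )
    return complexes


def postprocess(
    g: Interactome,
    complexes: list[NetworkModule],
    params: McodeParams | None = None,
) -> list[NetworkModule]:
    """k-core filter, fluff, optional haircut, then score ranking (stage 3).

    The reported ``mcode_score`` stays that of the pre-fluff membership;
    fluffed vertices join the member set only.
    """
    params = params or McodeParams()
    graph = g.graph
    surviving: list[tuple[set[str], frozenset[str], str, float]] = []
    for c in complexes:
        h = graph.subgraph(c.members)
        if h.number_of_nodes() == 0:
            continue
        core = nx.core_number(h)
        if max(core.values()) < params.k_core:
            continue
        members = set(c.members)
        if params.fluff:
            boundary = sorted(
                {v for u in members for v in graph[u]} - members
            )
            for v in boundary:
                if _closed_neighborhood_density(graph, v) > params.fluff_density_cutoff:
                    members.add(v)
        if params.haircut:
            while True:
                sub = graph.subgraph(members)
                leaves = [v for v in members if sub.degree[v] < 2]
                if not leaves or len(members) <= 1:
                    break
                members -= set(leaves)
            if not members:
                continue
        surviving.append((members, c.members, c.seed_vertex, c.mcode_score))
    surviving.sort(key=lambda t: (-t[3], t[2]))
    return [
        NetworkModule(
            label=f"M{i + 1}",
            members=frozenset(members),
            seed_vertex=seed,
            mcode_score=score,
            rank=i + 1,
            core_members=core_members,
        )
        for i, (members, core_members, seed, score) in enumerate(surviving)
    ]


def run_mcode(g: Interactome, params: McodeParams | None = None) -> list[NetworkModule]:
    """Full pipeline: weights -> prediction -> post-processing."""
    params = params or McodeParams()
    weights = vertex_weights(g)
    return postprocess(g, predict_complexes(g, weights, params), params)


def write_modules(modules: list[NetworkModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tsize\tscore\tseed\tmembers\n")
        for m in modules:
            fh.write(
                f"{m.label}\t{len(m)}\t{m.mcode_score:.6g}\t{m.seed_vertex}\t"
                + ";".join(sorted(m.members))
                + "\n"
            )


def read_modules(path: str | Path) -> list[NetworkModule]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        NetworkModule(
            label=row.label,
            members=frozenset(row.members.split(";")),
            seed_vertex=row.seed,
            mcode_score=float(row.score),
            rank=i + 1,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
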