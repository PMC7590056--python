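"""Independent brute-force oracles and small graph builders for the tests.

Every oracle here reimplements the quantity from first principles
(enumeration, union-find, matrix powers, exact fractions) without calling
the library code paths it is used to check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import networkx as nx

from ppinet.graph_core import Interactome


def build(edges, nodes=()) -> Interactome:
    """Interactome from an edge list (plus optional isolated nodes)."""
    g = nx.Graph()
    for v in nodes:
        g.add_node(v, chemical_count=0, sources=set())
    for a, b in edges:
        for v in (a, b):
            if v not in g:
                g.add_node(v, chemical_count=0, sources=set())
        g.add_edge(a, b)
    return Interactome(g)


def random_interactome(rng, n, p) -> Interactome:
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return Interactome(nx.relabel_nodes(g, {i: f"N{i:03d}" for i in range(n)}))


# -- union-find ----------------------------------------------------------

class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_oracle(g: Interactome) -> list[set[str]]:
    uf = UnionFind(g.nodes)
    for a, b in g.edges:
        uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for v in g.nodes:
        groups.setdefault(uf.find(v), set()).add(v)
    return list(groups.values())


def lcc_oracle(g: Interactome, genes) -> int:
    members = set(genes) & g.nodes
    if not members:
        return 0
    sub = build(
        [(a, b) for a, b in g.edges if a in members and b in members],
        nodes=members,
    )
    return max((len(c) for c in components_oracle(sub)), default=0)


# -- distances via boolean matrix powers ---------------------------------

def distances_oracle(g: Interactome) -> dict[tuple[str, str], int]:
    """All-pairs shortest paths from powers of the adjacency matrix."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for a, b in g.edges:
        adj[idx[a]][idx[b]] = adj[idx[b]][idx[a]] = True
    dist = {(v, v): 0 for v in nodes}
    reach = [[i == j or adj[i][j] for j in range(n)] for i in range(n)]
    for a, b in g.edges:
        dist[(a, b)] = dist[(b, a)] = 1
    for d in range(2, n):
        new = [
            [
                reach[i][j] or any(reach[i][k] and adj[k][j] for k in range(n))
                for j in range(n)
            ]
            for i in range(n)
        ]
        for i, j in itertools.product(range(n), range(n)):
            if new[i][j] and not reach[i][j]:
                dist[(nodes[i], nodes[j])] = d
        reach = new
    return dist


def shd_oracle(g: Interactome, genes) -> float:
    """Mean nearest-co-seed distance from the all-pairs matrix oracle."""
    members = sorted(set(genes) & g.nodes)
    dist = distances_oracle(g)
    vals = []
    for s in members:
        ds = [dist[(s, t)] for t in members if t != s and (s, t) in dist]
        if ds:
            vals.append(min(ds))
    return sum(vals) / len(vals)


# -- betweenness by exhaustive shortest-path enumeration -----------------

def _all_shortest_paths(g: Interactome, s: str, t: str) -> list[list[str]]:
    """All s-t paths of minimal length, by pure DFS enumeration."""
    adj = {v: set() for v in g.nodes}
    for a, b in g.edges:
        adj[a].add(b)
        adj[b].add(a)
    best: list[list[str]] = []
    best_len = [len(g.nodes)]

    def dfs(path):
        u = path[-1]
        if u == t:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(list(path))
            return
        if len(path) - 1 >= best_len[0]:
            return
        for v in sorted(adj[u]):
            if v not in path:
                path.append(v)
                dfs(path)
                path.pop()

    dfs([s])
    return best


def betweenness_oracle(g: Interactome) -> dict[str, float]:
    out = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


# -- MCC by exhaustive subset enumeration --------------------------------

def mcc_oracle(g: Interactome) -> dict[str, int]:
    nodes = sorted(g.nodes)
    edges = g.edges
    out = {v: 0 for v in nodes}

    def is_clique(sub):
        return all(
            tuple(sorted((a, b))) in edges
            for a, b in itertools.combinations(sub, 2)
        )

    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            sset = set(sub)
            maximal = not any(
                is_clique(tuple(sset | {w}))
                for w in nodes
                if w not in sset
            )
            if maximal:
                for v in sub:
                    out[v] += factorial(r - 1)
    return out


def mnc_oracle(g: Interactome) -> dict[str, int]:
    out = {}
    for v in sorted(g.nodes):
        nbrs = {u for u in g.nodes if tuple(sorted((u, v))) in g.edges}
        if not nbrs:
            out[v] = 0
            continue
        sub = build(
            [(a, b) for a, b in g.edges if a in nbrs and b in nbrs],
            nodes=nbrs,
        )
        out[v] = max(len(c) for c in components_oracle(sub))
    return out


def degree_oracle(g: Interactome) -> dict[str, int]:
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mat = [[0] * len(nodes) for _ in nodes]
    for a, b in g.edges:
        mat[idx[a]][idx[b]] = mat[idx[b]][idx[a]] = 1
    return {v: sum(mat[idx[v]]) for v in nodes}


# -- MCODE vertex weight by min-degree peeling ---------------------------

def vertex_weight_oracle(g: Interactome, v: str) -> float:
    """Highest k-core of the closed neighborhood, found by repeatedly
    peeling minimum-degree vertices and recording the deepest non-empty
    core."""
    nbrs = {u for u in g.nodes if tuple(sorted((u, v))) in g.edges}
    if not nbrs:
        return 0.0
    closed = nbrs | {v}
    edges = {
        (a, b)
        for a, b in g.edges
        if a in closed and b in closed
    }

    def core_of(k):
        verts = set(closed)
        while True:
            deg = {
                u: sum(1 for a, b in edges if u in (a, b) and a in verts and b in verts)
                for u in verts
            }
            drop = {u for u in verts if deg[u] < k}
            if not drop:
                return verts
            verts -= drop
            if not verts:
                return set()

    k_star, core = 0, set()
    for k in range(1, len(closed) + 1):
        c = core_of(k)
        if c:
            k_star, core = k, c
        else:
            break
    m = sum(1 for a, b in edges if a in core and b in core)
    nc = len(core)
    density = 2 * m / (nc * (nc - 1)) if nc > 1 else 0.0
    return k_star * density


# -- exact hypergeometric tail -------------------------------------------

def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] by exact rational summation."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


def bh_oracle(ps):
    """Hand step-up: p_(i) * m / i with running minimum from the top."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 1.0


def best_match_jaccard(block, modules, members_of=lambda m: m.members) -> float:
    return max((jaccard(block, members_of(m)) for m in modules), default=0.0)
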