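"""Connectivity significance of a gene set on an interactome.

Two localization statistics are compared against a resampling null of
equal-size random node sets:

* **LCC** -- size of the largest connected component of the subgraph induced
  by the gene set (larger than random = agglomeration; upper-tail test).
* **SHD** -- mean, over mapped seed proteins, of the shortest-path distance
  in the *full* network from each seed to its nearest other seed. A clique of
  seeds gives exactly 1.0; values near 1 indicate tight localization
  (lower-tail test). Seeds with no reachable co-seed are excluded from the
  mean and their count reported.

z-scores use the sample (n-1) standard deviation of the null draws; empirical
p-values use the (r+1)/(n_reps+1) pseudocount convention, so they lie in
(0, 1] and are never exactly zero at finite replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .graph_core import Interactome, _bfs_nearest

__all__ = [
    "NullSummary",
    "ShdResult",
    "lcc_size",
    "shd",
    "null_distribution",
    "significance",
]


class ShdResult(float):
    """SHD value that also carries the number of seeds excluded from the
    mean because they reach no other seed."""

    n_unreachable: int

    def __new__(cls, value: float, n_unreachable: int = 0) -> "ShdResult":
        obj = super().__new__(cls, value)
        obj.n_unreachable = n_unreachable
        return obj


@dataclass(frozen=True)
class NullSummary:
    statistic_name: str  # "LCC" or "SHD"
    observed: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    z_score: float  # nan when the null sd is zero
    z_defined: bool
    empirical_p: float
    n_reps: int
    rng_seed: int
    tail: str  # "upper" or "lower"
    n_undefined_null: int = 0

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_score": self.z_score if self.z_defined else float("nan"),
            "z_defined": self.z_defined,
            "empirical_p": self.empirical_p,
            "n_reps": self.n_reps,
            "rng_seed": self.rng_seed,
            "tail": self.tail,
            "n_undefined_null": self.n_undefined_null,
        }


# -- statistics ----------------------------------------------------------

def _lcc_from_adj(adj: dict[str, list[str]], members: set[str]) -> int:
    """Largest component of the subgraph induced on ``members`` (flood fill
    over a plain adjacency dict; no networkx objects in the inner loop)."""
    best = 0
    unseen = set(members)
    while unseen:
        start = unseen.pop()
        size = 1
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v in unseen:
                    unseen.discard(v)
                    size += 1
                    stack.append(v)
        if size > best:
            best = size
    return best


def lcc_size(g: Interactome, genes: Iterable[str]) -> int:
    """Size of the largest connected component of the gene-induced subgraph;
    0 when no gene maps to the network."""
    members = set(genes) & set(g.graph.nodes)
    if not members:
        return 0
    # neighbors outside `members` are skipped inside _lcc_from_adj via `unseen`
    adj = {v: list(g.graph[v]) for v in members}
    return _lcc_from_adj(adj, members)


def shd(g: Interactome, genes: Iterable[str]) -> ShdResult:
    """Mean distance from each mapped seed to its nearest other seed, in the
    full network. Requires at least 2 mapped genes."""
    members = sorted(set(genes) & set(g.graph.nodes))
    if len(members) < 2:
        raise ValueError(f"need >= 2 mapped genes for SHD, got {len(members)}")
    return _shd(g.graph, members)


def _shd(graph, members: Sequence[str]) -> ShdResult:
    member_set = set(members)
    dists = []
    unreachable = 0
    for s in members:
        member_set.discard(s)
        d = _bfs_nearest(graph, s, member_set)
        member_set.add(s)
        if d is None:
            unreachable += 1
        else:
            dists.append(d)
    if not dists:
        return ShdResult(float("nan"), unreachable)
    return ShdResult(sum(dists) / len(dists), unreachable)


# -- null model ----------------------------------------------------------

def _degree_bins(g: Interactome) -> dict[int, list[str]]:
    """Logarithmic (base-2) degree bins; degree-0 nodes get bin -1."""
    bins: dict[int, list[str]] = {}
    for v in sorted(g.graph.nodes):
        d = g.graph.degree[v]
        b = int(math.log2(d)) if d > 0 else -1
        bins.setdefault(b, []).append(v)
    return bins


def _sample_set(
    g: Interactome,
    set_size: int,
    rng: np.random.Generator,
    mode: str,
    reference: Sequence[str] | None,
    all_nodes: list[str],
    bins: dict[int, list[str]] | None,
) -> list[str]:
    if mode == "uniform":
        idx = rng.choice(len(all_nodes), size=set_size, replace=False)
        return [all_nodes[i] for i in idx]
    if mode == "degree_binned":
        assert reference is not None and bins is not None
        chosen: set[str] = set()
        out: list[str] = []
        bin_keys = sorted(bins)
        for seed in reference:
            d = g.graph.degree[seed]
            b = int(math.log2(d)) if d > 0 else -1
            # widen to neighboring bins when the home bin is exhausted
            for width in range(len(bin_keys) + 1):
                cands = [
                    v
                    for k in bin_keys
                    if abs(k - b) <= width
                    for v in bins[k]
                    if v not in chosen
                ]
                if cands:
                    pick = cands[rng.integers(len(cands))]
                    chosen.add(pick)
                    out.append(pick)
                    break
            else:  # pragma: no cover - only if set_size > |nodes|
                raise ValueError("cannot draw a degree-matched set")
        return out
    raise ValueError(f"unknown sampling mode {mode!r}")


def null_distribution(
    g: Interactome,
    set_size: int,
    n_reps: int,
    statistic: str,
    rng_seed: int,
    mode: str = "uniform",
    match_degrees_of: Iterable[str] | None = None,
) -> np.ndarray:
    """``n_reps`` draws of the statistic over random node sets of exactly
    ``set_size`` sampled without replacement.

    Fully reproducible: replicate ``i`` uses an RNG stream derived from
    ``(rng_seed, i)``, so the vector does not depend on evaluation order.
    ``degree_binned`` mode replaces each gene of ``match_degrees_of`` with a
    node from the same logarithmic degree bin.
    """
    vals = _null_both(g, set_size, n_reps, rng_seed, mode, match_degrees_of)
    if statistic == "LCC":
        return vals[0]
    if statistic == "SHD":
        return vals[1]
    raise ValueError(f"unknown statistic {statistic!r}")


def _null_both(
    g: Interactome,
    set_size: int,
    n_reps: int,
    rng_seed: int,
    mode: str = "uniform",
    match_degrees_of: Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LCC and SHD null vectors computed on the same sampled node sets."""
    all_nodes = sorted(g.graph.nodes)
    if set_size > len(all_nodes):
        raise ValueError(
            f"set_size {set_size} exceeds network size {len(all_nodes)}"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reference = None
    bins = None
    if mode == "degree_binned":
        if match_degrees_of is None:
            raise ValueError("degree_binned mode needs match_degrees_of")
        reference = sorted(set(match_degrees_of) & set(all_nodes))
        if len(reference) != set_size:
            raise ValueError("set_size must equal the mapped reference size")
        bins = _degree_bins(g)
    graph = g.graph
    lcc_vals = np.empty(n_reps)
    shd_vals = np.empty(n_reps)
    children = np.random.SeedSequence(rng_seed).spawn(n_reps)
    for i in range(n_reps):
        rng = np.random.default_rng(children[i])
        nodes = _sample_set(g, set_size, rng, mode, reference, all_nodes, bins)
        member_set = set(nodes)
        adj = {v: list(graph[v]) for v in member_set}
        lcc_vals[i] = _lcc_from_adj(adj, set(member_set))
        shd_vals[i] = float(_shd(graph, sorted(member_set))) if set_size >= 2 else np.nan
    return lcc_vals, shd_vals


def _summarize(
    name: str,
    observed: float,
    null_values: np.ndarray,
    tail: str,
    n_reps: int,
    rng_seed: int,
) -> NullSummary:
    finite = null_values[~np.isnan(null_values)]
    n_undef = int(len(null_values) - len(finite))
    mean = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    z_defined = sd > 0
    z = (observed - mean) / sd if z_defined else float("nan")
    if tail == "upper":
        r = int(np.sum(finite >= observed))
    else:
        r = int(np.sum(finite <= observed))
    p = (r + 1) / (len(finite) + 1)
    return NullSummary(
        statistic_name=name,
        observed=float(observed),
        null_values=null_values,
        null_mean=mean,
        null_sd=sd,
        z_score=float(z),
        z_defined=z_defined,
        empirical_p=float(p),
        n_reps=n_reps,
        rng_seed=rng_seed,
        tail=tail,
        n_undefined_null=n_undef,
    )


def significance(
    g: Interactome,
    genes: Iterable[str],
    n_reps: int = 1000,
    rng_seed: int = 0,
    mode: str = "uniform",
) -> tuple[NullSummary, NullSummary]:
    """LCC and SHD null summaries for a gene set.

    Both statistics are evaluated on the same random node sets (equal to the
    mapped seed-list size, sampled without replacement). The LCC test is
    upper-tailed (connectivity enrichment); SHD is lower-tailed (distances
    shrink when genes co-localize).
    """
    genes = set(genes)
    mapped = sorted(genes & set(g.graph.nodes))
    if len(mapped) < 2:
        raise ValueError("need >= 2 mapped genes for significance analysis")
    obs_lcc = lcc_size(g, mapped)
    obs_shd = shd(g, mapped)
    lcc_null, shd_null = _null_both(
        g, len(mapped), n_reps, rng_seed, mode, match_degrees_of=mapped
        if mode == "degree_binned"
        else None,
    )
    return (
        _summarize("LCC", obs_lcc, lcc_null, "upper", n_reps, rng_seed),
        _summarize("SHD", float(obs_shd), shd_null, "lower", n_reps, rng_seed),
    )
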