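"""Synthetic interactomes with planted structure, seed-score tables, and
gene-set collections -- everything the pipeline consumes, generated offline
with a single RNG seed and byte-stable outputs.

The generator emulates the statistical shape of a disease-gene network
study: a sparse heavy-tailed background network (preferential attachment by
default; Erdos-Renyi for analytically transparent tests), planted dense
blocks standing in for protein complexes / disease modules, a seed-gene
score table concentrated in the planted blocks with graded inference
scores, and gene sets with controlled overlap to chosen blocks.

Wiring convention: the background model spans the non-block nodes; each
block is wired internally with Bernoulli(p_within) and to the background
with Bernoulli(p_between). Planted blocks are pairwise non-adjacent --
inter-block connectivity arises only through background paths. A direct
edge between two equally dense blocks would let MCODE's greedy growth walk
across it and merge the blocks (their vertex weights pass each other's
inclusion threshold), making the planted truth unrecoverable by design
rather than by failure of the method.

The ground truth (block memberships, seed draws, set overlaps) is written
to a JSON record consumed only by tests, never by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import Interactome
from .enrichment import GeneSetCollection

__all__ = [
    "GeneSetSpec",
    "SyntheticSpec",
    "SyntheticData",
    "generate",
    "default_paper_like_spec",
    "write_synthetic",
]


@dataclass(frozen=True)
class GeneSetSpec:
    """One synthetic gene set: ``overlaps`` lists (block index, overlap
    count) pairs; the remainder is filled from non-block background."""

    name: str
    size: int
    overlaps: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    n_nodes: int = 1000
    background_model: str = "scale_free"  # or "er"
    background_param: float = 3  # attachment count (BA) or edge prob (ER)
    planted_modules: tuple[tuple[int, float], ...] = ()  # (size, p_within)
    p_between: float = 0.005
    seed_gene_fraction_in_modules: float = 0.7
    n_seed_genes: int = 100
    n_decoy_genes: int = 200
    score_range_selected: tuple[float, float] = (40.5, 100.0)
    score_range_unselected: tuple[float, float] = (1.0, 39.5)
    gene_set_specs: tuple[GeneSetSpec, ...] = ()
    rng_seed: int = 0

    def validate(self) -> None:
        sizes = [s for s, _ in self.planted_modules]
        if sum(sizes) > self.n_nodes:
            raise ValueError("planted module sizes exceed n_nodes")
        for s, p in self.planted_modules:
            if s < 2 or not 0 < p <= 1:
                raise ValueError(f"bad planted module ({s}, {p})")
        if not 0 <= self.seed_gene_fraction_in_modules <= 1:
            raise ValueError("seed_gene_fraction_in_modules must be in [0,1]")
        for gs in self.gene_set_specs:
            total_overlap = 0
            for mi, count in gs.overlaps:
                if mi >= len(self.planted_modules):
                    raise ValueError(f"gene set {gs.name}: no block {mi}")
                if count > sizes[mi]:
                    raise ValueError(
                        f"gene set {gs.name}: overlap {count} exceeds block "
                        f"{mi} size {sizes[mi]}"
                    )
                total_overlap += count
            if total_overlap > gs.size:
                raise ValueError(
                    f"gene set {gs.name}: overlaps exceed the set size"
                )
        if self.n_seed_genes + self.n_decoy_genes > self.n_nodes:
            raise ValueError("seed + decoy genes exceed n_nodes")
        lo, hi = self.score_range_selected
        if lo >= hi:
            raise ValueError("empty selected score range")


@dataclass
class SyntheticData:
    interactome: Interactome
    seed_table: pd.DataFrame  # columns: gene, inference_score
    gene_sets: GeneSetCollection
    truth: dict


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one synthetic dataset; byte-identical for identical rng_seed."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    names = [_gene_name(i) for i in range(spec.n_nodes)]
    perm = rng.permutation(spec.n_nodes)

    # planted blocks take the first slots of the permutation
    blocks: list[list[str]] = []
    cursor = 0
    for size, _ in spec.planted_modules:
        blocks.append(sorted(names[j] for j in perm[cursor : cursor + size]))
        cursor += size
    background = sorted(names[j] for j in perm[cursor:])
    block_nodes = sorted(x for b in blocks for x in b)

    g = nx.Graph()
    g.add_nodes_from(
        (v, {"chemical_count": 0, "sources": {"synthetic"}}) for v in names
    )

    # background model over non-block nodes
    n_bg = len(background)
    if spec.background_model == "scale_free":
        m = int(spec.background_param)
        bg = nx.barabasi_albert_graph(n_bg, m, seed=int(rng.integers(2**31)))
    elif spec.background_model == "er":
        bg = nx.gnp_random_graph(
            n_bg, float(spec.background_param), seed=int(rng.integers(2**31))
        )
    else:
        raise ValueError(f"unknown background model {spec.background_model!r}")
    g.add_edges_from((background[u], background[v]) for u, v in bg.edges)

    # block internals: Bernoulli(p_within)
    for block, (_, p_within) in zip(blocks, spec.planted_modules):
        for i in range(len(block)):
            draws = rng.random(len(block) - i - 1)
            for off, r in enumerate(draws, start=i + 1):
                if r < p_within:
                    g.add_edge(block[i], block[off])

    # block-to-background: Bernoulli(p_between)
    for block in blocks:
        for u in block:
            draws = rng.random(n_bg)
            for j in np.nonzero(draws < spec.p_between)[0]:
                g.add_edge(u, background[j])

    # seed genes: stated fraction from blocks (proportional to size), rest
    # uniform from the background
    n_planted = round(spec.seed_gene_fraction_in_modules * spec.n_seed_genes)
    n_planted = min(n_planted, len(block_nodes))
    seed_genes: list[str] = []
    if blocks and n_planted:
        sizes = np.array([len(b) for b in blocks], dtype=float)
        quota = np.floor(n_planted * sizes / sizes.sum()).astype(int)
        while quota.sum() < n_planted:  # distribute rounding remainder
            quota[int(np.argmax(sizes / (quota + 1)))] += 1
        for block, q in zip(blocks, quota):
            q = min(int(q), len(block))
            idx = rng.choice(len(block), size=q, replace=False)
            seed_genes.extend(block[i] for i in sorted(idx))
    n_rest = spec.n_seed_genes - len(seed_genes)
    idx = rng.choice(len(background), size=n_rest, replace=False)
    seed_genes.extend(background[i] for i in sorted(idx))
    seed_genes = sorted(seed_genes)

    # score table: seeds above threshold, decoys below
    lo, hi = spec.score_range_selected
    seed_scores = lo + (hi - lo) * rng.random(len(seed_genes))
    non_seeds = sorted(set(names) - set(seed_genes))
    idx = rng.choice(len(non_seeds), size=spec.n_decoy_genes, replace=False)
    decoys = [non_seeds[i] for i in sorted(idx)]
    dlo, dhi = spec.score_range_unselected
    decoy_scores = dlo + (dhi - dlo) * rng.random(len(decoys))
    table = pd.DataFrame(
        {
            "gene": seed_genes + decoys,
            "inference_score": np.concatenate([seed_scores, decoy_scores]).round(4),
        }
    ).sort_values("gene").reset_index(drop=True)

    # chemical-count node attribute: seeds get a small positive support count
    counts = dict(zip(seed_genes, rng.integers(1, 30, size=len(seed_genes))))
    for v, c in counts.items():
        g.nodes[v]["chemical_count"] = int(c)

    # gene sets with controlled overlap to blocks; filler avoids all blocks
    non_block_pool = sorted(set(names) - set(block_nodes))
    sets: dict[str, frozenset[str]] = {}
    set_truth: dict[str, dict] = {}
    for gs in spec.gene_set_specs:
        members: list[str] = []
        for mi, count in gs.overlaps:
            idx = rng.choice(len(blocks[mi]), size=count, replace=False)
            members.extend(blocks[mi][i] for i in sorted(idx))
        n_fill = gs.size - len(members)
        if n_fill > len(non_block_pool):
            raise ValueError(f"gene set {gs.name}: not enough background genes")
        idx = rng.choice(len(non_block_pool), size=n_fill, replace=False)
        members.extend(non_block_pool[i] for i in sorted(idx))
        sets[gs.name] = frozenset(members)
        set_truth[gs.name] = {
            "size": gs.size,
            "overlaps": [[mi, count] for mi, count in gs.overlaps],
        }
    collection = GeneSetCollection(
        name="synthetic_sets",
        sets=sets,
        descriptions={k: "synthetic gene set" for k in sets},
    )

    truth = {
        "rng_seed": spec.rng_seed,
        "n_nodes": spec.n_nodes,
        "background_model": spec.background_model,
        "planted_blocks": [list(b) for b in blocks],
        "seed_genes": seed_genes,
        "gene_sets": set_truth,
        "triple_enriched_blocks": sorted(
            {
                mi
                for mi in range(len(blocks))
                if all(
                    any(o[0] == mi for o in gs.overlaps)
                    for gs in spec.gene_set_specs
                )
                and spec.gene_set_specs
            }
        ),
    }
    return SyntheticData(
        interactome=Interactome(g),
        seed_table=table,
        gene_sets=collection,
        truth=truth,
    )


def default_paper_like_spec(rng_seed: int = 0) -> SyntheticSpec:
    """Desk-scale analogue of a disease-gene interactome study: 3000 genes,
    scale-free background, four planted modules of 60-74 members, 300 seed
    genes (70% inside modules) scored above a threshold of 40, and three
    evidence gene-set collections that overlap the first two modules."""
    return SyntheticSpec(
        n_nodes=3000,
        background_model="scale_free",
        background_param=3,
        planted_modules=((60, 0.9), (65, 0.9), (70, 0.9), (74, 0.9)),
        p_between=0.004,
        seed_gene_fraction_in_modules=0.7,
        n_seed_genes=300,
        n_decoy_genes=700,
        score_range_selected=(40.5, 100.0),
        score_range_unselected=(1.0, 39.5),
        gene_set_specs=(
            GeneSetSpec("GWAS", 120, ((0, 25), (1, 25))),
            GeneSetSpec("DEG", 150, ((0, 30), (1, 30))),
            GeneSetSpec("BRAIN", 200, ((0, 35), (1, 35))),
        ),
        rng_seed=rng_seed,
    )


def write_synthetic(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    """Emit the exact formats the pipeline reads: edge-list TSV, score TSV,
    GMT, and the truth JSON (tests only)."""
    from .graph_core import write_graph
    from .enrichment import write_gmt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out_dir / "edges.tsv",
        "scores": out_dir / "scores.tsv",
        "gmt": out_dir / "gene_sets.gmt",
        "truth": out_dir / "truth.json",
    }
    write_graph(data.interactome, paths["edges"], format="tsv")
    data.seed_table.to_csv(paths["scores"], sep="\t", index=False)
    write_gmt(data.gene_sets, paths["gmt"])
    # one GMT per set as well: evidence lists usually arrive as separate
    # files, and the all-collections prioritization rule needs them distinct
    for set_name in sorted(data.gene_sets.sets):
        single = GeneSetCollection(
            name=set_name,
            sets={set_name: data.gene_sets.sets[set_name]},
            descriptions={set_name: data.gene_sets.descriptions.get(set_name, "")},
        )
        p = out_dir / f"gene_set_{set_name}.gmt"
        write_gmt(single, p)
        paths[f"gmt_{set_name}"] = p
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1, sort_keys=True)
    return paths
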