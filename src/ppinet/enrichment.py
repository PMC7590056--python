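"""Gene-set overrepresentation: exact tests, BH-FDR, GMT I/O, and the
multi-collection module-prioritization rule.

For a query of size n drawn from a universe of size N containing a gene set
of size K, the overlap k is tested with the hypergeometric upper tail
P[X >= k] -- identical to the one-sided (greater) Fisher exact p of the
corresponding 2x2 table. BH adjustment is applied within each gene-set
collection. Module prioritization follows the "significant in every required
collection" rule on raw p-values (the per-set exact tests), with modules
ranked by summed -log10 p; BH-adjusted values are reported everywhere for
transparency.

The background universe is the single most result-sensitive free choice in
overrepresentation analysis; it is an explicit parameter (default: the
interactome node set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph_core import normalize_symbol
from .mcode import NetworkModule

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper_tail",
    "fisher_one_sided",
    "bh_adjust",
    "module_enrichment",
    "prioritize_modules",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named collection of gene sets (e.g. one GMT file)."""

    name: str
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (set name TAB description TAB genes...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 GMT fields")
            set_name, desc = fields[0], fields[1]
            genes = frozenset(
                normalize_symbol(x) for x in fields[2:] if x.strip()
            )
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {set_name!r} is empty")
            if set_name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            sets[set_name] = genes
            descriptions[set_name] = desc
    return GeneSetCollection(name=name or path.stem, sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Canonical-order GMT writer (sets and genes sorted)."""
    with open(path, "w") as fh:
        for set_name in sorted(collection.sets):
            desc = collection.descriptions.get(set_name, "")
            genes = "\t".join(sorted(collection.sets[set_name]))
            fh.write(f"{set_name}\t{desc}\t{genes}\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    Equals the one-sided Fisher exact p of the 2x2 table with margins
    (K, n, N). ``phyper(k-1, ..., lower.tail=FALSE)`` semantics: the upper
    tail includes k itself.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0) or 5e-324  # keep p in (0, 1]


def fisher_one_sided(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test of a 2x2 table [[a,b],[c,d]].

    Returns (odds_ratio, p). The odds ratio is the sample estimate
    a*d / (b*c): infinity when b*c = 0 with a*d > 0, nan when both products
    vanish. The p-value is the hypergeometric upper tail of the table's
    margins.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    p = hypergeom_upper_tail(a, a + b, a + c, a + b + c + d)
    return odds, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1; invariant to the
    order of the input vector."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def module_enrichment(
    modules: Sequence[NetworkModule],
    collections: Sequence[GeneSetCollection],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Overrepresentation of every module in every set of every collection.

    Genes outside the universe are dropped (with a warning) before counting;
    BH adjustment is applied within each collection. Columns include the 2x2
    counts, odds ratio, raw and adjusted p, gene ratio, -log10 p, and the
    semicolon-joined hit list.
    """
    universe = set(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    rows = []
    for coll in collections:
        for set_name in sorted(coll.sets):
            gene_set = coll.sets[set_name]
            outside = gene_set - universe
            if outside:
                logger.warning(
                    "%s/%s: %d genes outside universe dropped",
                    coll.name, set_name, len(outside),
                )
            K = len(gene_set & universe)
            for m in modules:
                query = m.members & universe
                dropped = len(m.members) - len(query)
                if dropped:
                    logger.warning(
                        "module %s: %d members outside universe dropped",
                        m.label, dropped,
                    )
                n = len(query)
                hits = sorted(query & gene_set)
                k = len(hits)
                odds, p = fisher_one_sided(
                    [[k, K - k], [n - k, N - K - n + k]]
                )
                rows.append(
                    {
                        "module": m.label,
                        "collection": coll.name,
                        "set_name": set_name,
                        "k": k,
                        "K": K,
                        "n": n,
                        "N": N,
                        "odds_ratio": odds,
                        "p_value": p,
                        "gene_ratio": k / n if n else float("nan"),
                        "neg_log10_p": -math.log10(p),
                        "hits": ";".join(hits),
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adjusted"] = np.nan
    for coll_name in df["collection"].unique():
        mask = df["collection"] == coll_name
        df.loc[mask, "p_adjusted"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    cols = [
        "module", "collection", "set_name", "k", "K", "n", "N",
        "odds_ratio", "p_value", "p_adjusted", "gene_ratio",
        "neg_log10_p", "hits",
    ]
    return df[cols].sort_values(["collection", "set_name", "module"]).reset_index(drop=True)


def prioritize_modules(
    results: pd.DataFrame,
    alpha: float = 0.05,
    required_collections: Sequence[str] | None = None,
) -> list[str]:
    """Modules significant (raw p < alpha) in EVERY required collection,
    ranked by combined evidence (sum over required collections of
    -log10 of the collection's best p). Returns ordered module labels;
    empty when no module qualifies.

    A module is significant within a collection when at least one of the
    collection's sets overlaps it at p < alpha (collections standing in for
    single evidence gene sets reduce to the plain per-set rule).
    """
    if results.empty:
        return []
    required = list(required_collections or sorted(results["collection"].unique()))
    missing = set(required) - set(results["collection"].unique())
    if missing:
        raise ValueError(f"collections absent from results: {sorted(missing)}")
    scored: list[tuple[float, str]] = []
    for label in results["module"].unique():
        sub = results[results["module"] == label]
        best = {}
        for coll in required:
            ps = sub.loc[sub["collection"] == coll, "p_value"]
            if ps.empty:
                raise ValueError(f"module {label} missing results for {coll!r}")
            best[coll] = float(ps.min())
        if all(best[coll] < alpha for coll in required):
            score = sum(-math.log10(best[coll]) for coll in required)
            scored.append((score, label))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [label for _, label in scored]
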