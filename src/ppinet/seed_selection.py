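"""Seed-gene selection from a gene-disease inference-score table.

Gene-disease association tables (CTD-style) rank genes by an inference score
derived from shared chemical evidence. Seeds are the genes whose score
exceeds a threshold; the default comparison is strict ``>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .graph_core import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = ["SeedList", "read_score_table", "select_seeds", "write_seed_list"]


@dataclass(frozen=True)
class SeedList:
    """Ranked (symbol, score) pairs, descending by score with symbol
    tie-break, plus the applied threshold and the selected subset."""

    entries: tuple[tuple[str, float], ...]
    threshold: float
    strict: bool = True

    @property
    def selected(self) -> tuple[tuple[str, float], ...]:
        if self.strict:
            return tuple(e for e in self.entries if e[1] > self.threshold)
        return tuple(e for e in self.entries if e[1] >= self.threshold)

    @property
    def selected_genes(self) -> list[str]:
        return [sym for sym, _ in self.selected]

    def __len__(self) -> int:
        return len(self.entries)


def read_score_table(
    path: str | Path,
    symbol_col: str = "gene",
    score_col: str = "inference_score",
) -> list[tuple[str, float]]:
    """Read a TSV/CSV score table into normalized, descending-sorted pairs.

    Duplicate symbols keep their maximum score (logged). Rows whose score
    does not parse as a real number raise with the offending row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (symbol_col, score_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path} header")
    scores = pd.to_numeric(df[score_col], errors="coerce")
    bad = df.index[scores.isna()].tolist()
    if bad:
        # +2: header line and 1-based numbering
        raise ValueError(
            f"unparseable score in {path} at rows {[i + 2 for i in bad[:10]]}"
        )
    pairs: dict[str, float] = {}
    n_dup = 0
    for sym, score in zip(df[symbol_col].map(normalize_symbol), scores):
        if sym in pairs:
            n_dup += 1
            pairs[sym] = max(pairs[sym], float(score))
        else:
            pairs[sym] = float(score)
    if n_dup:
        logger.warning(
            "%s: %d duplicate symbols collapsed (max score kept)", path, n_dup
        )
    return sorted(pairs.items(), key=lambda e: (-e[1], e[0]))


def select_seeds(
    pairs: Iterable[tuple[str, float]],
    threshold: float,
    strict: bool = True,
) -> SeedList:
    """Threshold the score-ranked pairs into a :class:`SeedList`.

    The comparison is strict ``>`` by default; ``strict=False`` switches to
    ``>=``. An empty selection warns but is not an error.
    """
    if not (threshold == threshold and abs(threshold) != float("inf")):
        raise ValueError(f"threshold must be finite, got {threshold!r}")
    entries = tuple(
        sorted(((s, float(v)) for s, v in pairs), key=lambda e: (-e[1], e[0]))
    )
    sl = SeedList(entries=entries, threshold=float(threshold), strict=strict)
    n = len(sl.selected)
    if n == 0:
        logger.warning("no genes pass threshold %s", threshold)
    else:
        logger.info("%d of %d genes pass threshold %s", n, len(entries), threshold)
    return sl


def write_seed_list(seeds: SeedList, path: str | Path) -> None:
    selected = {s for s, _ in seeds.selected}
    with open(path, "w") as fh:
        fh.write("gene\tinference_score\tselected\n")
        for sym, score in seeds.entries:
            fh.write(f"{sym}\t{score:g}\t{int(sym in selected)}\n")
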