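"""Downstream analyses over scored association tables.

Covers expression breadth (how many tissues a gene is expressed in, and
how bimodal that distribution is between tissue-specific and ubiquitous
genes), multi-dataset consistency (Venn-style overlap of association sets
restricted to a shared gene/tissue universe), the consensus mRNA reference
set (pairs supported at high confidence by several transcriptome datasets),
pooled evidence-type comparison, and the integrated-union vs. single-dataset
benchmark against a gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CONFIDENCE_LEVELS, ConfidenceCutoffs, classify_level_index
from .tables import AssociationTable, GoldStandard

__all__ = [
    "BreadthHistogram",
    "expression_breadth",
    "bimodality_fraction",
    "shared_universe",
    "venn_counts",
    "overlap_report",
    "build_mrna_reference",
    "pool_evidence",
    "integrated_vs_single",
    "IntegrationComparison",
]


def _level_rank(level: str) -> int:
    try:
        return CONFIDENCE_LEVELS.index(level)
    except ValueError:
        raise ValueError(f"unknown confidence level {level!r}") from None


# ---------------------------------------------------------------------------
# expression breadth
# ---------------------------------------------------------------------------


@dataclass
class BreadthHistogram:
    """Number of genes per expression-breadth value 0..n_tissues."""

    counts: np.ndarray
    level: str
    n_tissues: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != self.n_tissues + 1:
            raise ValueError("histogram needs one bin per breadth 0..n_tissues")

    @property
    def n_expressed_genes(self) -> int:
        return int(self.counts[1:].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"breadth": np.arange(self.n_tissues + 1), "n_genes": self.counts}
        )


def expression_breadth(
    table: AssociationTable,
    cutoffs: ConfidenceCutoffs,
    level: str = "medium",
    n_tissues: Optional[int] = None,
) -> tuple:
    """Per-gene count of tissues expressed at (or above) a confidence level.

    Returns ``(breadth, histogram)`` where ``breadth`` maps gene -> number
    of tissues whose score classifies at or above ``level``, and the
    histogram bins genes by breadth (bin 0 holds genes present in the table
    whose every score falls below the level).
    """
    rank = _level_rank(level)
    if rank == 0:
        raise ValueError("level must be low, medium or high")
    if n_tissues is None:
        n_tissues = len(table.tissues)
    df = table.data
    ok = classify_level_index(df["score"], cutoffs) >= rank
    breadth = (
        pd.Series(ok.astype(int), index=df.index)
        .groupby(df["gene"])
        .sum()
        .astype(int)
    )
    counts = np.bincount(breadth.to_numpy(), minlength=n_tissues + 1)
    if len(counts) > n_tissues + 1:
        raise ValueError("a gene is expressed in more tissues than n_tissues")
    return breadth, BreadthHistogram(counts, level, n_tissues)


def bimodality_fraction(hist: BreadthHistogram, k: int) -> float:
    """Fraction of expressed genes in the two extreme breadth bands.

    Counts genes with breadth <= k or breadth >= T - k + 1 among genes with
    breadth >= 1; a value near 1 means the tissue-specific / ubiquitous
    dichotomy is sharp.
    """
    T = hist.n_tissues
    if not 1 <= k < T / 2:
        raise ValueError(f"k must satisfy 1 <= k < {T / 2}")
    total = hist.n_expressed_genes
    if total == 0:
        raise ValueError("no expressed genes in histogram")
    extreme = hist.counts[1 : k + 1].sum() + hist.counts[T - k + 1 :].sum()
    return float(extreme) / total


# ---------------------------------------------------------------------------
# dataset consistency
# ---------------------------------------------------------------------------


def shared_universe(tables: Sequence[AssociationTable]) -> tuple:
    """Genes and tissues covered by every table in the list."""
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    genes = reduce(lambda a, b: a & b, (t.genes for t in tables))
    tissues = reduce(lambda a, b: a & b, (t.tissues for t in tables))
    if not genes or not tissues:
        raise ValueError("tables share no common genes or no common tissues")
    return genes, tissues


def venn_counts(sets: Mapping[str, Iterable]) -> Dict[str, int]:
    """Exclusive membership-pattern counts over 1-5 named association sets.

    Keys are bitstrings in declared set order (``"101"`` = in the first and
    third set only); every element of the union lands in exactly one
    pattern, so the counts sum to the union size.
    """
    names = list(sets)
    if not 1 <= len(names) <= 5:
        raise ValueError("venn_counts supports 1-5 sets")
    sets = {name: set(s) for name, s in sets.items()}
    union = set().union(*sets.values())
    counts: Dict[str, int] = {}
    for elem in union:
        pattern = "".join("1" if elem in sets[n] else "0" for n in names)
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def overlap_report(
    counts: Mapping[str, int],
    names: Optional[Sequence[str]] = None,
    precision: int = 1,
) -> dict:
    """Summary fractions (as percentages of the union) from Venn counts.

    Reports the share of associations common to all sets, common to at
    least k sets for every k, and unique to each individual set, plus the
    exclusive per-pattern percentages.  Percentages are unrounded floats;
    ``precision`` is carried along for formatting.
    """
    if not counts:
        raise ValueError("empty Venn counts")
    k = len(next(iter(counts)))
    if names is None:
        names = [f"set{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names must match the pattern width")
    union = sum(counts.values())
    if union == 0:
        raise ValueError("empty union")

    def pct(c: int) -> float:
        return 100.0 * c / union

    shared_all = counts.get("1" * k, 0)
    by_at_least = {
        m: sum(c for p, c in counts.items() if p.count("1") >= m)
        for m in range(1, k + 1)
    }
    unique = {
        name: counts.get("0" * i + "1" + "0" * (k - i - 1), 0)
        for i, name in enumerate(names)
    }
    return {
        "union": union,
        "names": list(names),
        "precision": precision,
        "shared_by_all": shared_all,
        "shared_by_all_pct": pct(shared_all),
        "shared_by_at_least": {m: pct(c) for m, c in by_at_least.items()},
        "unique_to": {name: pct(c) for name, c in unique.items()},
        "pattern_pct": {p: pct(c) for p, c in sorted(counts.items())},
    }


# ---------------------------------------------------------------------------
# consensus reference set and evidence pooling
# ---------------------------------------------------------------------------


def _high_pairs(table: AssociationTable, cutoffs: ConfidenceCutoffs, rank: int) -> set:
    df = table.data
    ok = classify_level_index(df["score"], cutoffs) >= rank
    return set(zip(df.loc[ok, "gene"], df.loc[ok, "tissue"]))


def build_mrna_reference(
    tables: Sequence[AssociationTable],
    cutoffs: Mapping[str, ConfidenceCutoffs],
    min_support: int = 3,
) -> set:
    """Consensus pairs with high-confidence support from >= min_support datasets."""
    if min_support > len(tables):
        raise ValueError("min_support exceeds the number of tables")
    rank = _level_rank("high")
    support: Dict[tuple, int] = {}
    for table in tables:
        for pair in _high_pairs(table, cutoffs[table.name], rank):
            support[pair] = support.get(pair, 0) + 1
    return {pair for pair, n in support.items() if n >= min_support}


def pool_evidence(
    tables: Sequence[AssociationTable],
    cutoffs: Mapping[str, ConfidenceCutoffs],
    level: str = "high",
) -> set:
    """Union of pairs classified at or above a level across the tables."""
    rank = _level_rank(level)
    pooled: set = set()
    for table in tables:
        pooled |= _high_pairs(table, cutoffs[table.name], rank)
    return pooled


# ---------------------------------------------------------------------------
# integration benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntegrationComparison:
    """Result of the integrated-union vs. top-N single-dataset benchmark."""

    fraction_integrated: float
    fraction_single: float
    n_extra: int
    n: int


def integrated_vs_single(
    integrated: Iterable[tuple],
    single: AssociationTable,
    gold: GoldStandard,
    universe: Optional[tuple] = None,
) -> IntegrationComparison:
    """Benchmark an integrated association set against one dataset's top scores.

    Restricted to the gene/tissue universe shared by the single dataset and
    the gold standard, the integrated set (size N) is compared with the N
    top-scoring associations of the single dataset (ties at the boundary
    broken by gene, then tissue).  Reports the gold-standard fraction of
    each list and the number of integrated associations absent from the
    single dataset altogether.
    """
    if universe is None:
        genes = single.genes & gold.genes
        tissues = single.tissues & gold.tissues
    else:
        genes, tissues = (set(u) for u in universe)
    gold_r = {(g, t) for g, t in gold.pairs if g in genes and t in tissues}
    integrated_r = {(g, t) for g, t in integrated if g in genes and t in tissues}
    n = len(integrated_r)
    df = single.data
    mask = df["gene"].isin(genes) & df["tissue"].isin(tissues)
    df = df.loc[mask]
    if n > len(df):
        raise ValueError(
            f"integrated set ({n}) larger than the single dataset's universe ({len(df)})"
        )
    df = df.sort_values(
        ["score", "gene", "tissue"], ascending=[False, True, True], kind="mergesort"
    )
    top = set(zip(df["gene"].iloc[:n], df["tissue"].iloc[:n]))
    single_all = set(zip(df["gene"], df["tissue"]))
    return IntegrationComparison(
        fraction_integrated=len(integrated_r & gold_r) / n if n else float("nan"),
        fraction_single=len(top & gold_r) / n if n else float("nan"),
        n_extra=len(integrated_r - single_all),
        n=n,
    )
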