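"""Core containers for gene-tissue association evidence.

An :class:`AssociationTable` holds one dataset's scored (gene, tissue)
associations; a :class:`GoldStandard` holds a set of curated associations
treated as uniformly correct.  Both round-trip through a plain TSV dialect
(tab-separated, UTF-8, header row, ``.`` decimal point, no quoting) and are
written sorted so that outputs diff bit-exactly between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["AssociationTable", "GoldStandard"]

#: canonical column order of the in-memory association frame
COLUMNS = ("gene", "tissue", "score")

#: column order of the on-disk TSV
TSV_COLUMNS = ("dataset", "gene", "tissue_term", "score")

#: float format used by every writer (deterministic, full double precision)
FLOAT_FORMAT = "%.12g"


@dataclass
class AssociationTable:
    """Per-dataset (gene, tissue) -> raw quality score records.

    Parameters
    ----------
    name:
        Dataset identifier (e.g. ``"gnf"``).
    family:
        Score family, one of ``expression_units``, ``rpkm``, ``fpkm``,
        ``est_count``, ``peptide_count``, ``ihc``, ``zscore``.
    data:
        Frame with columns ``gene``, ``tissue``, ``score``; at most one row
        per (gene, tissue) and no negative scores.
    """

    name: str
    family: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"association table missing column(s): {missing}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        dup = df.duplicated(["gene", "tissue"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate association ({row['gene']}, {row['tissue']}) "
                f"in dataset {self.name!r}"
            )
        if len(df) and (df["score"] < 0).any():
            row = df[df["score"] < 0].iloc[0]
            raise ValueError(
                f"negative score {row['score']} for ({row['gene']}, {row['tissue']})"
            )
        self.data = df

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set:
        return set(self.data["gene"])

    @property
    def tissues(self) -> set:
        return set(self.data["tissue"])

    def pairs(self) -> set:
        """The (gene, tissue) association set, scores discarded."""
        return set(zip(self.data["gene"], self.data["tissue"]))

    def sorted(self) -> pd.DataFrame:
        """Frame sorted by (gene, tissue) for reproducible output."""
        return self.data.sort_values(["gene", "tissue"], kind="mergesort").reset_index(
            drop=True
        )

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.sorted()
        out.insert(0, "dataset", self.name)
        out = out.rename(columns={"tissue": "tissue_term"})
        out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)

    @classmethod
    def from_tsv(cls, path: str | Path, family: str = "unknown") -> "AssociationTable":
        from .io import read_associations  # local import to avoid a cycle

        return read_associations(path, family=family)

    @classmethod
    def from_records(
        cls, name: str, family: str, records: Iterable[tuple]
    ) -> "AssociationTable":
        """Build from an iterable of (gene, tissue, score) triples."""
        df = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls(name, family, df)


@dataclass(frozen=True)
class GoldStandard:
    """Curated (gene, tissue) associations of uniformly highest confidence."""

    pairs: frozenset

    def __post_init__(self) -> None:
        for g, t in self.pairs:
            if not g or not t:
                raise ValueError("gold-standard pairs need non-empty identifiers")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair in self.pairs

    @property
    def genes(self) -> set:
        return {g for g, _ in self.pairs}

    @property
    def tissues(self) -> set:
        return {t for _, t in self.pairs}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "GoldStandard":
        return cls(frozenset((str(g), str(t)) for g, t in pairs))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(sorted(self.pairs), columns=["gene", "tissue_term"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GoldStandard":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("gene", "tissue_term"):
            if col not in df.columns:
                raise ValueError(f"gold standard file missing column {col!r}")
        return cls.from_pairs(zip(df["gene"], df["tissue_term"]))
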