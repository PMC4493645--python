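"""Per-dataset filtering, aggregation and scoring rules.

Each source technology carries its own conventions for turning raw
measurements into a (gene, tissue) -> score table:

* microarray expression units: drop cross-hybridizing (``_r/_i/_f/_x_at``)
  and control (``AFFX``) probe sets, map probes to genes through an alias
  file, average multiple probe sets per gene;
* EST clusters: sum EST counts over clusters mapping to the same gene;
* RNA-seq: use RPKM/FPKM values directly;
* mass spectrometry: digest the proteome in silico with trypsin (cleavage
  after K or R, up to two missed cleavages), assign observed peptides to
  the single gene whose theoretical digest contains them, and count the
  distinct peptides per tissue;
* immunohistochemistry: translate ordinal staining labels to the integers
  {0, 1, 3, 6} (consensus scoring lives in :mod:`tissuescore.ihc`).

The composition of these rules is :func:`build_association_table`.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calibration import ConfidenceCutoffs, TransformSpec
from .ontology import MajorTissueSet, OntologyDAG, map_to_major, match_tissue_name
from .tables import AssociationTable

__all__ = [
    "RawMeasurement",
    "DatasetProfile",
    "SCORE_FAMILIES",
    "filter_probe_sets",
    "map_aliases",
    "aggregate_gene_scores",
    "translate_staining",
    "tryptic_digest",
    "map_peptides_to_genes",
    "build_association_table",
    "read_alias_map",
    "STAINING_LEVELS",
]

log = logging.getLogger(__name__)

SCORE_FAMILIES = (
    "expression_units",
    "rpkm",
    "fpkm",
    "est_count",
    "peptide_count",
    "ihc",
    "zscore",
)


@dataclass(frozen=True)
class RawMeasurement:
    """One platform-level measurement before any mapping or aggregation."""

    source_id: str
    gene: str
    tissue: str
    value: object  # number, or ordinal staining label for IHC

    def __post_init__(self) -> None:
        if not self.tissue:
            raise ValueError("measurement tissue must be non-empty")
        if isinstance(self.value, (int, float)) and self.value < 0:
            raise ValueError(f"negative measurement value {self.value}")


@dataclass(frozen=True)
class DatasetProfile:
    """How one dataset is filtered, aggregated, thresholded and transformed."""

    name: str
    score_family: str
    aggregation: str  # "mean" | "sum"
    cutoffs: ConfidenceCutoffs
    transform: TransformSpec
    probe_filter: bool = False

    def __post_init__(self) -> None:
        if self.score_family not in SCORE_FAMILIES:
            raise ValueError(f"unknown score family {self.score_family!r}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(f"aggregation must be 'mean' or 'sum'")


# ---------------------------------------------------------------------------
# probe-set filtering (microarray platforms)
# ---------------------------------------------------------------------------

_PROBE_SUFFIX_RE = re.compile(r"_[rifx]_at$")


def filter_probe_sets(ids: Sequence[str]) -> list:
    """Drop cross-hybridizing and control probe-set names, keeping order.

    Removes names ending with ``_r_at``/``_i_at``/``_f_at``/``_x_at``
    (probes matching multiple targets) and names starting with ``AFFX``
    (spike-in controls).
    """
    return [
        pid
        for pid in ids
        if not pid.startswith("AFFX") and not _PROBE_SUFFIX_RE.search(pid)
    ]


# ---------------------------------------------------------------------------
# identifier aliasing
# ---------------------------------------------------------------------------


def read_alias_map(path) -> dict:
    """Read a 2-column TSV (alias, target) into alias -> tuple-of-targets."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ValueError("alias map needs two columns (alias, target)")
    out: dict = defaultdict(list)
    for alias, target in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if not alias or not target or pd.isna(alias) or pd.isna(target):
            raise ValueError("alias map contains empty identifiers")
        if target not in out[alias]:
            out[alias].append(target)
    return {k: tuple(v) for k, v in out.items()}


def map_aliases(
    measurements: Iterable[RawMeasurement], aliases: Mapping[str, Sequence[str]]
) -> list:
    """Replace each measurement's gene by its alias target(s).

    Measurements without an alias are dropped (count logged); a source
    mapping to k targets yields k measurements.
    """
    out = []
    dropped = 0
    for m in measurements:
        targets = aliases.get(m.gene)
        if not targets:
            dropped += 1
            continue
        for t in targets:
            out.append(RawMeasurement(m.source_id, t, m.tissue, m.value))
    if dropped:
        log.info("alias mapping dropped %d measurement(s) without a target", dropped)
    return out


def aggregate_gene_scores(values: Sequence[float], method: str) -> float:
    """Mean or sum of per-platform values for one (gene, tissue)."""
    values = list(values)
    if not values:
        raise ValueError("cannot aggregate an empty value list")
    if method == "mean":
        return sum(values) / len(values)
    if method == "sum":
        return float(sum(values))
    raise ValueError(f"unknown aggregation method {method!r}")


# ---------------------------------------------------------------------------
# immunohistochemistry staining labels
# ---------------------------------------------------------------------------

STAINING_LEVELS = {"not detected": 0, "low": 1, "medium": 3, "high": 6}


def translate_staining(label: str) -> int:
    """Ordinal staining label -> integer (not detected 0, low 1, medium 3, high 6)."""
    try:
        return STAINING_LEVELS[label.strip().lower()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown staining label {label!r}") from None


# ---------------------------------------------------------------------------
# in-silico tryptic digestion
# ---------------------------------------------------------------------------


def tryptic_digest(sequence: str, max_missed: int = 2) -> list:
    """All tryptic fragments of ``sequence`` with <= ``max_missed`` missed cleavages.

    Trypsin cleaves after every K or R (no proline exception; plain K/R
    cleavage is deterministic and a superset of the proline-aware rule).
    Returns ``(peptide, start)`` tuples, grouped by missed-cleavage count
    and ordered by position within each group.  With c internal cleavage
    sites the fragment count is sum_{j=0..m} max(0, c + 1 - j).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = sequence.strip().upper()
    if not seq:
        return []
    # cut points strictly inside the sequence, after each K/R
    bounds = [0]
    bounds += [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR"]
    bounds.append(len(seq))
    n_seg = len(bounds) - 1
    out = []
    for missed in range(max_missed + 1):
        for i in range(n_seg - missed):
            out.append((seq[bounds[i] : bounds[i + missed + 1]], bounds[i]))
    return out


def map_peptides_to_genes(
    observed: Iterable[tuple],
    proteome: Mapping[str, str],
    max_missed: int = 2,
    dataset: str = "proteomics",
) -> AssociationTable:
    """Assign observed peptides to genes and count unique peptides per tissue.

    ``observed`` yields (peptide, tissue, present) triples.  A peptide
    matches a gene iff it occurs in that gene's theoretical tryptic digest;
    peptides matching more than one gene are discarded as ambiguous.  The
    score of (gene, tissue) is the number of distinct matching peptides
    observed there.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    peptide_owners: dict = defaultdict(set)
    for gene, seq in proteome.items():
        for pep, _ in tryptic_digest(seq, max_missed):
            peptide_owners[pep].add(gene)
    unique_owner = {
        pep: next(iter(genes))
        for pep, genes in peptide_owners.items()
        if len(genes) == 1
    }
    seen: set = set()
    ambiguous = 0
    for pep, tissue, present in observed:
        if not present:
            continue
        pep = pep.strip().upper()
        gene = unique_owner.get(pep)
        if gene is None:
            if pep in peptide_owners:
                ambiguous += 1
            continue
        seen.add((gene, tissue, pep))
    if ambiguous:
        log.info("discarded %d observation(s) of shared peptides", ambiguous)
    counts: dict = defaultdict(int)
    for gene, tissue, _ in seen:
        counts[(gene, tissue)] += 1
    records = [(g, t, float(c)) for (g, t), c in sorted(counts.items())]
    return AssociationTable.from_records(dataset, "peptide_count", records)


# ---------------------------------------------------------------------------
# the per-dataset pipeline
# ---------------------------------------------------------------------------


def _resolve_tissue(
    label: str, dag: Optional[OntologyDAG], majors: Optional[MajorTissueSet]
):
    """Tissue label -> tuple of tissue terms (possibly several majors)."""
    if dag is None:
        return (label,)
    term = label if label in dag else match_tissue_name(label, dag)
    if term is None:
        return ()
    if majors is None:
        return (term,)
    return tuple(sorted(map_to_major(term, majors, dag)))


def build_association_table(
    measurements: Iterable[RawMeasurement],
    profile: DatasetProfile,
    aliases: Optional[Mapping[str, Sequence[str]]] = None,
    dag: Optional[OntologyDAG] = None,
    majors: Optional[MajorTissueSet] = None,
) -> AssociationTable:
    """Compose a dataset's full raw-measurement -> scored-association pipeline.

    Steps, in order: probe-set filtering (microarray profiles only), alias
    mapping, tissue-name resolution through the ontology (each term
    contributing to every major it back-maps to), then aggregation of all
    values per (gene, tissue term) with the profile's mean/sum rule.
    RPKM/FPKM values pass through unchanged except for the aggregation of
    samples that map to the same term.
    """
    measurements = list(measurements)
    if profile.probe_filter:
        kept = set(filter_probe_sets([m.source_id for m in measurements]))
        measurements = [m for m in measurements if m.source_id in kept]
    if aliases is not None:
        measurements = map_aliases(measurements, aliases)

    grouped: dict = defaultdict(list)
    unresolved = 0
    for m in measurements:
        value = m.value
        if profile.score_family == "ihc" and isinstance(value, str):
            value = translate_staining(value)
        terms = _resolve_tissue(m.tissue, dag, majors)
        if not terms:
            unresolved += 1
            continue
        for term in terms:
            grouped[(m.gene, term)].append(float(value))
    if unresolved:
        log.info(
            "%s: dropped %d measurement(s) with unresolvable tissue labels",
            profile.name,
            unresolved,
        )
    if not grouped:
        log.warning("%s: no measurements survived mapping; table is empty", profile.name)
        return AssociationTable.from_records(profile.name, profile.score_family, [])
    records = [
        (g, t, aggregate_gene_scores(vals, profile.aggregation))
        for (g, t), vals in sorted(grouped.items())
    ]
    return AssociationTable.from_records(profile.name, profile.score_family, records)
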