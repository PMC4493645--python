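"""Readers, writers, configuration and the end-to-end pipeline.

All tabular formats are plain TSV (tab-separated, UTF-8, header row, ``.``
decimal point, no quoting); every writer emits rows sorted on their natural
key so that two runs with the same seed produce byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from . import calibration as cal
from . import ihc as ihcmod
from . import simulate as sim
from .datasets import translate_staining
from .profiles import PUBLISHED_PROFILES
from .tables import FLOAT_FORMAT, AssociationTable, GoldStandard

__all__ = [
    "read_associations",
    "write_associations",
    "read_staining",
    "write_staining",
    "PipelineConfig",
    "run_pipeline",
    "PipelineError",
]

log = logging.getLogger(__name__)

TRANSCRIPTOME_DATASETS = ("gnf", "exon_array", "unigene", "rnaseq_atlas", "hpa_rnaseq")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------


def read_associations(path, family: str = "unknown") -> AssociationTable:
    """Read a (dataset, gene, tissue_term, score) TSV into a table.

    Errors name the missing column, the first non-numeric score line, or
    the first duplicated (gene, tissue) pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("dataset", "gene", "tissue_term", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() & df["score"].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        lineno = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: non-numeric score on line {lineno}")
    names = df["dataset"].unique()
    if len(names) > 1:
        raise ValueError(f"{path}: multiple dataset names {sorted(names)}")
    name = str(names[0]) if len(names) else "unknown"
    if family == "unknown" and name in PUBLISHED_PROFILES:
        family = PUBLISHED_PROFILES[name].score_family
    out = pd.DataFrame(
        {"gene": df["gene"], "tissue": df["tissue_term"], "score": scores}
    )
    return AssociationTable(name, family, out)


def write_associations(table: AssociationTable, path) -> None:
    table.to_tsv(path)


# ---------------------------------------------------------------------------
# staining tables
# ---------------------------------------------------------------------------


def read_staining(path) -> list:
    """Read a long-form (protein, antibody, tissue, staining) TSV.

    Staining entries may be ordinal labels ("high") or the integers
    0/1/3/6; each protein's matrix must be complete.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein", "antibody", "tissue", "staining"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")

    def as_value(x: str) -> int:
        try:
            return int(x)
        except ValueError:
            return translate_staining(x)

    df["value"] = df["staining"].map(as_value)
    tables = []
    for protein, grp in df.groupby("protein", sort=True):
        pivot = grp.pivot(index="antibody", columns="tissue", values="value")
        if pivot.isna().any().any():
            raise ValueError(f"{path}: incomplete staining matrix for {protein!r}")
        tables.append(
            ihcmod.StainingTable(
                protein=str(protein),
                antibodies=tuple(pivot.index),
                tissues=tuple(pivot.columns),
                values=pivot.to_numpy(dtype=int),
            )
        )
    return tables


def write_staining(tables, path) -> None:
    rows = []
    for t in tables:
        for i, ab in enumerate(t.antibodies):
            for j, tis in enumerate(t.tissues):
                rows.append((t.protein, ab, tis, int(t.values[i, j])))
    df = pd.DataFrame(rows, columns=["protein", "antibody", "tissue", "staining"])
    df.sort_values(["protein", "antibody", "tissue"], kind="mergesort").to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run.

    Either a ``simulation`` block or explicit input paths must be given.
    Dataset cutoffs and star transforms default to the shipped published
    values (see :mod:`tissuescore.profiles`).
    """

    outdir: Path = Path("tissuescore_out")
    seed: int = 1
    simulation: Optional[sim.SimulationConfig] = None
    association_paths: Dict[str, str] = field(default_factory=dict)
    gold_path: Optional[str] = None
    staining_path: Optional[str] = None
    curve_window: int = 100
    report_precision: int = 1
    fit_ihc_params: bool = True

    def validate(self) -> None:
        if self.simulation is None and not self.association_paths:
            raise ValueError(
                "config needs a simulation block or input association paths"
            )
        if self.simulation is None and self.gold_path is None:
            raise ValueError("config without simulation needs a gold-standard path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = None
        if "simulation" in raw and raw["simulation"] is not None:
            block = dict(raw["simulation"])
            if "antibody_counts" in block:
                block["antibody_counts"] = tuple(
                    (int(c), float(p)) for c, p in block["antibody_counts"]
                )
            if "profiles" in block:
                block["profiles"] = tuple(
                    sim.NoiseProfile(**p) for p in block["profiles"]
                )
            sim_cfg = sim.SimulationConfig(**block)
        inputs = raw.get("inputs", {}) or {}
        cfg = cls(
            outdir=Path(raw.get("outdir", "tissuescore_out")),
            seed=int(raw.get("seed", 1)),
            simulation=sim_cfg,
            association_paths=dict(inputs.get("associations", {}) or {}),
            gold_path=inputs.get("gold"),
            staining_path=inputs.get("staining"),
            curve_window=int(raw.get("curve_window", 100)),
            report_precision=int(raw.get("report_precision", 1)),
            fit_ihc_params=bool(raw.get("fit_ihc_params", True)),
        )
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _stage(name):
    """Decorator-ish helper: re-raise stage failures with the stage name."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def _fmt(x: float, precision: int) -> str:
    return f"{x:.{precision}f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> score -> calibrate -> analyze -> report.

    Writes association tables, enrichment curves, star-scored outputs,
    breadth histograms, Venn counts, the overlap report, the mRNA reference
    set and the integrated-vs-single comparison into ``config.outdir``, and
    returns a summary dictionary (also written as ``summary.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ------------------------------------------------------------- simulate
    with _stage("simulate"):
        if config.simulation is not None:
            scfg = replace(config.simulation, seed=config.seed)
            truth = sim.generate_truth(scfg)
            tables = {
                p.name: sim.simulate_dataset(truth, p, scfg.seed)
                for p in scfg.profiles
            }
            gold = sim.simulate_gold(
                truth, scfg.gold_coverage, scfg.gold_bias, scfg.seed
            )
            staining = sim.simulate_staining(
                truth,
                scfg.antibody_counts,
                scfg.antibody_error,
                scfg.seed,
                fraction=scfg.staining_fraction,
            )
        else:
            tables = {
                name: read_associations(path)
                for name, path in sorted(config.association_paths.items())
            }
            gold = GoldStandard.from_tsv(config.gold_path)
            staining = (
                read_staining(config.staining_path) if config.staining_path else []
            )
        gold.to_tsv(out / "gold.tsv")
        for name, table in sorted(tables.items()):
            table.to_tsv(out / f"associations_{name}.tsv")
            log.info("dataset %s: %d records", name, len(table))

    # ------------------------------------------------------------ ihc score
    with _stage("ihc-score"):
        if staining:
            if config.fit_ihc_params:
                params = ihcmod.fit_alpha_beta(
                    staining, gold, window=config.curve_window
                )
            else:
                params = ihcmod.IHCParams()
            summary["ihc_alpha"] = params.alpha
            summary["ihc_beta"] = params.beta
            ihc_table = ihcmod.score_staining(staining, params)
            tables["hpa_ihc"] = ihc_table
            ihc_table.to_tsv(out / "associations_hpa_ihc.tsv")
            log.info("ihc consensus: %d records", len(ihc_table))

    # ------------------------------------------------------------ calibrate
    with _stage("calibrate"):
        fit_rows = []
        summary["curves"] = {}
        for name, table in sorted(tables.items()):
            profile = PUBLISHED_PROFILES.get(name)
            curve = cal.enrichment_curve(table, gold, window=config.curve_window)
            curve.to_tsv(out / f"curve_{name}.tsv")
            fe = curve.points["fold_enrichment"]
            summary["curves"][name] = {
                "n_windows": len(curve),
                "fe_first_window": float(fe.iloc[0]),
                "fe_last_window": float(fe.iloc[-1]),
            }
            try:
                spec, rss = cal.fit_transform(curve, "log_linear")
                fit_rows.append(
                    (name, "log_linear", spec.params["a"], spec.params["b"], rss)
                )
            except ValueError as exc:
                log.warning("curve fit skipped for %s: %s", name, exc)
            if profile is not None:
                stars = profile.transform.evaluate(table.data["score"].to_numpy())
                star_df = table.data.assign(stars=np.round(stars, 6))
                star_df = star_df.sort_values(
                    ["gene", "tissue"], kind="mergesort"
                )
                star_df.to_csv(
                    out / f"stars_{name}.tsv",
                    sep="\t",
                    index=False,
                    float_format=FLOAT_FORMAT,
                )
        pd.DataFrame(
            fit_rows, columns=["dataset", "form", "a", "b", "rss"]
        ).to_csv(
            out / "transform_fits.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )

    # -------------------------------------------------------------- analyze
    with _stage("analyze"):
        cutoffs = {
            name: PUBLISHED_PROFILES[name].cutoffs
            for name in tables
            if name in PUBLISHED_PROFILES
        }

        summary["bimodality"] = {}
        for name, table in sorted(tables.items()):
            if name not in cutoffs:
                continue
            hist_frames = []
            for level in ("low", "medium", "high"):
                # breadth is relative to the tissues this dataset measured
                _, hist = an.expression_breadth(table, cutoffs[name], level)
                hist_frames.append(hist.to_frame().assign(level=level))
                if level == "medium" and hist.n_expressed_genes:
                    summary["bimodality"][name] = an.bimodality_fraction(hist, k=3)
            pd.concat(hist_frames).to_csv(
                out / f"breadth_{name}.tsv", sep="\t", index=False
            )

        transcriptome = [
            tables[n] for n in TRANSCRIPTOME_DATASETS if n in tables
        ]
        if len(transcriptome) >= 2:
            genes, tissues = an.shared_universe(transcriptome)
            summary["shared_universe"] = {
                "n_genes": len(genes),
                "n_tissues": len(tissues),
            }
            venn_rows = []
            summary["consistency"] = {}
            for level in ("low", "medium", "high"):
                named = {}
                for t in transcriptome:
                    pairs = an.pool_evidence([t], cutoffs, level)
                    named[t.name] = {
                        (g, ti) for g, ti in pairs if g in genes and ti in tissues
                    }
                counts = an.venn_counts(named)
                report = an.overlap_report(
                    counts, list(named), precision=config.report_precision
                )
                for pattern, count in sorted(counts.items()):
                    venn_rows.append((level, pattern, count))
                summary["consistency"][level] = {
                    "union": report["union"],
                    "shared_by_all_pct": report["shared_by_all_pct"],
                    "shared_by_at_least_4_pct": report["shared_by_at_least"].get(
                        4, float("nan")
                    ),
                }
            pd.DataFrame(
                venn_rows, columns=["level", "pattern", "count"]
            ).to_csv(out / "venn_transcriptome.tsv", sep="\t", index=False)

        reference = set()
        if len(transcriptome) >= 3:
            reference = an.build_mrna_reference(transcriptome, cutoffs, min_support=3)
            pd.DataFrame(
                sorted(reference), columns=["gene", "tissue_term"]
            ).to_csv(out / "mrna_reference.tsv", sep="\t", index=False)
            summary["mrna_reference_size"] = len(reference)
            summary["mrna_reference_not_in_gold"] = len(reference - gold.pairs)

        proteomics = [tables[n] for n in ("hpm", "hpa_ihc") if n in tables]
        pooled_trans = an.pool_evidence(transcriptome, cutoffs, "high") if transcriptome else set()
        pooled_prot = an.pool_evidence(proteomics, cutoffs, "high") if proteomics else set()
        evidence = {}
        if gold.pairs:
            evidence["curated"] = set(gold.pairs)
        if "textmining" in tables:
            evidence["textmining"] = an.pool_evidence(
                [tables["textmining"]], cutoffs, "medium"
            )
        if pooled_trans:
            evidence["transcriptomics"] = pooled_trans
        if pooled_prot:
            evidence["proteomics"] = pooled_prot
        if len(evidence) >= 2:
            counts_all = an.venn_counts(evidence)
            report_all = an.overlap_report(
                counts_all, list(evidence), precision=config.report_precision
            )
            pd.DataFrame(
                sorted(counts_all.items()), columns=["pattern", "count"]
            ).to_csv(out / "venn_evidence_unrestricted.tsv", sep="\t", index=False)
            ugenes = set.intersection(*({g for g, _ in s} for s in evidence.values()))
            utissues = set.intersection(*({t for _, t in s} for s in evidence.values()))
            restricted = {
                name: {(g, t) for g, t in s if g in ugenes and t in utissues}
                for name, s in evidence.items()
            }
            counts_r = an.venn_counts(restricted)
            report_r = an.overlap_report(
                counts_r, list(restricted), precision=config.report_precision
            )
            pd.DataFrame(
                sorted(counts_r.items()), columns=["pattern", "count"]
            ).to_csv(out / "venn_evidence_restricted.tsv", sep="\t", index=False)
            summary["evidence_overlap"] = {
                "restricted_union": report_r["union"],
                "restricted_ge2_pct": report_r["shared_by_at_least"].get(2, float("nan")),
                "unrestricted_union": report_all["union"],
                "unrestricted_unique_pct": report_all["shared_by_at_least"][1]
                - report_all["shared_by_at_least"].get(2, 0.0),
            }

        integrated = pooled_trans | pooled_prot
        if integrated and "gnf" in tables:
            comp = an.integrated_vs_single(integrated, tables["gnf"], gold)
            summary["integration"] = {
                "n": comp.n,
                "fraction_integrated": comp.fraction_integrated,
                "fraction_single": comp.fraction_single,
                "n_extra": comp.n_extra,
            }

    # --------------------------------------------------------------- report
    with _stage("report"):
        prec = config.report_precision
        lines = [f"tissuescore pipeline report (seed {config.seed})", ""]
        for name in sorted(tables):
            lines.append(f"dataset {name}: {len(tables[name])} associations")
        if "consistency" in summary:
            for level, rep in summary["consistency"].items():
                lines.append(
                    f"{level} confidence: {_fmt(rep['shared_by_all_pct'], prec)}% of "
                    f"{rep['union']} shared associations found by all transcriptome datasets"
                )
        if "integration" in summary:
            comp = summary["integration"]
            lines.append(
                f"integrated vs gnf (n={comp['n']}): "
                f"{_fmt(100 * comp['fraction_integrated'], prec)}% vs "
                f"{_fmt(100 * comp['fraction_single'], prec)}% in gold; "
                f"{comp['n_extra']} integrated associations absent from gnf"
            )
        (out / "summary.txt").write_text("".join(f"{ln}\n" for ln in lines))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
        )
    return summary
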