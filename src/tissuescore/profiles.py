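"""Published per-dataset confidence cutoffs and star transforms.

Each source dataset ships with low/medium/high cutoffs on its native score
scale and a calibrated transform onto the unified star confidence scale:

===============  =====================  ==================================
dataset          cutoffs (L/M/H)        stars(score)
===============  =====================  ==================================
unigene          1 / 10 / 20            6 / (1 + 0.229 * s**-7.898) - 1
gnf              50 / 100 / 250         log10(s) + 0.7
exon_array       50 / 100 / 250         2 * log10(s) - 3.56
rnaseq_atlas     0.5 / 1 / 5            log10(s) + 0.523
hpa_rnaseq       1 / 10 / 20            log10(s) - 0.176
hpa_ihc          0 / 1.1 / 1.9          s / 5.5
hpm              1 / 5 / 10             s / 30 + 0.5
textmining       0 / 2.5 / 3.5          s / 2.4, capped at 4 stars
===============  =====================  ==================================

All transforms clamp to [0, 5] stars except text mining, whose co-occurrence
z-scores are capped at 4 stars.
"""

from __future__ import annotations

from .calibration import ConfidenceCutoffs, TransformSpec
from .datasets import DatasetProfile

__all__ = ["PUBLISHED_PROFILES", "get_profile"]


def _p(name, family, aggregation, cutoffs, transform, probe_filter=False):
    return DatasetProfile(
        name=name,
        score_family=family,
        aggregation=aggregation,
        cutoffs=ConfidenceCutoffs(*cutoffs),
        transform=transform,
        probe_filter=probe_filter,
    )


PUBLISHED_PROFILES = {
    "unigene": _p(
        "unigene",
        "est_count",
        "sum",
        (1, 10, 20),
        TransformSpec("sigmoid", {"A": 6.0, "B": 0.229, "C": -7.898, "D": -1.0}),
    ),
    "gnf": _p(
        "gnf",
        "expression_units",
        "mean",
        (50, 100, 250),
        TransformSpec("log_linear", {"a": 1.0, "b": 0.7}),
        probe_filter=True,
    ),
    "exon_array": _p(
        "exon_array",
        "expression_units",
        "mean",
        (50, 100, 250),
        TransformSpec("log_linear", {"a": 2.0, "b": -3.56}),
    ),
    "rnaseq_atlas": _p(
        "rnaseq_atlas",
        "rpkm",
        "mean",
        (0.5, 1, 5),
        TransformSpec("log_linear", {"a": 1.0, "b": 0.523}),
    ),
    "hpa_rnaseq": _p(
        "hpa_rnaseq",
        "fpkm",
        "mean",
        (1, 10, 20),
        TransformSpec("log_linear", {"a": 1.0, "b": -0.176}),
    ),
    "hpa_ihc": _p(
        "hpa_ihc",
        "ihc",
        "mean",
        (0, 1.1, 1.9),
        TransformSpec("linear", {"a": 1 / 5.5, "b": 0.0}),
    ),
    "hpm": _p(
        "hpm",
        "peptide_count",
        "mean",
        (1, 5, 10),
        TransformSpec("linear", {"a": 1 / 30, "b": 0.5}),
    ),
    "textmining": _p(
        "textmining",
        "zscore",
        "mean",
        (0, 2.5, 3.5),
        TransformSpec("capped_linear", {"a": 1 / 2.4, "cap": 4.0}, ceiling=4.0),
    ),
}


def get_profile(name: str) -> DatasetProfile:
    """Look up a shipped dataset profile by name."""
    try:
        return PUBLISHED_PROFILES[name]
    except KeyError:
        raise KeyError(
            f"no published profile named {name!r}; "
            f"known: {sorted(PUBLISHED_PROFILES)}"
        ) from None
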