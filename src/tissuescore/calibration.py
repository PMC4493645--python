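"""Fold-enrichment calibration of raw quality scores.

Raw scores from heterogeneous platforms (expression units, RPKM/FPKM, EST
counts, peptide counts, staining consensus, z-scores) are made comparable
by benchmarking each dataset against a gold standard of curated gene-tissue
associations.  The central quantity is the *fold enrichment* of a set of
associations:

    FE = (fraction of the set found in the gold standard)
         / (fraction of all possible gene-tissue pairs found in the gold
            standard)

computed over the genes and tissues shared between the dataset and the gold
standard.  Sorting a dataset by score and computing FE in consecutive
windows of associations yields a score->enrichment curve; a parametric fit
of that curve (log-linear, sigmoid, linear, or capped-linear) transforms
raw scores onto a unified 0-5 "star" confidence scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tables import AssociationTable, GoldStandard

__all__ = [
    "TransformSpec",
    "ConfidenceCutoffs",
    "CalibrationCurve",
    "fold_enrichment",
    "enrichment_curve",
    "fit_transform",
    "to_stars",
    "classify_confidence",
    "classify_level_index",
    "CONFIDENCE_LEVELS",
]

log = logging.getLogger(__name__)

CONFIDENCE_LEVELS = ("below", "low", "medium", "high")


# ---------------------------------------------------------------------------
# score -> star transforms
# ---------------------------------------------------------------------------

_FORMS = ("log_linear", "sigmoid", "linear", "capped_linear")


@dataclass(frozen=True)
class TransformSpec:
    """A parametric transform from a raw score to star confidence.

    Forms
    -----
    ``log_linear``     a * log10(s) + b
    ``sigmoid``        A / (1 + B * s**C) + D
    ``linear``         a * s + b
    ``capped_linear``  min(a * s, cap)

    Evaluation is clamped to [floor, ceiling]; the ceiling defaults to five
    stars (text-mining z-scores are capped at four).  Non-positive scores
    fed to log/power forms evaluate to the floor.
    """

    form: str
    params: dict = field(default_factory=dict)
    floor: float = 0.0
    ceiling: float = 5.0

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown transform form {self.form!r}")
        object.__setattr__(self, "params", dict(self.params))

    def evaluate(self, score):
        s = np.asarray(score, dtype=float)
        p = self.params
        if self.form == "log_linear":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = p["a"] * np.log10(np.where(s > 0, s, np.nan)) + p["b"]
            bad = ~(s > 0)
            if np.any(bad):
                log.warning("log transform on %d non-positive score(s); clamped to floor",
                            int(np.sum(bad)))
                out = np.where(bad, self.floor, out)
        elif self.form == "sigmoid":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = p["A"] / (1.0 + p["B"] * np.where(s > 0, s, np.nan) ** p["C"]) + p["D"]
            out = np.where(s > 0, out, self.floor)
        elif self.form == "linear":
            out = p["a"] * s + p["b"]
        else:  # capped_linear
            out = np.minimum(p["a"] * s, p["cap"])
        out = np.clip(out, self.floor, self.ceiling)
        if np.isscalar(score) or np.ndim(score) == 0:
            return float(out)
        return out


def to_stars(score, spec: TransformSpec):
    """Evaluate a transform: raw dataset score -> star confidence."""
    return spec.evaluate(score)


# ---------------------------------------------------------------------------
# confidence cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceCutoffs:
    """Low/medium/high thresholds on a dataset's native score scale."""

    low: float
    medium: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.medium <= self.high):
            raise ValueError("cutoffs must satisfy low <= medium <= high")


def classify_confidence(score: float, cutoffs: ConfidenceCutoffs) -> str:
    """Classify a raw score as below/low/medium/high (boundary inclusive)."""
    if score >= cutoffs.high:
        return "high"
    if score >= cutoffs.medium:
        return "medium"
    if score >= cutoffs.low:
        return "low"
    return "below"


def classify_level_index(scores, cutoffs: ConfidenceCutoffs) -> np.ndarray:
    """Vectorized classification: 0=below, 1=low, 2=medium, 3=high."""
    s = np.asarray(scores, dtype=float)
    return (
        (s >= cutoffs.low).astype(int)
        + (s >= cutoffs.medium).astype(int)
        + (s >= cutoffs.high).astype(int)
    )


# ---------------------------------------------------------------------------
# fold enrichment
# ---------------------------------------------------------------------------


def fold_enrichment(pairs, gold: GoldStandard | set, genes, tissues) -> float:
    """Fold enrichment of ``pairs`` over random chance w.r.t. a gold standard.

    Both the candidate pairs and the gold standard are restricted to the
    given gene and tissue universe before counting.
    """
    genes = set(genes)
    tissues = set(tissues)
    gold_pairs = gold.pairs if isinstance(gold, GoldStandard) else set(gold)
    pairs_r = {(g, t) for g, t in pairs if g in genes and t in tissues}
    gold_r = {(g, t) for g, t in gold_pairs if g in genes and t in tissues}
    if not pairs_r:
        raise ValueError("no candidate pairs inside the gene x tissue universe")
    if not gold_r:
        raise ValueError("no gold-standard pairs inside the gene x tissue universe")
    background = len(gold_r) / (len(genes) * len(tissues))
    observed = len(pairs_r & gold_r) / len(pairs_r)
    return observed / background


# ---------------------------------------------------------------------------
# score -> enrichment curves
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Ordered (representative score, fold enrichment) points per window."""

    points: pd.DataFrame  # columns window, score, fold_enrichment, n_gold, n_window
    window_size: int

    def __len__(self) -> int:
        return len(self.points)

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False, float_format="%.12g")


def enrichment_curve(
    table: AssociationTable, gold: GoldStandard, window: int = 100
) -> CalibrationCurve:
    """Score->fold-enrichment curve in disjoint windows of associations.

    Records are restricted to the genes and tissues shared with the gold
    standard, sorted by descending score (gene/tissue lexicographic
    tie-break) and partitioned into consecutive windows of ``window``
    records; the final short window is kept only when it holds at least
    half a window.  Each point carries the window's median score and its
    fold enrichment over the shared universe.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    genes = table.genes & gold.genes
    tissues = table.tissues & gold.tissues
    df = table.data
    mask = df["gene"].isin(genes) & df["tissue"].isin(tissues)
    df = df.loc[mask]
    n = len(df)
    if n < window / 2:
        raise ValueError(
            f"only {n} records inside the shared universe; need at least {window / 2:g}"
        )
    gold_r = {(g, t) for g, t in gold.pairs if g in genes and t in tissues}
    if not gold_r:
        raise ValueError("no gold-standard pairs inside the shared universe")
    background = len(gold_r) / (len(genes) * len(tissues))

    df = df.sort_values(
        ["score", "gene", "tissue"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    in_gold = np.fromiter(
        ((g, t) in gold_r for g, t in zip(df["gene"], df["tissue"])),
        dtype=bool,
        count=n,
    )
    widx = np.arange(n) // window
    n_windows = int(widx[-1]) + 1
    sizes = np.bincount(widx, minlength=n_windows)
    if n_windows > 1 and sizes[-1] < window / 2:
        keep = widx < n_windows - 1
        df, in_gold, widx = df[keep], in_gold[keep], widx[keep]
        n_windows -= 1
        sizes = sizes[:-1]

    gold_counts = np.bincount(widx, weights=in_gold, minlength=n_windows)
    scores = df["score"].to_numpy()
    reps = np.array(
        [np.median(scores[widx == w]) for w in range(n_windows)], dtype=float
    )
    fe = (gold_counts / sizes) / background
    points = pd.DataFrame(
        {
            "window": np.arange(n_windows),
            "score": reps,
            "fold_enrichment": fe,
            "n_gold": gold_counts.astype(int),
            "n_window": sizes.astype(int),
        }
    )
    return CalibrationCurve(points, window)


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

_N_PARAMS = {"log_linear": 2, "linear": 2, "capped_linear": 2, "sigmoid": 4}


def _sigmoid(s, A, B, C, D):
    return A / (1.0 + B * np.power(s, C)) + D


def fit_transform(curve, form: str) -> tuple:
    """Least-squares fit of a parametric form to (score, enrichment) points.

    ``curve`` is a :class:`CalibrationCurve` or an (x, y) pair of arrays.
    Returns ``(TransformSpec, residual_sum_of_squares)``; the returned spec
    is unclamped (infinite floor/ceiling) since the fitted quantity is an
    enrichment, not a star score.
    """
    if form not in _FORMS:
        raise ValueError(f"unknown transform form {form!r}")
    if isinstance(curve, CalibrationCurve):
        x = curve.points["score"].to_numpy(dtype=float)
        y = curve.points["fold_enrichment"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    npar = _N_PARAMS[form]
    if len(x) < 2 * npar:
        raise ValueError(f"need >= {2 * npar} points to fit {form!r}, got {len(x)}")

    if form in ("linear", "log_linear"):
        design = np.log10(x) if form == "log_linear" else x
        if form == "log_linear" and np.any(x <= 0):
            raise ValueError("log_linear fit requires positive scores")
        a, b = np.polyfit(design, y, 1)
        params = {"a": float(a), "b": float(b)}
        resid = y - (a * design + b)
        spec = TransformSpec(form, params, floor=-math.inf, ceiling=math.inf)
        return spec, float(np.sum(resid**2))

    if form == "capped_linear":
        slope0 = (np.max(y) - np.min(y)) / max(np.ptp(x), 1e-12)
        p0 = (max(slope0, 1e-6), float(np.max(y)))
        popt, _ = curve_fit(
            lambda s, a, cap: np.minimum(a * s, cap), x, y, p0=p0, maxfev=20000
        )
        params = {"a": float(popt[0]), "cap": float(popt[1])}
        spec = TransformSpec(form, params, floor=-math.inf, ceiling=math.inf)
        resid = y - np.minimum(popt[0] * x, popt[1])
        return spec, float(np.sum(resid**2))

    # sigmoid: multi-start over exponent/prefactor seeds, keep best RSS
    if np.any(x <= 0):
        raise ValueError("sigmoid fit requires positive scores")
    amp0 = float(np.max(y) - np.min(y)) or 1.0
    d0 = float(np.min(y))
    best = None
    n_attempts = 0
    for c0 in (-0.5, -1.0, -2.0, -4.0, -8.0, -12.0, 1.0, 2.0):
        for b0 in (0.1, 1.0, 10.0):
            n_attempts += 1
            try:
                popt, _ = curve_fit(
                    _sigmoid, x, y, p0=(amp0, b0, c0, d0), maxfev=20000
                )
            except RuntimeError:
                continue
            resid = y - _sigmoid(x, *popt)
            rss = float(np.sum(resid**2))
            if np.isfinite(rss) and (best is None or rss < best[1]):
                best = (popt, rss)
    if best is None:
        raise RuntimeError(
            f"sigmoid fit failed to converge in {n_attempts} attempts of <=20000 "
            "iterations each"
        )
    popt, rss = best
    params = dict(zip("ABCD", (float(v) for v in popt)))
    spec = TransformSpec("sigmoid", params, floor=-math.inf, ceiling=math.inf)
    return spec, rss
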