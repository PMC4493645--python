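# Methods

This note documents the models implemented in `tissuescore`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Tissue ontology and major tissues

Tissue vocabularies are directed acyclic graphs of terms linked by is-a
relations.  Only is-a edges are traversed; other relationship types in an
OBO file are ignored, and obsolete terms are dropped at parse time.
Free-text tissue labels are resolved case-insensitively and exactly —
first against canonical names, then synonyms — with a configurable
blacklist for labels that denote no single tissue (e.g. "retina and
testis").  No fuzzy matching is attempted: a missed association is
recoverable, an invented one is not.

Analyses operate on a fixed set of *major tissues* (nominally 21 terms)
that must be mutually non-ancestral (`assert_non_overlapping`).  Any finer
term contributes its score to every major tissue on its ancestor paths; in
a DAG a term can legitimately map to more than one major, and the
propagation is kept symmetric across datasets rather than choosing one
path arbitrarily.  The major set is configuration, not a constant, since
different studies select different compromises between datasets.

## Per-dataset scoring rules

| family            | score                         | aggregation over sources |
|-------------------|-------------------------------|--------------------------|
| expression_units  | normalized microarray units   | mean over probe sets     |
| est_count         | ESTs per tissue               | sum over clusters        |
| rpkm / fpkm       | RNA-seq units, used directly  | mean if terms collide    |
| peptide_count     | distinct unique tryptic peptides | mean over samples of one term |
| ihc               | staining consensus (below)    | —                        |
| zscore            | co-occurrence z-score         | —                        |

Microarray probe sets matching multiple targets (names ending
`_r_at`/`_i_at`/`_f_at`/`_x_at`) and spike-in controls (prefix `AFFX`) are
removed before alias mapping; the filter applies only to profiles that
request it, since newer platforms use different naming conventions.
Aliases are applied before tissue-term mapping, and aggregation happens
once, at the (gene, term) level, so multi-probe and multi-sample
collapsing cannot double-aggregate.

In-silico digestion cleaves after every K or R with up to two missed
cleavages.  The proline exception (no cleavage before P) is deliberately
not applied: plain K/R cleavage is deterministic and produces a superset
of proline-aware fragments, so no observed peptide is missed; the cost is
a slightly larger theoretical peptide space.  Peptides matching more than
one gene's digest are discarded rather than fractionally assigned — a
"unique peptide" score should count unambiguous evidence only.

## Staining consensus

The consensus score of protein p in tissue t is
`alpha * quality_p * level_{p,t}` with the disagreement-based quality and
weighted level defined in the README.  Numerical conventions:

* `R2_p = 0` (single antibody or perfect agreement) makes the weights
  0/0; they are taken uniform, the continuity limit, so the level is the
  plain mean.  For a single antibody the raw staining values are used
  directly, per the published scheme.
* For `N_p >= 2` the per-tissue weight sum is `N_p − (tissue share of
  R2_p)/R2_p · N_p >= N_p − 1 > 0`, so the zero-weight-sum fallback
  (unweighted mean plus a warning) is a guard that cannot trigger for
  valid tables.
* Multi-antibody scores may exceed 6 (two agreeing "high" antibodies at
  alpha = 3 score 18).  No clamping is applied before calibration: the
  published transform (score/5.5) and cutoffs (1.1, 1.9) assume the
  unclamped scale.

`fit_alpha_beta` searches an exhaustive grid (default alpha 0.5–5 by 0.5,
beta 0–2 by 0.1; the surface is cheap because alpha and beta enter each
protein's score in closed form).  The objective is a *rank-discounted*
mean of per-window fold enrichment, with harmonic weights 1/(rank+1) over
score windows.  A plain unweighted mean over equal-size windows is
invariant to the ranking — window gold counts always sum to the total
gold count — and therefore cannot distinguish parameter settings at all;
discounting restores the intended meaning, rewarding parameters that
concentrate gold-standard associations in the top windows.  Ties break
toward smaller beta, then smaller alpha (prefer the simpler model).

## Calibration

Fold enrichment compares a pair set with a gold standard over the genes
and tissues shared between the two; both sets are restricted to that
universe before counting, and an empty restricted side is an error rather
than a zero.  Calibration curves use disjoint (not sliding) windows — the
points then carry independent binomial errors — of 100 associations by
default, sorted by descending score with a deterministic gene/tissue
tie-break.  The representative score of a window is its median.  A short
final window is kept only when it holds at least half a window, bounding
both discarded signal and point variance.

Four transform families cover the published score→star forms: log-linear,
sigmoid `A/(1+B·s^C)+D`, linear, and capped linear.  Star evaluation
clamps to [0, 5] (4 for text-mining z-scores, whose published form
"score/2.4" is capped at four stars); non-positive scores under log/power
forms evaluate to the floor with a warning.  Fitting uses linear least
squares where the form is linear in its parameters and
`scipy.optimize.curve_fit` otherwise; the four-parameter sigmoid is
multi-started over a grid of exponent/prefactor seeds and the best
residual sum of squares wins, which recovers noiseless parameters to
machine precision in the tested forms.  Confidence classification is
boundary-inclusive (score ≥ cutoff qualifies), so the published cutoffs
themselves sit at their own level.

## Integration analyses

Expression breadth counts, per gene, the tissues whose score classifies
at or above a level; it is always computed relative to the tissue panel
the dataset actually measured, since a dataset covering 11 of 21 tissues
cannot show breadth 19.  Bimodality is summarized as the fraction of
expressed genes in the two extreme bands (breadth ≤ k or ≥ T−k+1,
default k = 3).  Venn analyses restrict association sets to the shared
gene/tissue universe first (an unrestricted variant is exposed for
complementarity analyses); patterns are keyed by bitstrings in declared
set order.  The integrated-vs-single benchmark takes the N top-scoring
single-dataset associations, with ties at the boundary broken by gene
then tissue so the comparison is deterministic.

## Synthetic data

The generator emulates the statistical structure the analyses assume:

* **Truth.** Each gene is ubiquitous with probability 0.4 (breadth
  uniform in [T−2, T]) or tissue-specific (breadth uniform in [1, 3]),
  over T = 21 tissues and 20,000 genes by default — a sharply bimodal
  breadth distribution.
* **Scores.** Continuous families draw log-normal values; count families
  draw Poisson counts with a log-normal rate.  The lognormal-Poisson
  choice (over a gamma-Poisson/negative binomial) is deliberate: EST and
  peptide counts need both orders-of-magnitude rate heterogeneity and a
  thin left tail (deeply sampled libraries rarely miss a truly expressed
  gene entirely), and gamma mixing cannot provide both at once.
* **Structure linking score to annotation.** Tissue-specific genes reach
  higher expression in their tissues than housekeeping genes do anywhere
  (`specific_boost`, ×3–4), and background noise overlaps the weak-signal
  range — both well-documented features of the real platforms.  Together
  with a gold standard biased toward specific genes (inclusion
  probability ∝ breadth⁻¹), this makes the probability that an
  association is curated decline smoothly along the score ranking, which
  is exactly the property the calibration machinery measures.
* **Gold standard.** A fraction (default 0.3) of true pairs, per-gene
  weighted by breadth^(−bias); always a subset of the truth.
* **Staining.** True staining is 6 where expressed, 0 elsewhere; each
  antibody independently corrupts each tissue with probability
  `antibody_error` (default 0.2) by resampling uniformly from {0,1,3,6};
  antibody counts follow a distribution dominated by 1–2 antibodies.
* **Determinism.** One global seed feeds named substreams (per dataset,
  truth, gold, staining), so adding a dataset never perturbs another, and
  identical configurations produce byte-identical outputs.

Cross-dataset correlation arises solely through the shared truth matrix;
no correlated noise is injected.  Consequently the synthetic datasets
agree *more* strongly with each other than real platforms do, and passing
overlap tests say nothing about real batch effects, probe-sequence
artifacts, splice variation, or antibody cross-reactivity — none of which
are modeled.  The proteomics- and text-mining-like profiles are
deliberately noisier (heavier dropout, weaker signal separation), so
their calibration curves are visibly worse than the transcriptome
datasets', mirroring the relative quality ordering seen in real data;
monotone-calibration assertions are made for the five transcriptome-like
datasets.

Default problem sizes used by the test suite and the acceptance script —
20,000 genes for the end-to-end pipeline and breadth analyses, ~2,000
genes (≈20,000 associations) for windowed-calibration checks, 1,500
stained proteins for parameter selection — are large enough that the
binomial noise of 100-association windows does not mask the calibration
trend, while keeping a full pipeline run in the tens of seconds.

## Known limitations

* The ontology module implements exact name matching only; real dataset
  integration typically needs a manually curated label→term table, which
  can be supplied as a pre-resolved tissue column.
* The fold-enrichment framework measures relative quality, not precision:
  against an incomplete gold standard the false-positive rate is not
  identifiable, and no attempt is made to estimate it.
* The global fold-enrichment→star anchoring shared across companion
  resources is under-specified in the source material; the package ships
  the published per-dataset transforms as canonical and exposes
  re-fitting (`fit_transform`) for users with their own gold standard.
* Statistical significance of overlaps (hypergeometric/Fisher testing) is
  out of scope; the overlap reports are descriptive.
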