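# Methods

## Design and containers

The analysis targets a 7-week feeding trial sampled at day 0 and weeks 3,
5 and 7 in two tissues (gut, liver). All stage-wise statistics act on the
three consecutive contrasts: early (3w vs 0d), middle (5w vs 3w), late
(7w vs 5w). A `CountMatrix` couples an integer features × samples table
to a sample sheet (sample id, tissue, time point, replicate) and is the
entry point of every expression analysis; upstream read processing is out
of scope. Validation requires at least two replicates per present time
point, because every downstream test needs a within-group variance.

## Differential expression

Counts are modelled as NB(μ·s, α), Var = μ + αμ².

* **Size factors** are DESeq-style median-of-ratios: the reference is the
  per-feature geometric mean over zero-free features, a sample's factor is
  exp(median log-ratio), and factors are rescaled to geometric mean 1.
  When no feature is zero-free (common for sparse miRNA matrices) an
  explicit `pseudo_reference=True` fallback builds the reference from
  features expressed in at least half of the samples.
* **Dispersion** is estimated per feature by method of moments on
  normalised counts, α̂ = max(10⁻⁸, (s² − μ)/μ²), with within-group
  variances pooled by their degrees of freedom. At n = 3 this estimate is
  extremely noisy, and plugging it into a Wald statistic inflates the
  type-I error (~0.12 at nominal 0.05 in our null simulations). The stage
  pipeline therefore shares information across features: a parametric
  trend α(μ) = a₀ + a₁/μ is fitted to the moment estimates by
  iteratively reweighted least squares (points above 3× the trend are
  down-weighted as dispersion outliers, mirroring how dedicated NB DE
  engines treat them), and each feature is tested with
  max(α̂_feature, α_trend(μ)). Taking the maximum rather than the trend
  alone keeps genuinely noisy features conservative; in null simulations
  (2000 features, n = 3 vs 3, dispersion 0.1) the raw-p fraction below
  0.05 is 0.04–0.05 and planted |log2FC| = 2 effects are recovered with
  sensitivity ≈ 0.9 at BH 0.1.
* **Effect and test**: log2FC = log2((m_B + 0.5)/(m_A + 0.5)) on
  normalised means; the pseudocount stabilises low counts and caps the
  fold change of on/off features. SE follows by the delta method from
  Var(m) = (μ + αμ²)/n, and the two-sided p refers log2FC/SE to the
  standard normal. Features with zero counts in both groups are excluded
  before correction (they carry no information and would inflate the BH
  denominator); all-zero features inside `nb_wald` report log2FC = 0,
  p = 1, flagged.
* **Multiplicity**: Benjamini–Hochberg step-up within each contrast, with
  a stable (p, feature id) pre-sort so results are order-deterministic.
  Calling threshold: adjusted P < 0.05 (default).
* miRNA matrices (n = 2 per time point) run through identical machinery;
  a warning notes that power is minimal at two replicates.

## Immune gene library

The library is a two-level ontology: nine fixed top-level immune
processes (acute phase reactions; pattern recognition; antigen processing
and regulators; complement system; inflammatory cytokines and receptors;
adapters, effectors and signal transducers; innate immune cells related;
T/B cell antigen activation; other genes related to immune response) over
free-text immune categories. Genes may hold multiple memberships —
published category listings repeat categories across processes — so
tallies count memberships while distinct-gene counts are reported
separately. Category strings are compared case-insensitively after
whitespace normalisation when collapsing duplicate rows, because curated
tables mix capitalisations. Unknown process labels and empty gene ids are
load-time errors naming the offending row; absence of a queried gene from
the library is not an error (it classifies as non-immune).

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for k DE members of a set of size K within a universe of N
tested genes containing n DE genes. The universe is all features tested
for DE in that tissue, not the immune library alone — enrichment of
immune pathways needs a non-immune background. The rich factor is k/K.
BH runs across all sets with k ≥ 1 within one (stage, direction) query,
matching one dot-plot panel; significance is q < 0.05. Whether the
immune-library filter is applied to the gene list before testing or only
to the displayed rows afterwards is genuinely ambiguous in this style of
analysis, so both orders are exposed (`enrichment_filter` = "before" /
"after"); the default is after, which keeps the test's universe intact.

## Checkpoint selection

Member genes of each (process, category) are aggregated per sample to the
mean of log2(normalised count + 1); this single category-level value per
replicate is the simplest substrate consistent with t-testing categories
directly (a per-gene-majority alternative was considered and rejected as
underdetermined: no voting rule is implied by a category-level test).
Welch's unequal-variance t-test compares categories between time points
(n = 3 with no evidence of homoscedasticity), with BH across categories
within each comparison. Selection rules:

* gut — significant (adjusted p < 0.05) at 7w vs 5w or 7w vs 3w, and not
  significant at 7w vs 0d: perturbed, then restored to baseline;
* liver — significant at 3w, 5w or 7w vs 0d: durably altered. The liver
  rule deliberately has no return-to-baseline clause.

Rule evaluation is a pure function of the significance flags; each
selected row stores a trace of the clauses that fired. A raw-p mode
exists for sensitivity analysis, but adjusted p is the default since the
category tests are explicitly FDR-corrected.

## miRNA–mRNA networks

mRNA and miRNA libraries carry different replicate counts (3 vs 2), so
correlation pairs per-time-point means of log2(normalised + 1): four
paired points per (miRNA, gene). Pearson r on four points carries no
meaningful p-value and none is reported; no |r| cutoff is applied by
default (a configurable threshold exists but is off — the procedure is
overlap-then-sign, not correlation-thresholding). Edges are exactly the
predicted target pairs whose miRNA and gene are both DE in the stage;
each edge records both DE directions, sign(r) and an immune flag. Pairs
with a zero-variance profile on either side are dropped with a log entry.
Exports: SIF, GraphML (networkx), node/edge attribute TSVs with the
up/down regulation attribute per node, and a per-process summary of
immune target pairs with distinct-gene counts.

## Phenotype and morphometry

The eight growth formulas are implemented verbatim; two need comment.

* SGR uses the printed linear form 100 × (final − initial)/days by
  default even though published SGR values (≈ 3 %/day) are only
  reproducible with the compound form 100 × (ln final − ln initial)/days;
  the log form is available behind `log_form_sgr=True`. Fidelity first.
* Feed efficiency relates per-fish weight gain to feed; `feed_consumed`
  is a cage total (the basis ADFI requires), so FE converts it to g/fish
  using the stocking count when available.

Mean density implements the background-corrected intensity statistic
(ΣIntDen − mean background density × signal area)/image area, reading the
background term as per-pixel mean density times signal area — the only
dimensionally consistent bracketing of the published formula. Percent
area is 100 × true/total pixels. Group comparisons are two-sided Welch
t-tests at α = 0.05 for growth and α = 0.01 for morphology.

## Synthetic data generator

The generator emulates the trial: lognormal baselines (log-mean 5,
log-sd 1, i.e. median ≈ 150 counts), NB dispersion 0.1 (typical bulk
RNA-seq), n = 3 mRNA and n = 2 miRNA replicates per time point, 2000
genes and 200 miRNAs by default. Planted structure:

* *Stage DE*: a planted log2FC (default ±2, 50 genes/stage) switches on
  at the stage's later time point and persists, so each effect is
  differential in exactly one consecutive contrast.
* *Checkpoints*: 5 of 40 immune categories (8 genes each) have every
  member shifted +1.5 log2 units at 3w and 5w and restored at 7w (gut)
  or shifted from 3w onward (liver). Eight genes per category reflects
  that the curated checkpoint categories are multi-member gene families
  and gives the category-mean t-test adequate expected signal
  (E[t] ≈ 11) against the BH threshold across 40 categories; with very
  small families (≤4 genes) the category test is intrinsically
  underpowered at n = 3.
* *Couplings*: a planted target's mean is baseline × 2^(s·β·z(t)) with z
  the realised per-time-point z-profile of its miRNA, β = 1 and s = −1
  (negative) or +1 (positive pairs) — both signs occur in real
  integrations. Stage-DE effects are never planted inside pair targets
  or checkpoint categories, keeping each truth unambiguous.

Everything is a pure function of the config (mandatory seed):
regenerating with the same seed is byte-identical. The generator
reproduces the design's *structure*, not real grass carp expression:
library sizes are balanced, dispersion is homogeneous, library
categories are disjoint gene blocks, and no batch or library-composition
effects exist. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the declared model, not performance
on real sequencing data.

Phenotype simulation draws per-cage records around group means shaped
like a three-diet trial (FM / 40SBM / 70SBM, 3 cages, CV 2 %); zero CV
reproduces the configured means exactly. Morphometry inputs are
constructed images with known signal/background values and exact mask
coverage, so the formula outputs are known in closed form.

## Numerical choices and determinism

Dispersion floor 10⁻⁸; log2 pseudocount 0.5; BH via the standard step-up
with enforced monotonicity (statsmodels backend, verified against an
independent brute-force implementation); hypergeometric tails via scipy's
stable survival function (verified against exhaustive enumeration to
10⁻¹⁰ for all N ≤ 25). Degenerate cases are deterministic: zero variance
with equal means gives p = 1; all-zero features give log2FC = 0, p = 1;
flat correlation profiles are dropped rather than reported as NaN. All
randomness flows from explicit seeds; pipeline outputs contain no
timestamps, so reruns are byte-identical.

## Problem sizes

Default simulations (2000 genes × 12 samples, 200 miRNAs × 8 samples)
run the full simulate→report pipeline in a few seconds on one CPU; the
test suite and the acceptance script each complete in well under a
minute. These sizes were chosen as the smallest at which the planted
recovery rates are stable across seeds.

## Known limitations

* The NB Wald test with trend-moderated dispersion is a transparent
  re-implementation of the model family used by standard DE engines, not
  a re-implementation of any specific engine: no empirical-Bayes
  shrinkage of fold changes, no Cook's-distance outlier handling, no
  multi-factor designs.
* With n = 2 miRNA replicates per time point the stage tests have
  minimal power; miRNA DE calls should be treated as exploratory (the
  pipeline says so in a warning).
* Four-point Pearson correlations are sign indicators, not effect
  estimates.
* The liver checkpoint rule selects any durably altered category, so its
  selection set grows with any persistent expression change; this is the
  rule as defined, not a defect of the implementation.
* The category-level t-test treats member genes as exchangeable;
  categories dominated by one highly expressed gene are effectively
  single-gene tests.
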