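# Methods

## Scope and data model

`aarspan` analyzes a fixed 43-gene panel (37 unique aaRS genes — 20
cytoplasmic and 19 mitochondrial enzymes with GARS1/KARS1 dual-localized —
three AIMPs, three benchmark genes) over a catalog of cancer types with
known median overall survival (OS).  Inputs per cancer are sample-level:
a gene × sample matrix of thresholded copy-number calls in {−2…+2}, a
minimal MAF-like mutation table (sample, gene, 1-based protein position,
consequence ∈ {missense, nonsense, frameshift, fusion, other}), TPM-like
tumor and normal expression matrices, and a survival table (time in
months > 0, event indicator).  The packaged gene panel and 33-entry cancer
catalog ship as TSV fixtures inside the package, so nothing is downloaded.

Every gene × cancer map orders its columns by ascending median OS, ties
broken alphabetically by abbreviation.  This makes ordering deterministic
even though the catalog contains tied OS values (18.1 appears for ACC and
LUSC, 35.3 for OV and SKCM).

## Genomic level

Only the high-confidence ±2 calls count toward the alteration frequency
(amplification, deep deletion); ±1 calls (gain/shallow deletion) are noise
tolerant and excluded from event counting but *are* included in the mean
copy-number score, which averages all calls per gene.  A sample hit by two
or more distinct event classes (mutation, fusion, amplification, deep
deletion) is counted once, as "multiple"; fusions enter through the
mutation-table consequence column so that all discrete events share one
channel.  The per-residue mutation tally flags hotspots as residues with
count ≥ 3 (default `hotspot_min`), the smallest recurrence that separates
a cluster from a background of mutations spread across the protein.

## mRNA level

Fold change is computed as the difference of cohort means of log2(x+1);
the +1 pseudo-count defines behavior at zero expression.  The significance
gate is a one-way ANOVA across the two cohorts on the same scale (for two
groups this equals the pooled-variance F test).  Rows constant in both
cohorts get p = 1 when the means agree and p = 0 otherwise.  BH adjustment
is applied *within each cancer across the gene panel*: each cancer's
tumor-normal comparison is treated as its own experiment.  A call requires
both gates: |log2FC| ≥ log2(1.5) and q ≤ 0.05.  Cancers lacking a normal
cohort are marked not-evaluable and excluded from the per-gene totals (a
warning is logged); the supplied normal cohort is otherwise taken at face
value, since mismatched reference tissues are a property of the inputs the
pipeline should surface, not silently repair.

## Survival level

Patients are split at the median expression of one gene; ties at the
median go to the low group (the deterministic rule documented here, since
tool conventions differ).  A split whose high group comes out empty — all
values identical, or heavy ties at the median — is degenerate and the cell
is not evaluable.  The Kaplan–Meier curve uses the product-limit estimator
S(t) = Π (1 − d_i/n_i).  The two-group log-rank statistic accumulates
observed-minus-expected deaths and the hypergeometric variance over the
2×2 risk-set table at each distinct death time; the hazard ratio is the
Mantel–Haenszel form (O_hi/E_hi)/(O_lo/E_lo) from the same tabulation — a
closed-form estimate consistent with interpreting the HR as the ratio of
death probabilities between groups.  (An iterative proportional-hazards
fit would be an acceptable alternative; the closed form was chosen for
transparency and exact testability against hand tabulation.)  Cells with
zero observed events in either group have no defined HR; they are excluded
from score counting and from the BH pool rather than continuity-corrected,
to avoid fabricating evidence the data cannot support.  BH adjustment runs
globally across all evaluable cells because the survival map is presented
and thresholded as a single experiment.

## Integration

DNA score = mean of per-cancer mean copy-number values; mRNA score =
n_up − n_down; survival score = n_unfavorable − n_favorable.  Cells that
were not evaluable contribute zero to the counts (count-of-significant-
cancers semantics, not missingness propagation).  Each column is min-max
normalized; a constant column maps to 0.5 so it contributes neutrally
without a division by zero.  The composite is the unweighted mean of the
three normalized columns — no level is privileged — and genes are ranked
ascending (rank 1 = most cancer-inhibiting), composite ties broken
alphabetically.  Because min-max normalization absorbs affine rescaling,
the ranking is invariant to linear changes of units in any raw column, and
negating all three columns exactly reverses it.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
any particular dataset: per-gene categorical copy-number calls, Bernoulli
mutation hits (rate 0.02/gene/sample, matching the low 1–5% alteration
frequencies typical of essential genes) with uniform positions over a
nominal 500-residue protein, Gaussian log2(TPM+1) expression
(mean 5, SD 1 — a mid-abundance transcript), and exponential survival
times (baseline hazard 0.03/month, i.e. ~23-month median) with
administrative censoring at 60 months.  Archetypes: oncogene-like genes
get amplification-biased call probabilities (expected mean call +0.44), a
+1 log2 tumor expression shift, and +0.7 log hazard for the
high-expression group; suppressor-like genes are the mirror image; neutral
genes are symmetric noise.

The death hazard keys on *group membership* — the upper median-split half
of one designated driver gene's tumor expression — rather than on
continuous expression, so the true group hazard ratio equals
exp(log_hr_per_group) exactly and is a clean recovery target for the
downstream median-split analysis.  Drivers are assigned round-robin over
the planted genes; with at least as many cancers as planted genes, every
planted gene drives one cancer, where its marginal HR is unattenuated.
Two scenarios are built in: `small` (4 cancers × 40 symbolic genes ×
60/30 samples, 2+2 planted, seed 7) for fast iteration, and `paper_like`
(10 real cancer labels with their catalog OS values, the full 43-gene
panel, 200/100 samples, 5+5 planted, seed 42).  The planted sets follow
the amplification/deletion tendencies reported for these genes in the
pan-cancer literature (oncogene-like: GARS1, TARS1, EPRS1, DARS2, AIMP2;
suppressor-like: NARS1, SARS1, QARS1, LARS2, RARS2).

What the generator does **not** emulate: correlated copy-number segments
(neighboring-gene effects), realistic per-cancer sample sizes, mutation
signatures, tissue-specific expression baselines, or non-administrative
censoring.  Passing tests therefore demonstrate the pipeline's
correctness and calibration under its own model assumptions, not that the
biological conclusions transfer to real cohorts.

## Numerical choices and edge cases

* BH step-up implemented directly (sort, q(i) = min over the tail of
  p(j)·m/j, cap at 1, return in input order); verified against brute-force
  evaluation and statsmodels.
* Log-rank variance term skips risk sets of size 1 (variance contribution
  undefined); a map with zero total events returns (χ² = 0, p = 1).
* Expression back-transform 2^x − 1 is clipped at 0 so simulated TPM is
  never negative (the clip is active with probability ≈ 3·10⁻⁷ per value
  under the default parameters).
* One RNG stream per cohort, seeded once; iteration order is fixed, so
  equal configs give byte-identical cohorts and pipeline outputs.  The
  run manifest stores file names relative to its own directory, which
  keeps manifests byte-identical across output locations while still
  sufficing to reproduce a run bit-for-bit.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use the `small` scenario
for null calibration (200 replicates; ≈32,000 log-rank and ANOVA cells)
and the `paper_like` scenario for parameter recovery (50 replicates of the
10 driver cells each) and for the single-seed planted-archetype ranking
run.  These sizes give Monte-Carlo standard errors comfortably below the
tolerances being checked (e.g. the null log-rank rate has SE ≈ 0.001 at
32,000 cells).

## Known limitations

* The "multiple" alteration category follows this package's convention
  (≥ 2 distinct event classes per sample per gene); portal semantics for
  fusion-plus-CNV precedence vary and are not observable from summary
  figures.
* The BH scope choices (per-cancer for expression, global for survival)
  are documented conventions; other scopes are defensible.
* The Mantel–Haenszel HR is slightly conservative (biased toward the
  null) relative to a Cox fit at moderate event counts; the mean recovered
  log HR at the default settings is ≈ 0.66 against a truth of 0.70, within
  the package's stated ±0.1 band.
* No covariate adjustment, paired testing, batch correction, or
  protein-level analysis.
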