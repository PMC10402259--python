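# Methods

## The inference problem

A paired IP/input design measures, per gene *g*, counts in two library
types from each tissue sample: the immunoprecipitated ribosome-bound mRNA
of a tagged cell type and the bulk ("input") RNA of the same tissue. The
IP library is modelled as a convex mixture of two transcript pools,

    E[IP count]    = L · [ (1−c) · p_target(g) + c · p_ambient(g) ]
    E[input count] = L · p_ambient(g)

where `p_target` is the tagged cell type's transcript pool (normalised to
proportions, optionally weighted by a per-gene capture bias), `p_ambient`
the cell-type-proportion-weighted mixture over all cell types, `c` the
contamination fraction (non-specific co-purification with the beads), and
`L` the library size. After injury, `p_ambient` shifts both through
cell-type composition (inflammatory expansion) and through induction in
non-target cell types; both leak into the IP fraction through the `c`
channel and masquerade as target-cell regulation. Everything in this
package exists to separate that channel from genuine target-cell changes.

## Count model

Per-gene negative-binomial GLMs with log link; log RLE size factors enter
as offsets. Fitting is IRLS batched across genes (weights `μ/(1+αμ)`,
working response on the linear predictor scale), initialised from
least squares on `log((y+0.5)/s)`, converged at `max|Δβ| < 1e-8` (cap 100
iterations, non-converged genes flagged, not dropped). Coefficient
covariance is the inverse Fisher information at the final iterate.
Estimates are reported in log2 units; fitting is in natural log.

**Size factors.** Median-of-ratios over genes observed in every sample
(`factor_s = median_g count(g,s) / geomean_g`), not rescaled further.
Note two consequences of the formula itself: multiplying *all* counts by a
constant moves the geometric-mean reference identically and leaves the
factors unchanged, and scaling one column by `c` scales that column's
factor by `c` *relative to the others* (the common `c^(1/S)` reference
shift cancels in every ratio the normalization uses). A
`pseudo_reference=True` fallback (geometric mean over positive counts,
median over observed genes) covers matrices with no all-nonzero gene.

**Dispersion.** Per-gene method of moments on normalized counts within
design groups: `α̂ = (s² − μ·mean(1/s_f)) / μ²`, pooled across groups by
replicate weight, *then shrunk toward a trend* — the mean raw estimate
within expression-decile bins — with prior weight `prior_df = 10`
pseudo-replicates against the gene's own residual df (limma/edgeR style).
Shrinkage is on by default and this is a deliberate choice: with three
replicates per group the raw moment estimate has ~2 effective df, and
plugging it into a Wald statistic referred to the standard normal yields
a type-I error near 0.12 at nominal 0.05. With trend shrinkage the test
is calibrated (≈0.05–0.07 in the package's own null simulations).
`shrink=False` restores the raw estimator; the floor is 1e-8, cap 20.

**Tests.** Wald: `stat = estimate/se`, two-sided standard-normal p, BH
q-values within each contrast over the post-filter gene universe. LRT:
`2(ℓ_full − ℓ_reduced)` against chi-square with df equal to the design
rank difference (identical column spaces give df 0, stat 0, p 1 rather
than an error). Genes with a zero group mean are fitted on the GLM scale
(no pseudo-counts); reported log2FCs are capped at ±10 and flagged.

## Contrasts

* DE within a fraction: two-group design (condition vs reference) on that
  fraction's samples.
* Enrichment within a condition: two-group design on fraction
  (IP vs input); the coefficient is `Log2FC(Total)`.
* Differential enrichment: `~ condition + fraction + fraction:condition`
  on both fractions of the tested and reference conditions. The
  interaction coefficient equals the enrichment difference exactly when
  the per-condition fits share dispersions (the four-group model is
  saturated), which the test suite verifies. Positive sign = enrichment
  gained after injury. A `paired=True` mode replaces condition main
  effects with tissue-pair blocking dummies (pairs are nested within
  conditions); group-level fitting is the default since the interaction
  is identified without it.
* One set of size factors, estimated on the full filtered matrix, is
  shared by every contrast so all fold-changes refer to one normalization.

Genes with fewer than 10 total counts are removed before any fitting
(threshold inclusive: a row sum of exactly 10 is kept).

## Two-arm filtration

Thresholds (all configurable, all logged with the run): DE `|log2FC| ≥ 1`
at `q ≤ 0.05`; arm 1 `|delta| ≥ 1`, `q ≤ 0.05`, sign agreeing with the
expression change (magnitude equality is not required); arm 2 enrichment
`≥ 1` at `q ≤ 0.05` at the reference AND the tested condition
(`arm2_mode="all"` demands every timepoint instead); final call =
DE ∧ (arm1 ∨ arm2). Exact ties pass (inclusive comparisons throughout).
Down-regulated genes are filtered with mirrored signs. Enrichment
classes: depleted `≤ −0.5`, enriched `≥ 0.5`, highly selective `≥ 2.0`,
all significance-gated at `q ≤ 0.05`; non-significant genes are neutral.

The choice of "reference AND tested condition" for arm 2's "constant"
enrichment is the permissive endpoint reading; requiring all timepoints
is stricter and available by flag. An acute-specific selector keeps
up-filtered acute genes whose late-timepoint change is non-significant or
at least 1 log2 unit (two-fold) below the acute change.

## Set statistics

Hypergeometric overlap: exact upper tail `P[K ≥ k]`, expectation
`n1·n2/N`, representation factor `k/expectation` (NaN-flagged when the
expectation is zero; `p = 1` when a set is empty). Members outside an
explicit universe are dropped with a logged count.

Operon z-score: `K` uniform random subsets of the expressed background,
each the query's size, are drawn without replacement (by ranking i.i.d.
random keys, chunked for memory); the observed overlap is standardised by
the sample mean and sd (K−1 denominator) of the null overlaps. `K = 1000`
by default — the minimal historical procedure of 10 random sets is
available as `paper_mode` but its sd estimate is far too unstable to
support a z > 5 cutoff. With one query scored against many sets, one draw
list is shared across sets by default (`shared_draws=False` refreshes per
set). The expressed background is defined as genes surviving the
low-count filter in the IP fraction. `null_sd = 0` flags the z as
undefined rather than dividing by zero.

## QC

ΔΔCT folds: `2^−[(Ct_t,IP − Ct_ref,IP) − (Ct_t,input − Ct_ref,input)]`,
multiple reference transcripts combined by arithmetic Ct mean before
differencing (the standard choice; Ct is already a log-scale quantity).
Count-based marker folds use RLE-normalized counts with a +1 pseudo-count
(zero-safe, with a known attenuation toward 1 for low-expression
markers); per-cell-type verdicts are medians over markers × pairs.
PCA is run on feature-centered (optionally scaled) `log2(normalized+1)`
profiles via SVD; variance fractions are non-increasing and sum to ≤ 1.

## The synthetic scenario

The default ("paper-like") scenario: 2000 genes, 4 conditions
(naive, dpi2, dpi10, dpi42) × 2 fractions × 3 replicates = 24 samples,
contamination `c = 0.1`, library sizes log-uniform in 1–3 million,
per-gene dispersion log-normal around 0.05 (clipped to [0.005, 0.5]).
Gene architecture: 10% OL markers, 10% microglia markers, 7.5% astrocyte,
7.5% neuron markers — each ~500× specific for its own cell type (marker
leakage 0.2% of own-type expression, so the tagged-cell leak channel
stays far below the ambient channel, which is what makes contaminant
transcripts IP-depleted with essentially unchanged de-enrichment) — and
65% broadly expressed genes. Cell-type proportions shift from
(OL .20, microglia .10, astrocyte .30, neuron .40) at baseline to a
microglial peak of .45 acutely, resolving by the late timepoint. Injury
programs: 5% of OL-expressed genes get genuine OL log2FCs of ±2 acutely
(half persisting mid, ~30% late); 60% of microglia markers are induced
+2–4 log2 in microglia acutely (decaying later); a milder reactive
astrocyte program. Where the underlying study quantifies none of these
(it does not estimate its contamination fraction), the values are chosen
once as a realistic acute-CNS-injury scenario, not fitted to anything.

Ground truth: `true_ol_de` = tagged-cell |log2FC| above the DE threshold;
`contaminant_driven` = tagged cell silent (|log2FC| < 0.1) while the
*median-centered* ambient log2 change exceeds 1 — centering per condition
mirrors what median-of-ratios normalization removes, so a surge of a few
abundant transcripts does not flag every unchanged gene. The truth flags
are mutually exclusive by construction.

What the generator does **not** emulate: batch effects beyond library
size, GC/length bias, UMI or read-level structure, per-sample composition
jitter, partial-specificity markers, or genes regulated simultaneously in
the tagged cell and in the ambient pool. Passing tests therefore show the
pipeline's behaviour under a clean mixture model with strong markers; on
real data, marker impurity and correlated regulation will blur the
arm-1/arm-2 separation, and the filtration is expected (by design) to
trade sensitivity for specificity.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on simulated data
at the default scenario's scale: 2000-gene experiments for recovery
(20 replicate simulations) and null calibration, 10⁴ resamples for
checking the resampling null against exact hypergeometric moments, and
exhaustive enumeration for universes up to N = 25. Batched IRLS makes a
full 24-sample, 2000-gene analysis run in well under a second, so these
sizes are statistical choices, not compromises. All randomness flows from
one root seed, expanded per stage by hashing the stage name; repeated
runs are byte-identical except for `run.log`, which records wall-times.

## Known limitations

* The Wald reference is the standard normal; calibration relies on the
  dispersion shrinkage and degrades below three replicates per group.
* No Cook's-distance outlier handling, independent filtering, or
  fold-change shrinkage: reported log2FCs are raw MLEs, deliberately, so
  the fixed thresholds keep their meaning.
* The contamination fraction `c` is simulated, not estimated from data;
  the package filters its consequences rather than deconvolving it.
* Gene identifiers are opaque strings; no cross-database mapping.
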