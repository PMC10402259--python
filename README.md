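# riboclean

Contamination-aware analysis of paired IP/input translatome RNA-seq.

In Ribotag/TRAP experiments, a tagged cell type's ribosome-bound mRNA is
immunoprecipitated (**IP**) from whole tissue and sequenced alongside a
total-RNA **input** library from the same sample. After tissue injury or
inflammation, highly abundant transcripts from *other* cell types
(microglia/macrophages in particular) co-purify with the beads, so the IP
fraction's apparent differential expression is a mixture of genuine
cell-type-specific regulation and ambient contamination. `riboclean`
implements the analysis chain that separates the two, for bioinformaticians
analysing paired-fraction designs (conditions × {IP, input} × replicates).

## The model and statistics

Counts are modelled per gene with a negative-binomial GLM (log link, RLE
size factors as offsets, method-of-moments dispersion shrunk toward a
mean-expression trend):

* **Enrichment** within condition *c*: `Log2FC(Total) = log2(IP/input)`,
  the Wald-tested fraction coefficient.
* **Differential enrichment** for injury condition *s* vs reference:
  the fraction × condition interaction,
  `delta = Log2FC(Total)_s − Log2FC(Total)_ref`,
  with a likelihood-ratio test of the full vs additive model available for
  "any-timepoint" effects.
* **Two-arm filtration**: an IP-fraction DE call (`|log2FC| ≥ 1`,
  BH `q ≤ 0.05`) is kept only if
  * **arm 1** — its enrichment changed concordantly
    (`|delta| ≥ 1`, `q ≤ 0.05`, same sign as the expression change), or
  * **arm 2** — it is constantly highly enriched
    (`Log2FC(Total) ≥ 1`, `q ≤ 0.05`, at the reference *and* the tested
    condition), so the tagged cells are its major expressors.
* **Set statistics**: exact hypergeometric overlap tests with the
  representation factor `k / (n1·n2/N)`, and a resampling z-score
  comparing a gene list's overlap with a reference ("operon") set to
  random same-size draws from the expressed background (`z > 5` as a
  stringent specificity call).

A synthetic-data generator produces the full paired design (4 conditions ×
2 fractions × 3 replicates) from a cell-type mixture with known ground
truth: condition-dependent cell-type proportions (inflammatory expansion
after injury), cell-type-specific injury fold-changes, and IP libraries
contaminated by a tunable fraction of the ambient pool. Every downstream
claim in this package is tested against that truth.

## Worked example

```python
from riboclean.pipeline import RunConfig, run_all

art = run_all(RunConfig(seed=7, n_genes=2000), "runs/demo")
print(art["summary"][["n_de", "n_arm1", "n_arm2", "n_final"]])
```

```
           n_de  n_arm1  n_arm2  n_final
condition
dpi2        468      69      16       85
dpi10       289      21       7       28
dpi42       105      13       4       17
```

Of 468 nominal DE calls in the acute (dpi2) IP fraction, only 85 survive
filtration — 69 via changed enrichment, 16 via constant high enrichment.
Because this run is simulated, the truth-based evaluation is written too:

```
           n_true_de  recovery  contaminant_frac_unfiltered  contaminant_frac_final
condition
dpi2             100     0.820                        0.421                   0.000
dpi10             41     0.659                        0.737                   0.036
dpi42             33     0.515                        0.571                   0.000
```

At dpi2, 42% of unfiltered DE calls are ambient/contaminant-driven; after
filtration none are, while 82% of the genuinely regulated genes are kept.
The operon stage scores each gene-set against 1000 random expressed-gene
sets; the deliberately signal-bearing set stands out while random controls
stay near zero:

```
                           overlap  null_mean  null_sd      z  passes
synthetic_target_operon         42       4.07     1.91  19.85    True
synthetic_random_operon_1        4       4.20     1.92  -0.11   False
```

The same stages are exposed on the command line
(`riboclean simulate|qc|de|enrich|enrich-delta|overlap|operon-z|run-all`);
each writes plain TSV so every intermediate is inspectable and diff-able.

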