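# ratediv

Predicting intraspecific genetic diversity from long-term molecular
evolutionary rates — and reading species-specific selection out of the
deviations from that prediction.

## The scientific problem

Within a species, the amount of standing genetic variation differs widely
among genes. Under the neutral theory, both a gene's long-term molecular
evolutionary rate (`r = ν p`, mutation rate times the proportion of neutral
mutations) and its proportion of segregating sites (`q = ν p F`, with `F` a
genome-wide genealogical factor) are driven by the same quantity `p`, the
gene's freedom from functional constraint. Among-gene variation in `q`
should therefore be predictable from among-gene variation in `r`, which can
be estimated from the branch lengths of phylogenomic gene trees. Genes (or
trait-associated gene sets) whose observed diversity falls significantly
below or above the prediction are candidates for species-specific enhanced
or relaxed functional constraint — purifying or diversifying selection
acting in that one lineage.

`ratediv` implements this framework end to end for users with gene trees
(newick), population variant calls (VCF), feature annotations (BED-like),
a recombination map, and gene-set definitions:

- **tree_stats** — per-gene rate proxies (mean, median, truncated mean
  branch length `b̄⁽ⁱ⁾`, `b̃⁽ⁱ⁾`, `b̂̄⁽ⁱ⁾`), their Poisson sampling variance
  `V[b̄⁽ⁱ⁾] = b̄⁽ⁱ⁾/(M·l⁽ⁱ⁾)`, a Poisson branch-length resampler, and the
  closed-form MLE of the two-way multiplicative model
  `E[b_ik·L_i] = c·L_i·α_i·β_k` (gene effect × branch effect, with
  `Σ L_i α_i = Σ β_k = 1`).
- **polymorphism** — per-gene segregating sites `K`, singletons, de-novo
  counts and `q = K/L` from VCF records; nucleotide diversity π in 1000-bp
  windows; window feature labels (exon/5′-UTR/3′-UTR/intron/intergenic,
  intergenic meaning >100 kb from any gene boundary); genetic-map lookups
  with the Haldane map function.
- **bgs_model** — the background-selection/hitchhiking model
  `π = π₀ ∏ᵢ [1 − U·Δx·shᵢ/(2(shᵢ+Rᵢ)²)]` with rate-dependent selective
  effect `shᵢ = exp(α + β rᵢ)`, fitted per chromosome × feature by nonlinear
  least squares, plus the two-way ANOVA decomposition of the fitted
  parameters.
- **correlation** — raw and bias-corrected (disattenuated) correlation
  between rate and diversity, and the coalescent variance of `K`
  (`V(K) = E(K) + E(K)²·b_n/a_n²` and its non-equilibrium generalization).
- **diversity_model** — negative-binomial regression
  `log E[K] = log L + a + b·log(rate) + γ·D_X` with jointly estimated shape
  θ, and the alternative linear-rate form `E[K] = L(a + b·rate)·e^{γD_X}`.
- **species_selection** — per-gene lower-tail mid-p deviations and their
  normal quantiles z, gene-set t tests (negative t = enhanced constraint,
  positive t = relaxed), Benjamini–Hochberg selection, PCA of
  diversity-plus-rate matrices and correspondence analysis of −log₁₀(p)
  profiles across species.
- **synthetic_data** — seeded generators that emulate every input with its
  assumed statistical structure, each paired with a truth table so the
  pipeline can be validated without any download.

## Worked example

Simulate a reduced-scale cohort (500 genes, 51-branch trees) and run the
pipeline:

```bash
ratediv simulate --out demo/sim --seed 1 --n-genes 500 --n-branches 51
ratediv tree-stats --trees demo/sim/trees \
    --alignment-lengths demo/sim/alignment_lengths.tsv --out demo/ts
ratediv correlate --rates demo/ts/rate_summaries.tsv \
    --poly demo/sim/gene_polymorphism.tsv --out demo/corr
ratediv fit-diversity --rates demo/ts/rate_summaries.tsv \
    --poly demo/sim/gene_polymorphism.tsv --rate-proxy mean_bl --out demo/nb
ratediv selection --poly demo/sim/gene_polymorphism.tsv \
    --fit demo/nb/nb_fit.tsv --rates demo/ts/rate_summaries.tsv \
    --sets demo/sim/sets.tsv --rate-proxy mean_bl --out demo/sel
```

which prints

```
simulated inputs in demo/sim
wrote demo/ts/rate_summaries.tsv (500 genes)
raw r = 0.3352, corrected r = 0.3508
slope = 0.3939, theta = 10.12
0 of 100 sets significant at FDR 0.01
```

Reading the output: the raw Pearson correlation between each gene's mean
branch length and its segregating-site count is 0.3352; correcting for the
sampling noise of both estimates raises it to 0.3508. The negative-binomial
regression recovers the generator's rate elasticity (true slope 0.413,
fitted 0.394) and dispersion (true θ = 10, fitted 10.12). The gene sets in
this run are null sets, and none is called significant at FDR 0.01 — the
deviation test is calibrated. Stage options can also be given once in a
YAML file (`ratediv --config run.yaml <stage>`), with command-line flags
taking precedence.

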