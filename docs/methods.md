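# Methods

This note documents the models implemented in `ratediv`, the numerical and
design choices behind them, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Rate proxies from gene trees

A gene tree contributes its full branch-length multiset; zero-length
branches are retained (pruning them would bias conserved genes upward), and
no root edge is synthesized — maximum-likelihood gene trees are effectively
unrooted, so a rooted newick's two root-child branches are read as two
ordinary branches. Three per-gene rate proxies are computed: the mean branch
length (robust to missing taxa but sensitive to outlier branches), the
median (robust to outliers but collapsing to 0 when more than half the
branches are zero, as happens for strongly conserved genes at the
amino-acid level), and the truncated mean after removing the five longest
branches (default `truncate_k = 5`), which guards against both failure
modes. The truncated mean is reported as missing (NaN), never as 0, when a
tree has five or fewer branches. Downstream regressions accept any of the
three; the log-link regression defaults to the median.

Treating each branch's substitution count as Poisson with mean `b_ik·l_i`
gives the sampling variance of the mean branch length,
`V[b̄] = b̄/(M·l)`, and a resampling scheme (draw Poisson counts per branch,
re-summarize) that also yields the sampling distribution of the median,
for which no closed form is available. Column-bootstrap of alignments would
serve the same purpose but requires the alignments themselves; the Poisson
resampler needs only the tree.

## Two-way gene × branch effects

Scaled branch lengths `N_ik = b_ik·L_i` are modeled as Poisson with mean
`c·L_i·α_i·β_k` under the normalizations `Σ_i L_i α_i = Σ_k β_k = 1`. The
maximum-likelihood estimators have closed forms (row and column sums over
the grand total); the test suite verifies them against direct constrained
numerical likelihood maximization on random matrices up to 4×4 (tolerance
1e-6). Gene trees with missing taxa are handled by restricting every sum to
observed cells, which preserves the estimators' mean-per-gene logic; a
`require_complete` switch enforces complete matrices instead. Interactions
are reported as observed-over-predicted ratios per cell; `c` and the
normalized `β_k` are reported separately rather than folded together, so
the branch effect remains a proper composition. All-zero rows or columns
yield zero effects with a warning; an all-zero matrix is an error.

## Window diversity and the background-selection model

Nucleotide diversity per 1000-bp window uses the unbiased pairwise
estimator: per site `2p̂(1−p̂)·n/(n−1)` summed over the window and divided
by the width (this matches the common `--window-pi` semantics of variant
toolkits). Windows are labeled intergenic when they lie more than 100,000 bp
from every annotated gene boundary; otherwise by the feature class covering
the majority of the window, with ties broken by the precedence
exon > 5′-UTR > 3′-UTR > intron (the more constrained class wins).

Genetic-map positions are linearly interpolated (and extrapolated at map
ends) in cumulative cM; cM distances are converted to recombination
fractions with the Haldane map function `R = ½(1 − e^{−2d/100})`, the
standard choice when no mapping function is specified, and the only one of
the common choices that saturates at ½ as a fraction must.

The diversity of a target window is modeled as the neutral level π₀ reduced
by every exon window of the chromosome:

    π = π₀ ∏_i [1 − U·Δx·sh_i / (2·(sh_i + R_i)²)]
      ≈ π₀ exp( −Σ_i U·Δx·sh_i / (2·(sh_i + R_i)²) ),

with `sh_i = exp(α + β r_i)` tying the selective effect to the long-term
rate of the gene spanning exon window i. Defaults `U = 1e-8` per position
per haploid genome and `Δx = 1000` bp. The exponential form is what the
nonlinear least-squares fit uses (the product form is available for
evaluation, and the two agree to first order whenever the per-window terms
are small; both are exposed to make that check possible). Per-window terms
exceeding 1 in the product form are clamped with a warning.

Fitting uses Levenberg–Marquardt least squares over (π₀, α, β) with
multi-start over β ∈ {0, ±10, ±100}; π₀ is initialized from the mean π of
the 10% of target windows genetically farthest from any exon, and α from
log(0.01). (α, β) are weakly identified individually — many (α, β) pairs
produce nearly the same per-window reduction profile when the rate range is
modest — so the package's accuracy contract is on π₀ and on the reduction
factors π/π₀, not on the raw (α, β) coordinates. A fit whose reduction
profile is flat to 1e-6 is flagged unidentifiable. Fitted parameter tables
over a chromosome × feature grid can be decomposed by two-way ANOVA without
replication (residual = interaction), returning variance shares that sum to
1 and the two main-effect F-test p-values.

## Raw and corrected correlation

Both the rate proxy and the diversity count carry sampling noise, which
attenuates their observed Pearson correlation. The correction multiplies
the raw correlation by `√[(1 + E[V_S(B̂)]/V_G(B̂))·(1 + E[V_S(K̂)]/V_G(K̂))]`,
with sample means of the supplied per-gene sampling variances and the
among-gene variances of the observed vectors as plug-ins. Dividing by the
observed (rather than latent) variance makes this a first-order correction:
it under-corrects by O(ρ²) at noise-to-signal ratio ρ. An
`exact_disattenuation` mode divides by `V_G − E[V_S]` instead (the
classical errors-in-variables form); the default stays with the
observed-variance form for fidelity to the estimator this package is built
around, and the recovery tests use ρ = 0.1 per axis — the modest-noise
regime the correction targets, comparable to the raw-versus-corrected gap
the method produces on real cohorts. Corrected values are clamped to
[−1, 1] with a warning, since the estimator can overshoot at small n.

Per-gene sampling variances of `K` come from the coalescent:
`V(K) = E(K) + E(K)²·b_n/a_n²` at equilibrium, or
`V(K) = E(K) + E(K)²·V(T_c)/E(T_c)²` for an arbitrary history. The latter
is exactly the negative-binomial variance identity with
`θ = E(T_c)²/V(T_c)`, which motivates the regression family below.

## Negative-binomial diversity regression

The baseline model is `log E[K] = log L + a + b·log(rate) + γ·D_X`, with
gene length as offset and `D_X` absorbing the smaller effective population
size of the X chromosome. θ is estimated by maximum likelihood jointly with
the coefficients, via profile likelihood: for each candidate θ the
coefficients are fitted by IRLS (a GLM with fixed NB shape), and the exact
NB likelihood is maximized over log θ ∈ [−3, 25] to 1e-8 — the same
alternation classical NB-GLM implementations use. Genes with zero rate
under the chosen proxy are dropped (log undefined) with a logged count.
Very large fitted θ (the profile optimum running to the upper bound) means
overdispersion is ignorable and the fit is effectively Poisson; the
predictions then agree with a Poisson GLM to within 0.1%.

The alternative linear-rate form `E[K] = L(a + b·rate)·e^{γD_X}` keeps the
same NB likelihood and is fitted by Nelder–Mead with five starts from
method-of-moments values perturbed under a fixed seed; non-positive fitted
means are excluded by penalty. A positive intercept `a` is the
scientifically interesting quantity — diversity that survives within the
species for mutations destined for loss on the macroevolutionary scale — so
its sign is logged prominently and a profile-likelihood confidence interval
for it is provided. Zero-rate genes are retained in this form.

## Deviation p-values and gene-set tests

For each gene, the lower-tail probability of its observed `K` under the
fitted NB(μ, θ) measures its diversity deficit or excess. Because `K` is
discrete, the plain tail `P(X ≤ K)` is stochastically larger than uniform
and would bias every downstream z upward; the implementation therefore uses
the mid-p `P(X < K) + ½P(X = K)`, whose null mean is exactly ½ (verified by
exact summation in the tests). P-values are clamped to
[1e-300, 1 − 1e-16] before the normal-quantile transform.

A gene set's statistic is the one-sample t of its members' z values
(sample sd, m − 1 df); the p-value is two-sided, since shifts in both
directions (enhanced and relaxed constraint) are of interest and reported
by sign. Degenerate sets (zero spread) return t = 0, p = 1 when all z are
zero, and otherwise fall back to an sd floor of 1e-12 with a warning. Sets
below the minimum size (default 2) are skipped. Significant sets are
selected by Benjamini–Hochberg at a configurable FDR (default 0.01).

PCA of the genes × (per-species q, rate) matrix is SVD-based on
column-standardized data (q and rates live on different scales;
standardization is the default and can be disabled), with component signs
fixed so each component's largest-magnitude loading is positive.
Correspondence analysis of −log₁₀(p) profiles (p floored at 1e-300) follows
the standard construction: correspondence matrix, row/column masses, SVD of
the standardized residuals, principal coordinates scaled by singular
values; total inertia equals the matrix chi-square over the grand total.
All-zero rows or columns are dropped with a warning.

## Synthetic data: what it emulates, and what it does not

The generators produce, under a single seed that fully determines every
draw: (a) gene trees from the two-way Poisson substitution model, with the
total substitution count calibrated so the average mean branch length is
0.03 substitutions/site at any configured gene count (a typical
mammal-clade scale; an explicit `scale_c` overrides this); (b) per-gene
counts with NB structure — defaults slope 0.413 and intercept −2.177 (the
singleton-regression scale of human cohort data), θ = 10, X-linked genes a
fraction 0.04 of the genome with effect γ = −0.25, singletons a binomial
0.4 thinning of K, and de-novo counts Poisson and independent of the rate
so the null de-novo correlation is reproducible; (c) a 10-Mb synthetic
chromosome (one-tenth the scale of a large human chromosome) with 300
five-window genes, a linear 1.2 cM/Mb map, window diversity from the
background-selection model (π₀ = 0.001, α = −3, β = 50) plus Gaussian noise
of sd 1e-4, truncated at zero; (d) gene sets that are null or shifted —
shifted sets draw disjoint members and resample their K with the mean
multiplied by e^δ.

What the generators do not emulate: linkage between neighboring genes'
counts (spatial structure exists only at the window level), demographic
history and coalescent genealogies (counts are drawn directly from the NB,
not simulated through a coalescent), sequence evolution and alignment
error, ancestral-allele polarization, and overlapping genes. Passing tests
therefore demonstrate that the estimators recover the parameters of their
own assumed models at realistic scales and that the statistical machinery
is calibrated — not that those models are adequate for any particular real
cohort.

## Numerical choices and degenerate inputs

- Two-way effects: closed forms; zero rows/columns → zero effects with a
  warning; an all-zero matrix is an error.
- NB log-link: profile over log θ bounded in [−3, 25] (θ from 0.05 to
  ~7×10¹⁰), IRLS tolerance 1e-10, profile tolerance 1e-6 on log θ.
- Linear NB model: 5 Nelder–Mead starts, fixed seed 0; positivity by
  penalty; profile CI by bracketed bisection on the likelihood-ratio drop.
- Background-selection fit: LM least squares, ftol/xtol 1e-12, 5 β-starts;
  negative π₀ at the optimum is reported with a boundary warning.
- Mid-p clamping: [1e-300, 1 − 1e-16]; CA −log₁₀ floor 1e-300.
- BH: step-up on stably sorted p-values (cross-checked against the
  reference implementation in statsmodels in the tests).
- Ties among the "five longest" branches: stable input order; only the
  removed count affects the truncated mean.
- Multi-allelic sites: one segregating site for K, each alternate allele
  considered for singleton status; indels and non-SNP alleles skipped with
  a logged counter. Monomorphic records (AC = 0 or AC = AN) are read but
  never counted as segregating.
- A variant falling in two overlapping genes counts once in each
  (configurable), since per-gene q is a property of each gene's footprint.

## Problem sizes used by the checks

The acceptance checks run the NB recovery grid at 14,000 genes (the study's
gene-count scale), the correlation recovery at 10,000 genes, mid-p
calibration at 50,000 genes, set calibration on 2,000 null sets of 10, and
the full pipeline at one-tenth study scale (1,467 genes, 189-branch trees,
100 gene sets); the background-selection recovery uses the generator's
default 10-Mb chromosome with 2,000 target windows. These sizes keep the
whole suite to a few minutes on one CPU while leaving Monte-Carlo error
well below every asserted tolerance.

## Known limitations

- Branch identity across gene trees is keyed by generator-assigned branch
  ids or caller-supplied bipartition keys; the package does not itself
  reconcile topologically discordant gene trees against a reference
  topology.
- The intergenic diversity of real genomes is not modeled (the
  background-selection model is known to explain it poorly); only
  exon/UTR/intron windows are in scope.
- The (α, β) selection parameters of the background-selection model are
  reported but should be interpreted through the reduction profile they
  imply, not as independently meaningful coordinates (see above).
- No confidence intervals for the corrected correlation; no zero-inflated
  or quasi-likelihood count models; no enrichment lookups against external
  databases — coordinates and statistics are exported for downstream
  interpretation.
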