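"""Synthetic-data generators with the statistical structure the analysis
assumes.

Every generator is fully determined by the seed in its config and returns a
truth table next to its data, so each pipeline stage has a recovery oracle:

* gene trees follow the multiplicative gene-effect x branch-effect Poisson
  substitution model;
* per-gene segregating-site counts follow the negative-binomial log-link
  model driven by the gene's long-term rate, singletons are a binomial
  thinning of them, and de-novo counts are Poisson and independent of the
  rate (mutation-rate variation does not drive rate variation);
* window diversity on a synthetic chromosome follows the
  background-selection model with a linear genetic map;
* gene sets are either null (genes as-is) or shifted (counts resampled with
  the mean multiplied by exp(delta), emulating enhanced/reduced constraint).

Default scales mirror the study (14,671 genes, 96-taxon trees); tests run
them at reduced scale through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bgs_model import _predict_matrix
from .io_formats import (
    FeatureInterval,
    GeneTree,
    GeneticMap,
    VariantRecord,
    write_features,
    write_gene_sets,
    write_gene_tree,
    write_genetic_map,
    write_variants_vcf,
)


@dataclass
class BGSGeneratorConfig:
    """Synthetic chromosome for the background-selection model."""

    chrom_length: int = 10_000_000
    n_bgs_genes: int = 300
    exon_windows_per_gene: int = 5
    n_target_windows: int = 2000
    map_cM_per_Mb: float = 1.2
    pi0: float = 0.001
    alpha_sel: float = -3.0
    beta_sel: float = 50.0
    noise_sd: float = 1e-4
    rate_log_mean: float = float(np.log(0.02))
    rate_log_sd: float = 0.5
    U: float = 1e-8
    delta_x: int = 1000


@dataclass
class GeneratorConfig:
    """Master configuration; the seed fully determines every draw."""

    seed: int = 1
    n_genes: int = 14671
    n_branches: int = 189  # unrooted binary tree over 96 taxa
    gene_effect_sd: float = 0.7  # lognormal sd of relative gene rates
    branch_effect_sd: float = 0.5
    interaction_sd: float = 0.0  # 0 => interactions exactly 1
    scale_c: float | None = None  # total substitutions; None derives it from
    mean_branch_length: float = 0.03  # target mean branch length (subst/site)
    length_log_mean: float = 7.2  # lognormal gene length, median ~1340 bp
    length_log_sd: float = 0.6
    nb_slope: float = 0.413
    nb_intercept: float = -2.177
    nb_gamma: float = -0.25
    theta: float = 10.0
    prop_X: float = 0.04
    singleton_fraction: float = 0.4
    de_novo_rate: float = 2e-3  # aggregate de-novo rate per site over the cohort
    n_chromosomes: int = 5008  # sampled chromosomes in the cohort
    bgs: BGSGeneratorConfig = field(default_factory=BGSGeneratorConfig)
    set_sizes: tuple = tuple([10] * 100)
    set_delta: tuple = tuple([0.0] * 100)


def _draw_lengths(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    L = np.round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, cfg.n_genes))
    return np.maximum(L, 100).astype(int)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def gen_gene_trees(config: GeneratorConfig) -> tuple[list[GeneTree], dict]:
    """Gene trees under the two-way Poisson substitution model.

    Gene effects alpha_i and branch effects beta_k are drawn lognormal and
    normalized to sum_i L_i alpha_i = sum_k beta_k = 1; substitution counts
    N_ik ~ Poisson(c L_i alpha_i beta_k p_ik) give branch lengths
    b_ik = N_ik / L_i. Returns the trees (with branch ids shared across
    genes) and a truth dict with the generating effects.
    """
    rng = np.random.default_rng(config.seed)
    N, M = config.n_genes, config.n_branches
    L = _draw_lengths(rng, config)
    g_raw = rng.lognormal(0.0, config.gene_effect_sd, N)
    h_raw = rng.lognormal(0.0, config.branch_effect_sd, M)
    alpha = g_raw / float((L * g_raw).sum())
    beta = h_raw / h_raw.sum()
    # E[mean branch length of gene i] = c * alpha_i / M; calibrate c so the
    # across-gene average matches the configured mean branch length
    scale_c = config.scale_c
    if scale_c is None:
        scale_c = config.mean_branch_length * M / float(alpha.mean())
    mu = scale_c * np.outer(L * alpha, beta)
    if config.interaction_sd > 0:
        p_ik = rng.lognormal(-0.5 * config.interaction_sd**2, config.interaction_sd, (N, M))
        mu = mu * p_ik
    counts = rng.poisson(mu)
    b = counts / L[:, None]

    n_taxa = max(2, (M + 3) // 2) if M >= 2 else 1
    n_taxa = min(n_taxa, M) if M >= 1 else 1
    taxa = [f"T{j}" for j in range(n_taxa)]
    branch_ids = [f"b{k}" for k in range(M)]
    trees = [
        GeneTree(
            gene_id=f"G{i:05d}",
            branch_lengths=list(b[i]),
            taxon_labels=taxa,
            alignment_length=int(L[i]),
            branch_ids=branch_ids,
        )
        for i in range(N)
    ]
    truth = {
        "gene_id": [t.gene_id for t in trees],
        "alpha_true": alpha,
        "beta_true": beta,
        "branch_id": branch_ids,
        "L": L,
        "scale_c": scale_c,
    }
    return trees, truth


# ---------------------------------------------------------------------------
# per-gene polymorphism counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    return rng.negative_binomial(theta, theta / (theta + mu))


def gen_gene_polymorphism(
    config: GeneratorConfig, rates: np.ndarray, lengths: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-gene K / singleton / de-novo counts from given long-term rates.

    K ~ NB(mean L exp(a + b log r + g DX), shape theta); singletons are a
    binomial thinning of K; de-novo counts are Poisson(L u) and independent
    of the rate, so the pipeline reproduces the null de-novo correlation.
    The returned table includes the generating mean as column ``mu_true``.
    """
    rng = np.random.default_rng(config.seed + 1)
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    L = lengths if lengths is not None else _draw_lengths(rng, config)[:n]
    L = np.asarray(L)
    dx = (rng.random(n) < config.prop_X).astype(float)
    mu = L * np.exp(config.nb_intercept + config.nb_slope * np.log(rates) + config.nb_gamma * dx)
    K = _nb_draw(rng, mu, config.theta)
    singles = rng.binomial(K, config.singleton_fraction)
    de_novo = rng.poisson(L * config.de_novo_rate)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "K": K,
            "singletons": singles,
            "de_novo": de_novo,
            "L": L,
            "q": K / L,
            "chrom": np.where(dx == 1.0, "chrX", "chr1"),
            "is_X": dx == 1.0,
            "mu_true": mu,
        }
    )


# ---------------------------------------------------------------------------
# background-selection windows
# ---------------------------------------------------------------------------

def gen_bgs_windows(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneticMap]:
    """Window diversity shaped by background selection on a synthetic
    chromosome.

    Genes with lognormal long-term rates are placed along the chromosome;
    each contributes a run of exon windows. A linear genetic map converts
    positions to cM. Target-window diversity is the model prediction plus
    zero-mean Gaussian noise, truncated at 0. Returns (target windows with
    pi/map_cM and the noiseless ``pi_true``, exon window table with
    map_cM/rate, genetic map).
    """
    b = config.bgs
    rng = np.random.default_rng(config.seed + 2)
    width = b.delta_x
    n_windows = b.chrom_length // width

    # linear map: cumulative cM proportional to position
    gmap = GeneticMap(
        chrom="chrS",
        positions=[0, b.chrom_length],
        cumulative_cM=[0.0, b.map_cM_per_Mb * b.chrom_length / 1e6],
    )
    cm_per_bp = b.map_cM_per_Mb / 1e6

    # place genes (non-overlapping runs of exon windows)
    starts = rng.choice(
        n_windows - b.exon_windows_per_gene, size=b.n_bgs_genes, replace=False
    )
    starts.sort()
    rates = rng.lognormal(b.rate_log_mean, b.rate_log_sd, b.n_bgs_genes)
    exon_w = []
    exon_rate = []
    for s, r in zip(starts, rates):
        for j in range(b.exon_windows_per_gene):
            exon_w.append(s + j)
            exon_rate.append(r)
    exon_w = np.array(exon_w)
    exon_rate = np.array(exon_rate)
    exon_mid = exon_w * width + width // 2
    exon_cM = exon_mid * cm_per_bp

    # target windows sampled uniformly along the chromosome
    tgt_idx = rng.choice(n_windows, size=min(b.n_target_windows, n_windows), replace=False)
    tgt_idx.sort()
    tgt_mid = tgt_idx * width + width // 2
    tgt_cM = tgt_mid * cm_per_bp

    d = np.abs(tgt_cM[:, None] - exon_cM[None, :])
    R = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    pi_true = _predict_matrix(b.pi0, b.alpha_sel, b.beta_sel, R, exon_rate, b.U, width)
    pi_obs = np.maximum(pi_true + rng.normal(0.0, b.noise_sd, pi_true.size), 0.0)

    targets = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": tgt_idx * width,
            "pi": pi_obs,
            "pi_true": pi_true,
            "map_cM": tgt_cM,
        }
    )
    exons = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": exon_w * width,
            "map_cM": exon_cM,
            "rate": exon_rate,
        }
    )
    return targets, exons, gmap


# ---------------------------------------------------------------------------
# gene sets with shifted constraints
# ---------------------------------------------------------------------------

def gen_gene_sets(
    config: GeneratorConfig, genes: pd.DataFrame
) -> tuple[dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """Gene-set definitions with optional constraint shifts.

    Null sets (delta = 0) sample genes as-is. Shifted sets draw disjoint
    members and resample their K from NB(mean mu_true * exp(delta), theta),
    emulating reduced (delta > 0) or enhanced (delta < 0) constraint in the
    focal species. Returns (set definitions, truth table of deltas, gene
    table with the resampled counts applied).
    """
    rng = np.random.default_rng(config.seed + 3)
    if len(config.set_sizes) != len(config.set_delta):
        raise ValueError("set_sizes and set_delta must align")
    if any(s < 2 for s in config.set_sizes):
        raise ValueError("set sizes must be >= 2")
    table = genes.reset_index(drop=True).copy()
    gene_ids = table["gene_id"].to_numpy()
    mu = table["mu_true"].to_numpy(dtype=float) if "mu_true" in table else None

    shifted_pool = np.flatnonzero(np.array(config.set_delta) != 0.0)
    n_shifted_genes = int(sum(config.set_sizes[i] for i in shifted_pool))
    if n_shifted_genes > len(gene_ids):
        raise ValueError("not enough genes for disjoint shifted sets")
    disjoint = rng.choice(len(gene_ids), size=n_shifted_genes, replace=False)

    sets: dict[str, list[str]] = {}
    truth_rows = []
    cursor = 0
    K = table["K"].to_numpy().copy()
    for i, (size, delta) in enumerate(zip(config.set_sizes, config.set_delta)):
        sid = f"S{i:04d}"
        if delta != 0.0:
            idx = disjoint[cursor: cursor + size]
            cursor += size
            if mu is None:
                raise ValueError("shifted sets need a mu_true column")
            K[idx] = _nb_draw(rng, mu[idx] * np.exp(delta), config.theta)
        else:
            idx = rng.choice(len(gene_ids), size=size, replace=False)
        sets[sid] = [str(g) for g in gene_ids[idx]]
        truth_rows.append((sid, size, delta))
    table["K"] = K
    table["q"] = K / table["L"].to_numpy()
    truth = pd.DataFrame(truth_rows, columns=["set_id", "m", "delta"])
    return sets, truth, table


# ---------------------------------------------------------------------------
# toy literal-format emitters (io-path testing)
# ---------------------------------------------------------------------------

def gen_toy_vcf_inputs(
    seed: int = 1,
    n_genes: int = 5,
    gene_length: int = 1000,
    gap: int = 500,
    sites_per_gene: int = 8,
    n_chromosomes: int = 10,
) -> tuple[list[VariantRecord], list[FeatureInterval], GeneticMap]:
    """A small literal chromosome: genes as exon intervals, SNPs with AC/AN.

    Used to exercise the VCF/BED/map file paths end to end at toy scale.
    """
    rng = np.random.default_rng(seed)
    features = []
    variants = []
    pos_cursor = 100
    for g in range(n_genes):
        start = pos_cursor
        end = start + gene_length
        features.append(FeatureInterval("chr1", start, end, "exon", f"G{g:05d}"))
        sites = rng.choice(np.arange(start, end), size=sites_per_gene, replace=False)
        for s in np.sort(sites):
            ac = int(rng.integers(1, n_chromosomes))
            variants.append(
                VariantRecord("chr1", int(s) + 1, ac, n_chromosomes)
            )
        pos_cursor = end + gap
    gmap = GeneticMap("chr1", [0, pos_cursor + 1000], [0.0, (pos_cursor + 1000) * 1.2e-6])
    return variants, features, gmap


def emit_all(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic product in its standard on-disk format.

    Produces trees/*.nwk with an alignment-length sidecar,
    gene_polymorphism.tsv, window tables, features.bed, map.tsv, sets.tsv,
    a toy variants.vcf, and truth/*.tsv. Returns the path map.
    """
    outdir = Path(outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    trees, truth = gen_gene_trees(config)
    for t in trees:
        write_gene_tree(t, outdir / "trees" / f"{t.gene_id}.nwk")
    paths["trees"] = outdir / "trees"
    pd.DataFrame(
        {"gene_id": truth["gene_id"], "alignment_length": truth["L"]}
    ).to_csv(outdir / "alignment_lengths.tsv", sep="\t", index=False)
    paths["alignment_lengths"] = outdir / "alignment_lengths.tsv"
    pd.DataFrame(
        {"gene_id": truth["gene_id"], "alpha_true": truth["alpha_true"], "L": truth["L"]}
    ).to_csv(outdir / "truth" / "gene_effects.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"branch_id": truth["branch_id"], "beta_true": truth["beta_true"]}
    ).to_csv(outdir / "truth" / "branch_effects.tsv", sep="\t", index=False)

    mean_rates = np.array([np.mean(t.branch_lengths) for t in trees])
    mean_rates = np.maximum(mean_rates, 1e-8)
    poly = gen_gene_polymorphism(config, mean_rates, lengths=np.array(truth["L"]))
    poly.to_csv(outdir / "gene_polymorphism.tsv", sep="\t", index=False)
    paths["gene_polymorphism"] = outdir / "gene_polymorphism.tsv"

    targets, exons, gmap = gen_bgs_windows(config)
    targets.to_csv(outdir / "window_pi.tsv", sep="\t", index=False)
    exons.to_csv(outdir / "exon_windows.tsv", sep="\t", index=False)
    write_genetic_map(gmap, outdir / "map.tsv")
    paths["window_pi"] = outdir / "window_pi.tsv"
    paths["exon_windows"] = outdir / "exon_windows.tsv"
    paths["map"] = outdir / "map.tsv"

    sets, set_truth, poly2 = gen_gene_sets(config, poly)
    write_gene_sets(sets, outdir / "sets.tsv")
    set_truth.to_csv(outdir / "truth" / "set_deltas.tsv", sep="\t", index=False)
    poly2.to_csv(outdir / "gene_polymorphism.tsv", sep="\t", index=False)
    paths["sets"] = outdir / "sets.tsv"

    variants, features, toy_map = gen_toy_vcf_inputs(seed=config.seed)
    write_variants_vcf(variants, outdir / "variants.vcf")
    write_features(features, outdir / "features.bed")
    paths["variants"] = outdir / "variants.vcf"
    paths["features"] = outdir / "features.bed"
    return paths
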