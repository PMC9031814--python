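"""Per-gene long-term-rate summaries and the two-way Poisson branch model.

A gene tree's branch lengths measure substitutions per site along each
branch. Their mean, median and truncated mean serve as per-gene proxies for
the long-term molecular evolutionary rate. Across genes, scaled branch
lengths decompose multiplicatively into a gene effect (proportional to the
gene's share of neutral mutations) and a branch effect (time x mutation rate
of the branch); the closed-form maximum-likelihood estimators below follow
from a Poisson model for the substitution counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneTree

logger = logging.getLogger("ratediv")


@dataclass
class RateSummary:
    """Per-gene rate proxies with the sampling variance of the mean.

    ``truncated_mean_bl`` is the mean after removing the ``truncate_k``
    longest branches (NaN when the tree has too few branches); it guards the
    rate proxy against extremely long outlier branches, and against the
    median collapsing to 0 for highly conserved genes.
    """

    gene_id: str
    mean_bl: float
    median_bl: float
    truncated_mean_bl: float  # NaN when undefined
    total_bl: float
    n_branches: int
    sampling_var_mean: float


@dataclass
class EffectsFit:
    """Gene effects, branch effects and interactions of the two-way model.

    Normalizations: sum_i L_i * alpha_i = 1 and sum_k beta_k = 1, so
    ``scale_c`` absorbs the total substitution count. The interaction for a
    cell is the observed scaled branch length over its prediction; values far
    from 1 flag branch-specific shifts of a gene's constraint.
    """

    scale_c: float
    gene_effects: dict[str, float]
    branch_effects: dict[str, float]
    interactions: pd.DataFrame  # genes x branches, NaN where the cell is missing


def summarize_branch_lengths(tree: GeneTree, truncate_k: int = 5) -> RateSummary:
    """Mean, median and truncated-mean branch length of one gene tree.

    The median of an even number of branches is the average of the two middle
    order statistics. The truncated mean removes the ``truncate_k`` longest
    branches (ties broken by stable input order; only the count matters for
    the mean) and is reported as NaN when M <= truncate_k.
    """
    bl = np.asarray(tree.branch_lengths, dtype=float)
    m = bl.size
    total = float(bl.sum())
    mean = total / m
    median = float(np.median(bl))
    if m > truncate_k:
        if truncate_k > 0:
            keep = np.sort(bl)[:-truncate_k]
        else:
            keep = bl
        truncated = float(keep.mean())
    else:
        truncated = float("nan")
        logger.warning(
            "gene %s: %d branches <= truncate_k=%d; truncated mean undefined",
            tree.gene_id, m, truncate_k,
        )
    var = mean_branch_sampling_variance(mean, m, tree.alignment_length)
    return RateSummary(
        gene_id=tree.gene_id,
        mean_bl=mean,
        median_bl=median,
        truncated_mean_bl=truncated,
        total_bl=total,
        n_branches=m,
        sampling_var_mean=var,
    )


def summarize_trees(trees: list[GeneTree], truncate_k: int = 5) -> pd.DataFrame:
    """RateSummary table (one row per gene) for a tree collection."""
    rows = [summarize_branch_lengths(t, truncate_k=truncate_k) for t in trees]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "n_branches": [r.n_branches for r in rows],
            "total_bl": [r.total_bl for r in rows],
            "mean_bl": [r.mean_bl for r in rows],
            "median_bl": [r.median_bl for r in rows],
            "truncated_mean_bl": [r.truncated_mean_bl for r in rows],
            "sampling_var_mean": [r.sampling_var_mean for r in rows],
        }
    )


def mean_branch_sampling_variance(mean_bl: float, n_branches: int, alignment_length: int) -> float:
    """Stochastic variance of the mean branch length of one gene.

    Treating each branch's substitution count as Poisson with mean
    b_k * l, the variance of the mean branch length is mean_bl / (M * l).
    """
    if n_branches < 1 or alignment_length < 1:
        raise ValueError("need n_branches >= 1 and alignment_length >= 1")
    return mean_bl / (n_branches * alignment_length)


def poisson_branch_resample(
    tree: GeneTree, reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resample (mean, median) branch lengths under Poisson substitution noise.

    Per replicate and branch, a substitution count is drawn from
    Poisson(branch_length * alignment_length); the mean and median of the
    counts divided by the alignment length give one resampled (mean, median)
    pair. The same seed reproduces the same stream exactly.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    lam = np.asarray(tree.branch_lengths, dtype=float) * tree.alignment_length
    counts = rng.poisson(lam, size=(reps, lam.size))
    means = counts.mean(axis=1) / tree.alignment_length
    medians = np.median(counts, axis=1) / tree.alignment_length
    return means, medians


# ---------------------------------------------------------------------------
# two-way gene x branch effects
# ---------------------------------------------------------------------------

def branch_length_matrix(trees: list[GeneTree]) -> pd.DataFrame:
    """Genes x branches matrix of branch lengths, keyed by branch id.

    Requires trees that carry ``branch_ids`` (e.g. bipartition keys against a
    shared reference topology, or generator-assigned ids). A gene missing a
    branch leaves that cell NaN.
    """
    rows = {}
    for t in trees:
        if t.branch_ids is None:
            raise ValueError(f"gene {t.gene_id}: no branch ids; cannot align branches across genes")
        rows[t.gene_id] = dict(zip(t.branch_ids, t.branch_lengths))
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


def estimate_gene_branch_effects(
    scaled_lengths: pd.DataFrame,
    lengths: dict[str, int],
    require_complete: bool = False,
) -> EffectsFit:
    """Closed-form MLE of the two-way multiplicative Poisson branch model.

    ``scaled_lengths`` holds branch lengths b_ik (substitutions/site) as a
    genes x branches DataFrame; ``lengths`` maps gene_id to alignment length
    L_i. Under counts N_ik = b_ik * L_i ~ Poisson(c * L_i * alpha_i * beta_k)
    with the normalizations sum_i L_i alpha_i = sum_k beta_k = 1, the MLEs
    are the row/column sums below. Missing cells are simply excluded from the
    sums (set ``require_complete`` to forbid them instead).
    """
    B = scaled_lengths.astype(float)
    if require_complete and B.isna().any().any():
        raise ValueError("missing cells in branch-length matrix with require_complete=True")
    if (B.fillna(0.0) < 0).any().any():
        raise ValueError("negative branch lengths")
    L = pd.Series({g: float(lengths[g]) for g in B.index})
    N = B.mul(L, axis=0)  # scaled counts N_ik
    total = float(N.sum().sum())
    if total == 0:
        raise ValueError("all-zero branch-length matrix")

    gene_row_sums = B.sum(axis=1, skipna=True)  # sum_k b_ik
    branch_col_sums = N.sum(axis=0, skipna=True)  # sum_i b_ik L_i
    alpha = gene_row_sums / total
    beta = branch_col_sums / total

    zero_genes = alpha.index[alpha == 0]
    zero_branches = beta.index[beta == 0]
    if len(zero_genes):
        logger.warning("degenerate all-zero gene rows: %s", list(zero_genes))
    if len(zero_branches):
        logger.warning("degenerate all-zero branch columns: %s", list(zero_branches))

    pred = pd.DataFrame(
        total * np.outer(L * alpha, beta),
        index=B.index,
        columns=B.columns,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        interactions = N / pred
    interactions = interactions.where(B.notna())

    return EffectsFit(
        scale_c=total,
        gene_effects=alpha.to_dict(),
        branch_effects=beta.to_dict(),
        interactions=interactions,
    )


def two_way_poisson_loglik(
    scaled_lengths: pd.DataFrame,
    lengths: dict[str, int],
    c: float,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> float:
    """Poisson log-likelihood of scaled counts N_ik at given effects.

    Constant terms (log N!) are dropped; used by tests to cross-check the
    closed forms against direct numerical maximization.
    """
    B = scaled_lengths.to_numpy(dtype=float)
    L = np.array([float(lengths[g]) for g in scaled_lengths.index])
    N = B * L[:, None]
    mu = c * np.outer(L * alpha, beta)
    mask = ~np.isnan(N)
    with np.errstate(divide="ignore"):
        ll = N[mask] * np.log(mu[mask]) - mu[mask]
    # 0 * log(0) -> 0 by convention
    ll = np.where(np.isnan(ll) & (N[mask] == 0), -mu[mask], ll)
    return float(ll.sum())
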