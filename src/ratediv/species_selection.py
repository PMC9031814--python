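"""Species-specific selection signals from diversity deviations.

Observed segregating-site counts are compared with the negative-binomial
prediction from long-term rates: the lower-tail mid-p value of each gene
measures its deficit (enhanced constraint, small p) or excess (reduced
constraint, large p) of diversity. The p-values are mapped through the
standard-normal quantile, averaged within gene sets and referred to a
t-distribution; negative t marks enhanced constraint / purifying selection
in the focal species, positive t relaxed constraint / diversifying
selection. Significant sets are selected by Benjamini-Hochberg FDR. PCA of
diversity-plus-rate matrices and correspondence analysis of -log10(p)
profiles synthesize the signals across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ratediv")

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass
class GeneDeviation:
    gene_id: str
    observed_K: int
    mu: float
    theta: float
    p_lower: float
    z: float


@dataclass
class GeneSetResult:
    set_id: str
    m: int
    t_value: float
    p_value: float
    significant: bool = False


def gene_deviation_pvalue(
    observed_K: int, mu: float, theta: float, gene_id: str = ""
) -> GeneDeviation:
    """Lower-tail mid-p of an observed count under NB(mean mu, shape theta).

    The mid-p counts half the probability mass of the observed count:
    P(X < K) + 0.5 P(X = K). For a discrete statistic the plain lower tail
    is stochastically larger than uniform and would bias every normal
    quantile upward; the mid-p restores mean 1/2 under the null exactly.
    """
    if mu <= 0 or theta <= 0:
        raise ValueError("need mu > 0 and theta > 0")
    p_nb = theta / (theta + mu)
    p = stats.nbinom.cdf(observed_K - 1, theta, p_nb) + 0.5 * stats.nbinom.pmf(
        observed_K, theta, p_nb
    )
    p = float(np.clip(p, _P_FLOOR, _P_CEIL))
    return GeneDeviation(
        gene_id=gene_id,
        observed_K=int(observed_K),
        mu=float(mu),
        theta=float(theta),
        p_lower=p,
        z=float(stats.norm.ppf(p)),
    )


def gene_deviation_table(
    observed_K: np.ndarray, mu: np.ndarray, theta: float, gene_ids=None
) -> pd.DataFrame:
    """Vectorized mid-p deviations for many genes at one shape parameter."""
    observed_K = np.asarray(observed_K)
    mu = np.asarray(mu, dtype=float)
    p_nb = theta / (theta + mu)
    p = stats.nbinom.cdf(observed_K - 1, theta, p_nb) + 0.5 * stats.nbinom.pmf(
        observed_K, theta, p_nb
    )
    p = np.clip(p, _P_FLOOR, _P_CEIL)
    return pd.DataFrame(
        {
            "gene_id": gene_ids if gene_ids is not None else np.arange(len(mu)),
            "observed_K": observed_K,
            "mu": mu,
            "theta": theta,
            "p_lower": p,
            "z": stats.norm.ppf(p),
        }
    )


def gene_set_t_test(deviations: list[GeneDeviation] | np.ndarray, set_id: str = "") -> GeneSetResult:
    """One-sample t test of the normal-quantile deviations of a gene set.

    t = mean(z) / (sd(z)/sqrt(m)) with the sample sd; the two-sided p comes
    from the t distribution with m - 1 degrees of freedom. The sign of t
    carries the direction: negative = enhanced constraint, positive =
    relaxed constraint.
    """
    if isinstance(deviations, np.ndarray):
        z = deviations.astype(float)
    else:
        z = np.array([d.z for d in deviations], dtype=float)
    m = z.size
    if m < 2:
        raise ValueError("gene set needs at least two genes")
    sd = float(z.std(ddof=1))
    mean = float(z.mean())
    if sd == 0.0:
        if mean == 0.0:
            logger.warning("gene set %s: all z equal 0; t = 0", set_id)
            return GeneSetResult(set_id=set_id, m=m, t_value=0.0, p_value=1.0)
        logger.warning("gene set %s: zero spread with nonzero mean; sd floored", set_id)
        sd = 1e-12
    t = mean / (sd / np.sqrt(m))
    p = float(2.0 * stats.t.sf(abs(t), df=m - 1))
    return GeneSetResult(set_id=set_id, m=m, t_value=float(t), p_value=min(p, 1.0))


def gene_set_tests(
    deviations: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    min_size: int = 2,
) -> pd.DataFrame:
    """Run the set-level t test for every gene set with >= min_size members
    present in the deviation table; smaller sets are skipped with a log."""
    z_by_gene = dict(zip(deviations["gene_id"], deviations["z"]))
    rows = []
    skipped = 0
    for sid, members in gene_sets.items():
        z = np.array([z_by_gene[g] for g in members if g in z_by_gene])
        if z.size < min_size:
            skipped += 1
            continue
        r = gene_set_t_test(z, set_id=sid)
        rows.append((r.set_id, r.m, r.t_value, r.p_value))
    if skipped:
        logger.info("gene_set_tests: skipped %d sets below min size %d", skipped, min_size)
    return pd.DataFrame(rows, columns=["set_id", "m", "t_value", "p_value"])


def bh_select(p_values: np.ndarray, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection mask at the given FDR."""
    p = np.asarray(p_values, dtype=float)
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = ranked <= fdr * (np.arange(1, n + 1) / n)
    mask = np.zeros(n, dtype=bool)
    if passing.any():
        k = int(np.nonzero(passing)[0].max())
        mask[order[: k + 1]] = True
    return mask


# ---------------------------------------------------------------------------
# cross-species ordination
# ---------------------------------------------------------------------------

def pca_species(
    matrix: pd.DataFrame, standardize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """SVD-based PCA of a genes x (per-species q + rate) matrix.

    Columns are centered and, by default, scaled to unit variance. Component
    signs are fixed so the largest-magnitude loading of each component is
    positive. Returns (scores, loadings, explained-variance fractions).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two columns")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"constant column(s): {list(matrix.columns[zero])}")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    explained = var / var.sum()
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    scores = pd.DataFrame(U * s, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names)
    return scores, loadings, explained


def ca_profiles(
    matrix: pd.DataFrame, n_axes: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Correspondence analysis of a nonnegative items x species matrix.

    Typically applied to -log10(p) profiles. All-zero rows/columns are
    dropped with a warning. Returns row and column principal coordinates
    (scaled by singular values) and the inertia fractions; total inertia
    equals the matrix chi-square statistic over the grand total.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis needs nonnegative entries")
    keep_r = X.sum(axis=1) > 0
    keep_c = X.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning(
            "ca_profiles: dropped %d all-zero rows, %d all-zero columns",
            int((~keep_r).sum()), int((~keep_c).sum()),
        )
    X = X[np.ix_(keep_r, keep_c)]
    total = X.sum()
    if total == 0:
        raise ValueError("zero grand total")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    n_axes = min(n_axes, len(s))
    inertia = s**2
    frac = inertia / inertia.sum() if inertia.sum() > 0 else inertia
    row_coords = (U[:, :n_axes] * s[:n_axes]) / np.sqrt(r)[:, None]
    col_coords = (Vt[:n_axes].T * s[:n_axes]) / np.sqrt(c)[:, None]
    axes = [f"CA{j + 1}" for j in range(n_axes)]
    rows = pd.DataFrame(row_coords, index=matrix.index[keep_r], columns=axes)
    cols = pd.DataFrame(col_coords, index=matrix.columns[keep_c], columns=axes)
    return rows, cols, frac


def neglog10_profile(p_matrix: pd.DataFrame, floor: float = 1e-300) -> pd.DataFrame:
    """-log10 transform of a p-value matrix with flooring at 1e-300."""
    return -np.log10(p_matrix.clip(lower=floor))
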