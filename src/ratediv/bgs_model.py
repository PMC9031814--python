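"""Background-selection / hitchhiking model of window diversity.

Neutral diversity pi0 at a target window is reduced by purifying selection
acting on the exon windows of the chromosome. Each exon window i, with
selective effect sh_i and recombination fraction R_i to the target,
contributes a multiplicative factor

    1 - U * dx * sh_i / (2 * (sh_i + R_i)^2),

with U the deleterious mutation rate per position per haploid genome and dx
the window width. The selective effect is tied to the long-term molecular
evolutionary rate r_i of the gene spanning the window through
sh_i = exp(alpha + beta * r_i). The product over exon windows is well
approximated by the exponential of the summed (negated) terms, and that
exponential form is what the nonlinear least-squares fit uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("ratediv")

DEFAULT_U = 1e-8
DEFAULT_DELTA_X = 1000


@dataclass
class BGSParams:
    """Parameters of the background-selection model for one (chrom, feature)."""

    pi0: float
    alpha_sel: float
    beta_sel: float
    U: float = DEFAULT_U
    delta_x: int = DEFAULT_DELTA_X

    def sh(self, rates: np.ndarray) -> np.ndarray:
        return np.exp(self.alpha_sel + self.beta_sel * np.asarray(rates, dtype=float))


def _reduction_terms(
    R: np.ndarray, rates: np.ndarray, alpha: float, beta: float, U: float, delta_x: int
) -> np.ndarray:
    """Per-exon-window terms U*dx*sh / (2*(sh+R)^2); shape of R broadcast."""
    sh = np.exp(alpha + beta * np.asarray(rates, dtype=float))
    return U * delta_x * sh / (2.0 * (sh + R) ** 2)


def bgs_predict_pi(
    target_cM: float,
    exon_cM: np.ndarray,
    exon_rates: np.ndarray,
    params: BGSParams,
    mode: str = "exp_approx",
) -> float:
    """Predicted diversity of one target window given the chromosome's exons.

    ``exon_cM`` and ``exon_rates`` give each exon window's genetic-map
    position and the long-term rate of its gene; the recombination fraction
    to the target comes from the Haldane map function on cM distance.
    ``mode`` selects the exact product form or its exponential
    approximation. Product terms exceeding 1 (a reduction below zero) are
    clamped with a warning.
    """
    d = np.abs(np.asarray(exon_cM, dtype=float) - target_cM)
    R = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    terms = _reduction_terms(R, exon_rates, params.alpha_sel, params.beta_sel, params.U, params.delta_x)
    if mode == "product":
        if (terms > 1.0).any():
            logger.warning("bgs_predict_pi: %d per-window terms exceed 1; clamped", int((terms > 1).sum()))
            terms = np.clip(terms, 0.0, 1.0)
        return float(params.pi0 * np.prod(1.0 - terms))
    if mode == "exp_approx":
        return float(params.pi0 * np.exp(-terms.sum()))
    raise ValueError(f"unknown mode {mode!r}")


def _predict_matrix(
    pi0: float, alpha: float, beta: float,
    R_matrix: np.ndarray, exon_rates: np.ndarray, U: float, delta_x: int,
) -> np.ndarray:
    """Vectorized exp-approx prediction for all target windows at once."""
    terms = _reduction_terms(R_matrix, exon_rates[None, :], alpha, beta, U, delta_x)
    return pi0 * np.exp(-terms.sum(axis=1))


@dataclass
class BGSFitResult:
    params: BGSParams
    rss: float
    n_windows: int
    n_iterations: int
    flat_likelihood: bool = False


def fit_bgs(
    target_windows: pd.DataFrame,
    exon_windows: pd.DataFrame,
    U: float = DEFAULT_U,
    delta_x: int = DEFAULT_DELTA_X,
) -> BGSFitResult:
    """Nonlinear least-squares fit of (pi0, alpha, beta) for one chrom x feature.

    ``target_windows`` needs columns pi and map_cM; ``exon_windows`` needs
    map_cM and rate. The exponential-approximation form is fitted by
    trust-region least squares with multiple starts over beta; pi0 is
    initialized from the windows genetically farthest from any exon. A fit
    whose reduction factors are all ~1 regardless of (alpha, beta) is
    flagged flat (unidentifiable selection parameters).
    """
    pi_obs = target_windows["pi"].to_numpy(dtype=float)
    tgt_cM = target_windows["map_cM"].to_numpy(dtype=float)
    exon_cM = exon_windows["map_cM"].to_numpy(dtype=float)
    rates = exon_windows["rate"].to_numpy(dtype=float)
    if len(pi_obs) < 50:
        raise ValueError("need at least 50 target windows to fit")

    d = np.abs(tgt_cM[:, None] - exon_cM[None, :])
    R = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))

    # init pi0 from the 10% of targets farthest (in cM) from the nearest exon
    dist_to_exon = d.min(axis=1)
    k = max(1, len(pi_obs) // 10)
    far = np.argsort(dist_to_exon)[-k:]
    pi0_init = float(np.mean(pi_obs[far]))
    if pi0_init <= 0:
        pi0_init = max(float(np.mean(pi_obs)), 1e-6)

    def residuals(x):
        pi0, alpha, beta = x
        return _predict_matrix(pi0, alpha, beta, R, rates, U, delta_x) - pi_obs

    best = None
    for beta0 in (0.0, 10.0, -10.0, 100.0, -100.0):
        try:
            res = optimize.least_squares(
                residuals,
                x0=np.array([pi0_init, np.log(0.01), beta0]),
                method="lm" if len(pi_obs) >= 3 else "trf",
                xtol=1e-12, ftol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-18:
            best = res
    if best is None:
        raise RuntimeError("background-selection fit failed from all starts")

    pi0, alpha, beta = best.x
    if pi0 < 0:
        logger.warning("fit_bgs: negative pi0 at optimum (%.3g)", pi0)
    params = BGSParams(pi0=float(pi0), alpha_sel=float(alpha), beta_sel=float(beta), U=U, delta_x=delta_x)

    # flat-likelihood detection: reduction indistinguishable from none
    pred = _predict_matrix(pi0, alpha, beta, R, rates, U, delta_x)
    reduction = pred / pi0 if pi0 != 0 else np.ones_like(pred)
    flat = bool(np.ptp(reduction) < 1e-6)
    if flat:
        logger.warning("fit_bgs: selection parameters unidentifiable (flat reduction)")

    return BGSFitResult(
        params=params,
        rss=float(2.0 * best.cost),
        n_windows=len(pi_obs),
        n_iterations=int(best.nfev),
        flat_likelihood=flat,
    )


def reduction_factors(
    fit: BGSFitResult, target_cM: np.ndarray, exon_cM: np.ndarray, exon_rates: np.ndarray
) -> np.ndarray:
    """Per-target-window predicted diversity reduction pi/pi0 (exp form)."""
    d = np.abs(np.asarray(target_cM)[:, None] - np.asarray(exon_cM)[None, :])
    R = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    p = fit.params
    terms = _reduction_terms(R, np.asarray(exon_rates)[None, :], p.alpha_sel, p.beta_sel, p.U, p.delta_x)
    return np.exp(-terms.sum(axis=1))


# ---------------------------------------------------------------------------
# two-way variance decomposition of fitted parameters
# ---------------------------------------------------------------------------

def anova_decompose_params(fit_table: pd.DataFrame, param: str) -> dict:
    """Two-way ANOVA (no replication) of one fitted parameter over
    chromosome x feature.

    Returns the variance shares of the chromosome main effect, the feature
    main effect and the residual (interaction), which sum to 1, plus the two
    main-effect F-test p-values. Requires a complete grid with one value per
    cell.
    """
    grid = fit_table.pivot(index="chrom", columns="feature", values=param)
    if grid.isna().any().any():
        raise ValueError("incomplete chrom x feature grid")
    X = grid.to_numpy(dtype=float)
    a, b = X.shape  # chromosomes x features
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_chrom = b * float(((row_means - grand) ** 2).sum())
    ss_feature = a * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_resid = ss_total - ss_chrom - ss_feature
    if ss_total == 0:
        raise ValueError("no variance to decompose")

    df_chrom, df_feature = a - 1, b - 1
    df_resid = df_chrom * df_feature
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    f_chrom = (ss_chrom / df_chrom) / ms_resid if ms_resid > 0 else np.inf
    f_feature = (ss_feature / df_feature) / ms_resid if ms_resid > 0 else np.inf
    p_chrom = float(stats.f.sf(f_chrom, df_chrom, df_resid))
    p_feature = float(stats.f.sf(f_feature, df_feature, df_resid))

    return {
        "param": param,
        "share_chrom": ss_chrom / ss_total,
        "share_feature": ss_feature / ss_total,
        "share_residual": ss_resid / ss_total,
        "p_chrom": p_chrom,
        "p_feature": p_feature,
    }
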