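"""Raw and bias-corrected (disattenuated) correlation, and the coalescent
variance of the number of segregating sites.

Per-gene rate estimates and diversity counts both carry sampling noise, so
their observed Pearson correlation understates the latent among-gene
correlation. The correction multiplies the raw correlation by the square
root of the two inflation factors 1 + mean-sampling-variance /
among-gene-variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("ratediv")


@dataclass
class CorrelationResult:
    raw_r: float
    corrected_r: float
    inflation_B: float
    inflation_K: float
    n_genes: int


def corrected_correlation(
    b_hat: np.ndarray,
    k_hat: np.ndarray,
    vs_b: np.ndarray,
    vs_k: np.ndarray,
    exact_disattenuation: bool = False,
) -> CorrelationResult:
    """Attenuation-corrected correlation between rate and diversity vectors.

    ``vs_b`` and ``vs_k`` are per-gene sampling variances of the observed
    values. The default correction divides the mean sampling variance by the
    among-gene variance of the OBSERVED vector; ``exact_disattenuation``
    instead divides by the latent variance estimate (observed variance minus
    mean sampling variance), the classical errors-in-variables form. The
    corrected value is clamped to [-1, 1] with a warning if the estimator
    overshoots.
    """
    b_hat = np.asarray(b_hat, dtype=float)
    k_hat = np.asarray(k_hat, dtype=float)
    vs_b = np.asarray(vs_b, dtype=float)
    vs_k = np.asarray(vs_k, dtype=float)
    n = b_hat.size
    if not (b_hat.size == k_hat.size == vs_b.size == vs_k.size) or n < 3:
        raise ValueError("need four equal-length vectors with n >= 3")
    if (vs_b < 0).any() or (vs_k < 0).any():
        raise ValueError("negative sampling variances")

    var_b = float(np.var(b_hat, ddof=1))
    var_k = float(np.var(k_hat, ddof=1))
    if var_b == 0 or var_k == 0:
        raise ValueError("zero among-gene variance")

    raw = float(np.corrcoef(b_hat, k_hat)[0, 1])
    mean_vs_b = float(vs_b.mean())
    mean_vs_k = float(vs_k.mean())

    if exact_disattenuation:
        denom_b = var_b - mean_vs_b
        denom_k = var_k - mean_vs_k
        if denom_b <= 0 or denom_k <= 0:
            raise ValueError("sampling variance exceeds observed variance; latent variance <= 0")
        infl_b = var_b / denom_b
        infl_k = var_k / denom_k
    else:
        infl_b = 1.0 + mean_vs_b / var_b
        infl_k = 1.0 + mean_vs_k / var_k

    corrected = raw * math.sqrt(infl_b * infl_k)
    if abs(corrected) > 1.0:
        logger.warning("corrected correlation %.4f outside [-1, 1]; clamped", corrected)
        corrected = math.copysign(1.0, corrected)

    return CorrelationResult(
        raw_r=raw,
        corrected_r=corrected,
        inflation_B=infl_b,
        inflation_K=infl_k,
        n_genes=n,
    )


def watterson_a_b(n_chromosomes: int) -> tuple[float, float]:
    """Harmonic sums a_n = sum 1/i and b_n = sum 1/i^2 for i = 1..n-1."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n_chromosomes, dtype=float)
    return float((1.0 / i).sum()), float((1.0 / i**2).sum())


def variance_of_K(expected_K: float, n_chromosomes: int) -> float:
    """Equilibrium coalescent variance of the number of segregating sites.

    V(K) = E(K) + E(K)^2 * b_n / a_n^2. The first term is mutation
    randomness, the second the stochasticity of the genealogy.
    """
    if expected_K < 0:
        raise ValueError("expected_K must be >= 0")
    a_n, b_n = watterson_a_b(n_chromosomes)
    return expected_K + expected_K**2 * b_n / a_n**2


def variance_of_K_nonequilibrium(expected_K: float, mean_Tc: float, var_Tc: float) -> float:
    """Variance of K for a population with arbitrary history.

    V(K) = E(K) + E(K)^2 * V(Tc) / E(Tc)^2, with Tc the total coalescent
    waiting time of the genealogy. Matches the negative-binomial variance
    identity V = E + E^2 / theta at theta = E(Tc)^2 / V(Tc), which motivates
    the negative-binomial regression of K.
    """
    if mean_Tc <= 0 or var_Tc < 0:
        raise ValueError("need mean_Tc > 0 and var_Tc >= 0")
    return expected_K + expected_K**2 * var_Tc / mean_Tc**2
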