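"""Deviation p-values, gene-set tests, BH selection, PCA and CA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ratediv.species_selection import (
    bh_select,
    ca_profiles,
    gene_deviation_pvalue,
    gene_deviation_table,
    gene_set_t_test,
    gene_set_tests,
    neglog10_profile,
    pca_species,
)


class TestDeviationPvalue:
    def test_poisson_limit_zero_count(self):
        d = gene_deviation_pvalue(0, mu=5.0, theta=1e12)
        assert d.p_lower == pytest.approx(0.5 * np.exp(-5), rel=1e-6)
        assert d.z == pytest.approx(stats.norm.ppf(d.p_lower))

    def test_large_count_upper_tail(self):
        d = gene_deviation_pvalue(500, mu=5.0, theta=10.0)
        assert d.p_lower > 0.999
        assert d.z > 3.0

    def test_midp_averages_to_half(self):
        """Sum over the NB support of pmf * mid-p equals exactly 1/2."""
        mu, theta = 8.0, 4.0
        p_nb = theta / (theta + mu)
        ks = np.arange(0, 2000)
        pmf = stats.nbinom.pmf(ks, theta, p_nb)
        midp = stats.nbinom.cdf(ks - 1, theta, p_nb) + 0.5 * pmf
        assert float((pmf * midp).sum()) == pytest.approx(0.5, abs=1e-10)

    def test_vectorized_matches_scalar(self):
        tab = gene_deviation_table(np.array([0, 3, 10]), np.array([5.0, 5.0, 5.0]), 7.0)
        for i, k in enumerate([0, 3, 10]):
            d = gene_deviation_pvalue(k, 5.0, 7.0)
            assert tab["p_lower"].iloc[i] == pytest.approx(d.p_lower)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gene_deviation_pvalue(1, mu=0.0, theta=1.0)

    def test_null_uniformity(self):
        """Under the null — counts drawn from each gene's fitted NB mean —
        the mid-p values are approximately uniform."""
        rng = np.random.default_rng(71)
        n, theta = 50_000, 10.0
        L = np.maximum(np.round(rng.lognormal(7.2, 0.6, n)), 100)
        rates = rng.lognormal(np.log(0.03), 0.7, n)
        mu = L * np.exp(-2.177 + 0.413 * np.log(rates))
        K = rng.negative_binomial(theta, theta / (theta + mu), n)
        tab = gene_deviation_table(K, mu, theta)
        ks = stats.kstest(tab["p_lower"], "uniform").statistic
        assert ks < 0.02


class TestGeneSetTest:
    def test_symmetric_pair(self):
        r = gene_set_t_test(np.array([-1.0, 1.0]))
        assert r.t_value == 0.0 and r.p_value == 1.0

    def test_known_t_value(self):
        z = np.array([0.5, 1.0, 1.5, 2.0])
        r = gene_set_t_test(z)
        expected_t = z.mean() / (z.std(ddof=1) / 2)
        assert r.t_value == pytest.approx(expected_t)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(expected_t), df=3))

    def test_order_invariance(self):
        z = np.array([0.3, -1.2, 2.0, 0.1, -0.5])
        r1 = gene_set_t_test(z)
        r2 = gene_set_t_test(z[::-1].copy())
        assert r1.t_value == pytest.approx(r2.t_value)

    def test_degenerate_all_equal_zero(self):
        r = gene_set_t_test(np.zeros(5))
        assert r.t_value == 0.0 and r.p_value == 1.0

    def test_too_small_set(self):
        with pytest.raises(ValueError):
            gene_set_t_test(np.array([1.0]))

    def test_min_size_skip(self):
        dev = pd.DataFrame({"gene_id": ["a", "b", "c"], "z": [0.1, -0.2, 0.5]})
        out = gene_set_tests(dev, {"s1": ["a"], "s2": ["a", "b", "c"]})
        assert list(out["set_id"]) == ["s2"]

    def test_null_set_pvalues_uniform(self):
        rng = np.random.default_rng(72)
        pvals = []
        for _ in range(2000):
            z = stats.norm.ppf(rng.uniform(size=10))
            pvals.append(gene_set_t_test(z).p_value)
        assert stats.kstest(pvals, "uniform").statistic < 0.05

    def test_direction_of_shift(self):
        """Sets with inflated counts give positive t, deflated negative."""
        rng = np.random.default_rng(73)
        mu, theta = 30.0, 10.0
        t_up, t_down = [], []
        for _ in range(50):
            for delta, sink in [(0.3, t_up), (-0.3, t_down)]:
                K = rng.negative_binomial(theta, theta / (theta + mu * np.exp(delta)), 20)
                tab = gene_deviation_table(K, np.full(20, mu), theta)
                sink.append(gene_set_t_test(tab["z"].to_numpy()).t_value)
        assert np.median(t_up) > 0 > np.median(t_down)


class TestBH:
    def test_hand_computed_example(self):
        mask = bh_select(np.array([0.01, 0.02, 0.5]), fdr=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_ones(self):
        assert not bh_select(np.ones(10), fdr=0.05).any()

    def test_extreme_p_selected(self):
        p = np.concatenate([[1e-9], np.random.default_rng(1).uniform(0.2, 1, 999)])
        assert bh_select(p, fdr=0.01)[0]

    def test_step_up_monotone(self):
        rng = np.random.default_rng(74)
        p = rng.uniform(size=200)
        mask = bh_select(p, fdr=0.2)
        if mask.any():
            thresh = p[mask].max()
            assert ((p <= thresh) == mask).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(75)
        p = rng.uniform(size=500) ** 2
        ours = bh_select(p, fdr=0.1)
        ref = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        assert (ours == ref).all()


class TestPCA:
    def test_perfectly_correlated_columns(self):
        rng = np.random.default_rng(76)
        x = rng.normal(size=100)
        m = pd.DataFrame({"a": x, "b": 2 * x + 1})
        _, _, frac = pca_species(m)
        assert frac[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(77)
        m = pd.DataFrame(rng.normal(size=(200, 6)))
        _, _, frac = pca_species(m)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_loadings_match_eigendecomposition(self):
        rng = np.random.default_rng(78)
        m = pd.DataFrame(rng.normal(size=(5, 3)) @ np.diag([3.0, 1.0, 0.5]))
        _, loadings, frac = pca_species(m, standardize=True)
        C = np.corrcoef(m.to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        assert np.allclose(frac, w / w.sum(), atol=1e-10)
        for j in range(3):
            a = loadings.to_numpy()[:, j]
            b = v[:, j]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            pca_species(m)

    def test_sign_convention(self):
        rng = np.random.default_rng(79)
        m = pd.DataFrame(rng.normal(size=(50, 4)))
        _, loadings, _ = pca_species(m)
        for j in range(loadings.shape[1]):
            col = loadings.to_numpy()[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestCA:
    def test_independence_zero_inertia(self):
        r = np.array([0.2, 0.3, 0.5])
        c = np.array([0.6, 0.4])
        m = pd.DataFrame(np.outer(r, c) * 100)
        _, _, frac = ca_profiles(m)
        # all singular values ~0 -> total inertia ~0; fractions are 0/0 safe
        X = m.to_numpy() / m.to_numpy().sum()
        S = (X - np.outer(X.sum(1), X.sum(0))) / np.sqrt(np.outer(X.sum(1), X.sum(0)))
        assert np.linalg.norm(S) < 1e-12

    def test_row_coordinates_match_svd_oracle(self):
        rng = np.random.default_rng(80)
        m = pd.DataFrame(rng.uniform(0.1, 5, size=(3, 3)))
        rows, cols, frac = ca_profiles(m, n_axes=2)
        P = m.to_numpy() / m.to_numpy().sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, s, Vt = np.linalg.svd(S)
        expected = np.abs(U[:, :2] * s[:2] / np.sqrt(r)[:, None])
        assert np.allclose(np.abs(rows.to_numpy()), expected, atol=1e-10)
        assert np.allclose(frac, s**2 / (s**2).sum(), atol=1e-10)

    def test_total_inertia_equals_chi2_over_total(self):
        rng = np.random.default_rng(81)
        m = pd.DataFrame(rng.integers(1, 50, size=(6, 4)).astype(float))
        _, _, frac = ca_profiles(m)
        chi2 = stats.chi2_contingency(m.to_numpy())[0]
        X = m.to_numpy()
        P = X / X.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        total_inertia = (np.linalg.svd(S, compute_uv=False) ** 2).sum()
        assert total_inertia == pytest.approx(chi2 / X.sum(), rel=1e-10)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(82)
        m = pd.DataFrame(rng.uniform(0.1, 5, size=(5, 3)), index=list("abcde"))
        rows1, _, _ = ca_profiles(m)
        perm = ["c", "a", "e", "b", "d"]
        rows2, _, _ = ca_profiles(m.loc[perm])
        assert np.allclose(rows1.loc[perm].to_numpy(), rows2.to_numpy(), atol=1e-12)

    def test_all_zero_rows_dropped(self):
        m = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        rows, _, _ = ca_profiles(m)
        assert len(rows) == 2

    def test_neglog_profile_floors(self):
        m = pd.DataFrame({"s": [0.0, 1e-10, 0.5]})
        out = neglog10_profile(m)
        assert out["s"].iloc[0] == pytest.approx(300.0)
        assert out["s"].iloc[2] == pytest.approx(-np.log10(0.5))
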