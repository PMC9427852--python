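import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from tntseq import call_degs, estimate_size_factors, nb_wald_test
from tntseq.synthetic import SimulationSpec, simulate_paired_counts

A_COLS = ["A_1", "A_2", "A_3"]
B_COLS = ["B_1", "B_2", "B_3"]
LN2 = np.log(2.0)


def frame(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)


class TestSizeFactors:
    def test_identical_samples(self):
        counts = frame([[10, 10], [5, 5], [100, 100]])
        np.testing.assert_allclose(estimate_size_factors(counts).values, [1, 1])

    def test_doubled_library(self):
        counts = frame([[10, 20], [7, 14], [200, 400]])
        np.testing.assert_allclose(estimate_size_factors(counts).values,
                                   [2 ** -0.5, 2 ** 0.5])

    def test_single_sample_and_geometric_mean_one(self):
        assert estimate_size_factors(frame([[5]])).iloc[0] == 1.0
        rng = np.random.default_rng(0)
        counts = frame(rng.poisson(40, (100, 5)) + 1)
        sf = estimate_size_factors(counts)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_no_common_gene_errors(self):
        with pytest.raises(ValueError):
            estimate_size_factors(frame([[0, 5], [5, 0]]))


class TestWaldTest:
    def test_identical_conditions_give_null_result(self):
        counts = frame(np.tile([[20, 30, 25]], (5, 1)).repeat(2, axis=1)
                       [:, [0, 2, 4, 1, 3, 5]])
        # columns: (20,30,25) in both conditions
        a = frame(np.tile([20, 30, 25], (5, 1)))
        res = nb_wald_test(a, a.copy())
        np.testing.assert_allclose(res["log2_fold_change"].values, 0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"].values, 1, atol=1e-12)

    def test_fold_change_recovery_four_fold_shift(self):
        # direct NB draws with equal library sizes: median lfc near 2
        rng = np.random.default_rng(42)
        n = 500
        mu = 2.0 ** rng.normal(6, 1.5, n)
        alpha = 0.05
        draw = lambda m: rng.negative_binomial(1 / alpha, 1 / (1 + alpha * m),
                                               size=(3, n)).T
        a = frame(draw(mu))
        b = frame(draw(4 * mu))
        res = nb_wald_test(a, b, size_factors=np.ones(6))
        assert res["log2_fold_change"].median() == pytest.approx(2.0, abs=0.2)

    def test_swapping_conditions_negates_lfc(self):
        spec = SimulationSpec(n_genes=300, dispersion=0.05, seed=8)
        tx, _, _ = simulate_paired_counts(spec)
        fwd = nb_wald_test(tx[A_COLS], tx[B_COLS])
        rev = nb_wald_test(tx[B_COLS], tx[A_COLS])
        np.testing.assert_allclose(fwd["log2_fold_change"].values,
                                   -rev["log2_fold_change"].values, atol=1e-8)
        np.testing.assert_allclose(fwd["p_value"].values, rev["p_value"].values,
                                   atol=1e-8)

    def test_library_scaling_is_absorbed_by_normalisation(self):
        spec = SimulationSpec(n_genes=300, dispersion=0.05,
                              class_fractions={"unchanged": 0.9, "I": 0.05,
                                               "IV": 0.05}, seed=15)
        tx, _, _ = simulate_paired_counts(spec)
        res = nb_wald_test(tx[A_COLS], tx[B_COLS])
        scaled = tx.copy()
        scaled["A_2"] *= 3
        res2 = nb_wald_test(scaled[A_COLS], scaled[B_COLS])
        np.testing.assert_allclose(res["log2_fold_change"].values,
                                   res2["log2_fold_change"].values, atol=0.05)
        assert call_degs(res) == call_degs(res2)

    def test_wald_statistic_and_pvalue_consistency(self):
        spec = SimulationSpec(n_genes=100, dispersion=0.1, seed=3)
        tx, _, _ = simulate_paired_counts(spec)
        res = nb_wald_test(tx[A_COLS], tx[B_COLS])
        np.testing.assert_allclose(
            res["stat"].values,
            (res["log2_fold_change"] / res["lfc_se"]).values, atol=1e-8)
        np.testing.assert_allclose(
            res["p_value"].values,
            2 * stats.norm.sf(np.abs(res["stat"].values)), atol=1e-8)

    def test_null_pvalues_near_uniform(self):
        spec = SimulationSpec(n_genes=2000, n_per_condition=3, dispersion=0.1,
                              class_fractions={"unchanged": 1.0}, seed=2)
        tx, _, _ = simulate_paired_counts(spec)
        res = nb_wald_test(tx[A_COLS], tx[B_COLS])
        ks = stats.kstest(res["p_value"].values, "uniform").statistic
        assert ks < 0.05


class TestOracleEquivalence:
    """Wald statistics match a direct numeric NB likelihood fit."""

    @staticmethod
    def _oracle_stat(ka, kb, alpha):
        def fit(k):
            n_nb = 1.0 / alpha

            def nll(mu):
                p = 1.0 / (1.0 + alpha * mu)
                return -stats.nbinom.logpmf(k, n_nb, p).sum()

            res = optimize.minimize_scalar(nll, bounds=(1e-4, 1e7),
                                           method="bounded",
                                           options={"xatol": 1e-10})
            mu = res.x
            h = 1e-4 * mu
            d2 = (nll(mu + h) - 2 * nll(mu) + nll(mu - h)) / h ** 2
            var_log2 = 1.0 / (d2 * (mu * LN2) ** 2)
            return mu, var_log2

        mu_a, va = fit(ka)
        mu_b, vb = fit(kb)
        return np.log2(mu_b / mu_a) / np.sqrt(va + vb)

    def test_statistics_match_direct_fit(self):
        rng = np.random.default_rng(20)
        alpha = 0.1
        n = 20
        mu = 2.0 ** rng.normal(6, 1, n)
        shift = np.where(rng.random(n) < 0.5, 1.0, 3.0)
        ka = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), (3, n)).T
        kb = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu * shift),
                                   (3, n)).T
        res = nb_wald_test(frame(ka), frame(kb), dispersion=alpha,
                           size_factors=np.ones(6), shrink=False)
        oracle = np.array([self._oracle_stat(ka[i], kb[i], alpha)
                           for i in range(n)])
        np.testing.assert_allclose(res["stat"].values, oracle, atol=1e-3)


class TestCallDegs:
    def test_threshold_rules_are_strict(self):
        res = pd.DataFrame(
            {
                "log2_fold_change": [1.5, 1.0, 3.0, -1.4, -1.0],
                "p_value": [0.04, 0.04, 0.06, 0.01, 0.01],
            },
            index=["up_ok", "boundary_lfc", "high_p", "down_ok", "boundary_dn"],
        )
        up, down = call_degs(res)
        assert up == {"up_ok"}
        assert down == {"down_ok"}
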