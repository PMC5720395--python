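import numpy as np
import pytest
from scipy import optimize, stats

import somatic_dnds as sd
from somatic_dnds.dndscv import (combine_fisher, fit_nb_background, gene_lrt,
                                 indel_test, nb_sf, run_dndscv,
                                 shrunk_expected_syn, significance)
from somatic_dnds.synthetic_data import GeneTruth, TruthSheet


class TestShrunkExpectedSyn:
    def test_printed_example(self):
        theta, mu = 6.03, 4.0
        assert shrunk_expected_syn(5, theta, theta / mu) == pytest.approx(4.0, abs=1e-3)

    def test_matches_numeric_joint_likelihood_maximum(self):
        # oracle: maximize Poisson(n|s) * Gamma(s|alpha,beta) numerically
        for n_s, theta, mu in [(5, 6.03, 4.0), (0, 3.0, 2.0), (12, 1.5, 7.0),
                               (3, 20.0, 3.0)]:
            alpha, beta = theta, theta / mu

            def neg(s):
                s = s[0]
                if s <= 0:
                    return 1e9
                return -(n_s * np.log(s) - s + (alpha - 1) * np.log(s) - beta * s)

            res = optimize.minimize(neg, x0=[max(n_s, 1.0)], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12})
            assert shrunk_expected_syn(n_s, alpha, beta) == pytest.approx(
                res.x[0], rel=1e-4, abs=1e-6)

    def test_prior_dominates_limits(self):
        # large theta: shrinks to mu;  n=0, alpha=1: zero
        assert shrunk_expected_syn(5, 1e6, 1e6 / 4.0) == pytest.approx(4.0, rel=1e-3)
        assert shrunk_expected_syn(0, 1.0, 0.5) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            shrunk_expected_syn(3, 2.0, -0.1)


class TestNBBackground:
    def test_homogeneous_genes_near_poisson(self):
        rng = np.random.default_rng(0)
        expected = np.full(300, 6.0)
        n = rng.poisson(expected)
        fit = fit_nb_background(n, expected)
        assert fit.theta > 50  # little overdispersion left

    def test_recovers_gamma_overdispersion(self):
        rng = np.random.default_rng(1)
        theta = 6.03
        expected = np.full(3000, 8.0)
        lam = expected * rng.gamma(theta, 1 / theta, size=3000)
        n = rng.poisson(lam)
        fit = fit_nb_background(n, expected)
        assert fit.theta == pytest.approx(theta, rel=0.25)

    def test_covariate_absorbs_dispersion(self):
        rng = np.random.default_rng(2)
        J = 1500
        z = rng.normal(size=J)
        lam = 8.0 * np.exp(0.7 * z - 0.245)
        n = rng.poisson(lam)
        without = fit_nb_background(n, np.full(J, 8.0))
        with_cov = fit_nb_background(n, np.full(J, 8.0), covariates=z[:, None])
        assert with_cov.theta > 2 * without.theta

    def test_collinear_covariates_dropped(self):
        rng = np.random.default_rng(3)
        J = 200
        z = rng.normal(size=J)
        C = np.column_stack([z, 2 * z, rng.normal(size=J)])
        fit = fit_nb_background(rng.poisson(np.full(J, 5.0)), np.full(J, 5.0),
                                covariates=C)
        assert 1 not in fit.kept_covariates


class TestGeneLRT:
    def test_neutral_counts_give_omega_one_p_one(self):
        rho = np.array([1.0, 2.0, 0.3, 0.1])
        counts = (10, 20, 3, 1)
        res = gene_lrt(counts, rho, background="loc", test="free_3df")
        assert res["omegas"][1] == pytest.approx(1.0, rel=1e-6)
        assert res["p"] > 0.99

    def test_cv_shrinks_towards_background(self):
        # zero synonymous: loc is degenerate, cv stays finite via the Gamma prior
        rho = np.array([1.0, 2.0, 0.3, 0.1])
        counts = (0, 8, 0, 0)
        theta, mu = 6.03, 3.0
        cv = gene_lrt(counts, rho, background="cv", alpha=theta, beta=theta / mu,
                      test="tied_truncating_2df")
        assert np.isfinite(cv["omegas"][1]) and cv["omegas"][1] < 1e3
        loc = gene_lrt(counts, rho, background="loc", test="tied_truncating_2df")
        assert not np.isfinite(loc["omegas"][1]) or loc["omegas"][1] > cv["omegas"][1]

    def test_cv_converges_to_loc_with_many_synonymous(self):
        # as the dataset grows the NB-predicted count mu_j grows with n_s,
        # the Poisson term dominates the Gamma prior and cv -> loc
        rho = np.array([1.0, 2.0, 0.3, 0.1])
        theta = 6.03
        diffs = []
        for n_s in (2, 20, 200, 2000):
            counts = (n_s, int(1.5 * 2 * n_s), 0, 0)
            mu = 0.8 * n_s   # background prediction off by 20%, scale-tracking
            cv = gene_lrt(counts, rho, background="cv", alpha=theta,
                          beta=theta / mu)
            loc = gene_lrt(counts, rho, background="loc")
            diffs.append(abs(cv["omegas"][1] - loc["omegas"][1])
                         / loc["omegas"][1])
        assert diffs[-1] < 0.01
        assert diffs == sorted(diffs, reverse=True)

    def test_negative_one_sided_direction(self):
        rho = np.array([1.0, 2.0, 0.3, 0.1])
        depleted = gene_lrt((30, 10, 2, 0), rho, background="loc",
                            test="negative_1sided")
        enriched = gene_lrt((10, 80, 2, 0), rho, background="loc",
                            test="negative_1sided")
        assert depleted["p"] < 0.05
        assert enriched["p"] > 0.5

    def test_unif_requires_global_expectation(self):
        rho = np.array([1.0, 2.0, 0.3, 0.1])
        with pytest.raises(Exception):
            gene_lrt((1, 2, 0, 0), rho, background="unif")
        res = gene_lrt((1, 2, 0, 0), rho, background="unif", s_unif=1.2)
        assert 0 <= res["p"] <= 1

    def test_profile_ci_covers_planted_truth(self):
        rng = np.random.default_rng(4)
        rho = np.array([1.0, 2.0, 0.25, 0.08])
        omega_true = 8.0
        s_true = 12.0
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            counts = (rng.poisson(s_true),
                      rng.poisson(s_true * rho[1] * omega_true),
                      rng.poisson(s_true * rho[2]), rng.poisson(s_true * rho[3]))
            res = gene_lrt(counts, rho, background="loc", compute_ci=True)
            lo, hi = res["omega_ci"]["m"]
            covered += lo <= omega_true <= hi
        assert covered >= int(0.85 * n_rep)


class TestIndelTest:
    def test_zero_observed_is_one(self):
        assert indel_test(0, 0, mu=2.0, theta=4.0) == 1.0

    def test_unique_sites_resists_hotspot(self):
        # 5 indels at one site: unique-sites tests 1, total tests 5
        p_unique = indel_test(5, 1, mu=0.5, theta=4.0, mode="unique_sites")
        p_total = indel_test(5, 1, mu=0.5, theta=4.0, mode="total")
        assert p_unique > 0.3
        assert p_total < 0.05

    def test_nb_sf_matches_scipy(self):
        mu, theta = 3.0, 2.5
        p = theta / (theta + mu)
        assert nb_sf(4, mu, theta) == pytest.approx(stats.nbinom.sf(3, theta, p))


class TestFisherAndFDR:
    def test_fisher_examples(self):
        assert combine_fisher(1.0, 1.0) == pytest.approx(1.0)
        assert combine_fisher(0.05, 0.05) == pytest.approx(0.01752, abs=2e-4)
        assert combine_fisher(0.3, 1.0) >= 0.3
        assert combine_fisher(0.2, 0.7) == combine_fisher(0.7, 0.2)

    def test_bh_by_hand(self):
        q = significance(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)
        q = significance(np.ones(5))
        assert np.allclose(q, 1.0)

    def test_bh_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = significance(p).to_numpy()
        assert (np.argsort(p) == np.argsort(q, kind="stable")).all() or \
            np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_restricted_correction(self):
        import pandas as pd
        p = pd.Series([0.004, 0.5, 0.9, 0.004], index=list("abcd"))
        q_all = significance(p)
        q_rht = significance(p, mode="restricted", restricted_genes=["a"])
        assert list(q_rht.index) == ["a"]
        assert q_rht["a"] == pytest.approx(0.004)
        assert q_all["a"] > q_rht["a"]
        with pytest.raises(Exception):
            significance(p, mode="restricted", restricted_genes=[])

    def test_global_matrix_correction(self):
        import pandas as pd
        mat = pd.DataFrame({"g1": [0.001, 0.5], "g2": [0.9, 0.2]},
                           index=["d1", "d2"])
        q = significance(mat, mode="global_matrix_bh")
        assert q.shape == mat.shape
        assert q.loc["d1", "g1"] == pytest.approx(0.004)


@pytest.fixture(scope="module")
def planted_cohort():
    genome = sd.generate_genome(120, seed=17)
    cov, latent = sd.generate_covariates(genome.genes, seed=18,
                                         latent_rate_correlation=0.6)
    truth = TruthSheet(
        genes={"g0007": GeneTruth(omega_m=6.0, omega_t=25.0),
               "g0020": GeneTruth(omega_m=12.0, omega_t=12.0)},
        indel_background_rate=2e-5, indel_driver_rate=0.0)
    prof = sd.spectrum_preset("pancancer_like")
    records, _ = sd.generate_cohort(genome, truth, n_samples=180,
                                    spectrum=prof, seed=19, mean_burden=35,
                                    latent_rates=latent)
    return genome, cov, records


class TestRunDndscv:
    def test_planted_drivers_found_without_false_positives(self, planted_cohort):
        genome, cov, records = planted_cohort
        res = run_dndscv(records, genome.genes, covariates=cov)
        hits = set(res.table.index[res.table.q_sub < 0.05])
        assert {"g0007", "g0020"} <= hits
        assert len(hits) <= 3
        assert res.table.loc["g0007", "omega_t"] > 5

    def test_fisher_column_present_with_indels(self, planted_cohort):
        genome, cov, records = planted_cohort
        res = run_dndscv(records, genome.genes, covariates=cov)
        assert res.indel_background is not None
        assert res.table["p_global"].between(0, 1).all()

    def test_deterministic(self, planted_cohort):
        genome, cov, records = planted_cohort
        r1 = run_dndscv(records, genome.genes, covariates=cov)
        r2 = run_dndscv(records, genome.genes, covariates=cov)
        assert r1.table.equals(r2.table)
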