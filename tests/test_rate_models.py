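import numpy as np
import pytest

import somatic_dnds as sd
from somatic_dnds.rate_models import (FitError, SubstitutionModelSpec,
                                      aggregate_counts, compare_models_aic,
                                      driver_fraction, excess_background_test,
                                      fit_global_model, geneset_dnds,
                                      lost_fraction)
from somatic_dnds.simulate import PatientDesign, build_site_table, draw_class_counts


@pytest.fixture(scope="module")
def agg(neutral_counts, small_comps):
    return aggregate_counts(neutral_counts, small_comps)


class TestGlobalFit:
    def test_exact_expectation_recovers_omega_one(self, small_comps):
        L = sum(c.L for c in small_comps).astype(float)
        rng = np.random.default_rng(1)
        u = rng.gamma(2.0, 1.0, size=L.shape[0])
        n = u[:, None] * L   # counts exactly at neutral expectation
        fit = fit_global_model(n, L, SubstitutionModelSpec(1), "free",
                               compute_ci=False)
        for om in fit.omega.values():
            assert om == pytest.approx(1.0, abs=1e-8)
        # rates recovered up to the pinned reference scale
        mask = L.sum(axis=1) > 0
        ratio = fit.u[mask] / u[mask]
        assert np.allclose(ratio, 1.0, atol=1e-8)

    def test_matches_statsmodels_poisson_glm(self, agg):
        import statsmodels.api as sm
        n, L = agg
        fit = fit_global_model(n, L, SubstitutionModelSpec(1), "free",
                               compute_ci=False)
        # independent route: Poisson GLM with class + impact indicators
        mask = L > 0
        rows = np.argwhere(mask)
        y = n[mask]
        offset = np.log(L[mask])
        classes = sorted(set(rows[:, 0]))
        cmap = {c: k for k, c in enumerate(classes)}
        X = np.zeros((len(y), len(classes) + 3))
        for i, (ci, imp) in enumerate(rows):
            X[i, cmap[ci]] = 1.0
            if imp > 0:
                X[i, len(classes) + imp - 1] = 1.0
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        om_glm = np.exp(res.params[len(classes):])
        assert om_glm[0] == pytest.approx(fit.omega["m"], rel=1e-4)
        assert om_glm[1] == pytest.approx(fit.omega["n"], rel=1e-4)
        assert om_glm[2] == pytest.approx(fit.omega["e"], rel=1e-4)

    def test_neutral_simulation_ci_covers_one(self, agg):
        n, L = agg
        fit = fit_global_model(n, L, SubstitutionModelSpec(1), "free")
        lo, hi = fit.omega_ci["m"]
        assert lo < 1 < hi
        assert lo < fit.omega["m"] < hi

    def test_refuses_unidentifiable_or_invalid(self, small_comps):
        L = sum(c.L for c in small_comps).astype(float)
        with pytest.raises(FitError, match="synonymous"):
            fit_global_model(np.zeros_like(L), L)
        n = np.zeros_like(L)
        n[np.argwhere(L == 0)[0][0], np.argwhere(L == 0)[0][1]] = 3
        with pytest.raises(FitError, match="zero sites"):
            fit_global_model(n, L)

    def test_profile_ci_coverage_calibration(self, small_genome, index1,
                                             small_comps):
        """95% profile CIs for omega_m cover 1 in ~95% of neutral replicates."""
        table = build_site_table(small_genome.genes, index1)
        L = sum(c.L for c in small_comps)
        prof = sd.spectrum_preset("pancancer_like")
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            n = draw_class_counts(table, prof, 10000, seed=1000 + rep)
            fit = fit_global_model(n, L, SubstitutionModelSpec(1), "free")
            lo, hi = fit.omega_ci["m"]
            covered += lo <= 1 <= hi
        assert 0.92 <= covered / n_rep <= 0.98


class TestGenesetDnds:
    def test_all_genes_equals_global(self, neutral_counts, small_comps, agg):
        n, L = agg
        full = fit_global_model(n, L, compute_ci=False)
        sub = geneset_dnds(neutral_counts, small_comps,
                           [c.gene_id for c in neutral_counts], compute_ci=False)
        assert sub.omega["m"] == pytest.approx(full.omega["m"])
        assert sub.loglik == pytest.approx(full.loglik)

    def test_empty_intersection_raises(self, neutral_counts, small_comps):
        with pytest.raises(FitError, match="absent"):
            geneset_dnds(neutral_counts, small_comps, ["nope"])

    def test_planted_negative_selection_recovered(self, small_genome, index1,
                                                  small_comps):
        prof = sd.spectrum_preset("pancancer_like")
        design = [PatientDesign(f"p{i}", prof, 150, omega=0.5) for i in range(60)]
        records, truth = sd.simulate_cohort(design, small_genome.genes, seed=42)
        counts, _ = sd.count_by_gene(records, small_genome.genes, index1,
                                     collapse_mnv=False)
        fit = geneset_dnds(counts, small_comps, omega_structure="single")
        lo, hi = fit.omega_ci["all"]
        assert lo <= 0.5 <= hi
        assert fit.omega["all"] == pytest.approx(0.5, abs=0.06)


class TestModelComparison:
    def test_context_data_prefers_context_model(self, small_genome, index1,
                                                neutral_counts, small_comps, agg):
        n1, L1 = agg
        fit192 = fit_global_model(n1, L1, SubstitutionModelSpec(1), compute_ci=False)
        fit1 = fit_global_model(n1, L1, SubstitutionModelSpec(1, single_rate=True),
                                compute_ci=False)
        ranked = compare_models_aic([fit1, fit192])
        assert ranked[0][0] is fit192
        assert ranked[0][1] == 0.0

    def test_identical_fits_tie(self, agg):
        n, L = agg
        f1 = fit_global_model(n, L, compute_ci=False)
        f2 = fit_global_model(n, L, compute_ci=False)
        ranked = compare_models_aic([f1, f2])
        assert ranked[0][1] == ranked[1][1] == 0.0

    def test_mismatched_data_rejected(self, agg):
        n, L = agg
        f1 = fit_global_model(n, L, compute_ci=False)
        f2 = fit_global_model(n * 2, L, compute_ci=False)
        with pytest.raises(FitError, match="fingerprint"):
            compare_models_aic([f1, f2])


class TestExcessFormula:
    @pytest.mark.parametrize("omega,expected", [
        (1.95, 0.487), (1.72, 0.419), (2.21, 0.548), (10.0, 0.9), (1.0, 0.0)])
    def test_driver_fraction(self, omega, expected):
        assert driver_fraction(omega) == pytest.approx(expected, abs=5e-4)

    def test_lost_fraction(self):
        assert lost_fraction(0.8) == pytest.approx(0.2)
        assert lost_fraction(1.2) == 0.0

    def test_monotone_and_inverse(self):
        omegas = np.linspace(1.01, 50, 40)
        f = np.array([driver_fraction(o) for o in omegas])
        assert (np.diff(f) > 0).all()
        # inverse map omega = 1/(1-f) returns the input
        back = 1 / (1 - f)
        assert np.allclose(back, omegas, rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            driver_fraction(0.0)
        with pytest.raises(ValueError):
            lost_fraction(-1.0)


class TestExcessBackground:
    def test_planted_synonymous_excess_flagged(self, small_genome, index1,
                                               small_comps):
        prof = sd.spectrum_preset("pancancer_like")
        records = sd.simulate_neutral(small_genome.genes, prof, 6000, seed=7,
                                      n_samples=30)
        counts, _ = sd.count_by_gene(records, small_genome.genes, index1,
                                     collapse_mnv=False)
        n, L = aggregate_counts(counts, small_comps)
        gfit = fit_global_model(n, L, compute_ci=False)
        # plant a ~7x synonymous excess in one gene
        target = counts[3]
        syn_cells = np.nonzero(small_comps[3].L[:, 0])[0]
        base = max(1, target.n_s)
        extra = 6 * base
        target.n[syn_cells[0], 0] += extra
        res = excess_background_test(counts, small_comps, gfit,
                                     target_set=[target.gene_id],
                                     channel="synonymous", n_boot=200, seed=1)
        assert res.table.loc[target.gene_id, "q"] < 0.01
        assert res.table.loc[target.gene_id, "obs_exp_ratio"] > 3

    def test_counts_at_expectation_not_flagged(self, small_genome, index1,
                                               small_comps, agg):
        n, L = agg
        gfit = fit_global_model(n, L, compute_ci=False)
        # construct counts sitting exactly at their neutral expectation
        at_exp = []
        for c in small_comps:
            gc = sd.GeneCounts(c.gene_id, np.zeros_like(c.L))
            e_syn = float((gfit.u[:, None] * c.L)[:, 0].sum())
            syn_cells = np.nonzero(c.L[:, 0])[0]
            gc.n[syn_cells[0], 0] = int(round(e_syn))
            at_exp.append(gc)
        targets = [c.gene_id for c in at_exp[:10]]
        res = excess_background_test(at_exp, small_comps, gfit,
                                     target_set=targets, channel="synonymous",
                                     n_boot=100, seed=2)
        assert (res.table["q"] > 0.1).all()
        assert res.set_ratio == pytest.approx(1.0, abs=0.1)

    def test_small_passenger_set_rejected(self, neutral_counts, small_comps, agg):
        n, L = agg
        gfit = fit_global_model(n, L, compute_ci=False)
        with pytest.raises(FitError, match="passenger"):
            excess_background_test(neutral_counts, small_comps, gfit,
                                   target_set=[c.gene_id for c in neutral_counts[:55]],
                                   channel="synonymous")
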