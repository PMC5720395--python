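import numpy as np
import pytest
from scipy import stats

import somatic_dnds as sd
from somatic_dnds.rate_models import aggregate_counts, fit_global_model
from somatic_dnds.simulate import (PatientDesign, SimulationError,
                                   build_site_table, draw_class_counts,
                                   make_snp_blacklist, overfilter_sites,
                                   randomize_local, site_weights,
                                   spectrum_preset)


@pytest.fixture(scope="module")
def table(small_genome, index1):
    return build_site_table(small_genome.genes, index1)


class TestSpectra:
    def test_presets_have_expected_shape(self):
        for name in ("flat", "pancancer_like", "uv_like", "tobacco_like"):
            prof = spectrum_preset(name)
            assert prof.rates.shape == (192,) if name != "flat" else True
            assert (prof.rates >= 0).all() and prof.rates.sum() > 0

    def test_tsv_roundtrip(self, tmp_path):
        prof = spectrum_preset("pancancer_like")
        path = tmp_path / "spec.tsv"
        prof.to_tsv(path)
        back = sd.SpectrumProfile.from_tsv(path)
        assert np.allclose(back.rates, prof.rates)


class TestSimulateNeutral:
    def test_deterministic_per_seed(self, small_genome):
        prof = spectrum_preset("pancancer_like")
        r1 = sd.simulate_neutral(small_genome.genes, prof, 500, seed=9)
        r2 = sd.simulate_neutral(small_genome.genes, prof, 500, seed=9)
        r3 = sd.simulate_neutral(small_genome.genes, prof, 500, seed=10)
        assert r1 == r2
        assert r1 != r3

    def test_class_frequencies_match_spectrum(self, table):
        # chi-square goodness of fit of drawn class counts vs expected
        prof = spectrum_preset("pancancer_like")
        n = draw_class_counts(table, prof, 30000, seed=13)
        w = site_weights(table, prof)
        expected = np.zeros(192)
        np.add.at(expected, table.class_id, w)
        expected = expected / expected.sum() * 30000
        obs = n.sum(axis=1)
        keep = expected > 5
        chi2 = ((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001

    def test_per_sample_positions_unique(self, small_genome):
        prof = spectrum_preset("flat")
        recs = sd.simulate_neutral(small_genome.genes, prof, 2000, seed=3,
                                   n_samples=4)
        for s in {r.sample_id for r in recs}:
            pos = [(r.chromosome, r.position) for r in recs if r.sample_id == s]
            assert len(pos) == len(set(pos))


class TestSimulateCohort:
    def test_all_neutral_truth_one(self, small_genome, index1, small_comps):
        prof = spectrum_preset("pancancer_like")
        design = [PatientDesign(f"p{i}", prof, 100, 1.0) for i in range(30)]
        records, f = sd.simulate_cohort(design, small_genome.genes, seed=4)
        assert f == 1.0
        counts, _ = sd.count_by_gene(records, small_genome.genes, index1,
                                     collapse_mnv=False)
        n, L = aggregate_counts(counts, small_comps)
        fit = fit_global_model(n, L, omega_structure="single")
        lo, hi = fit.omega_ci["all"]
        assert lo <= 1 <= hi

    def test_weighted_mean_truth_formula(self, small_genome):
        prof = spectrum_preset("flat")
        design = [PatientDesign("a", prof, 100, 0.1),
                  PatientDesign("b", prof, 500, 1.0)]
        _, f = sd.simulate_cohort(design, small_genome.genes, seed=5)
        assert f == pytest.approx((100 * 0.1 + 500 * 1.0) / 600)

    def test_positive_omega_rejected(self):
        prof = spectrum_preset("flat")
        with pytest.raises(SimulationError, match="omega > 1"):
            PatientDesign("a", prof, 10, 1.5)

    def test_yaml_design_roundtrip(self, tmp_path):
        from somatic_dnds.simulate import load_cohort_design
        path = tmp_path / "design.yaml"
        path.write_text(
            "- {sample_id: a, spectrum: pancancer_like, burden: 100, "
            "omega: 0.5, replicates: 3}\n"
            "- {sample_id: solo, spectrum: flat, burden: 20}\n")
        design = load_cohort_design(path)
        assert len(design) == 4
        assert design[0].sample_id == "a000" and design[0].omega == 0.5
        assert design[3].sample_id == "solo" and design[3].omega == 1.0


class TestSpikeGermline:
    def test_zero_fraction_identity(self, neutral_records, small_genome):
        out = sd.spike_germline(neutral_records, small_genome.genes, 0.0, seed=1)
        assert out == list(neutral_records)

    def test_contamination_biases_dnds_down(self, small_genome, index1,
                                            small_comps, neutral_records, table):
        prof = spectrum_preset("pancancer_like")
        spiked = sd.spike_germline(neutral_records, small_genome.genes, 0.10,
                                   seed=2, spectrum=prof, table=table)
        assert len(spiked) == pytest.approx(len(neutral_records) / 0.9, rel=0.01)
        counts, _ = sd.count_by_gene(spiked, small_genome.genes, index1,
                                     collapse_mnv=False)
        n, L = aggregate_counts(counts, small_comps)
        fit = fit_global_model(n, L, omega_structure="single")
        assert fit.omega_ci["all"][1] < 1.0  # clearly below neutrality

    def test_bias_monotone_in_fraction(self, small_genome, index1, small_comps,
                                       neutral_records, table):
        prof = spectrum_preset("pancancer_like")
        omegas = []
        for frac in (0.05, 0.15):
            spiked = sd.spike_germline(neutral_records, small_genome.genes, frac,
                                       seed=3, spectrum=prof, table=table)
            counts, _ = sd.count_by_gene(spiked, small_genome.genes, index1,
                                         collapse_mnv=False)
            n, L = aggregate_counts(counts, small_comps)
            omegas.append(fit_global_model(n, L, omega_structure="single",
                                           compute_ci=False).omega["all"])
        assert omegas[1] < omegas[0] < 1.0


class TestOverfilterSites:
    def test_empty_blacklist_identity(self, neutral_records):
        kept, report = overfilter_sites(neutral_records, set())
        assert kept == list(neutral_records) and report["n_removed"] == 0

    def test_syn_enriched_filter_biases_dnds_up(self, small_genome, index1,
                                                small_comps, neutral_records):
        blk = make_snp_blacklist(small_genome.genes, n_sites=6000, seed=4,
                                 syn_enrichment=12.0)
        kept, report = overfilter_sites(neutral_records, blk)
        assert report["n_removed"] > 0
        counts, _ = sd.count_by_gene(kept, small_genome.genes, index1,
                                     collapse_mnv=False)
        n, L = aggregate_counts(counts, small_comps)
        fit = fit_global_model(n, L, omega_structure="single")
        assert fit.omega_ci["all"][0] > 1.0  # clearly above neutrality

    def test_balanced_blacklist_unbiased(self, small_genome, index1, small_comps,
                                         neutral_records):
        blk = make_snp_blacklist(small_genome.genes, n_sites=6000, seed=5,
                                 syn_enrichment=1.0)
        kept, _ = overfilter_sites(neutral_records, blk)
        counts, _ = sd.count_by_gene(kept, small_genome.genes, index1,
                                     collapse_mnv=False)
        n, L = aggregate_counts(counts, small_comps)
        fit = fit_global_model(n, L, omega_structure="single")
        lo, hi = fit.omega_ci["all"]
        assert lo <= 1 <= hi


class TestRandomizeLocal:
    def test_window_zero_identity(self, neutral_records, small_genome):
        out, rep = randomize_local(neutral_records, small_genome.reference,
                                   window_bp=0, seed=0)
        assert out == list(neutral_records)

    def test_context_preserved(self, neutral_records, small_genome):
        ref = small_genome.reference
        out, rep = randomize_local(neutral_records[:500], ref, window_bp=2000,
                                   context_width=1, seed=1)
        moved = 0
        for before, after in zip(neutral_records[:500], out):
            b = ref[before.chromosome][before.position - 2:before.position + 1]
            a = ref[after.chromosome][after.position - 2:after.position + 1]
            assert a == b
            assert after.ref == before.ref and after.alt == before.alt
            moved += after.position != before.position
        assert moved > 250  # most mutations find an eligible target

    def test_burden_and_context_counts_preserved(self, neutral_records,
                                                 small_genome):
        from collections import Counter
        out, _ = randomize_local(neutral_records, small_genome.reference,
                                 window_bp=1000, seed=2)
        assert Counter(r.sample_id for r in out) == \
            Counter(r.sample_id for r in neutral_records)
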