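import pytest

import somatic_dnds as sd
from somatic_dnds.genome_model import composition_matrix


@pytest.fixture(scope="session")
def index1():
    return sd.SubstitutionClassIndex(1)


@pytest.fixture(scope="session")
def toy_reference():
    # chr1 carries a minimal single-exon gene ATG GCA TGG TAA at positions 11-22
    seq = "ACGTACGTCC" + "ATGGCATGGTAA" + "GGCCACGTAC"
    return {"chr1": seq}


@pytest.fixture(scope="session")
def toy_gene(toy_reference):
    import pandas as pd
    table = pd.DataFrame([{"gene_id": "toy", "chromosome": "chr1", "strand": "+",
                           "cds_starts": "11", "cds_ends": "22"}])
    genes, skipped = sd.build_gene_model(toy_reference, table)
    assert not skipped
    return genes[0]


@pytest.fixture(scope="session")
def small_genome():
    return sd.generate_genome(60, seed=5, intron_probability=0.4)


@pytest.fixture(scope="session")
def small_comps(small_genome, index1):
    return [composition_matrix(g, index1) for g in small_genome.genes]


@pytest.fixture(scope="session")
def neutral_records(small_genome):
    prof = sd.spectrum_preset("pancancer_like")
    return sd.simulate_neutral(small_genome.genes, prof, 8000, seed=11, n_samples=20)


@pytest.fixture(scope="session")
def neutral_counts(neutral_records, small_genome, index1):
    counts, _ = sd.count_by_gene(neutral_records, small_genome.genes, index1,
                                 collapse_mnv=False)
    return counts
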