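"""Self-contained synthetic fixtures: toy genomes, covariates and cohorts with
planted selection, each carrying a machine-readable truth sheet.

Fixtures are regenerable byte-identically from (seed, parameters).  Planted
positive or negative selection is multiplicative on site rates — equivalent to
the omega parameterization of the Poisson model — so analytic expected counts
per gene follow directly from (t, r_i, L, omega) and every downstream estimate
can be checked against its generating truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import MutationRecord, write_catalog
from .genome_model import BASES, SubstitutionClassIndex, build_gene_model
from .simulate import (SimulationError, SpectrumProfile, build_site_table,
                       site_weights, _draw_unique)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GenomeFixture:
    reference: dict                  # chromosome -> sequence
    gene_table: pd.DataFrame
    genes: list
    seed: int
    params: dict = field(default_factory=dict)

    def fasta_text(self) -> str:
        parts = []
        for chrom, seq in self.reference.items():
            parts.append(f">{chrom}")
            parts.extend(seq[i:i + 80] for i in range(0, len(seq), 80))
        return "\n".join(parts) + "\n"

    def write(self, directory) -> None:
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "genome.fa").write_text(self.fasta_text())
        self.gene_table.to_csv(d / "genes.tsv", sep="\t", index=False)
        (d / "manifest.json").write_text(json.dumps(
            {"seed": self.seed, "params": self.params, "version": 1}, indent=2))


def _random_codons(rng, n: int, gc_bias: float) -> str:
    """n non-stop codons with the requested GC content bias."""
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    out = []
    while len(out) < n:
        draw = rng.choice(4, size=3, p=p)
        codon = "".join(BASES[i] for i in draw)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _random_seq(rng, n: int, gc_bias: float = 0.5) -> str:
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def generate_genome(n_genes: int, seed: int, mean_cds_length: int = 450,
                    sigma_log: float = 0.4, gc_bias: float = 0.45,
                    intron_probability: float = 0.3, intron_length: int = 30,
                    spacer: int = 20, chromosome: str = "chr1") -> GenomeFixture:
    """Generate a non-overlapping toy genome of validated coding genes.

    CDS lengths are lognormal around ``mean_cds_length`` (rounded to whole
    codons, minimum 3); a fraction of genes receive one GT..AG intron so the
    essential-splice machinery is exercised.  Deterministic per seed.
    """
    if n_genes < 1:
        raise SimulationError("n_genes must be >= 1")
    if mean_cds_length < 9:
        raise SimulationError("mean_cds_length must be >= 9")
    rng = np.random.default_rng(seed)
    chrom_parts = [_random_seq(rng, spacer + 5, gc_bias)]
    offset = len(chrom_parts[0])
    rows = []
    for g in range(n_genes):
        n_codons = max(3, int(round(float(
            rng.lognormal(np.log(mean_cds_length / 3), sigma_log)))))
        body = "ATG" + _random_codons(rng, n_codons - 2, gc_bias) \
            + STOP_CODONS[rng.integers(0, 3)]
        strand = "+" if rng.random() < 0.5 else "-"
        has_intron = rng.random() < intron_probability and n_codons >= 6
        if has_intron:
            cut = 3 * int(rng.integers(2, n_codons - 2))
            intron = "GT" + _random_seq(rng, intron_length - 4, gc_bias) + "AG"
            fragment = body[:cut] + intron + body[cut:]
            exon_spans = [(0, cut - 1), (cut + intron_length, len(fragment) - 1)]
        else:
            fragment = body
            exon_spans = [(0, len(fragment) - 1)]
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            fragment = fragment.translate(comp)[::-1]
            L = len(fragment)
            exon_spans = [(L - 1 - b, L - 1 - a) for (a, b) in exon_spans]
        start = offset + 1  # 1-based genomic start of the fragment
        intervals = [(start + a, start + b) for (a, b) in exon_spans]
        if strand == "-":
            intervals = sorted(intervals, key=lambda iv: -iv[0])
        rows.append({
            "gene_id": f"g{g:04d}", "chromosome": chromosome, "strand": strand,
            "cds_starts": ",".join(str(a) for a, _ in intervals),
            "cds_ends": ",".join(str(b) for _, b in intervals),
        })
        chrom_parts.append(fragment)
        chrom_parts.append(_random_seq(rng, spacer, gc_bias))
        offset += len(fragment) + spacer
    reference = {chromosome: "".join(chrom_parts)}
    gene_table = pd.DataFrame(rows)
    genes, skipped = build_gene_model(reference, gene_table)
    if skipped:
        raise SimulationError(f"generated genome failed validation: {skipped[:3]}")
    return GenomeFixture(reference=reference, gene_table=gene_table, genes=genes,
                         seed=seed,
                         params={"n_genes": n_genes, "mean_cds_length": mean_cds_length,
                                 "gc_bias": gc_bias,
                                 "intron_probability": intron_probability})


def generate_covariates(genes, seed: int, n_covariates: int = 20,
                        latent_rate_correlation: float = 0.5,
                        gamma_shape: float = 6.03):
    """Per-gene latent rate multipliers and a covariate matrix informative
    about them.

    Latent rates are Gamma(shape, scale=1/shape) — mean 1, the overdispersion
    scale typical of exome cohorts.  The first covariate column correlates
    with the standardized log-rate at ``latent_rate_correlation``; remaining
    columns are independent noise.  Returns (DataFrame, latent_rates).
    """
    if not 0 <= latent_rate_correlation <= 1:
        raise SimulationError("latent_rate_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    J = len(genes)
    rates = rng.gamma(shape=gamma_shape, scale=1.0 / gamma_shape, size=J)
    z = np.log(rates)
    z = (z - z.mean()) / max(z.std(), 1e-12)
    cols = {}
    rho_c = latent_rate_correlation
    cols["cv1"] = rho_c * z + np.sqrt(max(0.0, 1 - rho_c ** 2)) * rng.normal(size=J)
    for k in range(2, n_covariates + 1):
        cols[f"cv{k}"] = rng.normal(size=J)
    df = pd.DataFrame(cols, index=[g.gene_id for g in genes])
    return df, rates


@dataclass
class GeneTruth:
    omega_m: float = 1.0
    omega_t: float = 1.0
    indel_driver: bool = False
    rate_multiplier: float = 1.0


@dataclass
class TruthSheet:
    """Generating truth of a synthetic cohort, serialized with every fixture."""
    genes: dict                      # gene_id -> GeneTruth
    spectrum: str = "flat"
    n_samples: int = 0
    mean_burden: float = 0.0
    seed: int = 0
    indel_background_rate: float = 0.0   # per coding base per sample
    indel_driver_rate: float = 0.0       # per gene per sample

    def to_json(self, path=None) -> str:
        payload = {
            "version": 1,
            "spectrum": self.spectrum, "n_samples": self.n_samples,
            "mean_burden": self.mean_burden, "seed": self.seed,
            "indel_background_rate": self.indel_background_rate,
            "indel_driver_rate": self.indel_driver_rate,
            "genes": {g: asdict(t) for g, t in self.genes.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TruthSheet":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        genes = {g: GeneTruth(**t) for g, t in payload["genes"].items()}
        return cls(genes=genes, spectrum=payload["spectrum"],
                   n_samples=payload["n_samples"], mean_burden=payload["mean_burden"],
                   seed=payload["seed"],
                   indel_background_rate=payload.get("indel_background_rate", 0.0),
                   indel_driver_rate=payload.get("indel_driver_rate", 0.0))


def generate_cohort(genome: GenomeFixture, truth: TruthSheet, n_samples: int,
                    spectrum: SpectrumProfile, seed: int,
                    mean_burden: float = 30.0,
                    latent_rates: np.ndarray | None = None):
    """Simulate a cohort with planted selection and per-gene rate variation.

    Site weights are spectrum rate x gene rate multiplier x omega (per impact
    class): positive selection (omega > 1) up-weights non-synonymous sites,
    negative selection (omega < 1) down-weights them, exactly as in the
    Poisson model.  Per-sample burdens are Poisson(mean_burden).  Indel-driver
    genes receive extra indels at ``truth.indel_driver_rate`` per sample on
    top of a uniform background.  Returns (records, completed TruthSheet).
    """
    unknown = set(truth.genes) - {g.gene_id for g in genome.genes}
    if unknown:
        raise SimulationError(f"truth references unknown genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    index = SubstitutionClassIndex(spectrum.context_width)
    table = build_site_table(genome.genes, index)
    J = len(genome.genes)
    ids = [g.gene_id for g in genome.genes]
    t_by_gene = {g: truth.genes.get(g, GeneTruth()) for g in ids}
    gene_rate = np.array([t_by_gene[g].rate_multiplier for g in ids])
    if latent_rates is not None:
        gene_rate = gene_rate * np.asarray(latent_rates, dtype=float)
    om_m = np.array([t_by_gene[g].omega_m for g in ids])
    om_t = np.array([t_by_gene[g].omega_t for g in ids])
    w = site_weights(table, spectrum, gene_rate=gene_rate, omega_m=om_m, omega_t=om_t)
    w_neutral = site_weights(table, spectrum, gene_rate=gene_rate)
    cum = np.cumsum(w)
    # Poisson semantics: planted selection rescales the per-sample intensity,
    # so neutral genes keep their absolute rate and omega>1 genes gain the
    # excess (mean_burden refers to the neutral, omega=1 genome)
    burden_scale = w.sum() / w_neutral.sum()

    records: list[MutationRecord] = []
    for s in range(n_samples):
        sid = f"S{s:04d}"
        b = int(rng.poisson(mean_burden * burden_scale))
        recs, _ = _draw_unique(rng, cum, table, b, sid)
        records.extend(recs)
        # indels: uniform background over coding bases + planted drivers
        for gi, gene in enumerate(genome.genes):
            lam = truth.indel_background_rate * gene.cds_length
            if t_by_gene[ids[gi]].indel_driver:
                lam += truth.indel_driver_rate
            for _ in range(int(rng.poisson(lam))):
                k = int(rng.integers(0, gene.cds_length))
                pos = int(gene.genomic_positions[k])
                ref = genome.reference[gene.chromosome][pos - 1:pos + 1]
                records.append(MutationRecord(sid, gene.chromosome, pos, ref, ref[0]))

    completed = TruthSheet(genes={g: t_by_gene[g] for g in ids},
                           spectrum=spectrum.name, n_samples=n_samples,
                           mean_burden=mean_burden, seed=seed,
                           indel_background_rate=truth.indel_background_rate,
                           indel_driver_rate=truth.indel_driver_rate)
    return records, completed


def write_fixture_bundle(directory, genome: GenomeFixture, records,
                         truth: TruthSheet, covariates: pd.DataFrame | None = None):
    """Write a complete fixture: FASTA, gene table, catalog, truth, manifest."""
    import pathlib
    d = pathlib.Path(directory)
    genome.write(d)
    write_catalog(records, d / "catalog.tsv")
    truth.to_json(d / "truth.json")
    if covariates is not None:
        covariates.to_csv(d / "covariates.tsv", sep="\t")
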